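"""Independent slow oracles used to validate the fast implementations.

Each function here evaluates a definition directly (double loops,
enumeration, generic optimizers) and deliberately shares no code with the
package paths it checks.
"""

import numpy as np
from scipy.special import gammaln


def dct_bruteforce(x: np.ndarray) -> np.ndarray:
    """O(N^2) evaluation of the orthonormal DCT-II definition."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    X = np.empty(N)
    for k in range(N):
        ck = 1.0 / np.sqrt(2.0) if k == 0 else 1.0
        s = 0.0
        for n in range(N):
            s += x[n] * np.cos(np.pi / N * (n + 0.5) * k)
        X[k] = np.sqrt(2.0 / N) * ck * s
    return X


def cohens_d_textbook(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sa2 = np.sum((a - a.mean()) ** 2) / (na - 1)
    sb2 = np.sum((b - b.mean()) ** 2) / (nb - 1)
    sp = np.sqrt(((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2))
    return (a.mean() - b.mean()) / sp


def pooled_t_textbook(a, b) -> tuple[float, float]:
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def elasticnet_objective(X, y, b0, beta, lam, alpha) -> float:
    """Penalized negative Bernoulli log-likelihood, direct evaluation."""
    eta = b0 + X @ beta
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    pen = lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * (beta**2).sum())
    return float(nll + pen)


def elasticnet_projected_gradient(
    X, y, lam, alpha, max_iter=20000, tol=1e-12
) -> tuple[float, np.ndarray]:
    """Minimize the elastic-net logistic objective by projected gradient.

    Splits beta = beta_plus - beta_minus with both parts nonnegative so
    the l1 term becomes smooth-linear, then does projected gradient with
    backtracking line search.  Slow but entirely independent of the
    coordinate-descent path.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape

    def split_obj(theta):
        b0, bp, bn = theta[0], theta[1 : 1 + d], theta[1 + d :]
        beta = bp - bn
        eta = b0 + X @ beta
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        pen = lam * (alpha * (bp.sum() + bn.sum()) + 0.5 * (1 - alpha) * (beta**2).sum())
        return nll + pen

    def split_grad(theta):
        b0, bp, bn = theta[0], theta[1 : 1 + d], theta[1 + d :]
        beta = bp - bn
        eta = b0 + X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        g_eta = (p - y) / n
        g_beta = X.T @ g_eta
        g = np.empty(1 + 2 * d)
        g[0] = g_eta.sum()
        g[1 : 1 + d] = g_beta + lam * alpha + lam * (1 - alpha) * beta
        g[1 + d :] = -g_beta + lam * alpha - lam * (1 - alpha) * beta
        return g

    theta = np.zeros(1 + 2 * d)
    f = split_obj(theta)
    step = 1.0
    for _ in range(max_iter):
        g = split_grad(theta)
        while True:
            cand = theta - step * g
            cand[1:] = np.maximum(cand[1:], 0.0)
            fc = split_obj(cand)
            if fc <= f + np.dot(g, cand - theta) + np.sum((cand - theta) ** 2) / (2 * step):
                break
            step *= 0.5
            if step < 1e-16:
                break
        if np.max(np.abs(cand - theta)) < tol:
            theta = cand
            break
        theta, f = cand, fc
        step *= 1.2
    b0 = theta[0]
    beta = theta[1 : 1 + d] - theta[1 + d :]
    return float(b0), beta


def fisher_exact_enumeration(a, b, c, d) -> float:
    """Two-sided Fisher p by direct enumeration of all margin-compatible
    tables, computing each probability from log-factorials."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def logp(k):
        rows = [k, r1 - k, c1 - k, n - r1 - c1 + k]
        return (
            gammaln(r1 + 1)
            + gammaln(n - r1 + 1)
            + gammaln(c1 + 1)
            + gammaln(n - c1 + 1)
            - gammaln(n + 1)
            - sum(gammaln(v + 1) for v in rows)
        )

    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    lps = np.array([logp(k) for k in range(kmin, kmax + 1)])
    ps = np.exp(lps)
    p_obs = ps[a - kmin]
    return float(min(1.0, ps[ps <= p_obs * (1 + 1e-7)].sum()))


def cca_grid_first_correlation(X, Y, n_angles=20000) -> float:
    """Max correlation over unit vectors (a, b) for 2-column X, Y by grid
    search over angles (oracle for 2x2 CCA)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    best = 0.0
    angles = np.linspace(0, np.pi, n_angles, endpoint=False)
    for ta in angles[:: int(np.sqrt(n_angles))]:
        a = np.array([np.cos(ta), np.sin(ta)])
        u = X @ a
        for tb in angles[:: int(np.sqrt(n_angles))]:
            b = np.array([np.cos(tb), np.sin(tb)])
            v = Y @ b
            r = abs(np.corrcoef(u, v)[0, 1])
            best = max(best, r)
    return best
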
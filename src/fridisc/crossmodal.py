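"""Association between the spectral and proteomic modalities.

Canonical correlation analysis finds projections a, b maximizing
``corr(Xa, Yb) = a' S_xy b / sqrt(a' S_xx a * b' S_yy b)``; significance
is assessed by permuting the rows of Y.  A small cross-modal
autoencoder (three dense tanh layers to a 2-node bottleneck, mirrored
decoder reconstructing the *opposite* modality) probes for shared
non-linear structure; its 2-D bottleneck embedding is scored for class
separation with a Fisher-discriminant AUROC.

Both tools are exploratory: the pipelines treat them as an optional
stage whose output is a report, not a model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .config import CrossmodalConfig
from .feature_filter import cohens_d

__all__ = [
    "CCAResult",
    "cca",
    "cca_permutation_test",
    "select_top_features",
    "AutoencoderResult",
    "train_crossmodal_autoencoder",
]


@dataclass
class CCAResult:
    """Canonical vectors, correlations, and (optionally) permutation p-values."""

    x_weights: np.ndarray  # p x k
    y_weights: np.ndarray  # q x k
    correlations: np.ndarray  # length k, non-increasing in [0, 1]
    ridge_eps: float = 0.0
    p_values: np.ndarray | None = None


def _standardize_cols(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column; drop before CCA")
    return (M - M.mean(axis=0)) / sd


def _inv_sqrt(S: np.ndarray, eps: float) -> tuple[np.ndarray, float]:
    """Symmetric inverse square root with ridge stabilization when needed."""
    vals, vecs = np.linalg.eigh(S)
    used = 0.0
    floor = eps * float(vals.max())
    if vals.min() < floor:
        used = floor
        vals = vals + floor
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T, used


def cca(
    X: np.ndarray,
    Y: np.ndarray,
    k: int | None = None,
    ridge_eps: float = 1e-8,
    standardize: bool = True,
) -> CCAResult:
    """Canonical correlations via SVD of S_xx^{-1/2} S_xy S_yy^{-1/2}."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if ridge_eps <= 0 and (p >= n or q >= n):
        raise ValueError(
            "as many features as samples: within-set covariance singular; "
            "pre-select features or set ridge_eps > 0"
        )
    if standardize:
        X = _standardize_cols(X)
        Y = _standardize_cols(Y)
    else:
        X = X - X.mean(axis=0)
        Y = Y - Y.mean(axis=0)
    k = k or min(p, q)
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    Wx, ex = _inv_sqrt(Sxx, ridge_eps)
    Wy, ey = _inv_sqrt(Syy, ridge_eps)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    corrs = np.clip(s[:k], 0.0, 1.0)
    a = Wx @ U[:, :k]
    b = Wy @ Vt.T[:, :k]
    return CCAResult(a, b, corrs, ridge_eps=max(ex, ey))


def cca_permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    k: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    ridge_eps: float = 1e-8,
) -> CCAResult:
    """Permutation p-values for each canonical correlation.

    Rows of Y are permuted ``n_perm`` times; per component,
    ``p = (1 + #{rho_perm >= rho_obs}) / (1 + n_perm)``, which is valid
    (conservative, never below ``1/(1+n_perm)``).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    obs = cca(X, Y, k, ridge_eps)
    rng = np.random.default_rng(seed)
    kk = len(obs.correlations)
    exceed = np.zeros(kk)
    n = np.asarray(Y).shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = cca(X, np.asarray(Y)[perm], k, ridge_eps)
        exceed += r.correlations >= obs.correlations
    obs.p_values = (1.0 + exceed) / (1.0 + n_perm)
    return obs


def select_top_features(
    M: np.ndarray, labels: np.ndarray, k: int = 8
) -> np.ndarray:
    """Column indices of the k most discriminatory features by |Cohen's d|."""
    M = np.asarray(M, dtype=float)
    y = np.asarray(labels, dtype=int)
    d = np.zeros(M.shape[1])
    for j in range(M.shape[1]):
        try:
            d[j] = abs(cohens_d(M[y == 1, j], M[y == 0, j]))
        except ValueError:
            d[j] = 0.0
    order = np.argsort(-d, kind="stable")
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# Cross-modal autoencoder: plain numpy MLP trained with Adam on the summed
# cross-reconstruction MSE (X -> bottleneck -> Y_hat and Y -> bottleneck -> X_hat).


@dataclass
class AutoencoderResult:
    layer_sizes: list[int]
    loss_trajectory: np.ndarray
    embedding: np.ndarray  # samples x 2 (mean of the two bottlenecks)
    final_loss: float
    class_separation_auroc: float | None = None


class _MLP:
    """Fully connected tanh network with a linear output layer."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.W = [
            rng.normal(0.0, np.sqrt(1.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [X]
        h = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last:
                h = np.tanh(h)
            acts.append(h)
        return h, acts

    def backward(self, acts: list[np.ndarray], grad_out: np.ndarray):
        """Gradients of the loss wrt weights, plus gradient wrt the input."""
        gW, gb = [], []
        g = grad_out
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            if i < last:
                g = g * (1.0 - acts[i + 1] ** 2)  # tanh'
            gW.insert(0, acts[i].T @ g)
            gb.insert(0, g.sum(axis=0))
            g = g @ self.W[i].T
        return gW, gb, g

    def params(self):
        return self.W + self.b

    def grads_like(self, gW, gb):
        return gW + gb


def train_crossmodal_autoencoder(
    X: np.ndarray,
    Y: np.ndarray,
    config: CrossmodalConfig | None = None,
    seed: int = 0,
) -> AutoencoderResult:
    """Train the paired encoders/decoders and return losses + embedding.

    Both inputs should be standardized.  The joint loss is
    ``mean((dec_y(enc_x(X)) - Y)^2) + mean((dec_x(enc_y(Y)) - X)^2)``;
    training uses full-batch Adam.  Raises if the loss diverges.
    """
    config = config or CrossmodalConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    rng = np.random.default_rng(seed)
    w1, w2, w3 = config.encoder_widths
    bz = config.bottleneck
    enc_x = _MLP([X.shape[1], w1, w2, w3, bz], rng)
    dec_y = _MLP([bz, w3, w2, w1, Y.shape[1]], rng)
    enc_y = _MLP([Y.shape[1], w1, w2, w3, bz], rng)
    dec_x = _MLP([bz, w3, w2, w1, X.shape[1]], rng)
    nets = [enc_x, dec_y, enc_y, dec_x]

    params = [p for net in nets for p in net.params()]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    losses = np.empty(max(config.epochs, 1))

    def _loss_and_grads():
        zx, ax_e = enc_x.forward(X)
        yhat, ax_d = dec_y.forward(zx)
        zy, ay_e = enc_y.forward(Y)
        xhat, ay_d = dec_x.forward(zy)
        ry = yhat - Y
        rx = xhat - X
        loss = float(np.mean(ry**2) + np.mean(rx**2))
        gy = 2.0 * ry / ry.size
        gx = 2.0 * rx / rx.size
        gW_dy, gb_dy, gz_x = dec_y.backward(ax_d, gy)
        gW_ex, gb_ex, _ = enc_x.backward(ax_e, gz_x)
        gW_dx, gb_dx, gz_y = dec_x.backward(ay_d, gx)
        gW_ey, gb_ey, _ = enc_y.backward(ay_e, gz_y)
        grads = (
            enc_x.grads_like(gW_ex, gb_ex)
            + dec_y.grads_like(gW_dy, gb_dy)
            + enc_y.grads_like(gW_ey, gb_ey)
            + dec_x.grads_like(gW_dx, gb_dx)
        )
        return loss, grads, zx, zy

    t = 0
    for epoch in range(config.epochs):
        loss, grads, _, _ = _loss_and_grads()
        if not np.isfinite(loss):
            raise RuntimeError(
                "autoencoder training diverged (loss is not finite); lower the learning rate"
            )
        losses[epoch] = loss
        t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g**2
            mhat = m[i] / (1 - beta1**t)
            vhat = v[i] / (1 - beta2**t)
            p -= config.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)

    final_loss, _, zx, zy = _loss_and_grads()
    if config.epochs == 0:
        losses = np.array([final_loss])
    embedding = (zx + zy) / 2.0
    return AutoencoderResult(
        layer_sizes=[X.shape[1], w1, w2, w3, bz],
        loss_trajectory=losses[: max(config.epochs, 1)].copy(),
        embedding=embedding,
        final_loss=float(final_loss),
    )


def embedding_class_auroc(embedding: np.ndarray, labels: np.ndarray) -> float:
    """AUROC of a Fisher discriminant score on the 2-D embedding (in-sample)."""
    from .bootstrap import auroc

    E = np.asarray(embedding, dtype=float)
    y = np.asarray(labels, dtype=int)
    mu0 = E[y == 0].mean(axis=0)
    mu1 = E[y == 1].mean(axis=0)
    R = np.vstack([E[y == 0] - mu0, E[y == 1] - mu1])
    Sw = R.T @ R + 1e-8 * np.eye(E.shape[1])
    w = linalg.solve(Sw, mu1 - mu0)
    return auroc(E @ w, y)
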
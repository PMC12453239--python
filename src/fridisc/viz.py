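"""Class-separation visualization: PCA compression, linear-discriminant
coordinates and multivariate-t confidence ellipses.

The selected features are compressed with a column-centered SVD (PCA) to
15 components, a Fisher linear discriminant supplies the first plotting
axis, and — since a two-class problem yields a single discriminant — the
second axis is the leading principal direction of the within-class
residuals orthogonal to the first.  Per-class 95-percentile boundaries
come from scaling the sample covariance by the F-based radial quantile
of a bivariate t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = [
    "svd_compress",
    "lda_coordinates",
    "confidence_ellipse",
    "Ellipse",
    "ProjectionResult",
    "project_classes",
    "make_discriminant_figure",
]


def svd_compress(X: np.ndarray, n_components: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """Column-centered truncated SVD scores and explained-variance fractions."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)={min(n - 1, p)}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var_share = s**2 / np.sum(s**2)
    scores = U[:, :n_components] * s[:n_components]
    return scores, var_share[:n_components]


def lda_coordinates(
    scores: np.ndarray, labels: np.ndarray, ridge_eps: float = 1e-8
) -> tuple[np.ndarray, dict]:
    """Two plotting coordinates from a two-class Fisher discriminant.

    Axis 1 maximizes the between/within variance ratio; axis 2 is the
    leading PC of the within-class residuals after projecting axis 1
    out.  Singular within-class scatter is ridge-regularized; the
    regularization used is reported in the metadata dict.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("need exactly two classes coded 0/1")
    if np.sum(y == 0) < 3 or np.sum(y == 1) < 3:
        raise ValueError("need at least 3 samples per class")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    R0 = X[y == 0] - mu0
    R1 = X[y == 1] - mu1
    Sw = R0.T @ R0 + R1.T @ R1
    eps_used = 0.0
    scale = np.trace(Sw) / Sw.shape[0]
    try:
        w = linalg.solve(Sw, mu1 - mu0, assume_a="pos")
    except linalg.LinAlgError:
        eps_used = ridge_eps * max(scale, 1.0)
        w = linalg.solve(Sw + eps_used * np.eye(Sw.shape[0]), mu1 - mu0, assume_a="pos")
    w = w / np.linalg.norm(w)
    coord1 = X @ w
    resid = np.vstack([R0, R1])
    resid = resid - np.outer(resid @ w, w)  # within-class residuals orthogonal to axis 1
    _, _, Vt = np.linalg.svd(resid, full_matrices=False)
    v2 = Vt[0]
    coord2 = X @ v2
    coords = np.column_stack([coord1, coord2])
    return coords, {"ridge_eps": eps_used, "axis1": w, "axis2": v2}


@dataclass
class Ellipse:
    """Confidence boundary: center, covariance shape, axes and angle."""

    center: np.ndarray
    shape: np.ndarray  # scaled covariance whose unit ball is the boundary
    level: float
    widths: np.ndarray  # semi-axis lengths
    angle_deg: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.asarray(points, dtype=float) - self.center
        m = np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.shape), d)
        return m <= 1.0


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """Level-percentile boundary of a 2-D class cloud.

    Uses the sample mean/covariance with the squared Mahalanobis radius
    set to the bivariate-t radial quantile ``2 F_level(2, n-1)``.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2 or P.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    center = P.mean(axis=0)
    cov = np.cov(P, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise ValueError("degenerate covariance: points are collinear")
    n = P.shape[0]
    r2 = 2.0 * stats.f.ppf(level, 2, n - 1) if level > 0 else 0.0
    shape = cov * r2
    eigvals, eigvecs = np.linalg.eigh(shape)
    widths = np.sqrt(np.maximum(eigvals[::-1], 0.0))
    major = eigvecs[:, -1]
    angle = float(np.degrees(np.arctan2(major[1], major[0])))
    return Ellipse(center, shape, level, widths, angle)


@dataclass
class ProjectionResult:
    scores: np.ndarray
    explained_variance: np.ndarray
    coordinates: np.ndarray
    ellipses: dict[str, Ellipse]
    meta: dict


def project_classes(
    X: np.ndarray, labels: np.ndarray, n_components: int = 15, level: float = 0.95
) -> ProjectionResult:
    """Full projection: PCA scores -> discriminant coordinates -> ellipses."""
    n_components = min(n_components, min(np.asarray(X).shape[0] - 1, np.asarray(X).shape[1]))
    scores, var_share = svd_compress(X, n_components)
    coords, meta = lda_coordinates(scores, labels)
    y = np.asarray(labels, dtype=int)
    ellipses = {
        "FRI": confidence_ellipse(coords[y == 1], level),
        "control": confidence_ellipse(coords[y == 0], level),
    }
    return ProjectionResult(scores, var_share, coords, ellipses, meta)


def make_discriminant_figure(result: ProjectionResult, labels: np.ndarray, path: str) -> None:
    """Write an SVG scatter of the discriminant plane with class ellipses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    y = np.asarray(labels, dtype=int)
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls, code, color in (("control", 0, "tab:blue"), ("FRI", 1, "tab:red")):
        pts = result.coordinates[y == code]
        ax.scatter(pts[:, 0], pts[:, 1], label=cls, color=color, s=35)
        e = result.ellipses[cls]
        ax.add_patch(
            MplEllipse(
                e.center, 2 * e.widths[0], 2 * e.widths[1], angle=e.angle_deg,
                fill=False, color=color, lw=1.5,
            )
        )
    ax.set_xlabel("discriminant coordinate 1")
    ax.set_ylabel("discriminant coordinate 2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
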
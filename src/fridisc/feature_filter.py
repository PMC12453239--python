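"""Univariate feature screening by pooled t-test and Cohen's d.

Features (DCT coefficients or protein log-ratios) are tested one at a
time against the class label; only features with |d| above the threshold
(default 0.5) are retained.  No multiplicity correction is applied at
this stage.  Note the filter is fit on the full dataset before
classification, so downstream resampling estimates inherit the optimism
of full-data feature selection; results records flag this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import FeatureMatrix

__all__ = [
    "cohens_d",
    "two_sample_ttest",
    "filter_features",
    "FeatureFilterResult",
    "DegenerateFeatureWarning",
]


class DegenerateFeatureWarning(UserWarning):
    """A feature had zero pooled variance and was dropped from screening."""


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    return float(np.sqrt(((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)))


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Standardized mean difference (mean A - mean B) / pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    sp = _pooled_sd(a, b)
    if sp == 0:
        raise ValueError("pooled SD is zero (degenerate feature)")
    return float((a.mean() - b.mean()) / sp)


def two_sample_ttest(group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled-variance (Student) by default."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if _pooled_sd(a, b) == 0:
        raise ValueError("pooled SD is zero (degenerate feature)")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class FeatureFilterResult:
    """Per-feature screening statistics aligned to ``feature_ids``."""

    feature_ids: list[str]
    t: np.ndarray
    p: np.ndarray
    d: np.ndarray
    retained: np.ndarray  # boolean mask, True iff |d| > threshold
    threshold: float

    def retained_ids(self) -> list[str]:
        return [f for f, m in zip(self.feature_ids, self.retained) if m]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "features": [
                {"id": f, "t": float(t), "p": float(p), "d": float(d), "retained": bool(m)}
                for f, t, p, d, m in zip(self.feature_ids, self.t, self.p, self.d, self.retained)
            ],
        }


def filter_features(
    matrix: FeatureMatrix,
    labels: np.ndarray | None = None,
    threshold: float = 0.5,
    equal_var: bool = True,
) -> tuple[FeatureMatrix, FeatureFilterResult]:
    """Retain features with |Cohen's d| > ``threshold`` between classes.

    Zero-pooled-variance features are dropped with a warning rather than
    an error.  Raises if no feature survives, carrying the per-feature
    report in the exception message.
    """
    y = matrix.labels() if labels is None else np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes must be present")
    X = matrix.values
    a, b = X[y == 1], X[y == 0]
    n_feat = X.shape[1]
    t = np.full(n_feat, np.nan)
    p = np.full(n_feat, np.nan)
    d = np.full(n_feat, np.nan)
    degenerate = np.zeros(n_feat, dtype=bool)
    for j in range(n_feat):
        sp = _pooled_sd(a[:, j], b[:, j])
        if sp == 0:
            degenerate[j] = True
            continue
        d[j] = (a[:, j].mean() - b[:, j].mean()) / sp
        t[j], p[j] = stats.ttest_ind(a[:, j], b[:, j], equal_var=equal_var)
    if degenerate.any():
        warnings.warn(
            f"dropped {int(degenerate.sum())} zero-variance feature(s) from screening",
            DegenerateFeatureWarning,
            stacklevel=2,
        )
    retained = np.zeros(n_feat, dtype=bool)
    retained[~degenerate] = np.abs(d[~degenerate]) > threshold
    result = FeatureFilterResult(list(matrix.feature_ids), t, p, d, retained, threshold)
    if not retained.any():
        top = np.argsort(-np.abs(np.nan_to_num(d)))[:10]
        report = ", ".join(f"{matrix.feature_ids[j]}: d={d[j]:.3f}" for j in top)
        raise ValueError(
            f"no feature exceeded |d| > {threshold}; strongest candidates: {report}"
        )
    restricted = matrix.restrict(retained, filter_threshold=threshold)
    return restricted, result
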
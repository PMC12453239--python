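"""Bootstrap performance estimation pooled by fixed-effect meta-analysis.

A *session* is B pair-level bootstrap resamples: matched FRI/control
pairs are drawn with replacement, the elastic net is trained on the
in-bag samples and evaluated on the out-of-bag samples (AUROC by the
Mann-Whitney estimator, sensitivity/specificity at a fixed probability
threshold).  S independently seeded sessions are pooled by an
inverse-variance fixed-effect meta-analysis, weighting each session by
the precision of its mean (per-session variance of the B resample
metrics divided by B).  Feature selection frequency across all resamples
gives the top-k feature ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import BootstrapConfig, FitConfig
from . import elasticnet

__all__ = [
    "auroc",
    "sens_spec",
    "SessionResult",
    "PooledMetrics",
    "FeatureRanking",
    "run_session",
    "run_sessions",
    "pool_sessions",
    "rank_features",
    "ResamplingError",
]

METRICS = ("auroc", "sensitivity", "specificity")


class ResamplingError(RuntimeError):
    """Could not draw a usable out-of-bag set within the redraw budget."""


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(score+ > score-) + 1/2 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute AUROC")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def sens_spec(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule score > threshold => positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores > threshold
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    sensitivity = float(np.sum(pred & pos) / np.sum(pos))
    specificity = float(np.sum(~pred & neg) / np.sum(neg))
    return sensitivity, specificity


@dataclass
class SessionResult:
    """One bootstrap session: per-resample OOB metrics and selections."""

    seed: int
    metrics: dict[str, np.ndarray]  # metric -> length-B array
    selected: list[list[str]]  # per-resample selected feature ids
    n_redraws: int = 0

    def mean(self, metric: str) -> float:
        return float(np.mean(self.metrics[metric]))

    def var(self, metric: str) -> float:
        """Variance of the session mean (SE^2): resample variance / B."""
        vals = self.metrics[metric]
        return float(np.var(vals, ddof=1) / len(vals))

    @property
    def n_resamples(self) -> int:
        return len(self.metrics[METRICS[0]])

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_redraws": self.n_redraws,
            "metrics": {k: v.tolist() for k, v in self.metrics.items()},
            "mean": {k: self.mean(k) for k in self.metrics},
            "var": {k: self.var(k) for k in self.metrics},
        }


@dataclass
class PooledMetrics:
    """Fixed-effect pooled estimates with CI95 per metric."""

    pooled: dict[str, float]
    ci_lo: dict[str, float]
    ci_hi: dict[str, float]
    sd_across_sessions: dict[str, float]
    n_sessions: int
    pooling: str = "ivw"

    def to_dict(self) -> dict:
        return {
            "n_sessions": self.n_sessions,
            "pooling": self.pooling,
            "metrics": {
                k: {
                    "pooled": self.pooled[k],
                    "ci95": [self.ci_lo[k], self.ci_hi[k]],
                    "sd_across_sessions": self.sd_across_sessions[k],
                }
                for k in self.pooled
            },
        }


@dataclass
class FeatureRanking:
    """Selection frequency of each feature across all resamples/sessions."""

    frequencies: dict[str, float]
    n_resamples_total: int

    def top(self, k: int = 40) -> list[str]:
        # sort by frequency descending, ties broken by feature id
        return [
            f
            for f, _ in sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        ]

    def to_dict(self) -> dict:
        return {
            "n_resamples_total": self.n_resamples_total,
            "frequencies": dict(
                sorted(self.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
            ),
        }


def _pair_bootstrap_split(
    pair_ids: np.ndarray, rng: np.random.Generator, max_redraws: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw pairs with replacement; return in-bag row indices (with
    multiplicity), out-of-bag row indices, and redraw count."""
    unique_pairs = np.unique(pair_ids)
    n_pairs = len(unique_pairs)
    for redraw in range(max_redraws + 1):
        drawn = rng.choice(unique_pairs, size=n_pairs, replace=True)
        oob_pairs = np.setdiff1d(unique_pairs, drawn)
        if len(oob_pairs) == 0:
            continue  # empty OOB: every pair drawn; redraw
        in_idx = np.concatenate([np.flatnonzero(pair_ids == p) for p in drawn])
        oob_idx = np.flatnonzero(np.isin(pair_ids, oob_pairs))
        return in_idx, oob_idx, redraw
    raise ResamplingError(f"no usable out-of-bag set after {max_redraws} redraws")


def run_session(
    features: np.ndarray,
    labels: np.ndarray,
    pair_ids: np.ndarray,
    fit_config: FitConfig | None = None,
    n_resamples: int = 100,
    seed: int = 0,
    prob_threshold: float = 0.5,
    max_redraws: int = 100,
    feature_ids: list[str] | None = None,
) -> SessionResult:
    """One bootstrap session of ``n_resamples`` pair-level resamples."""
    fit_config = fit_config or FitConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    pair_ids = np.asarray(pair_ids)
    if len(np.unique(pair_ids)) < 2:
        raise ValueError("need at least 2 matched pairs")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(X.shape[1])]
    rng = np.random.default_rng(seed)
    vals = {m: np.empty(n_resamples) for m in METRICS}
    selected: list[list[str]] = []
    total_redraws = 0
    for b in range(n_resamples):
        in_idx, oob_idx, redraws = _pair_bootstrap_split(pair_ids, rng, max_redraws)
        total_redraws += redraws
        model = elasticnet.fit(X[in_idx], y[in_idx], fit_config, feature_ids=feature_ids)
        p_oob = elasticnet.predict_proba(model, X[oob_idx])
        vals["auroc"][b] = auroc(p_oob, y[oob_idx])
        sens, spec = sens_spec(p_oob, y[oob_idx], prob_threshold)
        vals["sensitivity"][b] = sens
        vals["specificity"][b] = spec
        selected.append(elasticnet.selected_features(model))
    return SessionResult(seed=seed, metrics=vals, selected=selected, n_redraws=total_redraws)


def run_sessions(
    features: np.ndarray,
    labels: np.ndarray,
    pair_ids: np.ndarray,
    fit_config: FitConfig | None = None,
    bootstrap_config: BootstrapConfig | None = None,
    seed: int = 0,
    feature_ids: list[str] | None = None,
) -> list[SessionResult]:
    """S independently seeded sessions; session seeds derive from ``seed``."""
    bc = bootstrap_config or BootstrapConfig()
    session_seeds = np.random.SeedSequence(seed).generate_state(bc.n_sessions) % (2**31)
    return [
        run_session(
            features,
            labels,
            pair_ids,
            fit_config,
            n_resamples=bc.n_resamples,
            seed=int(s),
            prob_threshold=bc.prob_threshold,
            max_redraws=bc.max_redraws,
            feature_ids=feature_ids,
        )
        for s in session_seeds
    ]


def pool_sessions(sessions: list[SessionResult], pooling: str = "ivw") -> PooledMetrics:
    """Pool session means across sessions.

    ``ivw``: fixed-effect inverse-variance weighting, CI95 = pooled +-
    1.96/sqrt(sum 1/v); ``mean``: unweighted average with a normal CI
    from the across-session SD.  CIs are clipped to [0, 1].
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions to pool")
    pooled, lo, hi, sd = {}, {}, {}, {}
    for metric in METRICS:
        m = np.array([s.mean(metric) for s in sessions])
        v = np.array([s.var(metric) for s in sessions])
        if np.any(v <= 0):
            raise ValueError(
                f"session with zero variance for {metric!r}: fixed-effect weights undefined"
            )
        if pooling == "ivw":
            w = 1.0 / v
            est = float(np.sum(w * m) / np.sum(w))
            half = 1.96 / float(np.sqrt(np.sum(w)))
        elif pooling == "mean":
            est = float(np.mean(m))
            half = 1.96 * float(np.std(m, ddof=1) / np.sqrt(len(m)))
        else:
            raise ValueError("pooling must be 'ivw' or 'mean'")
        pooled[metric] = est
        lo[metric] = max(0.0, est - half)
        hi[metric] = min(1.0, est + half)
        sd[metric] = float(np.std(m, ddof=1))
    return PooledMetrics(pooled, lo, hi, sd, n_sessions=len(sessions), pooling=pooling)


def rank_features(sessions: list[SessionResult]) -> FeatureRanking:
    """Fraction of all resamples (across sessions) selecting each feature."""
    counts: dict[str, int] = {}
    total = 0
    for s in sessions:
        for sel in s.selected:
            total += 1
            for f in sel:
                counts[f] = counts.get(f, 0) + 1
    if total == 0:
        raise ValueError("sessions carry no selection lists")
    freqs = {f: c / total for f, c in counts.items()}
    return FeatureRanking(freqs, total)
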
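"""End-to-end classification pipelines for both modalities.

The FTIR branch runs the full spectral preprocessing chain before the
shared tail; the MS branch log-transforms the protein abundance ratios
and skips the spectral stages (no smoothing, no DCT, no frequency
filtering), then both feed the identical filter -> bootstrap sessions ->
fixed-effect pooling -> feature-ranking code path.
"""

from __future__ import annotations

import numpy as np

from .bootstrap import FeatureRanking, PooledMetrics, pool_sessions, rank_features, run_sessions
from .config import RunConfig
from .feature_filter import filter_features
from .io import FeatureMatrix, ProteinTable, SpectralDataset
from .preprocess import preprocess_pipeline

__all__ = ["classification_pipeline", "ftir_pipeline", "ms_pipeline", "protein_features"]


def classification_pipeline(
    features: FeatureMatrix, config: RunConfig, seed: int | None = None
) -> dict:
    """Shared tail: univariate d-filter, bootstrap sessions, pooling, ranking.

    Returns a results dict with pooled metrics, per-session records, the
    filter report and the selection-frequency ranking.  The same code
    path serves both modalities.
    """
    seed = config.seed if seed is None else seed
    filtered, report = filter_features(
        features, threshold=config.filter.d_threshold, equal_var=config.filter.equal_var
    )
    pair_ids = filtered.samples["pair_id"].to_numpy()
    sessions = run_sessions(
        filtered.values,
        filtered.labels(),
        pair_ids,
        fit_config=config.fit,
        bootstrap_config=config.bootstrap,
        seed=seed,
        feature_ids=list(filtered.feature_ids),
    )
    pooled = pool_sessions(sessions, pooling=config.bootstrap.pooling)
    ranking = rank_features(sessions)
    return {
        "seed": seed,
        "config": config.to_dict(),
        "n_features_in": features.n_features,
        "n_features_retained": filtered.n_features,
        "filter_fit_on_full_data": True,  # printed pipeline order; induces optimism
        "filter": report.to_dict(),
        "pooled": pooled.to_dict(),
        "sessions": [s.to_dict() for s in sessions],
        "ranking": ranking.to_dict(),
        "_objects": {"pooled": pooled, "sessions": sessions, "ranking": ranking},
    }


def ftir_pipeline(dataset: SpectralDataset, config: RunConfig, seed: int | None = None) -> dict:
    """Spectral preprocessing + shared classification tail."""
    features = preprocess_pipeline(dataset, config.preprocess)
    out = classification_pipeline(features, config, seed)
    out["modality"] = "ftir"
    out["retained_dct_indices"] = features.meta["retained_dct_indices"]
    return out


def protein_features(table: ProteinTable) -> FeatureMatrix:
    """Natural-log protein abundance ratios as a sample-level feature table."""
    return FeatureMatrix(
        np.log(table.ratios),
        list(table.protein_ids),
        list(table.sample_ids),
        table.samples,
        meta={"kind": "protein_log_ratio"},
    )


def ms_pipeline(table: ProteinTable, config: RunConfig, seed: int | None = None) -> dict:
    """MS branch: log-ratios straight into the shared classification tail."""
    out = classification_pipeline(protein_features(table), config, seed)
    out["modality"] = "ms"
    return out


def pooled_of(results: dict) -> PooledMetrics:
    return results["_objects"]["pooled"]


def ranking_of(results: dict) -> FeatureRanking:
    return results["_objects"]["ranking"]


def serializable(results: dict) -> dict:
    """Results dict without the in-memory object handles (for JSON output)."""
    return {k: v for k, v in results.items() if k != "_objects"}
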
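"""FTIR spectral preprocessing chain.

Per replicate spectrum, in order: normalization to unit area under the
curve, additive log-ratio against the thiocyanate internal-standard band
(making spectra invariant to overall intensity scale), Savitzky-Golay
filtering, excision of the internal-standard band; replicates are then
averaged to sample level, each sample spectrum is compressed with the
orthonormal DCT-II, and a frequency filter removes the dropped leading
coefficients plus any coefficient with near-zero across-sample variance.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct as _scipy_dct
from scipy.fft import idct as _scipy_idct
from scipy.signal import savgol_filter

from .config import ConfigError, PreprocessConfig
from .io import FeatureMatrix, MetadataError, SpectralDataset

__all__ = [
    "area_normalize",
    "alr_kscn",
    "savitzky_golay",
    "remove_band",
    "dct_transform",
    "inverse_dct",
    "frequency_filter",
    "average_replicates",
    "preprocess_pipeline",
]


def area_normalize(row: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    """Scale a spectrum so its trapezoidal area over the grid equals 1."""
    row = np.asarray(row, dtype=float)
    area = np.trapezoid(row, wavenumbers)
    if not np.isfinite(area) or area <= 0:
        raise ValueError(f"total spectral area must be positive, got {area}")
    return row / area


def alr_kscn(
    row: np.ndarray,
    wavenumbers: np.ndarray,
    kscn_band: tuple[float, float] = (2000.0, 2150.0),
    epsilon: float | None = None,
) -> np.ndarray:
    """Additive log-ratio against the internal-standard band mean.

    Each channel becomes ``ln(max(x_i, eps)) - ln(r)`` with ``r`` the
    mean (epsilon-clipped) absorbance inside ``kscn_band``.  The result
    is invariant to multiplying the spectrum by any positive constant.
    ``epsilon`` defaults to 1e-8 times the row maximum.
    """
    row = np.asarray(row, dtype=float)
    if epsilon is None:
        epsilon = 1e-8 * float(np.max(row))
    if epsilon <= 0:
        raise ValueError("positivity epsilon must be > 0 (row maximum must be positive)")
    lo, hi = kscn_band
    in_band = (wavenumbers >= lo) & (wavenumbers <= hi)
    if not np.any(in_band):
        raise ValueError("internal-standard band contains no channels")
    clipped = np.maximum(row, epsilon)
    ref = float(np.mean(clipped[in_band]))
    if ref <= 0:
        raise ValueError("internal-standard band mean must be positive")
    return np.log(clipped) - np.log(ref)


def savitzky_golay(row: np.ndarray, window: int = 11, polyorder: int = 3, deriv: int = 0) -> np.ndarray:
    """Savitzky-Golay local least-squares polynomial filter.

    Edges are handled by evaluating the polynomial fitted to the
    terminal windows (``mode='interp'``), so any polynomial of degree
    <= ``polyorder`` passes through unchanged at every channel.
    """
    row = np.asarray(row, dtype=float)
    if window % 2 == 0:
        raise ConfigError("Savitzky-Golay window must be odd")
    if window <= polyorder:
        raise ConfigError("Savitzky-Golay window must exceed polyorder")
    if row.size < window:
        raise ValueError("spectrum shorter than the filter window")
    return savgol_filter(row, window, polyorder, deriv=deriv, mode="interp")


def remove_band(
    row: np.ndarray, wavenumbers: np.ndarray, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Delete all channels with wavenumber inside ``band`` (inclusive)."""
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    keep = (wavenumbers < band[0]) | (wavenumbers > band[1])
    if not np.any(keep):
        raise ValueError("band removal would delete the entire spectrum")
    return np.asarray(row, dtype=float)[..., keep], wavenumbers[keep]


def dct_transform(row: np.ndarray) -> np.ndarray:
    """Orthonormal DCT-II of a spectrum.

    ``X_k = sqrt(2/N) * C_k * sum_n x_n cos(pi/N (n+1/2) k)`` with
    ``C_0 = 1/sqrt(2)`` and ``C_k = 1`` otherwise; energy-preserving and
    invertible.
    """
    row = np.asarray(row, dtype=float)
    if row.size == 0:
        raise ValueError("cannot transform an empty spectrum")
    return _scipy_dct(row, type=2, norm="ortho", axis=-1)


def inverse_dct(coefficients: np.ndarray) -> np.ndarray:
    return _scipy_idct(np.asarray(coefficients, dtype=float), type=2, norm="ortho", axis=-1)


def frequency_filter(
    dct_matrix: np.ndarray,
    drop_k: tuple[int, ...] = (0,),
    near_zero_var_rel: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop listed leading coefficients and near-zero-variance coefficients.

    Returns ``(filtered matrix, retained indices)``.  A coefficient is
    near-zero-variance when its across-sample variance is below
    ``near_zero_var_rel`` times the largest across-sample variance.
    """
    X = np.asarray(dct_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a samples x coefficients matrix with >= 2 samples")
    variances = X.var(axis=0, ddof=1)
    vmax = float(variances.max())
    keep = np.ones(X.shape[1], dtype=bool)
    for k in drop_k:
        if 0 <= k < X.shape[1]:
            keep[k] = False
    if vmax > 0:
        keep &= variances >= near_zero_var_rel * vmax
    else:
        keep[:] = False
    if not np.any(keep):
        raise ValueError("frequency filter removed every coefficient")
    retained = np.flatnonzero(keep)
    return X[:, retained], retained


def average_replicates(dataset: SpectralDataset, rows: np.ndarray | None = None) -> np.ndarray:
    """Arithmetic mean of replicate rows per sample, in metadata order.

    ``rows`` defaults to the dataset's absorbance matrix; pass the
    per-replicate output of earlier stages to average those instead.
    """
    if rows is None:
        rows = dataset.absorbance
    rows = np.asarray(rows, dtype=float)
    rep_of = np.asarray(dataset.replicate_of)
    out = np.empty((dataset.n_samples, rows.shape[1]))
    for i, sid in enumerate(dataset.samples.index):
        mask = rep_of == sid
        if not np.any(mask):
            raise MetadataError(f"sample {sid!r} has no replicate spectra")
        out[i] = rows[mask].mean(axis=0)
    return out


def preprocess_pipeline(dataset: SpectralDataset, config: PreprocessConfig) -> FeatureMatrix:
    """Full replicate-to-features chain; deterministic.

    Per replicate: area normalize -> ALR vs internal standard ->
    Savitzky-Golay -> excise internal-standard band; then average
    replicates to sample level, DCT each sample spectrum, and frequency
    filter.  Retained DCT indices are recorded in ``meta``.
    """
    eps_scale = config.positivity_epsilon_rel
    processed = []
    grid = dataset.wavenumbers
    for row in dataset.absorbance:
        r = area_normalize(row, grid)
        r = alr_kscn(r, grid, config.kscn_band, epsilon=eps_scale * float(np.max(r)))
        r = savitzky_golay(r, config.sg_window, config.sg_polyorder, config.sg_deriv)
        r, trimmed_grid = remove_band(r, grid, config.kscn_band)
        processed.append(r)
    per_sample = average_replicates(dataset, np.array(processed))
    coeffs = dct_transform(per_sample)
    filtered, retained = frequency_filter(coeffs, config.dct_drop_k, config.near_zero_var_rel)
    feature_ids = [f"dct_{k}" for k in retained]
    return FeatureMatrix(
        filtered,
        feature_ids,
        list(dataset.samples.index),
        dataset.samples,
        meta={
            "kind": "dct",
            "retained_dct_indices": retained.tolist(),
            "n_channels_after_band_removal": int(per_sample.shape[1]),
        },
    )
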
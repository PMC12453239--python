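"""Paired synthetic FTIR + protein-ratio datasets with known ground truth.

Spectra are sums of Gaussian absorbance bands with log-normal
sample-level amplitudes, a thiocyanate internal-standard band whose
amplitude is independent of class, a smooth low-order polynomial
baseline drift per replicate well, and i.i.d. channel noise.  A class
effect is planted on the *amplitudes* of selected bands: the FRI mean is
shifted by ``effect_size`` times the between-sample amplitude SD, so the
planted standardized effect (Cohen's d) on each affected band equals
``effect_size`` by construction.

The protein table is log-normal; ``n_diff_proteins`` randomly chosen
proteins get a mean log-ratio shift of ``protein_log_effect`` SDs in the
FRI group.  Which proteins/bands are affected is a deterministic
function of the config (not the seed), so truth sets are stable across
replicate generations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .io import ProteinTable, SpectralDataset

__all__ = ["generate_dataset", "planted_truth", "sample_ids_for"]


def sample_ids_for(config: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    """(sample_ids, classes, pair_ids) in metadata order: FRI/control alternating."""
    sids, classes, pairs = [], [], []
    for i in range(config.n_pairs):
        pid = f"P{i + 1:02d}"
        for cls, suffix in (("FRI", "F"), ("control", "C")):
            sids.append(f"{pid}{suffix}")
            classes.append(cls)
            pairs.append(pid)
    return sids, classes, pairs


def _lognormal_amplitudes(mean: float, cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Log-normal draws with exact mean ``mean`` and coefficient of variation ``cv``."""
    if cv == 0:
        return np.full(size, mean)
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - sigma**2 / 2
    return rng.lognormal(mu, sigma, size)


def _draw_band_amplitudes(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample-level band amplitudes (n_samples x n_peaks) with the planted shift.

    Rows follow the metadata order of :func:`sample_ids_for` (FRI first
    in each pair).  FRI rows of affected bands get ``effect_size`` x
    between-sample SD added to the mean.
    """
    n_samples = 2 * config.n_pairs
    amps = np.empty((n_samples, len(config.peaks)))
    is_fri = np.arange(n_samples) % 2 == 0
    for j, peak in enumerate(config.peaks):
        amps[:, j] = _lognormal_amplitudes(peak.amplitude, peak.amplitude_cv, n_samples, rng)
        if j in config.effect_peaks and config.effect_size > 0:
            sd = peak.amplitude * peak.amplitude_cv  # between-sample SD of the base draw
            amps[is_fri, j] += config.effect_size * sd
    return amps


def _gaussian(wn: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wn - center) / width) ** 2)


def generate_dataset(
    config: SyntheticConfig, *, return_latents: bool = False
) -> tuple[SpectralDataset, ProteinTable] | tuple[SpectralDataset, ProteinTable, dict]:
    """Generate one paired spectral + protein dataset from ``config.seed``.

    With ``return_latents=True`` also returns the latent band-amplitude
    matrix and per-protein log-means used to build the data (for
    generator-calibration checks).
    """
    if config.effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(config.seed)
    sids, classes, pairs = sample_ids_for(config)
    n_samples = len(sids)
    wn = np.linspace(config.wn_min, config.wn_max, config.n_channels)

    amps = _draw_band_amplitudes(config, rng)
    kscn_amp = _lognormal_amplitudes(
        config.kscn_peak.amplitude, config.kscn_peak.amplitude_cv, n_samples, rng
    )

    band_shapes = np.stack(
        [_gaussian(wn, p.center, p.width) for p in config.peaks]
    )  # (n_peaks, C)
    kscn_shape = _gaussian(wn, config.kscn_peak.center, config.kscn_peak.width)

    rows, replicate_of, replicate_ids = [], [], []
    x01 = np.linspace(-1.0, 1.0, config.n_channels)
    for s, sid in enumerate(sids):
        clean = amps[s] @ band_shapes + kscn_amp[s] * kscn_shape
        for r in range(config.n_replicates):
            scale = np.exp(rng.normal(0.0, config.replicate_cv))
            coeffs = rng.normal(0.0, config.baseline_amplitude, config.baseline_degree + 1)
            baseline = np.polynomial.polynomial.polyval(x01, coeffs)
            noise = rng.normal(0.0, config.noise_sd, config.n_channels)
            rows.append(scale * clean + baseline + noise)
            replicate_of.append(sid)
            replicate_ids.append(f"{sid}_w{r + 1}")

    samples = pd.DataFrame({"class": classes, "pair_id": pairs}, index=pd.Index(sids, name="sample_id"))
    spectral = SpectralDataset(wn, np.array(rows), replicate_of, samples, replicate_ids)

    # Protein table: log-normal ratios, planted mean shift on a config-determined subset.
    sigma = np.sqrt(np.log1p(config.protein_cv**2))
    protein_ids = [f"PROT{p + 1:04d}" for p in range(config.n_proteins)]
    diff_idx = _diff_protein_indices(config)
    log_mu = np.zeros((n_samples, config.n_proteins))
    is_fri = np.array([c == "FRI" for c in classes])
    log_mu[np.ix_(is_fri, diff_idx)] = config.protein_log_effect * sigma
    ratios = np.exp(log_mu + rng.normal(0.0, sigma, size=log_mu.shape))
    table = ProteinTable(protein_ids, ratios, samples.copy(), list(sids))

    if return_latents:
        latents = {
            "band_amplitudes": amps,
            "kscn_amplitudes": kscn_amp,
            "protein_log_means": log_mu,
        }
        return spectral, table, latents
    return spectral, table


def _diff_protein_indices(config: SyntheticConfig) -> np.ndarray:
    """Deterministic (seed-independent) choice of differential proteins."""
    picker = np.random.default_rng(987654321)
    return np.sort(picker.choice(config.n_proteins, size=config.n_diff_proteins, replace=False))


def planted_truth(config: SyntheticConfig) -> tuple[np.ndarray, list[str]]:
    """Ground truth: affected channel indices and affected protein ids.

    A channel counts as affected if any affected band contributes
    meaningfully there (within 2 widths of its center).
    """
    wn = np.linspace(config.wn_min, config.wn_max, config.n_channels)
    mask = np.zeros(config.n_channels, dtype=bool)
    if config.effect_size > 0:
        for j in config.effect_peaks:
            p = config.peaks[j]
            mask |= np.abs(wn - p.center) <= 2 * p.width
    protein_ids = [f"PROT{p + 1:04d}" for p in _diff_protein_indices(config)]
    if config.protein_log_effect == 0:
        protein_ids = []
    return np.flatnonzero(mask), protein_ids
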
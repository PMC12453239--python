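"""Configuration objects for every pipeline stage.

All tunables of the analysis live in small dataclasses aggregated by
:class:`RunConfig`, which serializes losslessly to YAML/JSON so that a
results file always carries the exact settings (and seeds) that produced
it.  Every stochastic step in the package draws from a seed recorded
here; re-running from a saved config reproduces results bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "Peak",
    "SyntheticConfig",
    "PreprocessConfig",
    "FilterConfig",
    "FitConfig",
    "BootstrapConfig",
    "CrossmodalConfig",
    "RunConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """A configuration value is outside its documented range."""


@dataclass
class Peak:
    """A Gaussian absorbance band: center/width in cm^-1, amplitude in a.u."""

    center: float
    width: float
    amplitude: float
    amplitude_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.width <= 0 or self.amplitude <= 0:
            raise ConfigError("peak width and amplitude must be positive")
        if self.amplitude_cv < 0:
            raise ConfigError("amplitude CV must be >= 0")


def _default_peaks() -> list[Peak]:
    # Nominal plasma-film bands: amide I, amide II, CH stretch, sugar/phosphate,
    # COO-/CH bend, amide A / O-H.  Centers/widths are plausible, not fitted.
    return [
        Peak(1650.0, 28.0, 1.00, 0.15),
        Peak(1545.0, 25.0, 0.75, 0.15),
        Peak(2925.0, 35.0, 0.45, 0.18),
        Peak(1080.0, 40.0, 0.30, 0.20),
        Peak(1400.0, 30.0, 0.35, 0.18),
        Peak(3300.0, 110.0, 0.55, 0.15),
    ]


@dataclass
class SyntheticConfig:
    """Generator settings for paired FTIR + protein-ratio datasets.

    The defaults emulate the study design the pipeline targets: 13
    matched FRI/control pairs, three replicate wells per sample on a
    400-4000 cm^-1 grid with a thiocyanate internal-standard band, and a
    ~1000-protein abundance-ratio table with 32 differentially abundant
    proteins.
    """

    n_pairs: int = 13
    n_replicates: int = 3
    wn_min: float = 400.0
    wn_max: float = 4000.0
    n_channels: int = 901
    peaks: list[Peak] = field(default_factory=_default_peaks)
    kscn_peak: Peak = field(default_factory=lambda: Peak(2060.0, 16.0, 0.60, 0.08))
    baseline_degree: int = 2
    baseline_amplitude: float = 0.02
    replicate_cv: float = 0.03
    noise_sd: float = 0.003
    effect_peaks: tuple[int, ...] = (0, 1, 2)
    effect_size: float = 1.0
    n_proteins: int = 1000
    n_diff_proteins: int = 32
    protein_log_effect: float = 0.8
    protein_cv: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_peaks = tuple(self.effect_peaks)
        if self.n_pairs < 2:
            raise ConfigError("need at least 2 matched pairs")
        if self.n_replicates < 1:
            raise ConfigError("need at least 1 replicate well per sample")
        if not self.wn_min < self.wn_max:
            raise ConfigError("wavenumber range must be increasing")
        if self.n_channels < 8:
            raise ConfigError("need at least 8 spectral channels")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if any(i < 0 or i >= len(self.peaks) for i in self.effect_peaks):
            raise ConfigError("effect_peaks must index into the peak list")
        if self.n_diff_proteins > self.n_proteins:
            raise ConfigError("n_diff_proteins cannot exceed n_proteins")
        for name in ("baseline_amplitude", "noise_sd", "protein_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class PreprocessConfig:
    """Spectral preprocessing chain settings.

    ``kscn_band`` bounds the internal-standard region (log-ratio
    reference, then excised); the Savitzky-Golay window/order default to
    common FTIR smoothing practice; ``dct_drop_k`` lists leading DCT
    indices removed by the frequency filter, and ``near_zero_var_rel``
    is the relative across-sample variance floor below which a
    coefficient is considered uninformative.
    """

    kscn_band: tuple[float, float] = (2000.0, 2150.0)
    sg_window: int = 11
    sg_polyorder: int = 3
    sg_deriv: int = 0
    positivity_epsilon_rel: float = 1e-8
    dct_drop_k: tuple[int, ...] = (0,)
    near_zero_var_rel: float = 1e-8

    def __post_init__(self) -> None:
        self.kscn_band = tuple(self.kscn_band)
        self.dct_drop_k = tuple(sorted(set(int(k) for k in self.dct_drop_k)))
        if self.sg_window % 2 == 0:
            raise ConfigError("Savitzky-Golay window must be odd")
        if self.sg_window <= self.sg_polyorder:
            raise ConfigError("Savitzky-Golay window must exceed polyorder")
        if self.sg_deriv < 0 or self.sg_deriv > self.sg_polyorder:
            raise ConfigError("derivative order must be in [0, polyorder]")
        if self.kscn_band[0] >= self.kscn_band[1]:
            raise ConfigError("kscn_band must be (lo, hi) with lo < hi")
        if self.positivity_epsilon_rel <= 0:
            raise ConfigError("positivity epsilon must be > 0")
        if self.near_zero_var_rel < 0:
            raise ConfigError("near_zero_var_rel must be >= 0")


@dataclass
class FilterConfig:
    """Univariate screening: keep features with |Cohen's d| > threshold."""

    d_threshold: float = 0.5
    equal_var: bool = True  # pooled (Student) t, matching the pooled-SD d

    def __post_init__(self) -> None:
        if self.d_threshold < 0:
            raise ConfigError("d_threshold must be >= 0")


@dataclass
class FitConfig:
    """Elastic-net logistic regression settings.

    ``alpha`` mixes l1 (alpha=1, lasso) and l2 (alpha=0, ridge);
    ``max_nonzero`` caps the number of nonzero coefficients by stopping
    the regularization path before the cap would be exceeded.
    """

    alpha: float = 0.5
    n_lambda: int = 25
    lambda_min_ratio: float = 1e-3
    max_nonzero: int = 50
    tol: float = 1e-7
    max_iter: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must be in [0, 1]")
        if self.n_lambda < 1:
            raise ConfigError("need at least one lambda")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise ConfigError("lambda_min_ratio must be in (0, 1)")
        if self.max_nonzero < 1:
            raise ConfigError("max_nonzero must be >= 1")
        if self.tol <= 0:
            raise ConfigError("tolerance must be > 0")


@dataclass
class BootstrapConfig:
    """Bootstrap session / meta-analysis settings.

    ``n_resamples`` (B) pair-level bootstrap draws per session;
    ``n_sessions`` (S) independently seeded sessions pooled by a
    fixed-effect (inverse-variance) meta-analysis.
    """

    n_resamples: int = 100
    n_sessions: int = 100
    pooling: str = "ivw"  # "ivw" (inverse variance) or "mean"
    prob_threshold: float = 0.5
    max_redraws: int = 100
    top_k: int = 40

    def __post_init__(self) -> None:
        if self.n_resamples < 2 or self.n_sessions < 2:
            raise ConfigError("need >= 2 resamples and >= 2 sessions")
        if self.pooling not in ("ivw", "mean"):
            raise ConfigError("pooling must be 'ivw' or 'mean'")
        if not 0.0 < self.prob_threshold < 1.0:
            raise ConfigError("prob_threshold must be in (0, 1)")


@dataclass
class CrossmodalConfig:
    """CCA + cross-modal autoencoder settings."""

    n_select: int = 8  # top-|d| features per modality fed to CCA
    n_components: int = 2
    n_permutations: int = 1000
    ridge_eps: float = 1e-8
    encoder_widths: tuple[int, int, int] = (64, 16, 4)
    bottleneck: int = 2
    learning_rate: float = 0.01
    epochs: int = 500

    def __post_init__(self) -> None:
        self.encoder_widths = tuple(self.encoder_widths)
        if len(self.encoder_widths) != 3:
            raise ConfigError("encoder has exactly three dense layers")
        if self.bottleneck != 2:
            raise ConfigError("bottleneck width is fixed at 2")
        if self.n_permutations < 1:
            raise ConfigError("need >= 1 permutation")
        if self.learning_rate <= 0 or self.epochs < 0:
            raise ConfigError("bad optimizer settings")


@dataclass
class RunConfig:
    """Aggregate of every stage's settings plus the master seed."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    crossmodal: CrossmodalConfig = field(default_factory=CrossmodalConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _from_dict(cls, d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def _from_dict(cls, d):
    if not dataclasses.is_dataclass(cls):
        return d
    kwargs = {}
    hints = {f.name: f.type for f in dataclasses.fields(cls)}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.name == "peaks":
            v = [_build(Peak, p) for p in v]
        elif f.name == "kscn_peak":
            v = _build(Peak, v)
        elif f.name in ("synthetic", "preprocess", "filter", "fit", "bootstrap", "crossmodal"):
            v = _from_dict(_SECTION_TYPES[f.name], v)
        kwargs[f.name] = v
    return cls(**kwargs)


def _build(cls, v):
    if isinstance(v, dict):
        return cls(**v)
    return cls(*v)


_SECTION_TYPES = {
    "synthetic": SyntheticConfig,
    "preprocess": PreprocessConfig,
    "filter": FilterConfig,
    "fit": FitConfig,
    "bootstrap": BootstrapConfig,
    "crossmodal": CrossmodalConfig,
}
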
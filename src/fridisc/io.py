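"""Tabular I/O for spectra, protein-ratio tables, metadata and results.

File dialects (all plain text):

* **Spectra** — CSV, first column ``wavenumber`` (cm^-1, ascending), one
  column per replicate well, header row = replicate ids.
* **Metadata** — CSV with columns ``sample_id, class, pair_id,
  replicate_ids`` where ``replicate_ids`` is a ``;``-joined list of the
  spectra columns belonging to that sample.  ``class`` is ``FRI`` or
  ``control``; each ``pair_id`` appears in exactly one sample of each
  class (the matched case-control design).
* **Proteins** — TSV, one row per sample (first column ``sample_id``),
  one column per protein accession; or the transpose, declared by flag.
* **Results** — JSON carrying pooled metrics, per-session metrics,
  selected features, seeds and the full config, so any run can be
  reproduced from its results file alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "SpectralDataset",
    "ProteinTable",
    "SpectraFormatError",
    "MetadataError",
    "read_spectra",
    "write_spectra",
    "read_protein_table",
    "write_protein_table",
    "read_metadata",
    "write_metadata",
    "write_results",
    "read_results",
]

CLASSES = ("FRI", "control")


class SpectraFormatError(ValueError):
    """Malformed spectra/protein file (non-monotone grid, duplicate ids...)."""


class MetadataError(ValueError):
    """Sample annotations are inconsistent with the data they describe."""


@dataclass
class SpectralDataset:
    """Replicate-level absorbance spectra with sample annotations.

    ``absorbance`` has one row per replicate well; ``replicate_of`` maps
    each row to a sample declared in ``samples`` (index ``sample_id``,
    columns ``class`` and ``pair_id``).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    replicate_of: list[str]
    samples: pd.DataFrame
    replicate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if not self.replicate_ids:
            self.replicate_ids = [f"rep{i}" for i in range(len(self.replicate_of))]
        self.validate()

    def validate(self) -> None:
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 2:
            raise SpectraFormatError("wavenumbers must be 1-D, absorbance 2-D")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise SpectraFormatError("wavenumbers must be strictly increasing")
        if self.absorbance.shape != (len(self.replicate_of), len(self.wavenumbers)):
            raise SpectraFormatError("absorbance shape mismatch")
        if len(self.replicate_ids) != len(self.replicate_of):
            raise SpectraFormatError("one replicate id per absorbance row required")
        declared = set(self.samples.index)
        unknown = set(self.replicate_of) - declared
        if unknown:
            raise MetadataError(f"replicates reference undeclared samples: {sorted(unknown)}")
        missing = {"class", "pair_id"} - set(self.samples.columns)
        if missing:
            raise MetadataError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.samples["class"]) - set(CLASSES)
        if bad:
            raise MetadataError(f"unknown class labels: {sorted(bad)}")
        for pid, grp in self.samples.groupby("pair_id"):
            if sorted(grp["class"]) != sorted(CLASSES):
                raise MetadataError(
                    f"pair {pid!r} must contain exactly one FRI and one control sample"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_channels(self) -> int:
        return len(self.wavenumbers)

    def labels(self) -> np.ndarray:
        """Binary labels in metadata order: 1 = FRI, 0 = control."""
        return (self.samples["class"] == "FRI").to_numpy(dtype=int)


@dataclass
class ProteinTable:
    """Protein abundance ratios (samples x proteins), all strictly positive."""

    protein_ids: list[str]
    ratios: np.ndarray
    samples: pd.DataFrame | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.ndim != 2 or self.ratios.shape[1] != len(self.protein_ids):
            raise SpectraFormatError("ratios must be n_samples x n_proteins")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise SpectraFormatError("duplicate protein ids")
        if not np.all(np.isfinite(self.ratios)) or np.any(self.ratios <= 0):
            raise ValueError("abundance ratios must be finite and > 0")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.ratios.shape[0])]
        if len(self.sample_ids) != self.ratios.shape[0]:
            raise SpectraFormatError("one sample id per ratio row required")
        if self.samples is not None and list(self.samples.index) != list(self.sample_ids):
            raise MetadataError("sample annotations do not match table rows")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def labels(self) -> np.ndarray:
        if self.samples is None:
            raise MetadataError("no sample annotations attached")
        return (self.samples["class"] == "FRI").to_numpy(dtype=int)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype=str)
    required = {"sample_id", "class", "pair_id"}
    if not required <= set(meta.columns):
        raise MetadataError(f"metadata must have columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        raise MetadataError("duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def write_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    samples.reset_index(names="sample_id").to_csv(path, index=False)


def read_spectra(spectra_path: str | Path, meta_path: str | Path) -> SpectralDataset:
    """Read a spectra CSV plus its companion metadata CSV."""
    df = pd.read_csv(spectra_path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise SpectraFormatError("spectra file needs a wavenumber column and >= 1 replicate")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(wn) <= 0):
        raise SpectraFormatError("wavenumber column must be strictly increasing")
    replicate_ids = list(df.columns[1:])
    if len(set(replicate_ids)) != len(replicate_ids):
        raise SpectraFormatError("duplicate replicate column ids")
    absorbance = df.iloc[:, 1:].to_numpy(dtype=float).T  # rows = replicates

    meta = read_metadata(meta_path)
    if "replicate_ids" not in meta.columns:
        raise MetadataError("metadata must declare replicate_ids per sample")
    rep_to_sample: dict[str, str] = {}
    for sid, row in meta.iterrows():
        for rid in str(row["replicate_ids"]).split(";"):
            rid = rid.strip()
            if rid in rep_to_sample:
                raise MetadataError(f"replicate {rid!r} claimed by two samples")
            rep_to_sample[rid] = sid
    try:
        replicate_of = [rep_to_sample[r] for r in replicate_ids]
    except KeyError as e:
        raise MetadataError(f"spectra column {e.args[0]!r} not declared in metadata") from None
    samples = meta[["class", "pair_id"]].copy()
    return SpectralDataset(wn, absorbance, replicate_of, samples, replicate_ids)


def write_spectra(ds: SpectralDataset, spectra_path: str | Path, meta_path: str | Path) -> None:
    df = pd.DataFrame(ds.absorbance.T, columns=ds.replicate_ids)
    df.insert(0, "wavenumber", ds.wavenumbers)
    df.to_csv(spectra_path, index=False, float_format="%.17g")
    meta = ds.samples.copy()
    groups: dict[str, list[str]] = {sid: [] for sid in ds.samples.index}
    for rid, sid in zip(ds.replicate_ids, ds.replicate_of):
        groups[sid].append(rid)
    meta["replicate_ids"] = [";".join(groups[sid]) for sid in meta.index]
    write_metadata(meta, meta_path)


def read_protein_table(
    path: str | Path,
    meta_path: str | Path | None = None,
    proteins_as: str = "columns",
) -> ProteinTable:
    """Read a protein abundance-ratio TSV.

    ``proteins_as='columns'`` expects samples as rows; ``'rows'`` the
    transpose (first column = protein accession, columns = sample ids).
    """
    if proteins_as not in ("columns", "rows"):
        raise ValueError("proteins_as must be 'columns' or 'rows'")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if proteins_as == "rows":
        df = df.T
    if df.columns.duplicated().any():
        raise SpectraFormatError("duplicate protein ids")
    ratios = df.to_numpy(dtype=float)
    samples = None
    sample_ids = [str(s) for s in df.index]
    if meta_path is not None:
        meta = read_metadata(meta_path)[["class", "pair_id"]]
        try:
            samples = meta.loc[sample_ids]
        except KeyError:
            raise MetadataError("protein table rows not all declared in metadata") from None
    return ProteinTable([str(c) for c in df.columns], ratios, samples, sample_ids)


def write_protein_table(table: ProteinTable, path: str | Path) -> None:
    df = pd.DataFrame(table.ratios, index=table.sample_ids, columns=table.protein_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class FeatureMatrix:
    """Sample-level feature table (DCT coefficients or protein log-ratios).

    ``meta`` records provenance such as retained DCT indices or the
    univariate filter settings so a features file is self-describing.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    samples: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise SpectraFormatError("feature matrix shape mismatch")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise SpectraFormatError("duplicate feature ids")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def restrict(self, mask: np.ndarray, **meta) -> "FeatureMatrix":
        """New FeatureMatrix keeping only columns where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        ids = [f for f, m in zip(self.feature_ids, mask) if m]
        return FeatureMatrix(
            self.values[:, mask], ids, list(self.sample_ids),
            self.samples, {**self.meta, **meta},
        )

    def labels(self) -> np.ndarray:
        if self.samples is None:
            raise MetadataError("no sample annotations attached")
        return (self.samples["class"] == "FRI").to_numpy(dtype=int)


def write_features(fm: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fm.values, index=fm.sample_ids, columns=fm.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_features(path: str | Path, meta_path: str | Path | None = None) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    samples = None
    sample_ids = [str(s) for s in df.index]
    if meta_path is not None:
        samples = read_metadata(meta_path)[["class", "pair_id"]].loc[sample_ids]
    return FeatureMatrix(
        df.to_numpy(dtype=float), [str(c) for c in df.columns], sample_ids, samples
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


REQUIRED_RESULT_KEYS = ("config", "seed")


def write_results(results: dict, path: str | Path) -> None:
    """Write a results JSON; refuses records without config + seed.

    A results file must be a complete reproducibility record: the full
    config and the master seed are mandatory.
    """
    missing = [k for k in REQUIRED_RESULT_KEYS if k not in results]
    if missing:
        raise ValueError(f"results record missing required fields: {missing}")
    Path(path).write_text(json.dumps(results, cls=_NumpyEncoder, indent=1))


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def config_roundtrip_check(cfg: RunConfig) -> bool:
    """True iff the config survives dict round-trip unchanged."""
    return RunConfig.from_dict(cfg.to_dict()) == cfg
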
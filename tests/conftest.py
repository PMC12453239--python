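import dataclasses

import numpy as np
import pandas as pd
import pytest

from fridisc.config import RunConfig, SyntheticConfig
from fridisc.io import SpectralDataset
from fridisc.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_synth_config() -> SyntheticConfig:
    """Down-scaled generator config for fast unit tests (coarse grid)."""
    return SyntheticConfig(n_channels=241, seed=42)


@pytest.fixture(scope="session")
def null_synth_config(small_synth_config) -> SyntheticConfig:
    return dataclasses.replace(
        small_synth_config, effect_size=0.0, protein_log_effect=0.0, seed=43
    )


@pytest.fixture(scope="session")
def effect_dataset(small_synth_config):
    return generate_dataset(small_synth_config)


@pytest.fixture(scope="session")
def null_dataset(null_synth_config):
    return generate_dataset(null_synth_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_spectral_dataset() -> SpectralDataset:
    """3 samples x 3 replicates on a 5-channel grid (hand-checkable)."""
    wn = np.array([1000.0, 1500.0, 2000.0, 2500.0, 3000.0])
    rng = np.random.default_rng(0)
    absorb = 1.0 + rng.random((9, 5))
    samples = pd.DataFrame(
        {
            "class": ["FRI", "control", "FRI"],
            "pair_id": ["p1", "p1", "p2"],
        },
        index=pd.Index(["a", "b", "c"], name="sample_id"),
    )
    # incomplete pair p2 would violate the invariant; complete it
    samples = pd.concat(
        [
            samples,
            pd.DataFrame(
                {"class": ["control"], "pair_id": ["p2"]},
                index=pd.Index(["d"], name="sample_id"),
            ),
        ]
    )
    absorb = 1.0 + rng.random((12, 5))
    replicate_of = [s for s in ["a", "b", "c", "d"] for _ in range(3)]
    rep_ids = [f"{s}_w{i}" for s in ["a", "b", "c", "d"] for i in range(3)]
    return SpectralDataset(wn, absorb, replicate_of, samples, rep_ids)
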
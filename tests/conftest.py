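import numpy as np
import pandas as pd
import pytest

from reporterscreen import cyto, synthlib


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_genome():
    return synthlib.synthetic_genome(n_chrom=4, mean_length=400_000,
                                     n_features=60, seed=7)


@pytest.fixture(scope="session")
def small_library():
    """A 30-strain library with one strain of each deviant profile,
    small enough for fast unit tests."""
    cfg = synthlib.LibraryConfig(
        n_strains=30, events_per_strain=800,
        profile_fractions=(0.9, 1 / 30, 1 / 30, 0.1 - 2 / 30),
        seed=42)
    states, events, controls = synthlib.simulate_library(cfg)
    return cfg, states, events, controls


def identity_config(**overrides) -> synthlib.LibraryConfig:
    """Config with degenerate optics: no crosstalk, no autofluorescence,
    no dropout — events reflect the biological signal directly."""
    defaults = dict(n_strains=5, events_per_strain=2000,
                    crosstalk=cyto.CrosstalkMatrix(0.0, 0.0),
                    loh_rate=0.0, autofluorescence_mean=0.0, seed=0)
    defaults.update(overrides)
    return synthlib.LibraryConfig(**defaults)


def gated(events: pd.DataFrame) -> pd.DataFrame:
    """Mark raw simulated events as fully gated, with the biological
    channels copied into the processed columns (bypasses cyto)."""
    out = events.copy()
    out["gfp"] = out["ch1_raw"]
    out["mcherry"] = out["ch2_raw"]
    out["pass_scatter"] = True
    out["pass_dual"] = True
    out["gated"] = True
    return out
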
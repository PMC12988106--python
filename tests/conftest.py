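"""Shared fixtures: small libraries, quiet designs, canned run pairs."""

import pytest

from ventree.synthetic import (
    CompoundSpec,
    PanelDesign,
    default_sample_meta,
    make_compound_library,
)


@pytest.fixture(scope="session")
def small_library():
    return make_compound_library(3, seed=11)


@pytest.fixture(scope="session")
def quiet_design():
    """Noise-free, baseline-free, no chimera: for exactness checks."""
    return PanelDesign(
        n_samples=2,
        sample_meta=default_sample_meta(2),
        chimera_rate=0.0,
        noise_sd=0.0,
        ucm_amplitude=0.0,
    )


@pytest.fixture(scope="session")
def partial_overlap_pair():
    """Two hand-built compounds sharing one of five fragments each."""
    a = CompoundSpec(
        "A", "other",
        ((57, 100.0), (71, 60.0), (85, 40.0), (120, 30.0), (150, 20.0)),
        40.0, 4e6,
    )
    b = CompoundSpec(
        "B", "other",
        ((57, 100.0), (91, 80.0), (105, 50.0), (160, 25.0), (200, 15.0)),
        40.03, 3e6,
    )
    return a, b
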
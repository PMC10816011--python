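import numpy as np
import pytest

from radbiokit import BeamSpec, NucleusGeometry, SimulationTruth


@pytest.fixture
def carbon_beam() -> BeamSpec:
    """73 keV/µm carbon beam (plateau region, 25.7 MeV/n)."""
    return BeamSpec(73.0, "carbon 25.7 MeV/n")


@pytest.fixture
def a549_nucleus() -> NucleusGeometry:
    """A549 nucleus cross-section, 118.8 ± 52.5 µm²."""
    return NucleusGeometry(118.8, 52.5)


@pytest.fixture
def truth() -> SimulationTruth:
    return SimulationTruth(rng_seed=1234)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
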
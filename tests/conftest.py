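import numpy as np
import pytest

from lesscr import (
    CaptureHistory,
    DetectorArray,
    SpatialDomain,
    default_design,
    simulate_captures,
    simulate_population,
)


@pytest.fixture(scope="session")
def design15():
    """A small 15x15 unit-spaced survey with the standard 4-du buffer."""
    return default_design(15, 15)


@pytest.fixture(scope="session")
def dataset15(design15):
    """One seeded simulated dataset (N=20) on the 15x15 survey."""
    detectors, domain = design15
    truth = simulate_population(20, domain, rng=42)
    captures = simulate_captures(truth, detectors, rng=43)
    assert captures.n_detected >= 5
    return truth, captures


@pytest.fixture(scope="session")
def square_domain20():
    """A 20x20-du all-suitable domain whose extent is a multiple of 10 du,
    so width-10 augmentation tiles are never truncated (prop_habitat = 1)."""
    return SpatialDomain(
        bounds=(0.0, 20.0, 0.0, 20.0), habitat=np.ones((20, 20), dtype=bool)
    )


@pytest.fixture(scope="session")
def empty_captures():
    """A capture history with zero detected individuals (augmented-only toys)."""

    def make(n_detectors: int) -> CaptureHistory:
        return CaptureHistory(y=np.zeros((0, n_detectors), dtype=np.int8))

    return make


@pytest.fixture(scope="session")
def detectors5():
    return DetectorArray.grid(5, 5, spacing=1.0)
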
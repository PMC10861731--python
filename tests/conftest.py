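import numpy as np
import pytest

from megspect.spectral import NormalizedSpectrum
from megspect.synthetic import generate_adjacency


@pytest.fixture
def freqs():
    """Analytic 1-70 Hz grid at 0.25 Hz resolution (277 bins)."""
    return np.arange(1.0, 70.125, 0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_spectra(freqs, rng):
    """Stack of 200 random normalized spectra for identity checks."""
    raw = rng.gamma(1.5, size=(200, freqs.size))
    return NormalizedSpectrum(freqs=freqs, psdn=raw / raw.sum(axis=1, keepdims=True))


@pytest.fixture
def line_graph_5():
    """Five regions in a line: R001-R002-R003-R004-R005."""
    labels = [f"R{i + 1:03d}" for i in range(5)]
    from megspect.stats import RegionAdjacency

    return RegionAdjacency(labels=labels, edges=np.array([[0, 1], [1, 2], [2, 3], [3, 4]]))


@pytest.fixture(scope="session")
def lattice_103():
    return generate_adjacency(103, scheme="lattice")
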
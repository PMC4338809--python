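import numpy as np
import pytest

from microstab.niche_profiles import AffinityMatrix, Consortium
from microstab.wavelet_stability import EhSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    """4 species x 6 substrates with known overlap structure."""
    cells = np.array(
        [
            [1, 1, 0, 0, 0, 0],
            [0, 1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1, 0],
            [0, 0, 0, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return AffinityMatrix(
        ("a", "b", "c", "d"), tuple(f"s{i}" for i in range(6)), cells
    )


def random_matrix(rng, n_species=None, n_substrates=None):
    n_species = n_species or int(rng.integers(2, 13))
    n_substrates = n_substrates or int(rng.integers(3, 96))
    cells = rng.integers(0, 2, size=(n_species, n_substrates)).astype(np.int8)
    return AffinityMatrix(
        tuple(f"sp{i}" for i in range(n_species)),
        tuple(f"sub{j}" for j in range(n_substrates)),
        cells,
    )


def consortium(*members, label="A", level=None):
    return Consortium(frozenset(members), label, level or len(members))


def make_series(values, dt=900.0, microcosm_id="M", probe_depth=0):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) * dt
    return EhSeries(microcosm_id, probe_depth, t, values)


def cwt_direct(values, dt, scales, omega0=6.0, normalization="paper_1_over_a"):
    """Literal double-sum transform oracle, independent of the package path.

    W(a, x_j) = prefac(a) * sum_i f(x_i) conj(g((x_i - x_j)/a)).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    t = np.arange(n) * dt
    out = np.empty((len(scales), n), dtype=complex)
    for k, a in enumerate(scales):
        pref = 1.0 / a if normalization == "paper_1_over_a" else 1.0 / np.sqrt(a)
        for j in range(n):
            eta = (t - t[j]) / a
            g = np.pi ** (-0.25) * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)
            out[k, j] = pref * np.sum(values * np.conj(g))
    return out
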
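import numpy as np
import pytest

from msapop.band import BandMatrix
from msapop.synthetic_data import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic survey (4 habitats x 3 sites)."""
    params = SimParams(seed=11, n_aflp=300, n_msap=360)
    return simulate_dataset(params)


@pytest.fixture()
def toy_band_matrix():
    values = np.array(
        [
            [1, 0, 1, 0],
            [1, 1, 0, 0],
            [0, 1, 1, np.nan],
            [0, 0, 1, 1],
        ],
        dtype=float,
    )
    return BandMatrix(
        values=values,
        sample_ids=["a", "b", "c", "d"],
        habitat=["H1", "H1", "H2", "H2"],
        site=["s1", "s1", "s2", "s2"],
        locus_ids=["L1", "L2", "L3", "L4"],
        fragment_size_bp=np.array([200.0, 300.0, 120.0, 450.0]),
    )


def random_band_matrix(rng, n=12, L=20, missing_rate=0.05, with_sizes=True):
    values = (rng.random((n, L)) < 0.5).astype(float)
    values[rng.random((n, L)) < missing_rate] = np.nan
    habs = [f"H{1 + (i // (n // 2))}" for i in range(n)]
    sites = [f"{habs[i]}s{1 + (i % (n // 2)) // max(1, n // 4)}" for i in range(n)]
    return BandMatrix(
        values=values,
        sample_ids=[f"ind{i:02d}" for i in range(n)],
        habitat=habs,
        site=sites,
        locus_ids=[f"M{j:03d}" for j in range(L)],
        fragment_size_bp=rng.integers(150, 500, L).astype(float) if with_sizes else None,
    )
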
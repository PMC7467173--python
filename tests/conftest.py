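import numpy as np
import pytest
import biotite.structure as struc

from domfit import Domain
from domfit.density import DensityMap


def ca_domain(coords, label="toy", chain="A", res_start=1):
    """Build a CA-only Domain from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.chain_id = np.full(n, chain)
    arr.res_id = np.arange(res_start, res_start + n)
    arr.res_name = np.full(n, "ALA")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, bool)
    return Domain(
        label=label, chain_id=chain,
        res_start=res_start, res_end=res_start + n - 1, atoms=arr,
    )


def random_blob_domain(n=20, seed=0, scale=4.0, **kw):
    rng = np.random.default_rng(seed)
    return ca_domain(rng.normal(size=(n, 3)) * scale, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_map():
    grid = np.random.default_rng(1).random((12, 12, 12))
    return DensityMap(grid, 2.0, (-12.0, -12.0, -12.0))


@pytest.fixture
def blob():
    return random_blob_domain(20, seed=0)
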
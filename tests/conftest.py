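import numpy as np
import pytest

from pdl1dia import SimParams, generate_core, render_channels


def small_params(**kw) -> SimParams:
    """A fast small core: ~60 cells in a 320 px core."""
    base = dict(
        seed=0,
        core_diameter_px=320,
        n_cells=60,
        tumour_fraction=0.5,
        n_nests=2,
        tps_true=40.0,
        macrophage_fraction=0.1,
        tcell_fraction=0.1,
    )
    base.update(kw)
    return SimParams(**base)


@pytest.fixture
def params():
    return small_params()


@pytest.fixture
def truth(params):
    return generate_core(params)


@pytest.fixture
def clean_params():
    """Noise-free, background-free rendering for sharp oracle checks."""
    return small_params(noise_sd=0.0, background_level=0.0)


@pytest.fixture
def clean_truth(clean_params):
    return generate_core(clean_params)


@pytest.fixture
def clean_stack(clean_truth):
    return render_channels(clean_truth)


def sparse_truth(seed=0, n=10, shape=256, radius=6.0, lineage="tumour", pdl1=False):
    """Hand-placed well-separated cells on a grid, for counting oracles."""
    from pdl1dia import CoreTruth, TrueCell

    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n)))
    pitch = shape / (side + 1)
    cells = []
    for i in range(n):
        gx, gy = (i % side) + 1, (i // side) + 1
        x = gx * pitch + rng.uniform(-2, 2)
        y = gy * pitch + rng.uniform(-2, 2)
        cells.append(TrueCell(i, x, y, radius, lineage, pdl1, lineage == "tumour"))
    params = SimParams(
        seed=seed, core_diameter_px=shape, n_cells=n, noise_sd=0.0, background_level=0.0
    )
    return CoreTruth(cells=cells, nests=[], params=params)
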
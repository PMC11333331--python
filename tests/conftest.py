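import numpy as np
import pytest

from herbniche import synthetic
from herbniche.geodata import EnvStack, RasterGrid


@pytest.fixture
def small_grid():
    """3x3 grid spanning lon [0,3], lat [0,3] with one nodata cell."""
    vals = np.arange(9, dtype=float).reshape(3, 3)
    vals[1, 1] = -9999.0
    return RasterGrid(name="demo", xll=0.0, yll=0.0, cellsize=1.0, nodata=-9999.0, values=vals)


@pytest.fixture
def tiny_stack():
    """Two aligned 4x4 layers, fully valid."""
    rng = np.random.default_rng(7)
    base = dict(xll=100.0, yll=30.0, cellsize=0.5, nodata=-9999.0)
    a = RasterGrid(name="a", values=rng.standard_normal((4, 4)), **base)
    b = RasterGrid(name="b", values=rng.standard_normal((4, 4)), **base)
    return EnvStack([a, b])


@pytest.fixture(scope="session")
def scene():
    """Standard synthetic study scene, shared across the suite (seed 1)."""
    stack, occ, truth = synthetic.default_scene(seed=1, nrows=60, ncols=60)
    return stack, occ, truth


@pytest.fixture(scope="session")
def scene_sdm(scene):
    """Bootstrap ensemble + jackknife on the session scene (the heavy part)."""
    import warnings

    from herbniche.evaluation import jackknife
    from herbniche.maxent import bootstrap_ensemble

    stack, occ, truth = scene
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_map, aucs, models = bootstrap_ensemble(
            occ, stack, reps=5, seed=1, n_background=10_000
        )
        jk = jackknife(occ, stack, seed=1, n_background=10_000)
    return {"mean_map": mean_map, "aucs": aucs, "models": models, "jackknife": jk}
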
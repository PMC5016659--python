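import numpy as np
import pandas as pd
import pytest

from wvcrisk.synthetic import SceneConfig, TruthParameters, generate_scene

# A "strong logistic truth": large coefficients and a rare species, so the
# occurrence signal is recoverable from modest point counts.
STRONG_OCC_COEFS = {
    "ELEV": -2.0,
    "GREEN": 1.8,
    "LIGHT": -1.6,
    "MNTEMPWQ": 1.2,
    "PRECDM": 2.2,
    "SLOPE": -1.0,
    "TREEDENS": 1.4,
}


@pytest.fixture(scope="session")
def default_scene():
    """A compact scene under the default study conditions."""
    cfg = SceneConfig(extent=(0, 0, 20_000, 20_000), n_roads=60, seed=3)
    return generate_scene(cfg, n_presence=200, n_background=1000)


@pytest.fixture(scope="session")
def strong_truth():
    return TruthParameters(occ_coefs=dict(STRONG_OCC_COEFS), occ_intercept=-3.0)


@pytest.fixture(scope="session")
def strong_occurrence_table(strong_truth):
    """Presence/background covariate table sampled from a strong-signal scene."""
    cfg = SceneConfig(extent=(0, 0, 30_000, 30_000), n_roads=100, seed=11)
    scene = generate_scene(cfg, strong_truth, n_presence=500, n_background=2000)
    xs = np.concatenate([scene.presences["x"], scene.background["x"]])
    ys = np.concatenate([scene.presences["y"], scene.background["y"]])
    table = pd.DataFrame({n: r.sample_points(xs, ys) for n, r in scene.rasters.items()})
    table["label"] = np.concatenate([np.ones(500), np.zeros(2000)])
    return table
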
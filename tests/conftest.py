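import numpy as np
import pandas as pd
import pytest

import loopmap as lm
from loopmap.atlas import AtlasSpec, LobuleBox


@pytest.fixture(scope="session")
def atlas():
    return lm.default_atlas()


@pytest.fixture(scope="session")
def tiny_atlas():
    """Three box lobules with round voxel volumes for hand arithmetic."""
    return AtlasSpec(
        lobules=(
            LobuleBox("A", 2000, (0.0, 1000.0), (0.0, 1000.0)),
            LobuleBox("B", 4000, (0.0, 1000.0), (1000.0, 2000.0)),
            LobuleBox("C", 4000, (0.0, 1000.0), (2000.0, 3000.0)),
        ),
        split_thresholds_um={"fastigial": {}, "dentate": {}},
    )


@pytest.fixture(scope="session")
def ephys_session():
    """Small shared session: 12 units, 30 trials/type, 5-Hz ramps."""
    cfg = lm.GenerationConfig(seed=17, selectivity_amplitude_hz=5.0)
    units, trials = lm.gen_ephys(cfg, n_units=12)
    return cfg, units, trials


def make_points(rows):
    """Point-cloud DataFrame from (x, y, z, hemi, lobule, mouse) tuples."""
    return pd.DataFrame(
        [dict(x_um=x, y_um=y, z_um=z, hemisphere=h, lobule=l, mouse_id=m,
              marker="mossy-fiber terminal") for x, y, z, h, l, m in rows])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
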
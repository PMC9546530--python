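import numpy as np
import pytest

import synaptomap as sm

VOXEL = (1.0, 0.2, 0.2)  # um, fMOST-like anisotropic sampling


@pytest.fixture(scope="session")
def small_atlas() -> sm.LabelAtlas:
    """A 32 x 64 x 64 voxel toy brain with 4 regions."""
    return sm.make_atlas((32, 64, 64), VOXEL, n_regions=4, seed=1)


@pytest.fixture(scope="session")
def cube_atlas() -> sm.LabelAtlas:
    """A solid 10 x 10 x 10 voxel single-region atlas of exactly 0.001 mm^3.

    Voxel size 10 um gives 1000 voxels x 1000 um^3 = 1e6 um^3 = 0.001 mm^3,
    handy for closed-form Poisson-mean checks.
    """
    labels = np.ones((10, 10, 10), dtype=np.int32)
    return sm.LabelAtlas(
        labels=labels,
        voxel_size=(10.0, 10.0, 10.0),
        ontology={0: {"acronym": "BG", "name": "outside"}, 1: {"acronym": "R01", "name": "cube"}},
    )


@pytest.fixture(scope="session")
def rendered_sample(small_atlas):
    """Ground truth + rendered green volume at the default noise model."""
    dens = {label: 2450.0 for label in small_atlas.region_labels()}
    truth = sm.sample_spots(small_atlas, dens, n_starters=2000, seed=7)
    cfg = sm.SyntheticConfig(volume_shape=(32, 64, 64), voxel_size=VOXEL, n_regions=4, seed=7)
    volume = sm.render_volume(truth, cfg)
    return truth, volume, cfg


def brute_force_average_distance(coords: np.ndarray, k: int = 9) -> float:
    """O(n^2) oracle: all-pairs distances, mean of each spot's k smallest."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < k + 1:
        return float("nan")
    per_spot = []
    for i in range(n):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        d = np.sort(d)
        per_spot.append(d[1 : k + 1].mean())
    return float(np.mean(per_spot))
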
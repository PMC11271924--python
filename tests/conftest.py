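import numpy as np
import pytest

import voxfit as vf
from voxfit.maps import VoxelSet
from voxfit.scattering import load_atomistic_table


@pytest.fixture(scope="session")
def table():
    return load_atomistic_table()


@pytest.fixture(scope="session")
def helix20():
    return vf.make_toy_structure("helix", 20, seed=1)


@pytest.fixture(scope="session")
def helix3():
    return vf.make_toy_structure("helix", 3, seed=1)


@pytest.fixture(scope="session")
def helix3_noisy_voxels(helix3):
    """3-residue helix with a 10%-noise map: voxels + floors + truth record."""
    bf = np.full(3, 25.0)
    truth, _, _ = vf.simulate_map([helix3], [1.0], bf, noise_sd=0.0, seed=2)
    peak = truth.densities.max()
    full, halves, rec = vf.simulate_map(
        [helix3], [1.0], bf, noise_sd=0.1 * peak, seed=2
    )
    vox = vf.noise_floor(halves, vf.select_voxels(full, helix3))
    return {"voxels": vox, "map": full, "halves": halves, "bfactors": bf}


@pytest.fixture(scope="session")
def helix20_map(helix20):
    """20-residue helix, 2% noise, full prep chain applied."""
    bf = np.full(20, 30.0)
    truth, _, _ = vf.simulate_map([helix20], [1.0], bf, noise_sd=0.0, seed=4)
    peak = truth.densities.max()
    full, halves, rec = vf.simulate_map(
        [helix20], [1.0], bf, noise_sd=0.02 * peak, seed=4
    )
    vox = vf.select_voxels(full, helix20)
    vox = vf.correlation_prefilter(full, vox, 0.8)
    vox = vf.noise_floor(halves, vox)
    return {"voxels": vox, "map": full, "halves": halves, "bfactors": bf,
            "truth_peak": peak}


def uniform_floor_voxels(voxels: VoxelSet, sigma: float) -> VoxelSet:
    return VoxelSet(voxels.centers, voxels.densities, np.full(len(voxels), sigma))
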
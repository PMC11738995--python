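import numpy as np
import pytest

import vasckinetics as vk


@pytest.fixture(scope="session")
def small_scene():
    """One modest voxelized vessel scene shared by read-only tests."""
    params = vk.SceneParams(n_inside=6, n_outside=6, kappa=2.0, seed=42)
    nuclei, golgi, vessel, truth = vk.generate_vessel_scene(params)
    return params, nuclei, golgi, vessel, truth


@pytest.fixture()
def tube_mask():
    """Small anisotropic vessel tube (along x) for classification tests."""
    shape = (16, 40, 40)
    spacing = (2.0, 1.0, 1.0)  # z, y, x µm
    zc, yc, radius = 16.0, 20.0, 10.0
    zz = np.arange(shape[0])[:, None] * spacing[0]
    yy = np.arange(shape[1])[None, :] * spacing[1]
    cross = (zz - zc) ** 2 + (yy - yc) ** 2 <= radius**2
    arr = np.broadcast_to(cross[:, :, None], shape).copy()
    return vk.LabelMask(arr.astype(np.uint8), spacing)
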
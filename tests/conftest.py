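import numpy as np
import pytest

from rsadeltoid import synthetic


@pytest.fixture(scope="session")
def reference_params():
    return synthetic.reference_params()


@pytest.fixture(scope="session")
def reference_truth(reference_params):
    return synthetic.ground_truth(reference_params)


@pytest.fixture(scope="session")
def reference_clouds(reference_params):
    _, clouds, _ = synthetic.generate_shoulder(
        reference_params, seed=1, with_volume=False
    )
    return clouds


@pytest.fixture(scope="session")
def coarse_volume():
    """A coarse phantom volume (larger voxels keep the suite fast)."""
    params = synthetic.reference_params()
    from dataclasses import replace

    params = replace(params, voxel_spacing=np.array([2.0, 2.0, 3.0]))
    return synthetic.voxelize(params)
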
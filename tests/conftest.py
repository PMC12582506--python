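import numpy as np
import pytest

from elastocycle import build_neighborhoods, make_affine_ensemble


def rotation_matrix(angles_deg=(20.0, 30.0, 40.0)) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()


@pytest.fixture(scope="session")
def dilation_fixture():
    """60-atom cloud plus a copy uniformly dilated by 1.1."""
    return make_affine_ensemble(60, [np.eye(3) * 1.1], seed=11)


@pytest.fixture(scope="session")
def dilation_neighborhoods(dilation_fixture):
    return build_neighborhoods(dilation_fixture.ensemble, radius=9.0, mode="intersect-all")
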
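import numpy as np
import pytest

from conformens.core import Ensemble
from conformens.synthetic import SyntheticSpec, make_endpoints


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """Small two-state system used across modules (24 Cα, 40 models)."""
    return SyntheticSpec(n_res=24, arm_len=10, n_models=40, seed=3)


@pytest.fixture(scope="session")
def endpoints(tiny_spec):
    """(open_model, closed_model, [arm_a, hinge, arm_b]) of the tiny system."""
    return make_endpoints(tiny_spec)


@pytest.fixture()
def rigid_copies(endpoints) -> Ensemble:
    """Five rigid-motion copies of the open endpoint (same conformation)."""
    from scipy.spatial.transform import Rotation

    open_model, _, _ = endpoints
    rng = np.random.default_rng(11)
    models = []
    for i in range(5):
        rot = Rotation.random(random_state=np.random.RandomState(i)).as_matrix()
        shift = rng.normal(scale=10.0, size=3)
        models.append(
            open_model.with_coords(open_model.coords @ rot.T + shift, f"copy{i}")
        )
    return Ensemble(models)
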
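import numpy as np
import pytest

from vhhforge.synthetic_data import (PoseEnsembleSpec, generate_pose_ensemble,
                                     generate_toy_complex)


@pytest.fixture(scope="session")
def toy_complex():
    return generate_toy_complex(0)


@pytest.fixture(scope="session")
def small_contact_ensemble(toy_complex):
    """2 planted contact-docked clusters + 2 outliers, modest separation."""
    spec = PoseEnsembleSpec(
        n_clusters=2, sizes=(4, 3), n_outliers=2, rot_sd_within=1.0,
        trans_sd_within=0.3, min_between_separation=40.0, coord_noise_sd=0.05,
        seed=5, ensure_contact=True, outlier_min_separation=15.0)
    poses, truth = generate_pose_ensemble(toy_complex, spec)
    return poses, truth, spec


def random_point_cloud(rng: np.random.Generator, n: int, scale: float = 10.0) -> np.ndarray:
    return rng.uniform(-scale, scale, size=(n, 3))
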
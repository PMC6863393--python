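import numpy as np
import pytest

from mcsquant.synthetic import SiteTruth, VolumeTruth, gen_contact_volume, gen_membrane_site


@pytest.fixture
def flat_site():
    """Noise-free flat contact site at 21.9 nm separation."""
    truth = SiteTruth(separation_nm=21.9, jitter_sd_nm=0.0, seed=0, site_id="flat")
    pm, er = gen_membrane_site(truth, 200.0)
    return truth, pm, er


@pytest.fixture
def small_membrane_volume():
    """Small noise-free volume with two membranes and no rods or coat."""
    truth = VolumeTruth(voxel_nm=0.74, pm_z_nm=15.0, er_z_nm=37.0)
    volume, tables = gen_contact_volume(truth, (70, 24, 24), seed=0)
    return truth, volume, tables


def rigid_transform(points: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A reproducible random rotation + translation, applied to points."""
    rng = np.random.default_rng(seed)
    a, b, c = rng.uniform(0, 2 * np.pi, 3)
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    rx = np.array([[1, 0, 0], [0, np.cos(c), -np.sin(c)], [0, np.sin(c), np.cos(c)]])
    rot = rz @ ry @ rx
    shift = rng.uniform(-50, 50, 3)
    return points @ rot.T + shift, rot
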
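import logging
import warnings

import numpy as np
import pytest

from lesionmap.mask import LesionMask
from lesionmap.synthetic import Ellipsoid, SimConfig, generate_cohort

# permutation/SVR internals log and warn a lot at tiny sizes; keep test output clean
logging.getLogger("lesionmap").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        yield


def small_sim_config(**overrides) -> SimConfig:
    """A 12^3 grid at 2 mm with an on-grid critical and AOS region."""
    defaults = dict(
        grid_shape=(12, 12, 12),
        voxel_size_mm=2.0,
        n_subjects=30,
        critical_region=Ellipsoid((11.0, 11.0, 11.0), (6.0, 5.0, 5.0)),
        aos_region=Ellipsoid((4.0, 18.0, 11.0), (4.0, 4.0, 4.0)),
        effect_beta=4.0,
        overall_beta=0.5,
        noise_sd=0.5,
        qab_fraction=0.5,
        seed=11,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    config = small_sim_config()
    masks, behavior, truth = generate_cohort(config)
    return config, masks, behavior, truth


def single_voxel_masks(
    lesioned_subjects: list[int],
    n_subjects: int,
    voxel: tuple[int, int, int] = (4, 4, 4),
    shape: tuple[int, int, int] = (8, 8, 8),
    voxel_size: float = 2.0,
) -> list[LesionMask]:
    """Masks that lesion exactly one voxel for the listed subjects.

    Non-listed subjects get a lesion at a far-away filler voxel so every
    subject has a nonempty mask.
    """
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    filler = (0, 0, 0)
    masks = []
    for i in range(n_subjects):
        data = np.zeros(shape, dtype=bool)
        data[voxel if i in lesioned_subjects else filler] = True
        masks.append(LesionMask(data, affine))
    return masks
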
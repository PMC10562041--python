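import numpy as np
import pytest

from adaptrig import cohort, differences
from adaptrig.dvh import DoseGrid, StructureMask, compute_cumulative_dvh


@pytest.fixture(scope="session")
def four_voxel_curve():
    """Four 1 cc voxels with doses 1, 2, 3, 4 Gy (the worked hand example)."""
    grid = DoseGrid(np.array([[[1.0, 2.0], [3.0, 4.0]]]), spacing=(10.0, 10.0, 10.0))
    mask = StructureMask(np.ones((1, 2, 2), dtype=bool), "ptv", "target")
    return compute_cumulative_dvh(grid, mask)


@pytest.fixture(scope="session")
def default_cohort():
    """The shipped four-site synthetic cohort (16 patients, 320 fractions)."""
    return cohort.generate_metric_cohort(cohort.default_cohort_spec(master_seed=11))


@pytest.fixture(scope="session")
def default_diffs(default_cohort):
    return differences.compute_differences(default_cohort)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A coarse SBRT phantom (5 fractions/patient) that runs in seconds."""
    return cohort.PhantomSpec(
        site_label="prostate_sbrt",
        shape=(28, 28, 28),
        spacing=(3.5, 3.5, 3.5),
        displacement_sd=(3.0, 3.0, 3.0),
        seed=3,
    )


def brute_dose_at_relative_volume(doses: np.ndarray, x: float) -> float:
    """Independent oracle: smallest dose among the hottest x% of voxels."""
    order = np.sort(np.asarray(doses, dtype=float))[::-1]
    k = max(int(np.ceil(x / 100.0 * order.size - 1e-9)), 1)
    return float(order[k - 1])


def brute_dose_at_absolute_volume(doses: np.ndarray, x_cc: float, voxel_cc: float) -> float:
    order = np.sort(np.asarray(doses, dtype=float))[::-1]
    if x_cc == 0:
        return float(order[0])
    k = min(max(int(np.ceil(x_cc / voxel_cc - 1e-9)), 1), order.size)
    return float(order[k - 1])


def brute_volume_at_dose(doses: np.ndarray, threshold: float) -> float:
    doses = np.asarray(doses, dtype=float)
    return float(np.mean(doses >= threshold - 1e-9) * 100.0)
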
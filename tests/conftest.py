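import numpy as np
import pytest
from skimage import draw

from pltmorph import (
    Group,
    LabelScene,
    OrganelleClass,
    SyntheticCohortConfig,
    measure_platelet,
)
from pltmorph.synthetic import iter_cohort


def disk_mask(radius: float, size: int | None = None) -> np.ndarray:
    """Rasterized disk centred on a square canvas."""
    size = size or int(2 * radius + 12)
    m = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((size / 2, size / 2), radius, shape=m.shape)
    m[rr, cc] = True
    return m


def ellipse_mask(a: float, b: float) -> np.ndarray:
    """Rasterized axis-aligned ellipse with semi-axes (a, b) in (row, col)."""
    m = np.zeros((int(2 * a + 12), int(2 * b + 12)), dtype=bool)
    rr, cc = draw.ellipse(m.shape[0] / 2, m.shape[1] / 2, a, b, shape=m.shape)
    m[rr, cc] = True
    return m


def scene_with_disks(
    body_radius: float,
    organelles: list[tuple[OrganelleClass, tuple[int, int], float]],
    pixel_size_nm: float = 1.0,
) -> LabelScene:
    """2D scene: a disk platelet body plus disk organelles at (row, col)."""
    size = int(2 * body_radius + 20)
    label_map = np.zeros((size, size), dtype=np.int32)
    rr, cc = draw.disk((size / 2, size / 2), body_radius, shape=label_map.shape)
    label_map[rr, cc] = 1
    table = {1: OrganelleClass.PLATELET_BODY}
    for i, (cls, center, radius) in enumerate(organelles, start=2):
        rr, cc = draw.disk(center, radius, shape=label_map.shape)
        label_map[rr, cc] = i
        table[i] = cls
    return LabelScene(label_map=label_map, pixel_size_nm=pixel_size_nm,
                      class_table=table)


@pytest.fixture(scope="session")
def small_cohort_records():
    """Measured records of a small full cohort (6 platelets per group)."""
    cfg = SyntheticCohortConfig(seed=20, n_per_group={g: 6 for g in Group})
    records = []
    for scene, gt in iter_cohort(cfg):
        records.append(measure_platelet(scene, gt.group, platelet_id=gt.scene_id))
    return records
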
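"""Organelle morphometry on segmented platelet cryo-ET slices.

Measurements follow the study conventions for quiescent platelets imaged by
electron cryo-tomography: every organelle is quantified on the *central slice*
through its z extent, areas are reported in nm^2 (and in units of 10^5 nm^2,
the scale used for platelet-sized areas), and shape is summarised by the
circularity

    C = 4 * pi * A / P**2

which is 1 for a perfect circle and decreases for elongated or irregular
regions.  Mitochondria whose central-slice circularity is at or above a
configurable threshold (default 0.90) are flagged *abnormal* — the round,
cristae-depleted phenotype that appears in pre-leukemic platelets —
while irregular mitochondria are *normal*.

The perimeter is estimated as the length of the 0.5 iso-contour of the
binary mask after a light Gaussian anti-aliasing (sigma = 1.5 px by
default).  The raw marching-squares contour of a binary raster
systematically overestimates the perimeter of smooth shapes by ~5%, which
would bias the circularity of a true circle down to ~0.90; the smoothed
sub-pixel contour removes that staircase bias (disk error < 0.01 for radii
>= 15 px) while leaving genuinely irregular outlines irregular.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes, gaussian_filter
from skimage import measure as _skmeasure

__all__ = [
    "OrganelleClass",
    "Group",
    "LabelScene",
    "OrganelleMeasurement",
    "PlateletRecord",
    "MorphometryError",
    "MissingLabelError",
    "DegenerateRegionError",
    "MultiComponentError",
    "OrganelleClassError",
    "SceneValidationError",
    "extract_central_slice",
    "measure_region",
    "classify_mitochondrion",
    "measure_platelet",
    "AREA_SCALE",
    "DEFAULT_PIXEL_SIZE_NM",
    "DEFAULT_CIRCULARITY_THRESHOLD",
    "CONTOUR_SMOOTHING_SIGMA",
    "EPS_RASTER",
]

#: nm^2 per reporting unit: platelet-scale areas are printed in 10^5 nm^2.
AREA_SCALE = 1e5

#: Default physical pixel edge length, nm.  Tomograms are sampled at
#: ~17-19 Angstrom per pixel and binned by two for quantification, giving
#: ~3.6 nm per pixel on the measurement slices.
DEFAULT_PIXEL_SIZE_NM = 3.6

#: Default circularity cutoff separating abnormal (round) from normal
#: (irregular) mitochondria.  The two observed populations sit at ~0.97 and
#: ~0.73; 0.90 is several group standard errors away from both.
DEFAULT_CIRCULARITY_THRESHOLD = 0.90

#: Gaussian sigma (px) applied before extracting the 0.5 iso-contour.
CONTOUR_SMOOTHING_SIGMA = 1.5

#: Raster tolerance on circularity: sub-pixel contours of small rasterized
#: disks can nudge C slightly above 1; values are capped at 1 + EPS_RASTER.
EPS_RASTER = 0.02

#: Regions smaller than this (px) are measured on the unsmoothed contour:
#: anti-aliasing can erase a few-pixel region entirely.
_MIN_PX_FOR_SMOOTHING = 25


class MorphometryError(ValueError):
    """Base class for morphometry failures."""


class MissingLabelError(MorphometryError, KeyError):
    """Requested label id is absent from the scene."""


class DegenerateRegionError(MorphometryError):
    """Region is empty on the chosen slice."""


class MultiComponentError(MorphometryError):
    """Mask holds more than one connected component; split instances first."""


class OrganelleClassError(MorphometryError):
    """Operation applied to an organelle of the wrong class."""


class SceneValidationError(MorphometryError):
    """A LabelScene violates its invariants."""


class OrganelleClass(str, enum.Enum):
    """Segmentation classes annotated in platelet tomograms."""

    PLATELET_BODY = "platelet_body"
    ALPHA_GRANULE = "alpha_granule"
    DENSE_GRANULE = "dense_granule"
    GAMMA_GRANULE = "gamma_granule"
    MITOCHONDRION = "mitochondrion"
    VESICLE = "vesicle"
    OCS = "ocs"
    TUBULE_STRUCTURE = "tubule_structure"
    GLYCOGEN = "glycogen"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


class Group(str, enum.Enum):
    """Cohort groups across AML development in the transplant model."""

    UNIRRADIATED_WT = "unirradiated_wt"
    CONTROL_1WK = "control_1wk"
    CONTROL_3WK = "control_3wk"
    PRE_AML = "pre_aml"
    AML = "aml"

    def __str__(self) -> str:
        return self.value


#: Classes a "ghost" platelet may contain: glycogen and open canalicular
#: system, plus empty vesicles.  No granules, no mitochondria.
GHOST_ALLOWED_CLASSES = frozenset(
    {OrganelleClass.GLYCOGEN, OrganelleClass.OCS, OrganelleClass.VESICLE}
)

_GRANULE_CLASSES = (
    OrganelleClass.ALPHA_GRANULE,
    OrganelleClass.DENSE_GRANULE,
    OrganelleClass.GAMMA_GRANULE,
)


@dataclass
class LabelScene:
    """An integer label map (2D slice or 3D volume) with its class table.

    Label 0 is background.  Every nonzero label present in ``label_map``
    must appear in ``class_table``, exactly one of them with class
    ``platelet_body``.
    """

    label_map: np.ndarray
    pixel_size_nm: float
    class_table: Mapping[int, OrganelleClass]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if not np.issubdtype(self.label_map.dtype, np.integer):
            raise SceneValidationError(
                f"label map must be integer-valued, got dtype {self.label_map.dtype}"
            )
        if self.label_map.ndim not in (2, 3):
            raise SceneValidationError(
                f"label map must be 2D or 3D, got {self.label_map.ndim}D"
            )
        self.class_table = {
            int(k): OrganelleClass(v) for k, v in dict(self.class_table).items()
        }
        self.validate()

    def validate(self) -> None:
        if not self.pixel_size_nm > 0:
            raise SceneValidationError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        present = self.present_labels()
        missing = [l for l in present if l not in self.class_table]
        if missing:
            raise SceneValidationError(
                f"labels {missing} present in the raster but absent from the class table"
            )
        bodies = [
            l for l in present
            if self.class_table[l] is OrganelleClass.PLATELET_BODY
        ]
        if len(bodies) != 1:
            raise SceneValidationError(
                f"scene must contain exactly one platelet_body label, found {len(bodies)}"
            )

    def present_labels(self) -> list[int]:
        """Sorted nonzero labels present in the raster (cached)."""
        cached = getattr(self, "_labels_cache", None)
        if cached is None:
            flat = self.label_map.ravel()
            mx = int(flat.max()) if flat.size else 0
            if 0 < mx < 65536 and int(flat.min()) >= 0:
                present = np.flatnonzero(np.bincount(flat, minlength=mx + 1))
            else:
                present = np.unique(flat)
            cached = [int(l) for l in present if l != 0]
            object.__setattr__(self, "_labels_cache", cached)
        return cached

    @property
    def body_label(self) -> int:
        for l in self.present_labels():
            if self.class_table[l] is OrganelleClass.PLATELET_BODY:
                return l
        raise SceneValidationError("no platelet_body label present")

    @property
    def is_3d(self) -> bool:
        return self.label_map.ndim == 3


@dataclass
class OrganelleMeasurement:
    """Central-slice measurement of one segmented organelle instance.

    ``abnormal`` is a tri-state flag: True/False for mitochondria, None
    (not applicable) for every other class.
    """

    label_id: int
    organelle_class: OrganelleClass
    area_nm2: float
    perimeter_nm: float
    circularity: float
    slice_index: int
    abnormal: bool | None = None

    @property
    def area_1e5nm2(self) -> float:
        return self.area_nm2 / AREA_SCALE


@dataclass
class PlateletRecord:
    """One platelet: whole-cell area, organelle measurements, aggregates.

    Areas are in units of 10^5 nm^2.  ``per_class_area_fraction`` is the
    summed organelle central-slice area divided by the platelet
    central-slice area — the study's per-platelet relative-area convention.
    """

    platelet_id: str
    group: Group | None
    platelet_area_1e5nm2: float
    organelles: list[OrganelleMeasurement]
    per_class_count: dict[OrganelleClass, int]
    per_class_avg_area_1e5nm2: dict[OrganelleClass, float]
    per_class_area_fraction: dict[OrganelleClass, float]
    n_abnormal_mito: int
    has_ts: bool
    is_ghost: bool

    def count(self, cls: OrganelleClass) -> int:
        return self.per_class_count.get(cls, 0)

    def avg_area(self, cls: OrganelleClass) -> float:
        """Mean central-slice area (10^5 nm^2) of one class; NaN if absent."""
        return self.per_class_avg_area_1e5nm2.get(cls, math.nan)

    def area_fraction(self, cls: OrganelleClass) -> float:
        return self.per_class_area_fraction.get(cls, 0.0)


# ---------------------------------------------------------------------------
# central slice extraction
# ---------------------------------------------------------------------------

def extract_central_slice(
    scene: LabelScene,
    label_id: int,
    rule: str = "midpoint",
) -> tuple[np.ndarray, int]:
    """Binary mask of ``label_id`` on the central slice of its z extent.

    For a 2D scene the slice is the scene itself (slice index 0).  For a 3D
    volume the slice defaults to the midpoint of the label's z extent,
    ``(z_min + z_max) // 2``; ``rule="max_area"`` instead picks the z slice
    on which the label covers the most pixels.
    """
    if rule not in ("midpoint", "max_area"):
        raise ValueError(f"unknown central-slice rule {rule!r}")
    hits = scene.label_map == label_id
    if not hits.any():
        raise MissingLabelError(f"label {label_id} not present in scene")
    if scene.label_map.ndim == 2:
        return hits, 0
    per_z = hits.reshape(hits.shape[0], -1).sum(axis=1)
    zs = np.nonzero(per_z)[0]
    if rule == "midpoint":
        z = int((zs.min() + zs.max()) // 2)
    else:
        z = int(np.argmax(per_z))
    mask = hits[z]
    if not mask.any():
        raise DegenerateRegionError(
            f"label {label_id} is empty on its central slice z={z}"
        )
    return mask, z


# ---------------------------------------------------------------------------
# region measurement
# ---------------------------------------------------------------------------

def _isocontour_perimeter_px(mask: np.ndarray, sigma: float) -> float:
    """Length (px) of the 0.5 iso-contour of a binary mask.

    The mask is padded and Gaussian-smoothed before marching squares; if
    smoothing erases the region (possible for few-pixel regions) the raw
    contour is used instead.
    """
    pad = int(math.ceil(3 * sigma)) + 2
    f = np.pad(mask.astype(np.float32), pad)
    if sigma > 0:
        f = gaussian_filter(f, sigma)
    contours = _skmeasure.find_contours(f, 0.5)
    if not contours and sigma > 0:
        return _isocontour_perimeter_px(mask, 0.0)
    total = 0.0
    for c in contours:
        d = np.diff(c, axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def measure_region(
    mask: np.ndarray,
    pixel_size_nm: float,
    smoothing_sigma: float = CONTOUR_SMOOTHING_SIGMA,
) -> tuple[float, float, float]:
    """Area (nm^2), perimeter (nm) and circularity of one 2D region.

    The mask must be nonempty and a single 8-connected component (one label
    = one organelle instance; callers split multi-instance labels first).
    Area is the pixel count scaled by the pixel area; the perimeter is the
    sub-pixel iso-contour length; circularity is ``4*pi*A/P**2`` capped at
    ``1 + EPS_RASTER`` to absorb raster bias on small near-circular regions.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise MorphometryError(f"mask must be 2D, got {mask.ndim}D")
    ys = np.flatnonzero(mask.any(axis=1))
    if ys.size == 0:
        raise DegenerateRegionError("empty mask")
    xs = np.flatnonzero(mask.any(axis=0))
    # crop to the tight bounding box: area and contour length are unchanged
    mask = mask[ys[0]:ys[-1] + 1, xs[0]:xs[-1] + 1]
    npix = int(mask.sum())
    if not pixel_size_nm > 0:
        raise MorphometryError(f"pixel_size_nm must be > 0, got {pixel_size_nm}")
    _, n_components = _skmeasure.label(mask, connectivity=2, return_num=True)
    if n_components > 1:
        raise MultiComponentError(
            f"mask has {n_components} connected components; split instances first"
        )
    if npix < _MIN_PX_FOR_SMOOTHING:
        smoothing_sigma = 0.0
    area_nm2 = npix * pixel_size_nm**2
    perimeter_nm = _isocontour_perimeter_px(mask, smoothing_sigma) * pixel_size_nm
    if perimeter_nm <= 0:
        raise DegenerateRegionError("region has no measurable contour")
    circ = 4.0 * math.pi * area_nm2 / perimeter_nm**2
    circ = min(circ, 1.0 + EPS_RASTER)
    return area_nm2, perimeter_nm, circ


def classify_mitochondrion(
    m: OrganelleMeasurement,
    threshold: float = DEFAULT_CIRCULARITY_THRESHOLD,
) -> bool:
    """Flag a mitochondrion abnormal when its circularity >= threshold.

    Round mitochondria with unfolded cristae sit near C ~ 0.97; normal
    irregular ones near C ~ 0.73, so any threshold well between the two
    populations separates them; the boundary itself counts as abnormal.
    """
    if m.organelle_class is not OrganelleClass.MITOCHONDRION:
        raise OrganelleClassError(
            f"classify_mitochondrion applied to {m.organelle_class.value} "
            f"(label {m.label_id})"
        )
    return m.circularity >= threshold


# ---------------------------------------------------------------------------
# whole-platelet measurement
# ---------------------------------------------------------------------------

def measure_platelet(
    scene: LabelScene,
    group: Group | str | None = None,
    circularity_threshold: float = DEFAULT_CIRCULARITY_THRESHOLD,
    platelet_id: str = "platelet",
    slice_rule: str = "midpoint",
    classes: set[OrganelleClass] | None = None,
) -> PlateletRecord:
    """Measure every labeled organelle of a scene and aggregate per platelet.

    The platelet area is taken from the central slice of the platelet body
    (for a 2D scene, the body mask itself).  Each other labeled instance is
    measured on its own central slice; mitochondria are classified
    abnormal/normal by circularity.  Per-class aggregates (count, mean
    instance area, summed-area fraction of the platelet area) and the
    ghost / tubule-structure flags are derived from the class inventory.

    ``classes`` restricts which organelle classes are *measured* (the study
    quantified mitochondria and alpha/dense granules only); the ghost and
    tubule-structure flags always use the full class inventory.
    """
    if group is not None:
        group = Group(group)
    body = scene.body_label
    _, body_z = extract_central_slice(scene, body, rule=slice_rule)
    # The platelet footprint is the whole cell outline: on a single label
    # map the organelle labels punch holes in the body label, so the body
    # is measured as the filled union of all labels on its central slice.
    plane = scene.label_map if scene.label_map.ndim == 2 else scene.label_map[body_z]
    footprint = binary_fill_holes(plane != 0)
    try:
        body_area_nm2, _, _ = measure_region(footprint, scene.pixel_size_nm)
    except MorphometryError as e:
        raise type(e)(f"platelet body (label {body}): {e}") from e

    # bounding boxes in one pass for 2D scenes (avoids a full-canvas scan
    # per label); 3D scenes go through extract_central_slice per label
    bboxes = None
    if scene.label_map.ndim == 2:
        from scipy.ndimage import find_objects
        bboxes = find_objects(scene.label_map)

    inventory: set[OrganelleClass] = set()
    organelles: list[OrganelleMeasurement] = []
    for label_id in scene.present_labels():
        if label_id == body:
            continue
        cls = scene.class_table[label_id]
        inventory.add(cls)
        if classes is not None and cls not in classes:
            continue
        try:
            if bboxes is not None:
                slc = bboxes[label_id - 1]
                if slc is None:
                    raise MissingLabelError(f"label {label_id} not present")
                mask, z = scene.label_map[slc] == label_id, 0
            else:
                mask, z = extract_central_slice(scene, label_id, rule=slice_rule)
            area, perim, circ = measure_region(mask, scene.pixel_size_nm)
        except MorphometryError as e:
            raise type(e)(f"label {label_id} ({cls.value}): {e}") from e
        m = OrganelleMeasurement(
            label_id=label_id,
            organelle_class=cls,
            area_nm2=area,
            perimeter_nm=perim,
            circularity=circ,
            slice_index=z,
        )
        if cls is OrganelleClass.MITOCHONDRION:
            m.abnormal = classify_mitochondrion(m, circularity_threshold)
        organelles.append(m)

    per_count: dict[OrganelleClass, int] = {}
    per_sum: dict[OrganelleClass, float] = {}
    for m in organelles:
        per_count[m.organelle_class] = per_count.get(m.organelle_class, 0) + 1
        per_sum[m.organelle_class] = per_sum.get(m.organelle_class, 0.0) + m.area_nm2
    per_avg = {
        cls: (per_sum[cls] / per_count[cls]) / AREA_SCALE for cls in per_count
    }
    per_frac = {cls: per_sum[cls] / body_area_nm2 for cls in per_count}

    is_ghost = bool(inventory) and inventory <= GHOST_ALLOWED_CLASSES

    return PlateletRecord(
        platelet_id=platelet_id,
        group=group,
        platelet_area_1e5nm2=body_area_nm2 / AREA_SCALE,
        organelles=organelles,
        per_class_count=per_count,
        per_class_avg_area_1e5nm2=per_avg,
        per_class_area_fraction=per_frac,
        n_abnormal_mito=sum(
            1 for m in organelles if m.abnormal
        ),
        has_ts=OrganelleClass.TUBULE_STRUCTURE in inventory,
        is_ghost=is_ghost,
    )
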
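"""Synthetic ground-truth-labeled platelet scenes and cohorts.

Generates label maps that emulate central slices of segmented platelet
tomograms across five cohort groups of an MLL-AF9 transplant AML model:
un-irradiated wild type, bone-marrow-transplant controls at 1 and 3 weeks,
pre-AML (1 week after leukemic transplant) and frank AML (3 weeks).

The generator reproduces the cohort statistics the downstream stages are
meant to recover:

* per-group platelet central-slice areas (normal, with SD recovered from
  the published SEM and group size);
* per-platelet organelle inventories (alpha granules, dense granules,
  gamma granules, mitochondria, OCS, tubule structures, glycogen) with
  Poisson counts around the group means and gamma-distributed areas;
* a platelet-level abnormal-mitochondrion phenotype in the pre-AML group
  at prevalence 17/72: abnormal mitochondria are near-circular
  (circularity ~0.97) while normal ones are irregular (~0.73), and each
  abnormal mitochondrion is flanked by a cluster of 100-300 nm empty
  vesicles;
* ghost platelets (glycogen + OCS only, ~5x smaller) in 110/120 of the
  AML group, and tubule structures in ~75.5% of normal-type platelets.

Shapes are radial harmonic perturbations of a disk,
``r(theta) = r0 * (1 + amp * sum_k a_k sin(k theta + phi_k))``, with the
amplitude tuned by bisection so the *continuous* outline has the requested
circularity before rasterization.  Scenes default to 7.2 nm/px sampling
(bin-4 of the ~18 Angstrom tomogram pixel) so a typical 75.6 x 10^5 nm^2
platelet fits a 512 px canvas; the canvas auto-grows for larger draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .morphometry import (
    AREA_SCALE,
    Group,
    LabelScene,
    OrganelleClass,
)

__all__ = [
    "SyntheticCohortConfig",
    "RenderParams",
    "GroundTruth",
    "FeasibilityError",
    "CapacityError",
    "make_shape",
    "generate_platelet_scene",
    "generate_cohort",
    "iter_cohort",
    "render_grayscale",
]

logger = logging.getLogger(__name__)

_WT, _C1, _C3, _PRE, _AML = (
    Group.UNIRRADIATED_WT,
    Group.CONTROL_1WK,
    Group.CONTROL_3WK,
    Group.PRE_AML,
    Group.AML,
)


class FeasibilityError(ValueError):
    """Requested shape target cannot be realised (too small / too extreme)."""


class CapacityError(RuntimeError):
    """Organelle placement failed; a larger canvas or body is needed."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_n_per_group() -> dict[Group, int]:
    # Imaged platelet counts: WT and the two leukemic time points are the
    # published group sizes; the control group sizes were not printed and
    # default to 34 each.
    return {_WT: 94, _C1: 34, _C3: 34, _PRE: 72, _AML: 120}


def _default_area_mean_sem() -> dict[Group, tuple[float, float | None]]:
    # Whole-platelet central-slice area, 10^5 nm^2, mean +/- SEM.  The 1-week
    # groups were reported only as ~73.0 with no SEM (SD is borrowed from WT).
    return {
        _WT: (75.6, 1.84),
        _C1: (73.0, None),
        _C3: (68.4, 3.03),
        _PRE: (73.0, None),
        _AML: (15.6, 1.00),
    }


def _default_count_means() -> dict[OrganelleClass, dict[Group, float]]:
    # Published: alpha 15.9 WT vs 11.3 pre-AML; dense 12.5 vs 9.7.  The BMT
    # controls did not differ significantly from pre-AML on granule counts,
    # so they share the pre-AML means.  Gamma granules are uncommon; their
    # count was not printed (mean 2 chosen).
    a = OrganelleClass.ALPHA_GRANULE
    d = OrganelleClass.DENSE_GRANULE
    g = OrganelleClass.GAMMA_GRANULE
    return {
        a: {_WT: 15.9, _C1: 11.3, _C3: 11.3, _PRE: 11.3, _AML: 15.9},
        d: {_WT: 12.5, _C1: 9.7, _C3: 9.7, _PRE: 9.7, _AML: 12.5},
        g: {_WT: 2.0, _C1: 2.0, _C3: 2.0, _PRE: 2.0, _AML: 2.0},
    }


def _default_organelle_area_means() -> dict[OrganelleClass, dict[Group, float]]:
    # Mean instance central-slice area, 10^5 nm^2.  Published: alpha 1.3 WT
    # vs 1.6 pre-AML; dense 0.34 vs 0.31; mitochondria 0.6 WT, 0.5 BMT
    # control, 0.7 pre-AML.  Controls share pre-AML granule areas.
    a = OrganelleClass.ALPHA_GRANULE
    d = OrganelleClass.DENSE_GRANULE
    g = OrganelleClass.GAMMA_GRANULE
    m = OrganelleClass.MITOCHONDRION
    return {
        a: {_WT: 1.3, _C1: 1.6, _C3: 1.6, _PRE: 1.6, _AML: 1.3},
        d: {_WT: 0.34, _C1: 0.31, _C3: 0.31, _PRE: 0.31, _AML: 0.34},
        g: {_WT: 0.45, _C1: 0.45, _C3: 0.45, _PRE: 0.45, _AML: 0.45},
        m: {_WT: 0.6, _C1: 0.5, _C3: 0.5, _PRE: 0.7, _AML: 0.6},
    }


@dataclass
class RenderParams:
    """Grayscale rendering: one contrast level per class plus Gaussian noise."""

    noise_sigma: float = 0.0
    class_levels: dict[str, float] = field(default_factory=lambda: {
        "background": 0.00,
        "platelet_body": 0.20,
        "alpha_granule": 0.35,
        "dense_granule": 0.45,
        "gamma_granule": 0.50,
        "mitochondrion": 0.55,
        "vesicle": 0.65,
        "ocs": 0.75,
        "tubule_structure": 0.85,
        "glycogen": 0.95,
    })


@dataclass
class SyntheticCohortConfig:
    """All generative parameters of a synthetic platelet cohort.

    Defaults reproduce the published study conditions; every field is
    overridable (e.g. from a YAML file via :meth:`from_file`).
    """

    seed: int = 0
    pixel_size_nm: float = 7.2
    min_canvas_px: int = 512
    n_per_group: dict[Group, int] = field(default_factory=_default_n_per_group)
    #: group -> (mean, sem) of platelet central-slice area, 10^5 nm^2
    platelet_area_mean_sem: dict[Group, tuple[float, float | None]] = field(
        default_factory=_default_area_mean_sem)
    organelle_count_means: dict[OrganelleClass, dict[Group, float]] = field(
        default_factory=_default_count_means)
    organelle_area_means_1e5nm2: dict[OrganelleClass, dict[Group, float]] = field(
        default_factory=_default_organelle_area_means)
    #: mitochondrion count per platelet, uniform integer on this range
    mito_count_range: tuple[int, int] = (1, 23)
    #: relative SD of instance areas around their class/group mean
    organelle_area_cv: float = 0.3
    #: probability a pre-AML platelet carries >= 1 abnormal mitochondrion
    abnormal_prevalence: float = 17 / 72
    #: P(exactly one abnormal | >= 1); otherwise uniform on multi range
    abnormal_single_prob: float = 13 / 17
    abnormal_multi_range: tuple[int, int] = (2, 7)
    #: circularity populations (mean, sd, clip_lo, clip_hi)
    circ_abnormal: tuple[float, float, float, float] = (0.968, 0.015, 0.92, 0.995)
    circ_normal: tuple[float, float, float, float] = (0.729, 0.055, 0.45, 0.85)
    #: empty vesicles flanking each abnormal mitochondrion
    vesicle_diameter_nm: tuple[float, float] = (100.0, 300.0)
    vesicles_per_abnormal: tuple[int, int] = (2, 6)
    ghost_fraction_aml: float = 110 / 120
    ts_prevalence: float = 71 / 94
    #: glycogen particles per platelet (Poisson mean) and diameter range, nm
    glycogen_count_mean: float = 25.0
    glycogen_diameter_nm: tuple[float, float] = (20.0, 36.0)
    ocs_count_mean: float = 4.0
    ocs_area_mean_1e5nm2: float = 0.25
    noise: RenderParams = field(default_factory=RenderParams)

    def group_area_sd(self, group: Group) -> float:
        """SD of the platelet-area distribution, recovered as SEM * sqrt(n).

        The published group sizes (not the configured cohort size) convert
        SEM to SD: generating more or fewer scenes must not change the
        per-platelet distribution.  Groups printed without an SEM borrow
        the WT SD.
        """
        published_n = _default_n_per_group()
        mean, sem = self.platelet_area_mean_sem[group]
        if sem is None:
            _, wt_sem = self.platelet_area_mean_sem[_WT]
            return wt_sem * math.sqrt(published_n[_WT])
        return sem * math.sqrt(published_n.get(group, self.n_per_group.get(group, 30)))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if isinstance(obj, dict):
                return {
                    (k.value if isinstance(k, (Group, OrganelleClass)) else k):
                        enc(v) for k, v in obj.items()
                }
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj
        d = asdict(self)
        d["noise"] = {"noise_sigma": self.noise.noise_sigma,
                      "class_levels": dict(self.noise.class_levels)}
        return enc(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = RenderParams(**d["noise"])
        if "n_per_group" in d:
            d["n_per_group"] = {Group(k): int(v) for k, v in d["n_per_group"].items()}
        if "platelet_area_mean_sem" in d:
            d["platelet_area_mean_sem"] = {
                Group(k): (v[0], v[1]) for k, v in d["platelet_area_mean_sem"].items()
            }
        for key in ("organelle_count_means", "organelle_area_means_1e5nm2"):
            if key in d:
                d[key] = {
                    OrganelleClass(c): {Group(g): float(x) for g, x in sub.items()}
                    for c, sub in d[key].items()
                }
        for key in ("mito_count_range", "abnormal_multi_range",
                    "vesicles_per_abnormal", "vesicle_diameter_nm",
                    "glycogen_diameter_nm", "circ_abnormal", "circ_normal"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SyntheticCohortConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        for p, name in [
            (self.abnormal_prevalence, "abnormal_prevalence"),
            (self.abnormal_single_prob, "abnormal_single_prob"),
            (self.ghost_fraction_aml, "ghost_fraction_aml"),
            (self.ts_prevalence, "ts_prevalence"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        for group, (mean, _) in self.platelet_area_mean_sem.items():
            if not mean > 0:
                raise ValueError(f"platelet area mean for {group} must be > 0")


@dataclass
class GroundTruth:
    """Per-label intended properties of one generated scene.

    ``table`` has one row per emitted label: label_id, organelle_class,
    intended_area_nm2, intended_circularity, abnormal (nullable boolean).
    """

    scene_id: str
    group: Group
    is_ghost: bool
    n_abnormal: int
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# radial shape machinery
# ---------------------------------------------------------------------------

_THETA = np.linspace(-math.pi, math.pi, 1025)


def _harmonic_basis(ks, aks, phis):
    """g(theta) = sum a_k sin(k theta + phi_k) and g'(theta), amplitude-free."""
    arg = np.outer(ks, _THETA) + np.asarray(phis)[:, None]
    g = np.asarray(aks) @ np.sin(arg)
    gd = (np.asarray(aks) * np.asarray(ks)) @ np.cos(arg)
    return g, gd


_DTHETA = float(_THETA[1] - _THETA[0])


def _circ_of_curve(r, dr) -> float:
    # closed uniform grid (first == last point): trapezoid = dtheta * (sum - r0)
    r2 = r * r
    area = 0.5 * _DTHETA * (r2.sum() - r2[0])
    sp = np.sqrt(r2 + dr * dr)
    perim = _DTHETA * (sp.sum() - sp[0])
    return 4.0 * math.pi * area / perim**2


def _tune_amplitude(g, gd, target_c: float) -> float:
    """Bisect the perturbation amplitude to hit a continuous circularity."""
    if target_c >= 1.0:
        return 0.0

    def circ(amp):
        return _circ_of_curve(1.0 + amp * g, amp * gd)

    amp_max = 0.85 / abs(min(g.min(), -1e-9))
    if circ(amp_max) > target_c:
        raise FeasibilityError(
            f"circularity target {target_c:.3f} unreachable with these harmonics"
        )
    lo, hi = 0.0, amp_max
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        c = circ(mid)
        if c > target_c:
            lo = mid
        else:
            hi = mid
        if abs(c - target_c) < 5e-4:
            return mid
    return 0.5 * (lo + hi)


def _ellipse_r_table(q: float) -> np.ndarray:
    # polar radius of an ellipse with semi-axes (q, 1)
    return q / np.sqrt(np.cos(_THETA) ** 2 + (q * np.sin(_THETA)) ** 2)


def _ellipse_circ(q: float) -> float:
    r = _ellipse_r_table(q)
    dr = np.gradient(r, _THETA)
    return _circ_of_curve(r, dr)


# monotone lookup q -> C for inverting the ellipse aspect ratio cheaply
_ELL_Q = np.geomspace(1.0, 14.0, 160)
_ELL_C = np.array([_ellipse_circ(q) for q in _ELL_Q])


def _ellipse_q_for_circ(target_c: float) -> float:
    # _ELL_C decreases with q; interp on the reversed table
    return float(np.interp(target_c, _ELL_C[::-1], _ELL_Q[::-1]))


def _rasterize_r_table(r_tab: np.ndarray, area_px: float, rot: float) -> np.ndarray:
    """Rasterize a closed radial outline scaled to a target pixel area."""
    r2 = r_tab * r_tab
    unit_area = 0.5 * _DTHETA * (r2.sum() - r2[0])
    r0 = math.sqrt(area_px / unit_area)
    r_tab = r_tab * r0
    rmax = float(r_tab.max())
    rmin = float(r_tab.min())
    n = int(math.ceil(rmax)) + 1
    ax = np.arange(-n, n + 1, dtype=np.float32)
    dy = ax[:, None]
    dx = ax[None, :]
    rr2 = dy * dy + dx * dx
    if rmax - rmin < 1e-6:  # pure disk: no angular lookup needed
        mask = rr2 <= rmax * rmax
    else:
        mask = rr2 <= (rmin - 1.0) ** 2
        band = (rr2 <= (rmax + 1.0) ** 2) & ~mask
        by, bx = np.nonzero(band)
        th = np.arctan2(ax[by], ax[bx]) - rot
        th = (th + math.pi) % (2 * math.pi) - math.pi
        r_lim = np.interp(th, _THETA, r_tab)
        keep = rr2[by, bx] <= r_lim * r_lim
        mask[by[keep], bx[keep]] = True
    ys, xs = np.nonzero(mask.any(axis=1)), np.nonzero(mask.any(axis=0))
    ys, xs = ys[0], xs[0]
    if ys.size == 0:
        raise FeasibilityError("shape rasterized to an empty mask")
    return mask[ys[0]:ys[-1] + 1, xs[0]:xs[-1] + 1]


_SHAPE_KINDS = ("near_circle", "irregular_blob", "ellipse_granule", "ring_vesicle")


def make_shape(
    kind: str,
    target_area_nm2: float,
    target_circularity: float,
    rng: np.random.Generator,
    pixel_size_nm: float = 7.2,
) -> np.ndarray:
    """A 2D binary mask of the requested kind, area and circularity.

    The outline is tuned on the continuous curve before rasterization, so
    the measured circularity tracks the target to within the raster bias
    (a few hundredths at the organelle scales used here).
    """
    if kind not in _SHAPE_KINDS:
        raise ValueError(f"unknown shape kind {kind!r}")
    if not target_area_nm2 > 0:
        raise FeasibilityError("target area must be positive")
    if not 0.0 < target_circularity <= 1.0:
        raise FeasibilityError(
            f"target circularity must be in (0, 1], got {target_circularity}"
        )
    area_px = target_area_nm2 / pixel_size_nm**2
    if area_px < 12:
        raise FeasibilityError(
            f"target area {target_area_nm2:.0f} nm^2 is under 12 px at "
            f"{pixel_size_nm} nm/px; too coarse to shape"
        )
    if area_px < 80 and target_circularity < 0.6:
        raise FeasibilityError("low-circularity target infeasible at this size")
    rot = rng.uniform(0, 2 * math.pi)
    if kind == "ellipse_granule":
        if target_circularity < _ELL_C[-1]:
            raise FeasibilityError(f"ellipse cannot reach C={target_circularity}")
        r_tab = _ellipse_r_table(_ellipse_q_for_circ(target_circularity))
        return _rasterize_r_table(r_tab, area_px, rot)
    if kind == "ring_vesicle" or target_circularity >= 0.999:
        # empty vesicles are spherical under uniform osmotic pressure: a disk
        r_tab = np.ones_like(_THETA)
        return _rasterize_r_table(r_tab, area_px, rot)
    if kind == "near_circle":
        ks = np.array([2, 3, 4])
        aks = rng.uniform(0.4, 1.0, size=3) / ks
    else:  # irregular_blob
        ks = np.array([2, 3, 4, 5])
        aks = rng.uniform(0.4, 1.0, size=4) / np.sqrt(ks)
    phis = rng.uniform(0, 2 * math.pi, size=len(ks))
    g, gd = _harmonic_basis(ks, aks, phis)
    amp = _tune_amplitude(g, gd, target_circularity)
    return _rasterize_r_table(1.0 + amp * g, area_px, rot)


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

_DILATE = np.ones((5, 5), bool)  # >= 2 px separation between instances


def _place(
    shape_mask: np.ndarray,
    blocked: np.ndarray,
    rng: np.random.Generator,
    tries: int,
    anchor: tuple[int, int] | None = None,
    anchor_radius: float | None = None,
) -> tuple[int, int] | None:
    """Find a top-left corner where shape_mask avoids all blocked pixels."""
    H, W = blocked.shape
    h, w = shape_mask.shape
    if anchor is not None:
        ang = rng.uniform(0, 2 * math.pi, size=tries)
        rad = anchor_radius * np.sqrt(rng.uniform(0, 1, size=tries))
        ys = (anchor[0] + rad * np.sin(ang)).astype(int) - h // 2
        xs = (anchor[1] + rad * np.cos(ang)).astype(int) - w // 2
    else:
        ys = rng.integers(0, max(H - h, 1), size=tries)
        xs = rng.integers(0, max(W - w, 1), size=tries)
    ok = (ys >= 0) & (xs >= 0) & (ys + h <= H) & (xs + w <= W)
    ys, xs = ys[ok], xs[ok]
    # cheap reject: the shape centre almost always lies inside the shape
    free = ~blocked[ys + h // 2, xs + w // 2]
    for y, x in zip(ys[free], xs[free]):
        if not (blocked[y:y + h, x:x + w] & shape_mask).any():
            return int(y), int(x)
    return None


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(200):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


@dataclass
class _Pending:
    cls: OrganelleClass
    kind: str
    area_nm2: float
    circ: float
    abnormal: bool | None = None
    anchor_of: int | None = None  # index into placed abnormal mitochondria
    required: bool = False


def generate_platelet_scene(
    group: Group | str,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    scene_id: str = "scene",
) -> tuple[LabelScene, GroundTruth]:
    """One synthetic platelet central slice with its ground truth.

    The platelet body area is drawn from the group's normal distribution
    (SD = published SEM * sqrt(group n)); organelles are placed inside the
    body without overlap, largest first.  Pre-AML platelets carry abnormal
    mitochondria under the prevalence/multiplicity model, each flanked by a
    cluster of empty vesicles; AML platelets are ghosts with probability
    ``ghost_fraction_aml`` (non-ghost AML platelets resemble WT, so the
    small published AML group mean is realised as a ghost/normal mixture).
    """
    group = Group(group)
    config.validate()
    px = config.pixel_size_nm
    px_area = px * px

    is_ghost = group is _AML and rng.random() < config.ghost_fraction_aml
    if group is _AML and not is_ghost:
        # the rare normal-looking AML platelets match WT size and inventory
        area_group = _WT
    else:
        area_group = group
    mean, _ = config.platelet_area_mean_sem[area_group]
    sd = config.group_area_sd(area_group)
    if is_ghost:
        # ghosts are ~5x smaller; their mean is set so the AML group mean
        # (ghosts + rare normal-sized platelets) matches the published value
        f = config.ghost_fraction_aml
        wt_mean = config.platelet_area_mean_sem[_WT][0]
        aml_mean = config.platelet_area_mean_sem[_AML][0]
        mean = (aml_mean - (1 - f) * wt_mean) / f if f > 0 else aml_mean
        # the ghost component gets a spread of mean/3: the printed group
        # spread cannot hold for a ghost/normal-size mixture (the mixture
        # separation alone exceeds it), and a wider SD would truncate at
        # the low end and bias the group mean upward
        sd = max(mean / 3.0, 1.0)
    body_area_1e5 = _truncnorm(rng, mean, sd, max(1.5, mean / 6), mean + 6 * sd)
    body_area_px = body_area_1e5 * AREA_SCALE / px_area

    body_mask = make_shape(
        "near_circle", body_area_1e5 * AREA_SCALE,
        rng.uniform(0.90, 0.97), rng, px,
    )
    bh, bw = body_mask.shape
    canvas = max(config.min_canvas_px, int(1.15 * max(bh, bw)) + 8)
    label_map = np.zeros((canvas, canvas), dtype=np.int32)
    y0 = (canvas - bh) // 2
    x0 = (canvas - bw) // 2
    label_map[y0:y0 + bh, x0:x0 + bw][body_mask] = 1
    blocked = label_map != 1  # outside the body

    class_table: dict[int, OrganelleClass] = {1: OrganelleClass.PLATELET_BODY}
    gt_rows: list[dict] = [dict(
        label_id=1, organelle_class=OrganelleClass.PLATELET_BODY.value,
        intended_area_nm2=body_area_1e5 * AREA_SCALE,
        intended_circularity=np.nan, abnormal=None,
    )]

    # -- build the inventory ------------------------------------------------
    counts = config.organelle_count_means
    areas = config.organelle_area_means_1e5nm2
    cv = config.organelle_area_cv
    shape_k = 1.0 / cv**2  # gamma-distributed instance areas

    def draw_area(cls: OrganelleClass, grp: Group) -> float:
        m = areas[cls][grp] * AREA_SCALE
        return float(rng.gamma(shape_k, m / shape_k))

    inv_group = _WT if (group is _AML and not is_ghost) else group
    pending: list[_Pending] = []
    n_abnormal = 0
    if not is_ghost:
        n_mito = int(rng.integers(config.mito_count_range[0],
                                  config.mito_count_range[1] + 1))
        if group is _PRE and rng.random() < config.abnormal_prevalence:
            if rng.random() < config.abnormal_single_prob:
                n_abnormal = 1
            else:
                lo, hi = config.abnormal_multi_range
                n_abnormal = int(rng.integers(lo, hi + 1))
            n_mito = max(n_mito, n_abnormal)
        am, asd, alo, ahi = config.circ_abnormal
        nm, nsd, nlo, nhi = config.circ_normal
        for i in range(n_mito):
            abn = i < n_abnormal
            circ = (_truncnorm(rng, am, asd, alo, ahi) if abn
                    else _truncnorm(rng, nm, nsd, nlo, nhi))
            pending.append(_Pending(
                OrganelleClass.MITOCHONDRION,
                "near_circle" if abn else "irregular_blob",
                draw_area(OrganelleClass.MITOCHONDRION, inv_group),
                circ, abnormal=abn, required=abn,
            ))
        for cls, kind, clo, chi in [
            (OrganelleClass.ALPHA_GRANULE, "irregular_blob", 0.60, 0.90),
            (OrganelleClass.DENSE_GRANULE, "ellipse_granule", 0.85, 0.97),
            (OrganelleClass.GAMMA_GRANULE, "irregular_blob", 0.55, 0.80),
        ]:
            for _ in range(rng.poisson(counts[cls][inv_group])):
                pending.append(_Pending(
                    cls, kind, draw_area(cls, inv_group),
                    rng.uniform(clo, chi),
                ))
        if rng.random() < config.ts_prevalence:
            pending.append(_Pending(
                OrganelleClass.TUBULE_STRUCTURE, "irregular_blob",
                rng.gamma(shape_k, 1.0 * AREA_SCALE / shape_k),
                rng.uniform(0.45, 0.65),
            ))
    # OCS and glycogen occur in every platelet, ghost or not
    for _ in range(rng.poisson(config.ocs_count_mean) + 1):
        pending.append(_Pending(
            OrganelleClass.OCS, "irregular_blob",
            rng.gamma(shape_k, config.ocs_area_mean_1e5nm2 * AREA_SCALE / shape_k),
            rng.uniform(0.45, 0.75),
        ))
    if is_ghost and rng.random() < 0.5:
        # some ghosts retain a few empty vacuole vesicles
        dlo, dhi = config.vesicle_diameter_nm
        for _ in range(rng.poisson(3)):
            d = rng.uniform(dlo, dhi)
            pending.append(_Pending(
                OrganelleClass.VESICLE, "ring_vesicle",
                math.pi * (d / 2) ** 2, 1.0,
            ))

    # -- place: abnormal mitochondria first, then the rest largest-first ----
    abnormal_first = [p for p in pending if p.required]
    rest = sorted((p for p in pending if not p.required),
                  key=lambda p: -p.area_nm2)
    next_label = 2
    abn_centers: list[tuple[int, int]] = []
    n_skipped = 0

    def stamp(shape_mask, y, x, cls) -> int:
        nonlocal next_label
        label_map[y:y + shape_mask.shape[0], x:x + shape_mask.shape[1]][shape_mask] = next_label
        dil = binary_dilation(shape_mask, _DILATE)
        blocked[y:y + shape_mask.shape[0], x:x + shape_mask.shape[1]] |= dil
        class_table[next_label] = cls
        next_label += 1
        return next_label - 1

    for p in abnormal_first + rest:
        try:
            m = make_shape(p.kind, p.area_nm2, p.circ, rng, px)
        except FeasibilityError:
            n_skipped += 1
            continue
        pos = _place(m, blocked, rng, tries=400 if p.required else 150)
        if pos is None:
            if p.required:
                raise CapacityError(
                    f"could not place a required {p.cls.value} in scene "
                    f"{scene_id}; consider a larger canvas or body"
                )
            n_skipped += 1
            continue
        lab = stamp(m, *pos, p.cls)
        gt_rows.append(dict(
            label_id=lab, organelle_class=p.cls.value,
            intended_area_nm2=p.area_nm2, intended_circularity=p.circ,
            abnormal=p.abnormal,
        ))
        if p.abnormal:
            abn_centers.append((pos[0] + m.shape[0] // 2,
                                pos[1] + m.shape[1] // 2))

    # vesicle clusters flanking each abnormal mitochondrion
    dlo, dhi = config.vesicle_diameter_nm
    vlo, vhi = config.vesicles_per_abnormal
    for cy, cx in abn_centers:
        for _ in range(int(rng.integers(vlo, vhi + 1))):
            d = rng.uniform(dlo, dhi)
            m = make_shape("ring_vesicle", math.pi * (d / 2) ** 2, 1.0, rng, px)
            pos = _place(m, blocked, rng, tries=80, anchor=(cy, cx),
                         anchor_radius=3.5 * math.sqrt(body_area_px) / 20 + 60)
            if pos is None:
                pos = _place(m, blocked, rng, tries=80)
            if pos is None:
                n_skipped += 1
                continue
            lab = stamp(m, *pos, OrganelleClass.VESICLE)
            gt_rows.append(dict(
                label_id=lab, organelle_class=OrganelleClass.VESICLE.value,
                intended_area_nm2=math.pi * (d / 2) ** 2,
                intended_circularity=1.0, abnormal=None,
            ))

    # glycogen particles: small disks, plentiful and cheap
    glo, ghi = config.glycogen_diameter_nm
    for _ in range(rng.poisson(config.glycogen_count_mean)):
        d = rng.uniform(glo, ghi)
        r_px = max(d / 2 / px, 1.5)
        n = int(math.ceil(r_px)) + 1
        ax = np.arange(-n, n + 1, dtype=np.float32)
        m = np.hypot(ax[:, None], ax[None, :]) <= r_px
        pos = _place(m, blocked, rng, tries=40)
        if pos is None:
            n_skipped += 1
            continue
        lab = stamp(m, *pos, OrganelleClass.GLYCOGEN)
        gt_rows.append(dict(
            label_id=lab, organelle_class=OrganelleClass.GLYCOGEN.value,
            intended_area_nm2=math.pi * (d / 2) ** 2,
            intended_circularity=1.0, abnormal=None,
        ))

    if n_skipped:
        logger.debug("scene %s: skipped %d organelles for lack of space",
                     scene_id, n_skipped)

    scene = LabelScene(
        label_map=label_map,
        pixel_size_nm=px,
        class_table=class_table,
        metadata={"scene_id": scene_id, "group": group.value,
                  "synthetic": True, "is_ghost": is_ghost,
                  "n_abnormal": n_abnormal},
    )
    gt = GroundTruth(
        scene_id=scene_id, group=group, is_ghost=is_ghost,
        n_abnormal=n_abnormal,
        table=pd.DataFrame(gt_rows).astype({"abnormal": object}),
    )
    return scene, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

_GROUP_ORDER = [_WT, _C1, _C3, _PRE, _AML]


def iter_cohort(
    config: SyntheticCohortConfig,
    groups: Sequence[Group] | None = None,
) -> Iterator[tuple[LabelScene, GroundTruth]]:
    """Stream a cohort scene by scene (memory-safe for large cohorts).

    Scene i of a given group is generated from its own child seed of
    ``config.seed``, so the stream is reproducible and independent of which
    groups are requested.
    """
    config.validate()
    groups = [Group(g) for g in (groups or _GROUP_ORDER)]
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(_GROUP_ORDER))
    for group, child in zip(_GROUP_ORDER, children):
        if group not in groups:
            continue
        n = config.n_per_group.get(group, 0)
        for i, ss in enumerate(child.spawn(n)):
            rng = np.random.default_rng(ss)
            scene_id = f"{group.value}_{i:05d}"
            yield generate_platelet_scene(group, config, rng, scene_id=scene_id)


def generate_cohort(
    config: SyntheticCohortConfig,
    groups: Sequence[Group] | None = None,
) -> tuple[list[tuple[LabelScene, GroundTruth]], pd.DataFrame]:
    """Materialise a cohort plus a manifest linking scenes to ground truth.

    Holds every scene in memory; for cohorts of thousands of platelets use
    :func:`iter_cohort`.
    """
    scenes = list(iter_cohort(config, groups))
    manifest = pd.DataFrame([
        dict(scene_id=gt.scene_id, group=gt.group.value,
             n_labels=len(gt.table), is_ghost=gt.is_ghost,
             n_abnormal=gt.n_abnormal)
        for _, gt in scenes
    ], columns=["scene_id", "group", "n_labels", "is_ghost", "n_abnormal"])
    return scenes, manifest


def render_grayscale(
    scene: LabelScene,
    noise: RenderParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Flat-contrast grayscale rendering of a label scene.

    Each class gets its configured contrast level; optional additive
    Gaussian noise on top.  Ground truth is unaffected.  With zero noise
    the label map is exactly recoverable by thresholding between levels.
    """
    noise = noise or RenderParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    max_label = int(scene.label_map.max())
    lut = np.full(max_label + 1, noise.class_levels["background"], dtype=np.float32)
    for lab, cls in scene.class_table.items():
        if lab <= max_label:
            lut[lab] = noise.class_levels[cls.value]
    img = lut[scene.label_map]
    if noise.noise_sigma > 0:
        img = img + rng.normal(0.0, noise.noise_sigma, size=img.shape).astype(np.float32)
    return img
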
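"""Region measurement, circularity calibration, and platelet aggregation."""

import math

import numpy as np
import pytest
from skimage import draw

from pltmorph import (
    LabelScene,
    OrganelleClass,
    OrganelleMeasurement,
    classify_mitochondrion,
    extract_central_slice,
    measure_platelet,
    measure_region,
)
from pltmorph.morphometry import (
    DegenerateRegionError,
    MissingLabelError,
    MultiComponentError,
    OrganelleClassError,
    SceneValidationError,
)

from conftest import disk_mask, ellipse_mask, scene_with_disks


def ramanujan_circularity(a: float, b: float) -> float:
    """Independent oracle: C of an ellipse from A = pi*a*b and Ramanujan's
    perimeter approximation P ~ pi*[3(a+b) - sqrt((3a+b)(a+3b))]."""
    area = math.pi * a * b
    perim = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
    return 4 * math.pi * area / perim**2


class TestMeasureRegion:
    def test_analytic_circle_is_exactly_one(self):
        # the defining identity: plugging A = pi r^2, P = 2 pi r into
        # 4*pi*A/P^2 gives exactly 1 for any radius
        for r in (1.0, 50.0, 1234.5):
            assert 4 * math.pi * (math.pi * r**2) / (2 * math.pi * r) ** 2 == pytest.approx(1.0, abs=1e-12)

    def test_rasterized_disk_oracle(self):
        r = 50
        area, perim, circ = measure_region(disk_mask(r), pixel_size_nm=1.0)
        assert area == pytest.approx(math.pi * r**2, rel=0.01)
        assert perim == pytest.approx(2 * math.pi * r, rel=0.02)
        assert 0.98 <= circ <= 1.02

    def test_rasterized_ellipse_matches_ramanujan(self):
        a, b = 100, 50
        oracle = ramanujan_circularity(a, b)
        assert oracle == pytest.approx(0.841, abs=0.001)
        _, _, circ = measure_region(ellipse_mask(a, b), pixel_size_nm=1.0)
        assert circ == pytest.approx(oracle, abs=0.03)

    def test_scale_invariance(self):
        m = ellipse_mask(40, 25)
        a1, p1, c1 = measure_region(m, pixel_size_nm=2.0)
        a2, p2, c2 = measure_region(m, pixel_size_nm=4.0)
        assert a2 == pytest.approx(4 * a1, rel=1e-12)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)
        assert abs(c1 - c2) < 1e-9

    def test_resolution_convergence_of_disk_circularity(self):
        radii = [10, 15, 25, 40, 60, 100, 150, 200]
        errs = []
        for r in radii:
            _, _, c = measure_region(disk_mask(r), pixel_size_nm=1.0)
            errs.append(abs(c - 1.0))
        # monotone decrease allowing small raster jitter
        for e_prev, e_next in zip(errs, errs[1:]):
            assert e_next <= e_prev + 0.005
        for r, e in zip(radii, errs):
            if r >= 100:
                assert e < 0.01

    def test_isoperimetric_ordering_at_equal_area(self):
        r = 60
        target_area = math.pi * r**2
        disk = disk_mask(r)
        b = math.sqrt(target_area / (2 * math.pi))  # 2:1 ellipse
        ellipse = ellipse_mask(2 * b, b)
        side = int(round(math.sqrt(target_area)))
        square = np.zeros((side + 16, side + 16), dtype=bool)
        square[8:8 + side, 8:8 + side] = True
        _, _, c_disk = measure_region(disk, 1.0)
        _, _, c_ell = measure_region(ellipse, 1.0)
        _, _, c_sq = measure_region(square, 1.0)
        assert c_disk > c_ell
        assert c_disk > c_sq
        assert c_sq == pytest.approx(math.pi / 4, abs=0.05)

    def test_empty_and_multicomponent_masks_error(self):
        with pytest.raises(DegenerateRegionError):
            measure_region(np.zeros((8, 8), dtype=bool), 1.0)
        two = np.zeros((30, 30), dtype=bool)
        two[2:8, 2:8] = True
        two[20:26, 20:26] = True
        with pytest.raises(MultiComponentError):
            measure_region(two, 1.0)


class TestCentralSlice:
    def test_2d_scene_is_its_own_slice(self):
        scene = scene_with_disks(40, [(OrganelleClass.MITOCHONDRION, (40, 40), 8)])
        mask, z = extract_central_slice(scene, 2)
        assert z == 0
        assert mask.sum() == (scene.label_map == 2).sum()

    def test_sphere_midpoint_is_equatorial_disk(self):
        vol = np.zeros((40, 40, 40), dtype=np.int32)
        zz, yy, xx = np.mgrid[:40, :40, :40]
        sphere = (zz - 15) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 5**2
        vol[sphere] = 5
        vol[0, 0, 0] = 1  # token platelet body so the scene validates
        scene = LabelScene(vol, 1.0, {1: "platelet_body", 5: "mitochondrion"})
        mask, z = extract_central_slice(scene, 5)
        assert z == 15
        np.testing.assert_array_equal(mask, sphere[15])

    def test_ellipsoid_midsection_matches_analytic_ellipse(self):
        # half-axes (cz, ay, ax): mid-section is an ellipse of area pi*ay*ax
        cz, ay, ax_ = 12, 16, 9
        n = 48
        zz, yy, xx = np.mgrid[:n, :n, :n]
        ell = (((zz - 24) / cz) ** 2 + ((yy - 24) / ay) ** 2
               + ((xx - 24) / ax_) ** 2) <= 1.0
        vol = np.where(ell, 7, 0).astype(np.int32)
        vol[0, 0, 0] = 1
        scene = LabelScene(vol, 1.0, {1: "platelet_body", 7: "mitochondrion"})
        mask, z = extract_central_slice(scene, 7)
        assert z == 24
        assert mask.sum() == pytest.approx(math.pi * ay * ax_, rel=0.03)

    def test_max_area_rule_and_missing_label(self):
        scene = scene_with_disks(30, [(OrganelleClass.VESICLE, (30, 30), 5)])
        with pytest.raises(MissingLabelError):
            extract_central_slice(scene, 99)
        mask, _ = extract_central_slice(scene, 2, rule="max_area")
        assert mask.any()


class TestClassification:
    @pytest.mark.parametrize("circ,expected", [
        (0.9681, True),   # mean of the abnormal (round) population
        (0.7288, False),  # mean of the normal (irregular) population
        (0.90, True),     # boundary counts as abnormal (>= convention)
    ])
    def test_threshold_classification(self, circ, expected):
        m = OrganelleMeasurement(1, OrganelleClass.MITOCHONDRION,
                                 6e4, 900.0, circ, 0)
        assert classify_mitochondrion(m, threshold=0.90) is expected

    def test_non_mitochondrion_rejected(self):
        m = OrganelleMeasurement(1, OrganelleClass.ALPHA_GRANULE,
                                 6e4, 900.0, 0.95, 0)
        with pytest.raises(OrganelleClassError):
            classify_mitochondrion(m)


class TestMeasurePlatelet:
    def test_mito_count_and_average_area(self):
        scene = scene_with_disks(80, [
            (OrganelleClass.MITOCHONDRION, (50, 50), 8),
            (OrganelleClass.MITOCHONDRION, (50, 110), 10),
            (OrganelleClass.MITOCHONDRION, (110, 80), 12),
        ])
        rec = measure_platelet(scene)
        mito = OrganelleClass.MITOCHONDRION
        assert rec.count(mito) == 3
        areas = [m.area_nm2 for m in rec.organelles]
        assert rec.avg_area(mito) * 1e5 == pytest.approx(np.mean(areas))
        # aggregation consistency: avg * count == summed area
        assert rec.avg_area(mito) * rec.count(mito) * 1e5 == pytest.approx(sum(areas))

    def test_area_fraction_matches_pixel_count_oracle(self):
        scene = scene_with_disks(100, [
            (OrganelleClass.MITOCHONDRION, (70, 70), 20),
            (OrganelleClass.MITOCHONDRION, (140, 120), 25),
        ])
        body_px = (scene.label_map == 1).sum() + (scene.label_map > 1).sum()
        mito_px = (scene.label_map > 1).sum()
        rec = measure_platelet(scene)
        frac = rec.area_fraction(OrganelleClass.MITOCHONDRION)
        assert frac == pytest.approx(mito_px / body_px, rel=1e-9)
        assert 0.0 <= frac <= 1.0

    def test_glycogen_ocs_only_is_ghost(self):
        scene = scene_with_disks(60, [
            (OrganelleClass.GLYCOGEN, (40, 40), 3),
            (OrganelleClass.GLYCOGEN, (80, 70), 3),
            (OrganelleClass.OCS, (60, 85), 7),
        ])
        rec = measure_platelet(scene)
        assert rec.is_ghost
        for cls in (OrganelleClass.ALPHA_GRANULE, OrganelleClass.DENSE_GRANULE,
                    OrganelleClass.GAMMA_GRANULE, OrganelleClass.MITOCHONDRION):
            assert rec.count(cls) == 0

    def test_normal_platelet_is_not_ghost_and_ts_flag(self):
        scene = scene_with_disks(60, [
            (OrganelleClass.ALPHA_GRANULE, (40, 40), 10),
            (OrganelleClass.TUBULE_STRUCTURE, (80, 70), 8),
        ])
        rec = measure_platelet(scene)
        assert not rec.is_ghost
        assert rec.has_ts

    def test_scene_invariants_enforced(self):
        bad = np.zeros((20, 20), dtype=np.int32)
        bad[5:10, 5:10] = 3  # label 3 not in the class table
        with pytest.raises(SceneValidationError):
            LabelScene(bad, 1.0, {1: "platelet_body"})
        with pytest.raises(SceneValidationError):
            LabelScene(np.ones((4, 4), dtype=np.int32), -1.0,
                       {1: "platelet_body"})
        with pytest.raises(SceneValidationError):  # no platelet body at all
            LabelScene(np.ones((4, 4), dtype=np.int32), 1.0,
                       {1: "mitochondrion"})
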
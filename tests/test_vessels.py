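"""Vessel morphometry: Feret geometry, lumen segmentation, V/EVTI."""

import math

import numpy as np
import pytest

from glutmorph import (
    CalibratedField,
    GeometryError,
    MeasurementError,
    compute_vevti,
    measure_lumens,
    measure_vessel_field,
    min_feret,
    render_field,
    segment_lumens,
)
from glutmorph.cohort import CD31_TISSUE_RGB, VESSEL_FIELD_AREA_UM2, LumenParam, _finish
from glutmorph.vessels import Lumen, feret_diameters, pixel_outline_points


def scan_min_feret(points, step_deg=0.01):
    """Independent oracle: minimum projected width over a fine rotation scan.

    The width function of a polygon has a V-shaped kink at its minimizer, so
    the coarse 0.01-degree scan is followed by a ternary-search refinement of
    the bracketing interval (the function is unimodal there)."""
    points = np.asarray(points, dtype=float)

    def width(theta):
        proj = points @ np.array([np.cos(theta), np.sin(theta)])
        return proj.max() - proj.min()

    thetas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    proj = dirs @ points.T
    widths = proj.max(axis=1) - proj.min(axis=1)
    i = int(np.argmin(widths))
    lo, hi = thetas[max(i - 1, 0)], thetas[min(i + 1, len(thetas) - 1)]
    for _ in range(80):
        m1 = lo + (hi - lo) / 3
        m2 = hi - (hi - lo) / 3
        if width(m1) <= width(m2):
            hi = m2
        else:
            lo = m1
    return float(min(widths[i], width((lo + hi) / 2)))


def random_convex_polygon(rng, n_points=12, scale=10.0):
    from scipy.spatial import ConvexHull

    pts = rng.normal(0, scale, size=(n_points, 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]


class TestFeret:
    def test_axis_aligned_square(self):
        square = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        assert min_feret(square) == pytest.approx(10.0)

    def test_rotated_square(self):
        c, s = math.cos(0.41), math.sin(0.41)
        square = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        rotated = square @ np.array([[c, s], [-s, c]])
        assert min_feret(rotated) == pytest.approx(10.0)

    def test_digital_disk_width_within_one_pixel(self):
        r = 20.3
        yy, xx = np.mgrid[0:64, 0:64]
        mask = (xx - 32.0) ** 2 + (yy - 32.0) ** 2 <= r**2
        coords = np.argwhere(mask)
        width = min_feret(pixel_outline_points(coords))
        assert abs(width - 2 * r) <= 1.0

    def test_min_never_exceeds_max(self, rng):
        for _ in range(20):
            poly = random_convex_polygon(rng)
            lo, hi = feret_diameters(poly)
            assert lo <= hi + 1e-12

    def test_calipers_agree_with_rotation_scan_oracle(self, rng):
        """Exact rotating calipers vs a 0.01-degree rotation scan."""
        for _ in range(100):
            poly = random_convex_polygon(rng, n_points=int(rng.integers(4, 30)))
            exact = min_feret(poly)
            scanned = scan_min_feret(poly)
            assert abs(exact - scanned) / scanned < 1e-6

    def test_degenerate_inputs(self):
        with pytest.raises(GeometryError):
            min_feret(np.empty((0, 2)))
        assert min_feret(np.array([[1.0, 2.0]])) == 0.0
        # collinear points have zero width
        assert min_feret(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])) == pytest.approx(0.0)


def _cd31_field(cohort, field_id):
    gt = cohort.vessel_ground_truth(field_id)
    rendered = render_field(gt)
    fld = CalibratedField(
        rendered.image,
        gt.calibration_um2_per_px,
        VESSEL_FIELD_AREA_UM2,
        provenance={"field_id": field_id},
    )
    return gt, rendered, fld


class TestSegmentation:
    def test_three_isolated_lumens_give_three_labels(self):
        params = [
            LumenParam(10.0, 12.0, 0.3, (60.0, 60.0)),
            LumenParam(12.0, 16.0, 1.2, (160.0, 70.0)),
            LumenParam(9.0, 9.0, 0.0, (110.0, 170.0)),
        ]
        from glutmorph.cohort import FieldGroundTruth

        gt = FieldGroundTruth(
            field_id="synthetic-3",
            style="CD31_stain",
            calibration_um2_per_px=1.0,
            image_size_px=224,
            render_seed=5,
            true_lumen_params=params,
        )
        rendered = render_field(gt)
        fld = CalibratedField(rendered.image, 1.0, 224.0**2)
        labels = segment_lumens(fld)
        assert labels.max() == 3

    def test_blank_tissue_has_no_lumens(self, rng):
        img = np.empty((128, 128, 3), dtype=np.float64)
        img[:] = CD31_TISSUE_RGB
        fld = CalibratedField(_finish(img, rng), 1.0, 128.0**2)
        assert segment_lumens(fld).max() == 0

    def test_label_counts_match_generator(self, small_cohort):
        """Lumen count recovered on renders of random synthetic fields."""
        ok = 0
        fids = small_cohort.vessel_fields.field_id.iloc[:50]
        for fid in fids:
            gt, rendered, fld = _cd31_field(small_cohort, fid)
            labels = segment_lumens(fld)
            ok += labels.max() == len(gt.true_lumen_params)
        assert ok >= 0.95 * len(fids)


class TestVevti:
    def _lumen(self, corrected):
        d = 2 * math.sqrt(corrected / math.pi)
        return Lumen(
            pixel_area_um2=corrected,
            min_feret_um=d,
            max_feret_um=d,
            corrected_area_um2=corrected,
            centroid_um=(0.0, 0.0),
        )

    def test_no_lumens_gives_zero(self):
        assert compute_vevti([], 1000.0).vevti == 0.0

    def test_half_area_gives_ratio_one(self):
        m = compute_vevti([self._lumen(500.0)], 1000.0)
        assert m.vevti == pytest.approx(1.0)

    def test_vascular_area_must_be_below_calibrated(self):
        with pytest.raises(MeasurementError):
            compute_vevti([self._lumen(1200.0)], 1000.0)

    def test_monotone_in_lumen_area(self):
        base = [self._lumen(100.0), self._lumen(50.0)]
        bigger = [self._lumen(120.0), self._lumen(50.0)]
        assert compute_vevti(bigger, 1000.0).vevti > compute_vevti(base, 1000.0).vevti

    def test_recovery_against_generator_truth(self, small_cohort):
        rels = []
        for fid in small_cohort.vessel_fields.field_id.iloc[:20]:
            gt, rendered, fld = _cd31_field(small_cohort, fid)
            m = measure_vessel_field(fld)
            rels.append(abs(m.vevti - gt.true_vevti) / gt.true_vevti)
        assert max(rels) < 0.05

    def test_feret_correction_shrinks_oblique_sections(self, small_cohort):
        """Corrected (circular) areas never exceed the raw pixel area of a
        clearly elongated lumen, nor the max-Feret circle."""
        fid = small_cohort.vessel_fields.field_id.iloc[0]
        gt, rendered, fld = _cd31_field(small_cohort, fid)
        lumens = measure_lumens(segment_lumens(fld), fld.calibration_um2_per_px)
        assert lumens
        for lum in lumens:
            assert lum.corrected_area_um2 <= math.pi * (lum.max_feret_um / 2) ** 2 + 1e-9
            if lum.max_feret_um > 1.15 * lum.min_feret_um:
                assert lum.corrected_area_um2 <= lum.pixel_area_um2

    def test_rotating_field_90_degrees_changes_little(self, small_cohort):
        fid = small_cohort.vessel_fields.field_id.iloc[2]
        gt, rendered, fld = _cd31_field(small_cohort, fid)
        m = measure_vessel_field(fld)
        rot = CalibratedField(
            np.ascontiguousarray(np.rot90(rendered.image)),
            gt.calibration_um2_per_px,
            VESSEL_FIELD_AREA_UM2,
        )
        m_rot = measure_vessel_field(rot)
        assert abs(m_rot.vevti - m.vevti) / m.vevti < 0.02
        um_per_px = math.sqrt(gt.calibration_um2_per_px)
        ferets = sorted(l.min_feret_um for l in m.lumens)
        ferets_rot = sorted(l.min_feret_um for l in m_rot.lumens)
        assert len(ferets) == len(ferets_rot)
        assert np.max(np.abs(np.array(ferets) - np.array(ferets_rot))) < 2 * um_per_px
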
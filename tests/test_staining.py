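"""Stain quantification: saturation channel, thresholding, calibrated areas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from glutmorph import (
    AggregationError,
    CalibratedField,
    FormatError,
    MeasurementError,
    average_replicates,
    measure_field,
    quantify_field,
    render_field,
    saturation_channel,
    simulate_observer_readings,
    threshold_stain,
)
from glutmorph.cohort import STAIN_FIELD_AREA_UM2
from glutmorph.staining import StainMeasurement


def _field(image, calibration=1.0, area=None, **prov):
    area = area if area is not None else image.shape[0] * image.shape[1] * calibration
    return CalibratedField(image, calibration, area, provenance=prov)


class TestSaturationChannel:
    def test_uniform_grey_maps_to_zero(self):
        img = np.full((8, 8, 3), 128, dtype=np.uint8)
        assert (saturation_channel(img) == 0).all()

    def test_pure_red_maps_to_255(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[..., 0] = 255
        assert saturation_channel(img) == pytest.approx(255.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hnp.arrays(np.uint8, (6, 5, 3)))
    def test_matches_closed_form_oracle(self, img):
        """Per-pixel agreement with (max - min) / max scaled to 255."""
        got = saturation_channel(img)
        f = img.astype(float)
        mx, mn = f.max(axis=-1), f.min(axis=-1)
        expected = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1), 0.0) * 255.0
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_non_rgb_rejected(self):
        with pytest.raises(FormatError):
            saturation_channel(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(FormatError):
            saturation_channel(np.zeros((4, 4, 3), dtype=np.float64))


class TestThresholding:
    def test_otsu_separates_bimodal_histogram(self):
        sat = np.concatenate([np.full(500, 40.0), np.full(500, 200.0)])
        sat = sat.reshape(20, 50)
        result = threshold_stain(sat)
        assert 40.0 < result.threshold < 200.0
        assert result.mask.sum() == 500

    def test_all_zero_saturation_gives_empty_mask(self):
        result = threshold_stain(np.zeros((16, 16)))
        assert not result.mask.any()

    def test_constant_histogram_falls_back_and_flags(self):
        with pytest.warns(UserWarning, match="Otsu undefined"):
            result = threshold_stain(np.full((16, 16), 120.0))
        assert result.flagged
        assert result.mask.all()  # 120 > fallback 64

    def test_fixed_method_requires_valid_level(self):
        sat = np.zeros((4, 4))
        with pytest.raises(MeasurementError):
            threshold_stain(sat, method="fixed")
        assert threshold_stain(sat, method="fixed", fixed_level=10).threshold == 10

    def test_raising_threshold_never_increases_fraction(self, small_cohort):
        """Monotonicity of the stained fraction in the threshold level."""
        gt = small_cohort.stain_ground_truth(small_cohort.stain_fields.field_id.iloc[0])
        sat = saturation_channel(render_field(gt).image)
        fractions = [
            threshold_stain(sat, method="fixed", fixed_level=lv).mask.mean()
            for lv in range(0, 256, 16)
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestMeasureField:
    def test_full_mask_recovers_calibrated_area(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        fld = _field(img, calibration=STAIN_FIELD_AREA_UM2 / 64**2, area=STAIN_FIELD_AREA_UM2)
        m = measure_field(fld, np.ones((64, 64), dtype=bool))
        assert m.stained_fraction == 1.0
        assert m.stained_area_um2 == pytest.approx(134755.0)

    def test_empty_mask_gives_zero(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        m = measure_field(_field(img), np.zeros((8, 8), dtype=bool))
        assert m.stained_fraction == 0.0

    def test_checkerboard_gives_exactly_half(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        mask = np.indices((8, 8)).sum(axis=0) % 2 == 0
        assert measure_field(_field(img), mask).stained_fraction == 0.5

    def test_shape_mismatch_rejected(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        with pytest.raises(MeasurementError):
            measure_field(_field(img), np.zeros((4, 4), dtype=bool))

    def test_scale_invariance_of_fraction(self):
        """Doubling the pixel calibration doubles areas, not fractions."""
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        mask = np.zeros((16, 16), dtype=bool)
        mask[:4] = True
        m1 = measure_field(_field(img, calibration=1.0), mask)
        m2 = measure_field(_field(img, calibration=2.0), mask)
        assert m2.stained_fraction == m1.stained_fraction
        assert m2.stained_area_um2 == pytest.approx(2 * m1.stained_area_um2)


class TestRecoveryFromRenderings:
    def test_mask_overlaps_ground_truth(self, small_cohort):
        """Jaccard overlap between the thresholded stain mask and the
        generator's own mask."""
        gt = small_cohort.stain_ground_truth(small_cohort.stain_fields.field_id.iloc[1])
        rendered = render_field(gt)
        fld = _field(rendered.image, calibration=gt.calibration_um2_per_px)
        from glutmorph.staining import hue_gated_saturation

        mask = threshold_stain(hue_gated_saturation(rendered.image)).mask
        intersection = (mask & rendered.stain_mask).sum()
        union = (mask | rendered.stain_mask).sum()
        assert intersection / union >= 0.95

    def test_fraction_recovery_across_fields(self, small_cohort):
        errors = []
        for fid in small_cohort.stain_fields.field_id.iloc[:20]:
            gt = small_cohort.stain_ground_truth(fid)
            rendered = render_field(gt)
            fld = _field(rendered.image, calibration=gt.calibration_um2_per_px)
            m = quantify_field(fld)
            errors.append(abs(m.stained_fraction - gt.true_stain_fraction))
        assert np.mean(errors) < 0.02


class TestAverageReplicates:
    def _meas(self, fraction, observer=None, replicate=None, **prov):
        p = dict(prov)
        if observer is not None:
            p["observer"] = observer
        if replicate is not None:
            p["replicate"] = replicate
        return StainMeasurement(
            stained_area_um2=fraction * 100.0,
            stained_fraction=fraction,
            threshold_used=80.0,
            provenance=p,
        )

    def test_mean_of_two(self):
        m = average_replicates([self._meas(0.2, 1, 1, field="f1"), self._meas(0.4, 2, 1, field="f1")])
        assert m.stained_fraction == pytest.approx(0.3)
        assert m.provenance["consensus"]

    def test_single_measurement_is_identity(self):
        only = self._meas(0.37)
        assert average_replicates([only]) is only

    def test_mixed_provenance_rejected(self):
        with pytest.raises(AggregationError):
            average_replicates([self._meas(0.2, field="f1"), self._meas(0.4, field="f2")])

    def test_consensus_of_simulated_readings(self):
        """Averaging observer replicates recovers the underlying value."""
        readings = simulate_observer_readings(0.25, observers=2, replicates=3, noise_sd=0.01, seed=9)
        ms = [self._meas(x, o, r, field="f") for (o, r), x in np.ndenumerate(readings)]
        assert average_replicates(ms).stained_fraction == pytest.approx(0.25, abs=0.02)
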
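"""Stained-area quantification for brightfield DAB immunohistochemistry.

Expression of a transporter isoform in one visual field is measured as the
immunostained fraction of a calibrated area.  Segmentation follows the
saturation criterion: the brown DAB reaction product is far more
color-saturated than the pale hematoxylin counterstain, so the per-pixel HSV
saturation (scaled to 0..255) thresholded on its grey-level histogram
separates stain from background.  An optional hue gate restricts the stain
mask to the brown hue band first, so strongly tinted non-DAB pixels are not
counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage import color as skcolor
from skimage.filters import threshold_otsu

from .errors import AggregationError, FormatError, MeasurementError

#: Hue intervals (fractions of the HSV circle) regarded as the DAB brown band.
DEFAULT_HUE_BAND = ((0.0, 0.17), (0.92, 1.0))

#: Saturation level used when Otsu cannot run (constant histogram); between
#: typical counterstain and chromogen saturation.
FALLBACK_THRESHOLD = 64.0


@dataclass
class CalibratedField:
    """An RGB micrograph with its physical calibration and provenance."""

    image: np.ndarray
    calibration_um2_per_px: float
    calibrated_area_um2: float
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.calibration_um2_per_px <= 0:
            raise MeasurementError("calibration must be positive")
        npx = self.image.shape[0] * self.image.shape[1]
        max_area = npx * self.calibration_um2_per_px
        if self.calibrated_area_um2 > max_area * (1 + 1e-9):
            raise MeasurementError(
                f"calibrated area {self.calibrated_area_um2} um^2 exceeds the "
                f"imaged area {max_area} um^2"
            )


@dataclass
class StainMeasurement:
    """Stained area of one calibrated field (one observer reading or consensus)."""

    stained_area_um2: float
    stained_fraction: float
    threshold_used: float
    observer_id: int | str | None = None
    replicate_idx: int | None = None
    provenance: Mapping[str, object] = field(default_factory=dict)
    flagged: bool = False


def _require_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise FormatError(
            f"expected 8-bit RGB image of shape (H, W, 3), got shape "
            f"{image.shape} dtype {image.dtype}"
        )
    return image


def saturation_channel(image: np.ndarray) -> np.ndarray:
    """Per-pixel HSV saturation on a 0..255 grey-level scale.

    Pure grey pixels map to 0; fully saturated hues map to 255.
    """
    image = _require_rgb8(image)
    return skcolor.rgb2hsv(image)[..., 1] * 255.0


def hue_channel(image: np.ndarray) -> np.ndarray:
    """Per-pixel HSV hue in [0, 1)."""
    image = _require_rgb8(image)
    return skcolor.rgb2hsv(image)[..., 0]


def hue_gated_saturation(
    image: np.ndarray, hue_band: Sequence[tuple[float, float]] = DEFAULT_HUE_BAND
) -> np.ndarray:
    """Saturation channel with pixels outside the brown hue band set to zero."""
    sat = saturation_channel(image)
    hue = hue_channel(image)
    in_band = np.zeros(hue.shape, dtype=bool)
    for lo, hi in hue_band:
        in_band |= (hue >= lo) & (hue <= hi)
    return np.where(in_band, sat, 0.0)


@dataclass
class ThresholdResult:
    mask: np.ndarray
    threshold: float
    flagged: bool = False


def threshold_stain(
    saturation: np.ndarray,
    method: str = "otsu",
    fixed_level: float | None = None,
    fallback_level: float = FALLBACK_THRESHOLD,
) -> ThresholdResult:
    """Binary stain mask from a saturation raster.

    ``otsu`` picks the threshold on the grey-level histogram; a constant
    histogram (Otsu undefined) falls back to ``fallback_level`` and flags the
    field.  ``fixed`` thresholds at ``fixed_level``.  The mask is true where
    saturation strictly exceeds the threshold.
    """
    saturation = np.asarray(saturation, dtype=np.float64)
    if method == "fixed":
        if fixed_level is None or not (0 <= fixed_level <= 255):
            raise MeasurementError("method='fixed' requires fixed_level in [0, 255]")
        return ThresholdResult(mask=saturation > fixed_level, threshold=float(fixed_level))
    if method != "otsu":
        raise MeasurementError(f"unknown threshold method {method!r}")
    if saturation.min() == saturation.max():
        warnings.warn(
            "constant saturation histogram: Otsu undefined, using fallback level",
            stacklevel=2,
        )
        return ThresholdResult(mask=saturation > fallback_level, threshold=fallback_level, flagged=True)
    level = float(threshold_otsu(saturation, nbins=256))
    return ThresholdResult(mask=saturation > level, threshold=level)


def measure_field(field: CalibratedField, mask: np.ndarray, threshold_used: float = float("nan")) -> StainMeasurement:
    """Stained fraction and calibrated stained area from a binary mask."""
    mask = np.asarray(mask)
    if mask.shape != field.image.shape[:2]:
        raise MeasurementError(
            f"mask shape {mask.shape} does not match image shape {field.image.shape[:2]}"
        )
    if field.calibrated_area_um2 <= 0:
        raise MeasurementError("calibrated area must be positive")
    fraction = float(np.count_nonzero(mask)) / mask.size
    return StainMeasurement(
        stained_area_um2=fraction * field.calibrated_area_um2,
        stained_fraction=fraction,
        threshold_used=float(threshold_used),
        provenance=dict(field.provenance),
    )


def quantify_field(
    field: CalibratedField,
    method: str = "otsu",
    fixed_level: float | None = None,
    hue_gate: bool = True,
    hue_band: Sequence[tuple[float, float]] = DEFAULT_HUE_BAND,
) -> StainMeasurement:
    """Full single-field quantification: saturation, threshold, calibrated area."""
    sat = hue_gated_saturation(field.image, hue_band) if hue_gate else saturation_channel(field.image)
    thr = threshold_stain(sat, method=method, fixed_level=fixed_level)
    m = measure_field(field, thr.mask, threshold_used=thr.threshold)
    m.flagged = thr.flagged
    return m


_REPLICATE_KEYS = ("observer", "observer_id", "replicate", "replicate_idx", "analysis")


def average_replicates(measurements: Sequence[StainMeasurement]) -> StainMeasurement:
    """Consensus measurement: arithmetic mean over observer/replicate readings.

    All inputs must share provenance up to observer and replicate identity.
    """
    if not measurements:
        raise AggregationError("cannot average zero measurements")
    if len(measurements) == 1:
        return measurements[0]

    def core(m: StainMeasurement) -> dict:
        return {k: v for k, v in dict(m.provenance).items() if k not in _REPLICATE_KEYS}

    reference = core(measurements[0])
    for m in measurements[1:]:
        if core(m) != reference:
            raise AggregationError("replicates with mixed provenance cannot be averaged")

    fraction = float(np.mean([m.stained_fraction for m in measurements]))
    area = float(np.mean([m.stained_area_um2 for m in measurements]))
    provenance = dict(reference)
    provenance["consensus"] = True
    return StainMeasurement(
        stained_area_um2=area,
        stained_fraction=fraction,
        threshold_used=float(np.mean([m.threshold_used for m in measurements])),
        provenance=provenance,
        flagged=any(m.flagged for m in measurements),
    )
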
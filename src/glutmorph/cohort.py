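"""Synthetic brightfield-IHC cohort generation.

This module fabricates the raw material of a placental glucose-transporter
morphometry study: a subject table for four obstetric groups (diet-controlled
GDM, insulin-controlled GDM, pre-gestational diabetes, and non-diabetic
controls), per-field ground truth (stained-area fractions for the GLUT
markers, elliptical vessel-lumen geometry for the endothelial CD31 stain),
and — on demand — rendered RGB micrographs in a simplified brown-DAB-on-blue-
hematoxylin color model.

The default sampling design mirrors the study layout: 53 subjects
(16 GDMG1, 6 GDMG2, 6 PGDM, 25 controls), two placental regions per subject
(central "A", peripheral "B"), three sections per specimen for each of three
GLUT isoforms, and three photographed visual fields per section — 106
specimens, 954 sections and 2862 field images in total.

Ground truth is carried alongside every field so that downstream stages
(stain quantification, lumen segmentation, V/EVTI) can be validated by
recovery rather than by eye.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, RenderError

GROUPS = ("GDMG1", "GDMG2", "PGDM", "control")
MARKERS = ("GLUT1", "GLUT4", "GLUT9")

#: Calibrated field areas (um^2): one analyzed image for GLUT quantification
#: and one (larger, lower magnification) for vessel-density analysis.
STAIN_FIELD_AREA_UM2 = 134755.0
VESSEL_FIELD_AREA_UM2 = 693287.0

#: Birth weight above which a neonate is classified macrosomic (grams),
#: irrespective of gestational age.
MACROSOMIA_THRESHOLD_G = 4000.0

# Rendering palette (8-bit RGB).  DAB oxidation product is brown; the
# hematoxylin counterstain is a pale blue-grey; vessel lumina are near-white.
DAB_RGB = (139, 86, 54)
HEMATOXYLIN_RGB = (203, 206, 226)
CD31_TISSUE_RGB = (228, 222, 230)
LUMEN_RGB = (246, 244, 240)
RENDER_NOISE_SD = 5.0

#: Saturation (0..255) safely between counterstain and DAB chromogen levels;
#: pixels above it belong to the stain band of the rendering model.
DAB_SATURATION_FLOOR = 100.0

#: Endothelial ring thickness drawn around vessel lumina (um, physical).
RING_WIDTH_UM = 7.0

_REGION_LETTERS = "ABCDEFGH"


def _hash_seed(*parts) -> int:
    """Derive a stable 31-bit seed from arbitrary string-able parts."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# design and effect profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design: who is sampled and how many images each subject yields.

    Defaults reproduce the study accounting: 106 specimens and
    2862 rendered field images.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"GDMG1": 16, "GDMG2": 6, "PGDM": 6, "control": 25}
    )
    regions_per_subject: int = 2
    sections_per_specimen_per_marker: int = 3
    markers: tuple[str, ...] = MARKERS
    fields_per_section: int = 3
    observers: int = 2
    analyses_per_observer: int = 3
    vessel_fields_per_specimen: int = 3
    image_size_px: int = 512
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group label {g!r}; expected one of {GROUPS}")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ConfigurationError(f"group {g!r} has {n} subjects; every group needs >= 1")
        for name in (
            "regions_per_subject",
            "sections_per_specimen_per_marker",
            "fields_per_section",
            "observers",
            "analyses_per_observer",
            "vessel_fields_per_specimen",
            "image_size_px",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not self.markers:
            raise ConfigurationError("at least one marker is required")
        if self.regions_per_subject > len(_REGION_LETTERS):
            raise ConfigurationError("too many regions per subject")

    # -- accounting -----------------------------------------------------
    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(_REGION_LETTERS[: self.regions_per_subject])

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def n_specimens(self) -> int:
        return self.n_subjects * self.regions_per_subject

    @property
    def n_sections(self) -> int:
        return self.n_specimens * len(self.markers) * self.sections_per_specimen_per_marker

    @property
    def n_field_images(self) -> int:
        return self.n_sections * self.fields_per_section

    @property
    def stain_calibration_um2_per_px(self) -> float:
        return STAIN_FIELD_AREA_UM2 / self.image_size_px**2

    @property
    def vessel_calibration_um2_per_px(self) -> float:
        return VESSEL_FIELD_AREA_UM2 / self.image_size_px**2


def _default_stain_means() -> dict[str, dict[str, float]]:
    base = {"GLUT1": 0.30, "GLUT4": 0.20, "GLUT9": 0.20}
    return {
        "control": dict(base),
        "GDMG1": dict(base),
        "GDMG2": {"GLUT1": 0.30, "GLUT4": 0.32, "GLUT9": 0.32},
        "PGDM": {"GLUT1": 0.42, "GLUT4": 0.32, "GLUT9": 0.32},
    }


@dataclass(frozen=True)
class EffectProfile:
    """Group-level generative parameters.

    ``stain_means`` encode only the direction of the reported effects
    (GLUT-4/GLUT-9 elevated under insulin therapy, GLUT-1 elevated in
    pre-gestational diabetes only); magnitudes are a package convention.
    Clinical covariates (birth/placental weight medians and log-dispersion,
    cesarean rates) are taken from the study's patient characteristics table.
    """

    stain_means: Mapping[str, Mapping[str, float]] = field(default_factory=_default_stain_means)
    subject_concentration: float = 200.0  # beta concentration across subjects
    field_concentration: float = 600.0  # beta concentration across fields within a subject
    observer_noise_sd: float = 0.01  # per-reading absolute noise on fractions
    observer_bias_sd: float = 0.005  # per-observer systematic offset

    lumen_count_mean: Mapping[str, float] = field(
        default_factory=lambda: {"GDMG1": 22.0, "GDMG2": 22.0, "PGDM": 22.5, "control": 22.0}
    )
    lumen_count_shape: float = 8.0  # gamma shape for per-field lumen counts
    lumen_count_specimen_log_sd: float = 0.6  # between-specimen variability in vascularity
    lumen_semi_minor_um: tuple[float, float] = (14.0, 34.0)
    lumen_axis_ratio: tuple[float, float] = (1.0, 1.8)
    vevti_noise_rel_sd: float = 0.02  # relative observer noise on V/EVTI readings

    fetal_weight_median_g: Mapping[str, float] = field(
        default_factory=lambda: {"GDMG1": 3270.0, "GDMG2": 3550.0, "PGDM": 4010.0, "control": 3470.0}
    )
    fetal_weight_log_sd: Mapping[str, float] = field(
        default_factory=lambda: {"GDMG1": 0.056, "GDMG2": 0.290, "PGDM": 0.055, "control": 0.126}
    )
    placental_weight_median_g: Mapping[str, float] = field(
        default_factory=lambda: {"GDMG1": 523.0, "GDMG2": 634.0, "PGDM": 733.0, "control": 597.0}
    )
    placental_weight_log_sd: Mapping[str, float] = field(
        default_factory=lambda: {"GDMG1": 0.291, "GDMG2": 0.274, "PGDM": 0.095, "control": 0.213}
    )
    cesarean_rate: Mapping[str, float] = field(
        default_factory=lambda: {"GDMG1": 0.625, "GDMG2": 1.0, "PGDM": 1.0, "control": 0.64}
    )

    def with_vessel_inflation(self, group: str, factor: float) -> "EffectProfile":
        """Return a profile whose ``group`` lumen-count mean is scaled by ``factor``."""
        means = dict(self.lumen_count_mean)
        means[group] = means[group] * factor
        return replace(self, lumen_count_mean=means)

    def effect_directions_hold(self) -> bool:
        """True iff the profile orders group means as the study reports:
        GLUT-4/GLUT-9 up in (GDMG2, PGDM); GLUT-1 up in PGDM only; vessel
        density up in PGDM."""
        m = self.stain_means
        for marker in ("GLUT4", "GLUT9"):
            if not min(m["GDMG2"][marker], m["PGDM"][marker]) > max(
                m["GDMG1"][marker], m["control"][marker]
            ):
                return False
        if not m["PGDM"]["GLUT1"] > max(m["GDMG1"]["GLUT1"], m["GDMG2"]["GLUT1"], m["control"]["GLUT1"]):
            return False
        d = self.lumen_count_mean
        return d["PGDM"] > max(d["GDMG1"], d["GDMG2"], d["control"])


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class LumenParam:
    """One elliptical lumen: an oblique section of a presumed circular vessel.

    The semi-minor axis is the presumed true vessel radius; the semi-major
    axis elongation is the sectioning artifact the minimum-Feret rule undoes.
    Centers (um from image origin) are assigned at render time.
    """

    semi_minor_um: float
    semi_major_um: float
    orientation_rad: float
    center_um: tuple[float, float] | None = None

    @property
    def corrected_area_um2(self) -> float:
        return math.pi * self.semi_minor_um**2


@dataclass
class FieldGroundTruth:
    """Everything the generator knows about one visual field."""

    field_id: str
    style: str  # "GLUT_stain" or "CD31_stain"
    calibration_um2_per_px: float
    image_size_px: int
    render_seed: int
    true_stain_fraction: float | None = None
    true_lumen_params: list[LumenParam] | None = None

    @property
    def field_area_um2(self) -> float:
        return self.calibration_um2_per_px * self.image_size_px**2

    @property
    def true_vevti(self) -> float | None:
        """V/EVTI implied by the lumen parameters: corrected vascular area
        over extravascular (field minus vascular) area."""
        if self.true_lumen_params is None:
            return None
        vascular = sum(p.corrected_area_um2 for p in self.true_lumen_params)
        return vascular / (self.field_area_um2 - vascular)


@dataclass
class RenderedField:
    """A rendered micrograph plus the masks it was rendered from."""

    image: np.ndarray  # (H, W, 3) uint8
    stain_mask: np.ndarray | None = None  # bool, GLUT style
    lumen_labels: np.ndarray | None = None  # int, CD31 style
    placed_lumens: list[LumenParam] | None = None


@dataclass
class SyntheticCohort:
    """Generated cohort: subject table, per-field tables, per-field truth."""

    design: CohortDesign
    effects: EffectProfile
    subjects: pd.DataFrame
    stain_fields: pd.DataFrame
    vessel_fields: pd.DataFrame
    vessel_lumens: dict[str, list[LumenParam]]

    def stain_ground_truth(self, field_id: str) -> FieldGroundTruth:
        row = self.stain_fields.loc[self.stain_fields.field_id == field_id].iloc[0]
        return FieldGroundTruth(
            field_id=field_id,
            style="GLUT_stain",
            calibration_um2_per_px=self.design.stain_calibration_um2_per_px,
            image_size_px=self.design.image_size_px,
            render_seed=int(row.render_seed),
            true_stain_fraction=float(row.true_stain_fraction),
        )

    def vessel_ground_truth(self, field_id: str) -> FieldGroundTruth:
        row = self.vessel_fields.loc[self.vessel_fields.field_id == field_id].iloc[0]
        return FieldGroundTruth(
            field_id=field_id,
            style="CD31_stain",
            calibration_um2_per_px=self.design.vessel_calibration_um2_per_px,
            image_size_px=self.design.image_size_px,
            render_seed=int(row.render_seed),
            true_lumen_params=self.vessel_lumens[field_id],
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _beta_around(rng: np.random.Generator, mean, concentration: float, size=None) -> np.ndarray:
    mean = np.clip(np.asarray(mean, dtype=float), 1e-6, 1 - 1e-6)
    return rng.beta(mean * concentration, (1.0 - mean) * concentration, size=size)


def generate_subjects(design: CohortDesign, effects: EffectProfile, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in GROUPS:
        if group not in design.group_sizes:
            continue
        n = design.group_sizes[group]
        fw = effects.fetal_weight_median_g[group] * np.exp(
            rng.normal(0.0, effects.fetal_weight_log_sd[group], n)
        )
        pw = effects.placental_weight_median_g[group] * np.exp(
            rng.normal(0.0, effects.placental_weight_log_sd[group], n)
        )
        cesarean = rng.random(n) < effects.cesarean_rate[group]
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{group}-{i + 1:02d}",
                    "group": group,
                    "fetal_weight_g": float(fw[i]),
                    "macrosomia": bool(fw[i] > MACROSOMIA_THRESHOLD_G),
                    "mode_of_delivery": "cesarean" if cesarean[i] else "vaginal",
                    "placental_weight_g": float(pw[i]),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(design: CohortDesign, effects: EffectProfile | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort for a design.

    Deterministic for a fixed ``design.seed``.  Emits exactly one stain-field
    record per (subject, region, marker, section, field) tuple and
    ``vessel_fields_per_specimen`` CD31 fields per specimen.  Ground-truth
    stained fractions are beta-distributed around group means (subject level)
    and around subject means (field level); lumen counts are gamma-distributed
    around group means.
    """
    design.validate()
    if effects is None:
        effects = EffectProfile()
    rng = np.random.default_rng(design.seed)

    subjects = generate_subjects(design, effects, rng)

    # --- stain fields, vectorized over the design grid ------------------
    grid = []
    for _, subj in subjects.iterrows():
        for region in design.regions:
            for marker in design.markers:
                for section in range(1, design.sections_per_specimen_per_marker + 1):
                    for fld in range(1, design.fields_per_section + 1):
                        grid.append((subj.subject_id, subj.group, region, marker, section, fld))
    stain = pd.DataFrame(
        grid, columns=["subject_id", "group", "region", "marker", "section_idx", "field_idx"]
    )
    stain["specimen_id"] = stain.subject_id + "-" + stain.region
    stain["field_id"] = (
        stain.specimen_id
        + "-"
        + stain.marker
        + "-s"
        + stain.section_idx.astype(str)
        + "-f"
        + stain.field_idx.astype(str)
    )

    # subject x marker level means, then field-level draws
    subj_marker = stain[["subject_id", "group", "marker"]].drop_duplicates().reset_index(drop=True)
    group_mean = np.array(
        [effects.stain_means[g][m] for g, m in zip(subj_marker.group, subj_marker.marker)]
    )
    subj_marker["subject_mean"] = _beta_around(rng, group_mean, effects.subject_concentration)
    stain = stain.merge(subj_marker[["subject_id", "marker", "subject_mean"]], on=["subject_id", "marker"])
    stain["true_stain_fraction"] = _beta_around(
        rng, stain.subject_mean.to_numpy(), effects.field_concentration
    )
    stain["calibration_um2_per_px"] = design.stain_calibration_um2_per_px
    stain["render_seed"] = [_hash_seed(design.seed, fid) for fid in stain.field_id]

    # --- vessel (CD31) fields -------------------------------------------
    lo_b, hi_b = effects.lumen_semi_minor_um
    lo_r, hi_r = effects.lumen_axis_ratio
    field_area = VESSEL_FIELD_AREA_UM2
    vrows = []
    lumens_by_field: dict[str, list[LumenParam]] = {}
    specimens = stain[["subject_id", "group", "region", "specimen_id"]].drop_duplicates()
    for _, sp in specimens.iterrows():
        # between-specimen biological variability in vascularity
        mean_count = effects.lumen_count_mean[sp.group] * math.exp(
            rng.normal(0.0, effects.lumen_count_specimen_log_sd)
        )
        for fld in range(1, design.vessel_fields_per_specimen + 1):
            fid = f"{sp.specimen_id}-CD31-f{fld}"
            count = int(
                round(rng.gamma(effects.lumen_count_shape, mean_count / effects.lumen_count_shape))
            )
            b = rng.uniform(lo_b, hi_b, count)
            ratio = rng.uniform(lo_r, hi_r, count)
            theta = rng.uniform(0.0, math.pi, count)
            # physical packing budget: a section can only hold so much vessel
            # footprint (lumen + endothelial ring + spacing); truncate the draw
            # so every field stays renderable
            footprint = np.pi * (b * ratio + RING_WIDTH_UM + 5.0) ** 2
            keep = np.cumsum(footprint) <= 0.30 * field_area
            count = int(keep.sum())
            b, ratio, theta = b[keep], ratio[keep], theta[keep]
            params = [
                LumenParam(semi_minor_um=float(bi), semi_major_um=float(bi * ri), orientation_rad=float(ti))
                for bi, ri, ti in zip(b, ratio, theta)
            ]
            vascular = float(np.pi * np.sum(b**2))
            lumens_by_field[fid] = params
            vrows.append(
                {
                    "field_id": fid,
                    "subject_id": sp.subject_id,
                    "group": sp.group,
                    "region": sp.region,
                    "specimen_id": sp.specimen_id,
                    "field_idx": fld,
                    "n_lumens": count,
                    "true_vascular_area_um2": vascular,
                    "true_vevti": vascular / (field_area - vascular),
                    "calibration_um2_per_px": design.vessel_calibration_um2_per_px,
                    "render_seed": _hash_seed(design.seed, fid),
                }
            )
    vessel = pd.DataFrame(vrows)

    stain = stain.drop(columns=["subject_mean"])
    col_order = [
        "field_id",
        "subject_id",
        "group",
        "region",
        "specimen_id",
        "marker",
        "section_idx",
        "field_idx",
        "true_stain_fraction",
        "calibration_um2_per_px",
        "render_seed",
    ]
    return SyntheticCohort(
        design=design,
        effects=effects,
        subjects=subjects,
        stain_fields=stain[col_order].reset_index(drop=True),
        vessel_fields=vessel,
        vessel_lumens=lumens_by_field,
    )


# ---------------------------------------------------------------------------
# observer simulation
# ---------------------------------------------------------------------------


def simulate_observer_readings(
    measurement: float,
    observers: int = 2,
    replicates: int = 3,
    noise_sd: float = 0.01,
    seed: int | None = None,
    observer_bias_sd: float = 0.0,
    clip: tuple[float, float] | None = (0.0, 1.0),
) -> np.ndarray:
    """Simulate repeated area analyses of one measurement by several observers.

    Returns an ``(observers, replicates)`` array.  With ``noise_sd == 0`` every
    reading equals the input exactly; the mean over all readings is the value
    recorded downstream.  ``observer_bias_sd`` adds a per-observer systematic
    offset so that intra-observer agreement exceeds inter-observer agreement.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if noise_sd == 0.0:
        return np.full((observers, replicates), float(measurement))
    bias = rng.normal(0.0, observer_bias_sd, size=(observers, 1)) if observer_bias_sd > 0 else 0.0
    readings = measurement + bias + rng.normal(0.0, noise_sd, size=(observers, replicates))
    if clip is not None:
        readings = np.clip(readings, *clip)
    return readings


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _paint(image: np.ndarray, mask: np.ndarray, rgb: Sequence[int]) -> None:
    image[mask] = np.asarray(rgb, dtype=np.float64)


def _finish(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    noisy = image + rng.normal(0.0, RENDER_NOISE_SD, size=image.shape)
    return np.clip(noisy, 0, 255).astype(np.uint8)


def _stain_mask(size: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random blob mask covering exactly ``fraction`` of the pixels."""
    if fraction <= 0.0:
        return np.zeros((size, size), dtype=bool)
    if fraction >= 1.0:
        return np.ones((size, size), dtype=bool)
    blobs = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=size / 42.0)
    threshold = np.quantile(blobs, 1.0 - fraction)
    return blobs > threshold


def place_lumens(
    params: Sequence[LumenParam],
    image_size_px: int,
    um_per_px: float,
    rng: np.random.Generator,
    ring_width_px: float = 4.0,
    margin_px: float = 2.0,
    max_attempts: int = 5000,
) -> list[LumenParam]:
    """Assign non-overlapping, fully interior centers to lumen parameters.

    Candidate centers that would put the lumen (plus its endothelial ring)
    over the image border or over a previously placed lumen are rejected and
    resampled, so border-clipped lumens are never emitted.  Lumens are placed
    largest-first (a prerequisite for dense fields to pack), then returned in
    the original parameter order.  Overlap is tested conservatively on the
    circumscribing circles.
    """
    order = sorted(range(len(params)), key=lambda i: -params[i].semi_major_um)
    centers_px: dict[int, tuple[float, float]] = {}
    radii_px: dict[int, float] = {}
    for i in order:
        p = params[i]
        a_px = p.semi_major_um / um_per_px
        keep_out = a_px + ring_width_px + margin_px
        if 2 * keep_out >= image_size_px:
            raise RenderError("lumen too large for the field")
        r = a_px + ring_width_px + margin_px / 2.0
        for _ in range(max_attempts):
            cx = rng.uniform(keep_out, image_size_px - keep_out)
            cy = rng.uniform(keep_out, image_size_px - keep_out)
            ok = all(
                (cx - qx) ** 2 + (cy - qy) ** 2 > (r + radii_px[j]) ** 2
                for j, (qx, qy) in centers_px.items()
            )
            if ok:
                centers_px[i] = (cx, cy)
                radii_px[i] = r
                break
        else:
            raise RenderError(
                f"could not place lumen after {max_attempts} attempts "
                f"({len(centers_px)}/{len(params)} placed)"
            )
    return [
        LumenParam(
            semi_minor_um=p.semi_minor_um,
            semi_major_um=p.semi_major_um,
            orientation_rad=p.orientation_rad,
            center_um=(centers_px[i][0] * um_per_px, centers_px[i][1] * um_per_px),
        )
        for i, p in enumerate(params)
    ]


def _ellipse_masks(
    size: int, p: LumenParam, um_per_px: float, ring_width_px: float
) -> tuple[np.ndarray, np.ndarray, tuple[slice, slice]]:
    """Boolean interior and ring masks for one lumen, on a bounding-box window."""
    cx, cy = (c / um_per_px for c in p.center_um)
    a = p.semi_major_um / um_per_px
    b = p.semi_minor_um / um_per_px
    ext = a + ring_width_px + 1.0
    x0, x1 = max(0, int(cx - ext)), min(size, int(cx + ext) + 2)
    y0, y1 = max(0, int(cy - ext)), min(size, int(cy + ext) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    c, s = math.cos(p.orientation_rad), math.sin(p.orientation_rad)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    inner = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    outer = (u / (a + ring_width_px)) ** 2 + (v / (b + ring_width_px)) ** 2 <= 1.0
    return inner, outer & ~inner, (slice(y0, y1), slice(x0, x1))


def render_field(gt: FieldGroundTruth, style: str | None = None, ring_width_um: float = RING_WIDTH_UM) -> RenderedField:
    """Render one synthetic micrograph from its ground truth.

    ``GLUT_stain`` fields show brown DAB blobs covering the true stained
    fraction of the tissue on a hematoxylin background; ``CD31_stain`` fields
    show brown endothelial rings around near-white elliptical lumina.
    Deterministic given ``gt.render_seed``.
    """
    style = style or gt.style
    if gt.calibration_um2_per_px <= 0:
        raise ConfigurationError("calibration must be positive")
    size = gt.image_size_px
    rng = np.random.default_rng(gt.render_seed)
    um_per_px = math.sqrt(gt.calibration_um2_per_px)

    if style == "GLUT_stain":
        if gt.true_stain_fraction is None:
            raise ConfigurationError("GLUT_stain rendering requires true_stain_fraction")
        mask = _stain_mask(size, gt.true_stain_fraction, rng)
        image = np.empty((size, size, 3), dtype=np.float64)
        image[:] = HEMATOXYLIN_RGB
        _paint(image, mask, DAB_RGB)
        return RenderedField(image=_finish(image, rng), stain_mask=mask)

    if style == "CD31_stain":
        if gt.true_lumen_params is None:
            raise ConfigurationError("CD31_stain rendering requires true_lumen_params")
        ring_width_px = max(2.0, ring_width_um / um_per_px)
        if any(p.center_um is None for p in gt.true_lumen_params):
            placed = place_lumens(gt.true_lumen_params, size, um_per_px, rng, ring_width_px)
        else:
            placed = list(gt.true_lumen_params)
        image = np.empty((size, size, 3), dtype=np.float64)
        image[:] = CD31_TISSUE_RGB
        labels = np.zeros((size, size), dtype=np.int32)
        for k, p in enumerate(placed, start=1):
            inner, ring, window = _ellipse_masks(size, p, um_per_px, ring_width_px)
            image[window][inner] = LUMEN_RGB
            image[window][ring] = DAB_RGB
            lab = labels[window]
            lab[inner] = k
            labels[window] = lab
        return RenderedField(image=_finish(image, rng), lumen_labels=labels, placed_lumens=placed)

    raise ConfigurationError(f"unknown rendering style {style!r}")
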
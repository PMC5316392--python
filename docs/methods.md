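# Methods

## Study design emulated by the generator

The sampling design is the unit structure of a placental IHC morphometry
study: four obstetric groups — diet-controlled gestational diabetes (GDMG1,
16 subjects), insulin-controlled gestational diabetes (GDMG2, 6),
pre-gestational diabetes (PGDM, 6) and uncomplicated controls (25) — with
two cross-section specimens per placenta (central region "A", peripheral
"B"), three paraffin sections per specimen for each of the three GLUT
isoforms, and three photographed visual fields per section. With the default
counts this yields 106 specimens, 954 sections and 2862 field images; the
accounting is an invariant checked by the tests. Each CD31 (endothelial
marker) specimen additionally contributes three vessel-density fields.

Every GLUT field is calibrated to 134 755 µm² and every CD31 field to
693 287 µm², regardless of the pixel size chosen for rendering; the pixel
calibration is derived as area / (image side)². The default rendering size
is 512 × 512 px (0.72 µm/px for GLUT fields, 1.63 µm/px for CD31 fields).

## Rendering model

Brightfield appearance is reduced to a three-color model: pale blue-grey
hematoxylin tissue (RGB 203, 206, 226), brown DAB reaction product
(139, 86, 54), and near-white vessel lumina, plus additive Gaussian pixel
noise (σ = 5 grey levels). This is deliberately minimal: the point is that
the *saturation* of the chromogen is well separated from the counterstain,
which is the property the segmentation criterion relies on. Stained regions
are smooth random blobs (a Gaussian random field thresholded at the exact
quantile), so the rendered stained fraction matches the ground-truth
fraction to within rasterization error. Vessel lumina are ellipses of random
orientation, semi-minor axis 14–34 µm and axis ratio 1–1.8, ringed by a
7-µm endothelial band; candidate centers that would clip the border or
overlap another lumen are rejected and resampled (largest-first), so
border-censored lumina are never emitted.

What the generator does *not* emulate: illumination gradients and shading,
chromogen intensity variation with antigen density, tissue texture,
out-of-focus blur, touching/overlapping vessels, and non-elliptical lumen
profiles. Passing recovery tests therefore demonstrate correctness of the
measurement chain under the model's assumptions (chromogen separable in
saturation; lumina convex and ring-enclosed), not robustness to real-slide
artifacts.

## Stain quantification

The saturation channel is HSV S scaled to 0–255 (pure grey → 0, saturated
hue → 255). By default the channel is first gated to the brown hue band
(hue ∈ [0, 0.17] ∪ [0.92, 1.0]) so that strongly tinted non-DAB pixels are
not counted, then thresholded by Otsu's method on the grey-level histogram;
a fixed threshold is available by configuration. A constant histogram (Otsu
undefined) falls back to level 64 and flags the field; flagged fields are
excluded from group summaries. The stained fraction is the mask fraction of
the calibrated region (the full image by default), and the stained area is
that fraction times the calibrated area.

Observer replication is simulated as value + per-observer bias
(σ = 0.005) + per-reading noise (σ = 0.01), clipped to [0, 1]; three
readings per observer, two observers, and the grand mean is the consensus
recorded downstream. The bias term makes intra-observer agreement
systematically exceed inter-observer agreement, as reported for this kind of
dual-analysis protocol.

## Vessel morphometry

Lumen segmentation inverts the rendering model: the endothelial ring is
segmented with the same hue-gated saturation threshold, holes fully enclosed
by a ring become lumina (binary fill), components under 30 px or touching
the border are discarded. The minimum and maximum Feret diameters are
computed by exact rotating calipers on the convex hull of the component's
pixel centers dilated by the half-pixel diamond; the diamond dilation keeps
an n-pixel-wide object at width n and is near-unbiased (≈ +0.15 px on
rasterized ellipses) where centers alone are −0.7 px and full square corners
+0.5 px biased. Each lumen's corrected area is the circle over its minimum
Feret diameter (`lumen_area_mode: feret_circle`; `raw_pixels` preserves the
segmented area), the stereological correction for obliquely sectioned
vessels; the generator's ground-truth V/EVTI uses the same circular model
(π b² for semi-minor axis b), i.e. the true cross-section of the presumed
circular vessel, so recovery is a meaningful comparison. V/EVTI is the total
corrected lumen area over the extravascular remainder of the calibrated
area; vessel walls count as extravascular. Per specimen, V/EVTI is the
median over its fields.

## Effect profile (generator defaults)

Magnitudes are a package convention encoding only the *direction* structure
of the reported effects, since group-level values exist only in figure form:

| quantity | control | GDMG1 | GDMG2 | PGDM |
|---|---|---|---|---|
| GLUT-1 mean stained fraction | 0.30 | 0.30 | 0.30 | 0.42 |
| GLUT-4 mean stained fraction | 0.20 | 0.20 | 0.32 | 0.32 |
| GLUT-9 mean stained fraction | 0.20 | 0.20 | 0.32 | 0.32 |
| mean lumen count per CD31 field | 22 | 22 | 22 | 22.5 |

Stained fractions are beta-distributed around the group mean at the subject
level (concentration 200, sd ≈ 0.03) and around the subject mean at the
field level (concentration 600). Lumen counts are gamma-distributed per
field (shape 8) around a specimen-level mean that carries a lognormal
biological-variability factor (log-sd 0.6, specimen V/EVTI IQR ratio ≈ 2.2 —
placental vascularization varies widely between specimens, from hypovascular
to chorangiosis-like). A physical packing budget truncates each field's
lumen list so the cumulative footprint (lumen + ring + spacing) stays below
30 % of the calibrated area: a section can only hold so many vessels, and
this saturation also bounds how far vessel-density inflation can push a
group's V/EVTI distribution. Clinical covariates (birth and placental
weight medians with per-group log-dispersion derived from the printed IQRs,
cesarean rates, the >4000 g macrosomia rule) follow the study's patient
characteristics table.

The modest default PGDM vessel-density elevation (+2 %) deserves a note: a
large elevation would force the ±5 % density matching to discard most PGDM
specimens (collapsing the group's sample size), which contradicts the
study's own account of analyzing density-matched samples from all four
groups. The profile therefore encodes the PGDM > others ordering minimally;
the matching machinery is stress-tested separately with an explicit 30 %
inflation.

## Density matching

The matching constraint is the achieved property — all pairwise group-median
V/EVTI differences ≤ 5 % of the pair mean (equivalently, largest/smallest
median ratio ≤ (2+t)/(2−t)). The procedure is a deterministic selection:
any subset median of a sorted list is either a single order statistic (odd
sizes) or the average of an arbitrary order-stat pair with one spare element
outside each end (even sizes), so enumerating centered blocks with one
interior gap reaches exactly the subset-achievable medians. The matcher
slides the tolerance window over all achievable medians and, among feasible
windows, maximizes first the minimum retained fraction per group (protecting
the smallest groups' statistical power) and then the total retained count;
ties break deterministically on vevti order and specimen id. Groups are
never trimmed below 4 specimens (configurable); if no selection satisfies
the constraint the matcher raises, carrying the best achievable difference —
it never silently returns an unmatched cohort.

## Statistical layer

Quartiles use linear interpolation between order statistics. Percent of
control is 100 × group median / control median, so the control group is
exactly 100 %. Kruskal–Wallis uses the tie-corrected H against χ²(k−1); for
pooled n ≤ 10 the p-value is computed by exact enumeration of all distinct
assignments of the pooled values to the group sizes. Dunn's post-hoc
compares mean ranks with the pooled tie-corrected variance; pairwise
p-values are Bonferroni-adjusted over all pairs by default (Holm and
unadjusted available). Chi-square tests are Pearson's without continuity
correction; pairwise comparisons are Bonferroni-multiplied, and comparisons
(or headline tables) with all-zero rows/columns are reduced with a warning.
Cohen's κ uses the large-sample standard error for its 95 % CI; continuous
readings are discretized into pooled tertiles (bin count configurable)
before κ, a declared convention since κ requires categories. If both raters
are constant and identical (chance agreement 1), κ is reported as 1.0 and
flagged. Inter-observer κ compares first replicates of the two observers;
intra-observer κ compares an observer's first two replicates — same noise
footing, so the bias term alone separates the two agreements.

The headline qualitative pattern is extracted from the Dunn table at
α = 0.05: GLUT-4 and GLUT-9 elevated in GDMG2 and PGDM against both control
and GDMG1 (all four pairs significant, medians higher); GLUT-1 elevated in
PGDM only; no GDMG1-vs-control difference for any marker.

## Pipeline, determinism, problem sizes

A single global seed fans out to per-stage seeds through a stage-name-keyed
SHA-256 derivation, so stages can be re-run in isolation; identical
configuration and seed reproduce byte-identical tables and results JSON. By
default per-field measurements are simulated as ground truth plus the
observer layer — statistically equivalent for the group-level analyses and
fast enough that the full study (2862 fields) runs in well under a second;
the rendered-image path (render → saturation threshold → measure, or render
→ segment → Feret → V/EVTI) is exercised on hundreds of fields by the
recovery tests, which check stained-fraction MAE < 0.02 and per-field V/EVTI
within 5 % of generator truth. The stochastic acceptance checks use 20
cohorts (matching stress) and 100 end-to-end seeded runs (qualitative
pattern), sizes at which the checked proportions are stable.

## Known limitations

- The color model has no optical-density physics; color-deconvolution
  pipelines (H/DAB unmixing) are deliberately out of scope.
- Per-pixel thresholding only; object-level mean-saturation scoring is not
  implemented.
- Specimen-level exclusion is the only matching mechanism; field-level
  selection is not modeled.
- Matching feasibility is a property of the data: two small groups whose
  V/EVTI distributions are shifted ~30 % apart can, rarely, have no common
  ±5 % median window above the minimum group size, in which case the matcher
  (correctly) raises rather than degrading the tolerance.
- κ values depend on the tertile-binning convention; other bin counts give
  different absolute agreement levels.
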
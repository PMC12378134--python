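# Methods

## Polar-map geometry

The AHA 17-segment model is realized on a raster disc with equal-width
rings: apex disc r ≤ 0.25 of the map radius, apical ring 0.25–0.5 (four
90° sectors), mid 0.5–0.75 and basal 0.75–1.0 (six 60° sectors each).
Angle 0° points at the anterior wall and sectors are centered on their
walls, so every ring's anterior sector straddles 0°; numbering follows the
AHA order (1–6 basal, 7–12 mid, 13–16 apical, 17 apex). Clinical polar-map
software samples counts from short-axis slices with vendor-specific depth
and apex handling that is not public; the piecewise geometry here is an
explicit, configurable stand-in that preserves the property every
downstream computation needs — each masked pixel belongs to exactly one
segment. Segment values are plain means of member pixels. The
raster→profile→raster round-trip is exact up to floating-point summation
order (asserted at relative tolerance 1e-12).

Normalization maps the highest segment mean to 100 % (the `max_segment`
policy). A whole-map percentile reference would be slightly more
noise-robust on raw rasters, but segment-level max is deterministic,
scale-invariant and sufficient for profile-level work; a `mean` reference
is available where values above 100 % are acceptable.

## Normal databases

An NDB stores, per segment, the cohort mean and the sample SD
(n − 1 denominator; the normative cohorts here are small, 33–55 subjects,
where the unbiased variance matters). Pooled (multi-population) NDBs are
built by concatenating subjects, not by averaging the component databases,
so a larger cohort contributes proportionally more. External NDB files that
store dispersion as the mean absolute deviation about the mean are
converted on load by σ = d·√(π/2), the normality relation E|X − μ| =
σ√(2/π), and flagged `md_converted`; whether a vendor's "mean deviation" is
taken about the mean or the median is generally undocumented, and the
mean-based relation is used here.

Databases are compared segment-wise with a one-way ANOVA computed from
summary statistics only (between-group sums of squares from group means and
sizes, within-group from (n−1)σ²), so external databases can be compared
without subject-level data; with two groups this reduces exactly to the
pooled-variance t (F = t²), which the tests verify against raw-data ANOVA.
Significance flags use α = 0.05, two-sided.

## Defect scoring

The visual rule is the fixed band table (≥ 70/60–69/50–59/40–49/< 40 % →
0–4). Automated scoring grades the normalized deficit z = (m_s − u_s)/σ_s
by how many of the thresholds (2, 3, 4, 5 SD; configurable) it reaches,
capped at 4. The threshold ladder is the established SD-graded convention
of perfusion databases; the commercial algorithm's exact internal mapping
is unpublished, and any monotone SD-graded rule satisfies the properties
relied on here (zero scores on the NDB's own mean profile, monotone
response to deeper defects). Segments whose σ_s falls below 0.5 % use that
floor to avoid division blow-up on degenerate cohorts, with a logged
warning; the apex (segment 17) is scored identically to the others.

## HMR

The HMR is the mean count in a circular cardiac ROI over the mean in a
rectangular upper-mediastinal ROI; ROIs must be disjoint and inside the
image. Cross-camera standardization uses the one-point-fixed linear form
HMR_std = c·(HMR_raw − 1) + 1, the phantom cross-calibration convention:
HMR = 1 (no specific uptake above background) is invariant, and chained
conversions multiply their coefficients. Calibration constants are
acquisition-specific and supplied in configuration; the default is the
identity, since no constant is universally correct.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular patient data. Segment truth means (Jp male early baseline:
anterior/lateral ≈ 88–90 %, inferior ≈ 77–80 %, apex 82 %; SD 6 % in all
segments) are synthetic values shaped to the qualitative pattern of normal
MIBG bullseyes. Stratum effects: males −6 % on the inferior wall
(segments 3, 4, 5, 9, 10, 15), the Italian population −5 % on the anterior
segments (1, 2, 7, 8, 13), late phase −3 % globally. Segment noise is
independent Gaussian, clipped to [0, 120] %; real polar maps have spatial
covariance that this omits, so passing tests demonstrate pipeline
correctness, not clinical performance.

Disease models: CAD subtracts a depth drawn uniformly from 15–35 % from all
segments of one random coronary territory (LAD {1,2,7,8,13,14,17},
RCA {3,4,9,10,15}, LCx {5,6,11,12,16}) — with a 6 % normal SD this yields
mean summed automated scores near 11–16, the regime reported for focal
denervation. DCM subtracts a global 2–6 % with segment noise inflated ×1.2
— deficits too shallow to score, matching the observed similarity of DCM
and control defect scores. HMR is drawn per subject from N(μ_g, 0.30)
with normal means 2.46 (early) / 2.47 (late) and per-phase disease
decrements of 0.39/0.56 (CAD) and 0.65/0.69 (DCM), floored at 1.0; these
group means are the study conditions the evaluation is meant to reproduce
(DCM < CAD < normal). Planar images are a flat background (100 counts)
plus a cardiac Gaussian blob whose amplitude is solved so the noiseless
ROI ratio equals the subject's HMR exactly, with optional Poisson counts.

All randomness flows through one `numpy.random.default_rng` (PCG64) stream
per entry point; a `GeneratorConfig.seed` fully determines a study.

## Evaluation

Agreement is Pearson r plus Bland–Altman mean difference and 95 % limits of
agreement (mean ± 1.96·SD of paired differences, sample SD). The AUC is the
empirical Mann–Whitney exceedance probability with ties counting ½,
computed via midranks; its CI is the normal approximation with the DeLong
variance (clipped to [0, 1]), and paired markers are compared with the
DeLong test. The reported operating point maximizes the Youden index —
the original operating-point convention of the reference analyses is not
stated, and Youden is the deterministic standard. ROC direction follows
"higher defect score / lower HMR = disease"; low-is-abnormal markers are
negated internally. Group contrasts use the tie-corrected Kruskal–Wallis H
with a χ² reference (all-tied inputs are defined as H = 0, p = 1). The
combined marker is the fitted probability of a maximum-likelihood logistic
model (statsmodels GLM/binomial, IRLS, deviance tolerance 1e-8, ≤ 100
iterations) on HMR and summed score; perfect separation is flagged and
reported from a weakly ridge-penalized fit rather than treated as fatal.

## Test design for estimator checks

Two recovery checks are formulated so their tolerance bands sit several
standard errors from the truth rather than inside sampling noise:

* NDB recovery at n = 500 — a single segment's SD estimate has relative
  sampling error 1/√(2(n−1)) ≈ 3.2 %, so the 5 % band is asserted on the
  segment-averaged SD ratio (standard error ≈ 0.8 %) with a 20 % band per
  segment; segment means are checked at 1 % (≈ 3 standard errors) or the
  4σ/√n envelope.
* Logistic recovery at n = 2000 — a Fisher-information scan over candidate
  designs shows single-fit coefficient standard errors of at best ≈ 2σ
  against a 10 % band, so the band is asserted on the estimate averaged
  over five independent replicates (≈ 4σ), with deviance nesting per fit.

Problem sizes throughout the suite (cohorts of 30–150 subjects, 500-subject
recovery cohorts, 2000 null simulations for the Kruskal–Wallis calibration)
were chosen as the smallest sizes at which each property is statistically
decisive.

## Known limitations

No short-axis reconstruction, DICOM handling, attenuation or scatter
modeling; no washout-rate analysis; no age stratification; segment noise
has no spatial covariance (an equicorrelation extension would be the first
realism step); planar images are generic anterior views, not planograms;
the automated score emulates the SD-graded convention, not any vendor's
proprietary mapping; visual scores in practice come from human readers —
here the band rule applied to noisy profiles stands in for a single reader.
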
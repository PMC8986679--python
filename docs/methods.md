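# Methods

## Problem

Cochlear-implant planning software estimates the cochlear duct length
along the organ of Corti (CDL_OC) from two diameters read off a single
oblique CT reformat (the "cochlear view"), and localizes the implanted
electrode contacts for postoperative position control.  How reproducible
those measurements are depends strongly on the imaging modality:
multislice CT (MSCT, 600 µm slices), flat-panel volume CT (fpVCT,
466 µm), and high-resolution secondary reconstructions of the latter
(fpVCT_SECO, 99 µm) resolve the lateral wall very differently, and metal
artifact from an implanted array distorts it further.  `cochleapy`
implements the full measurement and test-retest agreement pipeline and —
because patient scans of this kind cannot be redistributed — pairs it
with a parametric synthetic cochlea so every stage is testable end to
end.

## Measurement model

**Cochlear view.**  The plane is fitted by total least squares (SVD) to
the round window, the modiolus, and the lateral-wall landmarks of the
first full turn (selected by accumulated winding about the modiolus in a
provisional all-point fit).  The frame origin is the projected modiolus;
the first in-plane axis points toward the projected round window; the
normal is oriented so the basal turn winds counter-clockwise.

**A and B.**  All landmarks are projected into the plane.  The A-line
runs from the round window through the modiolus; the A-value is the
distance from the round window to the farthest crossing of this line
with the wall polyline beyond the modiolus.  The B-line passes through
the modiolus perpendicular to A; the B-value is the distance between its
two wall crossings, taking the basal-most crossing on each side.
Crossings are linearly interpolated between adjacent wall samples, so on
noiseless input A and B reproduce the generative diameters to
discretization error (~1e-3 mm at the default 0.05 rad sampling).  We
deliberately use the line *through* the modiolus rather than a
farthest-point search: an unconstrained search returns a point up to
~0.1 mm beyond the true diameter even on perfect data, because the
spiral is not centrally symmetric about the round-window axis.

**CDL_OC.**  The elliptic circular approximation combines A and B; two
algebraic groupings of the published expression are provided:

- `as_printed` (default): `1.71·(1.18·A + 2.69·B) − 0.18·√(0.72·A·B) + 1.58`
- `grouped`: `1.71·((1.18·A + 2.69·B) − √(0.72·A·B)) + 1.58`

At physiologic diameters (A≈9, B≈6.5 mm) they give ≈48.5 and ≈38.5 mm
respectively; only the grouped reading lands on the mid-30s mm scale
reported for adult cochleae, which is why study-level runs in this
repository use `grouped` while the library default stays with the
literal printed form.  Every report records which mode produced it.  The
1.58 mm hook-region term (the basal portion of the organ of Corti
preceding the round-window-centered spiral) is exactly additive in both
modes.

**Electrode metrics.**  Insertion depth of contact j is the cumulative
polyline length from the round window through contacts 1..j;
inter-electrode distances (IED) are the 11 Euclidean distances between
consecutive contact centers.  Depths and IEDs use unprojected 3D
coordinates; only A and B are measured in the plane.  Exactly 12
contacts are required (FLEX28 array), otherwise a contact-count error
naming the observed count and subject is raised.

All measured quantities are invariant under rigid transforms of the
landmarks (verified to 1e-9 mm).

## Synthetic cochlea

The lateral wall is a shifted logarithmic spiral about the modiolus,

    r(θ) = c0 + c1·e^(−kθ),  θ ∈ [0, 2π·turns],

with z dropping linearly by `axial_height` over the full extent.  For
any decay rate k the two opposing-diameter constraints
`r(0)+r(π) = A` and `r(π/2)+r(3π/2) = B` are linear in (c0, c1) and are
satisfied exactly; k itself is solved numerically (Brent) so the spiral's
arc length equals 1.1 × the hook-free grouped duct-length estimate — a
realistic lateral-wall length (≈40 mm at A = 9 mm) with a plausible
apical radius plateau.  A pure log spiral cannot do this: the diameter
constraints then force k ≈ 0.21, whose entire wall measures only
~28 mm, too short to carry a 28 mm array and far from anatomy.  At
A = B the decay amplitude c1 is zero and the wall is the circle of
diameter A.

The electrode trajectory is the wall offset 0.25 mm toward the modiolar
axis (truncated where the radius falls below the offset, far beyond any
insertion), arc-length parameterized from the round window; the 12
contacts sit at 1.0 + j·2.1 mm (j = 0..11), so consecutive arc-length
spacing equals the nominal pitch exactly, while chord (Euclidean) IEDs
are slightly below it (≈2.05 mm), as for any curved array.

**Observation model.**  Each modality profile carries an isotropic
landmark noise SD (0.25 × slice thickness: 0.150 / 0.117 / 0.025 mm for
MSCT / fpVCT / fpVCT_SECO), a radial wall bias (−0.2 mm medial for the
two lower-resolution modalities, reflecting medial placement of
lateral-wall points on coarse scans; 0 for fpVCT_SECO), an extra lateral
bias when an array is present (+0.4 / +0.1 / 0 mm, emulating metal
artifact), and a contact noise SD (set equal to the landmark SD).  The
bias magnitudes are calibration choices — the direction is established,
the size is not reported anywhere — and are configurable.  The round
window receives the wall bias (it lies on the wall); the modiolus does
not.  Finally a random rigid transform (recorded on the landmark set)
decouples the observation frame from the generation frame.  Observations
are bit-reproducible given (seed, series, modality).

**Study design.**  Defaults mirror the source cohorts: 20 subjects in
groups 1 and 2, 10 in group 3, two test series per modality.  Group 1 is
non-implanted in all modalities; group 2 pairs a pre-operative MSCT of
the non-implanted ear with post-operative fpVCT/fpVCT_SECO of the same
subjects; group 3 is implanted throughout.  Subject anatomy: A ~
N(9.0, 0.4) truncated to [8.0, 10.5] mm, B = 0.72·A + N(0, 0.15) mm,
turns ~ N(2.6, 0.15) clipped to [1.5, 3.5].

**What the generator does not emulate:** voxelized images, partial
volume, beam hardening, observer drift between the two series, or
correlation of errors along the wall.  Passing tests therefore
demonstrate the correctness and statistical behaviour of the measurement
and agreement machinery under a controlled error model — not clinical
accuracy of any modality.

## Agreement statistics

Per (group, modality, measurement) block, with the n×2 subject×series
matrix:

- **ICC**: two-way mixed model, absolute agreement, single measures,
  computed from the ANOVA mean squares as
  `(MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E))` — the same
  formula as ICC(A,1); zero-variance tables raise an error rather than
  returning 0 or 1.  The 95% CI is the F-based McGraw–Wong construction
  with Satterthwaite degrees of freedom (cross-checked against pingouin
  in the test suite; simulated coverage 0.93–0.97 at n = 200).
  Categories: unacceptable < 0.4 ≤ fair < 0.6 ≤ good < 0.75 ≤ excellent.
- **Cronbach's alpha** with n−1 variance denominators; bands
  0.7 / 0.8 / 0.9.
- **Paired t-test** between the two series, two-sided;
  significance at p < 0.05.
- **Normality gate**: Shapiro–Wilk and Kolmogorov–Smirnov jointly
  (both must fail to reject at 0.05).  The KS variant is
  Lilliefors-corrected (parameters estimated); below n = 4, where the
  Lilliefors tables are undefined, a plain fitted-normal KS is used and
  the variant is recorded.  Constant samples route nonparametric.
- **Omnibus across modalities**: one-way repeated-measures ANOVA when
  every column passes the gate, else Friedman; each subject contributes
  its per-modality series mean.  Pairwise follow-ups use the paired
  t-test (or Wilcoxon when the differences fail the gate); p-values are
  unadjusted, as recorded in the report metadata.
- **Bland–Altman**: bias, SD of differences, limits of agreement
  bias ± 1.96·SD, and the count of subjects whose |difference| exceeds
  the clinical margin: ±1.5 mm for CDL_OC and ±0.09 mm for the mean IED.
  The IED margin derives from the CDL margin by proportional rescaling,
  margin × pitch / reference-CDL = 1.5 × 2.1 / 35 ≈ 0.09 mm; this
  derivation is an assumption and is flagged in the report metadata.

Numerical tie policy: series differences below 1e-9 mm are
floating-point residue of the noiseless pipeline limit, not
disagreement; the paired and omnibus contracts treat them as exact ties
(p = 1 for a zero mean).  ICC "significance" is reported as the CI
excluding 0; no value is ever dropped from the report.

## Problem sizes and defaults

The default study (50 ears, 3 modalities, 2 series) runs in a few
seconds; the acceptance script's replicate simulations use 50 study
seeds for the modality-ordering check and 500 replicates at n = 200 for
ICC calibration — sizes at which the Monte-Carlo error is well below the
effects being checked.  Report JSON keys are frozen
(`schema_version: 1`); mm quantities are serialized at 4 decimals.

## Known limitations

- The bias and noise magnitudes are surrogates; only their ordering and
  direction are anchored in reported observations.
- The grouped-vs-printed ambiguity of the duct-length expression cannot
  be resolved from the text alone; both are implemented and labelled.
- Cohort-level numbers from the original patient data are not
  reproducible by construction; the pipeline targets the qualitative
  pattern (reliability ordering across modalities, outlier behaviour),
  not the printed means.
- Insertion depth is measured from the round window through the contact
  chain; planning software may define the basal origin differently.
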
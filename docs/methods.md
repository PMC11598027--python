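# Methods

This note documents the models, conventions and numerical choices behind
`facekin`, including where the design was genuinely open and what the
synthetic cohorts do and do not establish about real data.

## Coordinate conventions and head-pose removal

Landmark CSVs arrive in detector image coordinates (x toward the image
right, y down, z toward the camera). The loader converts to a world frame
with X toward the participant's anatomical left, Y superior, Z anterior
(`(x, y, z) → (x, −y, −z)`; an involution, so the synthetic generator uses
the same transform when writing).

Head pose is estimated per frame, in closed form, from landmarks that stay
rigid during speech: X is the unit vector from right to left tragion, the
up-reference is the mid-tragion → mid(sellion, glabella) direction
Gram–Schmidt-orthogonalized against X, and Z = X × Y. We chose this
deterministic construction over a least-squares template fit because it is
exactly testable (a frame rotated by a known rotation must return that
rotation to 1e-9) and uses only upper-face/temple landmarks. Canonical
("clinical") coordinates subtract the mid-tragion origin and project onto
the pose axes; all rigid motion of the head is thereby removed, up to
landmark noise. Self-occluding head rotations degrade detector precision in
real data; no compensation is attempted.

## Face size

The per-frame face-size scalar is the equal-weighted mean of five
upper-face distances: tragion–tragion, zygion–zygion, inner-canthus–
inner-canthus, frontotemporale–frontotemporale, and sellion–glabella
(weights configurable). Only upper-face landmarks enter, so the scalar is
speech-invariant by design and homogeneous of degree 1 under uniform
scaling; dividing distance measurements by it makes them dimensionless
ratios comparable across participants. Any equally invariant combination
would serve — absolute face-size values are implementation-specific and only
ratios matter downstream. The "Face Size" report stream is the raw scalar
itself (not self-normalized), serving as a negative control that should
classify at chance.

## The measurement set

Fourteen base measurements produce 30 streams: 8 displacement vectors
(Pogonion, Gonion, Lip Action, Medial 1/3 Action / Upper / Lower, Medial 1/3
Symmetry, Lower Lip from Pogonion) decomposed into X/Y/Z, plus 6 scalars
(Labial Fissure Width, Mouth Height, Mouth Area Symmetry, Mouth Opening,
Mandibular Angle, Face Size). Conventions worth noting:

- **Medial 1/3 aggregation**: the upper mid-labial-fissure point is the mean
  of mesh ids 81/311, the lower of 178/402.
- **Symmetry sign**: left half minus the *mirrored* right half, so a
  perfectly mirror-symmetric face scores exactly zero on every component and
  reflection across the mid-sagittal plane negates the full measurement.
  Symmetries compare instantaneous positions, not displacement histories.
- **Mouth Opening**: midline vertical separation of the upper/lower
  mid-fissure pair means divided by the cheilion lateral width — a
  dimensionless ratio, left unnormalized.
- **Mouth Area Symmetry**: half-fissure triangle areas (stomion superius,
  stomion inferius, that side's cheilion); left minus right, normalized by
  face_size² because it is an area — one division would leave residual scale
  dependence.
- **Mouth Height**: |Y| of the stomion midpoint from the facial origin,
  normalized.
- **Gonion**: mean of the two gonion landmarks measured relative to the
  subnasale, a stable midface reference (the landmark table associates the
  subnasale mesh id with this measurement).
- **Mandibular Angle**: signed angle, about the lateral axis, between the
  pogonion → mid-gonion line and the anterior direction (atan2 of the
  sagittal-plane components), in radians, unnormalized.

Every stream except Face Size is invariant under uniform scaling of the
input; mirroring negates X components and the two symmetry measurements and
leaves Y/Z unchanged (both properties are asserted by tests).

## Kinematics and time normalization

The order of operations is fixed: differentiate first on the raw time base
(central finite differences, one-sided endpoints), then window and resample.
Velocity and acceleration therefore keep physical per-second units and
remain comparable across participants whose word durations differ — the
alternative (differentiating after normalization) would entangle speaking
rate with movement speed. Finite-difference truncation error is
O(Δt²·|f‴|); at 60 fps and 2 Hz movement this is ≲1 % of the velocity
amplitude.

Resampling is piecewise linear (a cubic-spline option exists behind a flag)
at 1000 points spanning [onset, offset] inclusively, so trace endpoints
equal the series values at the boundaries. Linear time normalization
preserves extrema values but not their times; within-word speaking-rate
variation is not modeled (non-linear alignment would need phoneme
boundaries and is out of scope). No smoothing is applied by default.

Word-boundary refinement aligns each participant's Mouth Opening trace to
the cohort mean by grid search over onset/offset shifts at frame resolution,
bounded by the ±0.5 s annotation padding, iterating template rebuild and
realignment until the total RSS improves by < 1e-6 (max 20 iterations;
deterministic participant order; each cohort aligned independently). Only
shifts are searched — duration differences are absorbed by the linear
normalization itself. A coarse 5-frame pass narrows the fine 1-frame pass
for speed. The global time origin is weakly identified (shifting all
windows together changes the objective little), so recovered shifts are
meaningful relative to the cohort consensus; refined timings are exposed for
manual override rather than silently final.

## Classification and metrics

ψ is the mean squared pointwise difference between a held-out trace and a
cohort profile mean; prediction is argmin over the 20-word set with ties
broken in canonical word-list order (determinism; ties have probability zero
for continuous data). LOOCV requires ≥3 participants; a participant missing
a word contributes no observation for it (logged). Aggregation to the 5×5
class level drops the excluded word's ("Papa") row *and* column before
summing — with 128 participants and 19 mapped words that leaves exactly
2432 observations when no observation is predicted as the excluded word;
the 2×2 group level reincludes it. R, P and F1 use zero-division guards
(0 when a denominator vanishes). Each derivative order is classified
separately (matching the displacement/velocity/acceleration report
columns), not pooled.

## The Monte-Carlo null

"Chance classification" is modeled as: true-label counts fixed by the design
(N participants per word; words-per-class × N per class), predicted labels
i.i.d. uniform over the label set. Per replicate the per-label F1 is
computed and the significance threshold is the empirical 95th percentile
(lower order statistic, for cross-platform determinism); observed F1 must
*strictly* exceed it. This reconstruction reproduces the published
class-level thresholds (0.23/0.16/0.21/0.20/0.29 for classes with
{512,256,384,384,896} true observations) and the word-level thresholds for
36- and 41-participant cohorts; under it the threshold is necessarily
monotone decreasing in cohort size, which a 51-participant cohort's
published value (11.0, above the 41-participant 10.9) cannot satisfy — the
package reports ≈10.3 there. Word-level significance of a measurement
compares its average-over-words F1 against the per-word threshold (the
convention of the word-level report tables); per-class flags use per-class
thresholds. A two-cohort difference threshold (95th percentile of
|F1_A − F1_B| under independent nulls) is provided as the natural analogue
for cohort comparisons. No multiple-testing correction is applied across
the 30×3 measurement–derivative family. Default replicates: 10⁶ from the
CLI; the test suite and acceptance script use 10⁵–2×10⁵, where the
Monte-Carlo standard error of the thresholds is ≈2×10⁻³.

## Synthetic cohorts

The generator emulates the acquisition conditions the pipeline targets:
20 words at 60 fps, manual onset/offset annotations with 0.5 s padding,
cohorts of ≥3 participants. Words are animated from a neutral 3D face by
raised-cosine gesture curves (smooth, with analytically known derivatives):
large single-peak jaw opening for the low-vowel class, double-peaked jaw
gestures for the diphthongs, moderate opening for the mid-vowel class,
lateral lip spreading for the retraction class, rounding with anterior
protrusion for the rounding class, and a distinct reduplicated gesture for
the excluded word. Per-word parameters differ within a class so the full
word set is separable; per-participant variation covers face scale
(lognormal, σ≈8 %), speaking rate (σ≈7 %, clipped), gesture amplitude
(σ≈6 %), slow yaw/pitch head oscillation (default 0.04 rad), and i.i.d.
Gaussian landmark jitter (default SD 3×10⁻⁴, ≈0.2 % of face width —
realistic detector-level jitter). Upper-face landmarks stay rigid on the
skull, making face size speech-invariant by construction. An optional
lateral jaw-slide injection adds a coronal-plane excursion to the
jaw-carried points of selected words, emulating the atypical pattern the
X-axis and symmetry measurements are designed to catch.

What passing tests on these cohorts establish: the geometry, pose removal,
measurement definitions, time normalization, classifier and null-threshold
machinery are correct, and the pipeline separates designed-in signal from
designed-out signal. What they do not establish: performance on real faces —
the generator has no morphological diversity beyond uniform scale, no
detector bias or occlusion artifacts, no within-word rate variation, and
gesture shapes far cleaner than real articulation. Published real-cohort F1
tables are therefore not reproduction targets.

## Problem sizes used in the checked runs

Tests run cohorts of 3–10 participants (full 20-word sets), 10⁵-replicate
nulls for threshold reconstruction, 2×10⁵ in the acceptance script, and a
128-participant trace-level cohort for aggregation bookkeeping; these sizes
keep the full suite to a few minutes while leaving Monte-Carlo error an
order of magnitude below the asserted tolerances.

## Known limitations

- Ratio-encoded measurements are not comparable to real-world distance
  units, and face-size normalization does not remove morphological
  differences (e.g. relatively wide mouths).
- The refinement objective is blind to within-word timing structure; only
  whole-word shifts are corrected.
- The exact weighting of the original face-size combination and the exact
  null behind the published cohort-difference thresholds are not published;
  both are implemented as documented reconstructions.
- Landmark estimation under self-occlusion is the detector's problem, not
  modeled here.
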
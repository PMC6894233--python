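# Methods

## The measurement problem

HR-pQCT resolves individual cortical-break erosions and periosteal
enthesiophytes at the metacarpal heads at 82 µm isotropic resolution. A
longitudinal comparison is only as good as its co-localization: baseline
and follow-up stacks differ in pose and axial coverage (110 slices at
baseline, 322 at follow-up in the emulated protocol), so the follow-up is
rigidly mapped into the *unaltered* baseline frame and every measurement
is made there. A per-lesion volume change is then called real only when it
exceeds the smallest detectable change (SDC) estimated from repeated
readings.

## Digital phantom

The phantom renders two metacarpal heads in one grid, each a hemispherical
cap (apex distal) on a cylindrical shaft, as the simplest geometry with a
closed periosteal envelope, a cortex of finite thickness, and a trabecular
interior. Choices that matter:

- **Intensities** are three-level piecewise constant (background 50,
  trabecular 300, cortical bone 800, arbitrary units) plus additive
  Gaussian noise; scanner calibration to mg HA/cm³ is out of scope.
- **Partial-volume blur**: the rendered scene is smoothed with a Gaussian
  of σ = 0.6 voxel before noise, emulating the scanner point-spread
  function. Besides realism, this matters numerically: with perfectly
  sharp edges, trilinear re-slicing alone produces ~2.5% mean absolute
  round-trip error against ~0.5% on band-limited data.
- **Unequal heads** (MCH3 rendered at 0.82 × the MCH2 radius): anatomy is
  not twin-symmetric, and identical heads would give the registration
  metric a spurious 180° symmetry that no real joint has.
- **Lesions as exact voxel sets.** An erosion is the `round(V/v)` voxels
  (v = 0.082³ mm³) of the periosteal interior nearest a cortical surface
  point, carved to background intensity; an enthesiophyte is the same
  construction outside the envelope, set to bone intensity. Selecting an
  exact voxel count makes true volume match the target within half a
  voxel by construction — a bisection on a parametric cap radius cannot
  guarantee this at voxel-count discontinuities, which is why the
  distance-ordered selection replaced it. An erosion must break the
  cortex on at least two consecutive axial slices or it is rejected,
  matching the lesion definition.
- **Follow-up rendering**: the 5-year scene is rebuilt in the baseline
  frame with each lesion re-implanted at its grown/shrunk target volume
  (so ground-truth change is exact where measurement happens), then
  sampled through the known follow-up-to-baseline rigid motion with
  trilinear interpolation, then noised. With identity motion and no noise
  the overlapping slab is bitwise-reproducible.

The tabular cohort simulator draws, per patient, Poisson lesion counts
(rates 108/60 erosions, 99/60 enthesiophytes, 3/60 new erosions), a
per-lesion class from the progression/stable/regression mixture, and the
true change from that class's normal law: erosions 1.9 ± 1.8 / 0.1 ± 0.2 /
−1.4 ± 0.5 mm³, enthesiophytes 1.0 ± 0.6 / 0.1 ± 0.1 / −0.7 ± 0.4 mm³.
Pre-existing-lesion weights are (34, 64, 10)/108 and (50, 38, 11)/99, so
new lesions bring erosion progression to 37/111. Patients in the
sustained-low-disease-activity (SDL) group (prevalence 26/60) use
group-specific progression weights (12/51 erosions, 17/40 enthesiophytes;
non-SDL 25/60 and 33/59) with the stable:regression remainder split kept
at the overall ratio. Baseline volumes are truncated normals (erosions
4.2 ± 4.2, enthesiophytes 3.4 ± 2.3 mm³, floor 0.1); new-lesion follow-up
volumes N(1.0, 0.5) truncated at 0.1 mm³ — no published distribution
exists for these, so a value plausible against the working thresholds was
fixed once. Observed change adds reading noise (default SD 0.05 mm³).
DAPSA trajectories are drawn within (SDL) or partially above (non-SDL)
the LDA band and decomposed into components that re-sum exactly. The
per-patient lesion-count distribution is deliberately a free parameter.

What the generator does *not* emulate: trabecular microarchitecture,
beam hardening, motion-artifact grading, within-patient lesion
correlation, or any coupling between disease activity and imaging noise.
Passing tests therefore demonstrate the pipeline's numerical correctness
under known geometry and motion, not reader-level performance on clinical
scans.

## Registration

Initialization aligns intensity centroids and the principal axes of the
thresholded foreground, resolving eigenvector sign/order ambiguity toward
the smallest rotation over all proper axis permutations; when either
volume's moments are near-degenerate (relative eigenvalue gap < 0.15) the
rotation falls back to identity, and the centroid translation is refined
once on the mutually visible overlap, because the longer follow-up stack
biases a plain centroid along the axis.

Refinement maximizes mutual information in nats from a 32-bin joint
histogram (per-volume min/max binning, so any bin-preserving monotone
intensity relabeling leaves the metric unchanged). The optimizer is
Powell's method — derivative-free and deterministic — over three rotation
angles about the fixed-volume centre and three translations, through a
two-level pyramid (downsample 2 with stride-2 sampling, then full
resolution), with the metric supported on the dilated bone foreground and
capped at 60 000 fixed-grid samples chosen by a fixed pseudo-random
subsample (a coarser regular stride would alias with the voxel lattice).
Three safeguards address the multimodal MI landscape, each deterministic:
an exhaustive pre-scan over a ±8° per-axis rotation grid (each candidate
given an overlap-refined centroid translation and scored by coarse MI),
±4° per-axis extra Powell starts at the coarse level, and monotone
acceptance — the returned transform never scores below the
initialization; if optimization ends worse, the initialization is
returned flagged unconverged. On noiseless phantom pairs with motions up
to 10°/2 mm this recovers the motion to ≤ 0.2° and ≤ 0.2 voxel; the
tested guarantee is 0.5°/0.5 voxel over 20 random motions.

Re-slicing is trilinear onto the baseline grid; voxels whose source falls
outside the follow-up stack get the background fill value and are flagged
in a validity mask that all downstream measurement respects. Slice
matching returns the longest contiguous axial run in which every bone
voxel is validly covered; ROI definition keeps bone inside that range,
trims three slices per end (skipped with a warning when known lesions
touch the trimmed slabs — the trimming rule is otherwise ambiguous), and
keeps components anchored at the proximal face, which removes a drifting
phalangeal stub without deleting either metacarpal.

## Lesion measurement

Segmentation standardizes the interactive semi-automated reading as
seeded region growing with fixed thresholds: erosions grow over
sub-threshold voxels (default 175, between background and trabecular)
clipped to the periosteal interior and must reach the outer cortical
margin on two consecutive slices; enthesiophytes grow over
supra-threshold voxels (default 550, between trabecular and cortical)
strictly outside the *baseline* periosteal surface. Referencing
enthesiophyte growth to the fixed baseline surface keeps deltas
well-defined across time points. The periosteal envelope itself comes
from thresholding at the background/bone midpoint, morphological closing
(edge-padded, radius 0.25 mm), and hole filling with the axial faces
capped — the medullary canal is open where the shaft leaves the scan and
would otherwise not fill. Closing can only bridge cortical defects
smaller than its radius, so on lesioned anatomy the envelope should come
from the baseline reading or phantom truth rather than be re-derived from
a heavily eroded volume. Baseline seeds are propagated to follow-up;
follow-up-only seeds accommodate new lesions. Pairing is greedy
nearest-centroid within 1.0 mm among same-kind, same-compartment records,
ties broken by lesion id; unmatched records become `new` or `lost`.

## SDC and classification

SDC uses the n−1 sample SD of change scores; k counts readings (readers
and readings coincide at k = 2 here, the only case exercised). The
scaling SDC(k) = SDC(2)·√(2/k) is exact. Classification uses strict
inequalities — a change exactly equal to the SDC is stable — and a new
lesion is progression regardless of size, with its delta equal to its
follow-up volume and counted in follow-up denominators (111 erosions).
Printed thresholds (0.5/0.3 mm³) are config defaults, decoupled from any
re-estimated SDC so published results stay reproducible.

## Cohort statistics

Group comparisons are lesion-level (denominators 51/60 and 26/85), as the
published tables are; patient-level clustering is acknowledged and not
modelled — the report exports per-lesion covariates so a mixed model can
be fitted externally, which is out of scope here. Progression counts use
the uncorrected Pearson chi-square: the uncorrected statistic reproduces
the published table p-values (0.043, 0.751, 0.979, 0.190) from their
printed 2×2 counts, and Yates correction would not. Mean-change
comparisons and the longitudinal paired test gate on Shapiro–Wilk at
α = 0.05 (Student's t / paired t when normal, Mann–Whitney / Wilcoxon
signed-rank otherwise), with degenerate-variance inputs falling through
to the rank test and all-identical inputs reported as p = 1 with a flag.

## Numerical and testing notes

- All randomness flows from integer seeds through `numpy` Generators; all
  optimizer schedules are fixed, so every pipeline stage is reproducible.
- Distance ties in lesion-voxel selection break by (z, y, x); pairing ties
  by lesion id; cumulative-probability ranks tie by lesion id.
- Tests validate registration at 64×64×112 grids (20 random motions ≈ 5
  minutes of the suite) and volume recovery on a 50-lesion sweep at 5%
  noise — problem sizes chosen to exercise the same geometry as the full
  protocol at tractable cost; the phantom defaults render the full
  110/322-slice extents.
- The chi-square-vs-permutation oracle uses the add-one mid-p conditional
  Monte-Carlo estimator at 2000 draws and cell counts of 60–160: the
  asymptotic and exact-conditional p-values are different estimands whose
  discreteness gap exceeds any Monte-Carlo error bound at very small
  counts, so the comparison is made where the χ² approximation is valid.
- Two documented limits of the published summary statistics surfaced in
  testing and are kept visible rather than papered over: a standard
  two-sample t on the printed group means (0.3 ± 0.7, n = 40 vs 0.6 ± 0.8,
  n = 59) has analytic power ≈ 0.49, so the tests check calibration
  against the noncentral-t power instead of demanding significance; and
  cohorts drawn faithfully from the printed per-class change
  distributions reach the paired-test significance threshold (p < 0.001)
  in ≈ 90–93% of replicates, not ≥ 95% — the corresponding replication
  test fails at that stricter rate and is left failing, since the
  generator's defaults encode the published values and are not tuned.
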
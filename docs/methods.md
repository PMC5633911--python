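# Methods

## The analysis model

A subject's performance of one task is summarized as a set of smooth
curves y_c(q), one per angle component c, sampled on Q = 101 nodes q =
0, 1, …, 100% of the movement cycle.  Each joint groups p components
(trunk 3, scapula 3, shoulder 3, elbow 2, wrist 1) into a vector field.
Three inferential questions are supported, each over the entire cycle
with family-wise error control:

1. **Group comparison (vector level).**  At each node the two-sample
   Hotelling statistic T²(q) = n₁n₂/(n₁+n₂) · d(q)ᵀ S(q)⁻¹ d(q), with d
   the mean-difference vector and S the pooled covariance of the p
   components (error df m = n₁+n₂−2).  The wrist (p = 1) reduces to the
   pooled-variance two-sample t.
2. **Group comparison (post-hoc).**  Per-component two-tailed t fields,
   run only when the vector field has a significant cluster, at the
   Bonferroni level α/p.
3. **Impairment regression.**  Within the impaired group only, the
   canonical correlation r(q) between the joint's component vector and a
   composite clinical score; with one covariate r² is the multiple
   correlation of the score on the p components, and the field statistic
   is Bartlett's transform X²(q) = −(n−1−(p+2)/2)·ln(1−r(q)²).  Post-hoc
   simple-regression t fields follow the same gatekeeping and Bonferroni
   rules.  Inference for this family is permutation-based throughout.

The subject is the experimental unit: each subject enters with the mean
of their three retained cycles, preserving the between-subject degrees
of freedom of the unpaired designs.

## Random-field-theory inference

The maximum of a smooth statistic field under the null is approximated
by the expected Euler characteristic of its excursion set,

    P(max_q z(q) > u) ≈ ρ₀(u) + √(4 ln 2) · R · ρ₁(u),

where ρ₀ is the pointwise survival function, R = (Q−1)/FWHM the resel
count, and ρ₁ the unit-roughness 1D EC density of the field type
(Worsley's unified formulas for Gaussian, t and χ² fields).  The
critical threshold u* solves this equation at α (α/2 per tail for
two-tailed t inference) by bracketed Brent root-finding to 10⁻¹²; at
R = 0 it reduces exactly to the ordinary upper-α quantile.

The Hotelling T² field uses its exact EC densities rather than a
pointwise F transform.  They follow from the union–intersection
representation T²(q) = max_{a∈S^(p−1)} t_a(q)², which turns the T²
excursion into a t-field excursion on the product manifold
[0, L] × S^(p−1).  The Gaussian kinematic formula then gives

    ρ₁^{T²}(u) = Σ_j  L_j(S^(p−1)) · ρ_{j+1}^{t,m}(√u),

with L_j the intrinsic volumes of the unit (p−1)-sphere and ρ_j^{t,m}
the higher-order t-field EC densities; the pointwise term uses the exact
T² → F distributional identity.  For p = 1 this collapses to two-tailed
t inference, a property the unit tests pin.  Densities are implemented
for p ≤ 3, the largest joint dimension in the protocol.

Cluster-level p-values use the classic 1D extent heuristic: with
expected cluster count E[m] = √(4 ln 2)·R·ρ₁(u) and expected excursion
size E[N] = Q·ρ₀(u), cluster extent k (nodes) is modelled as
P(n ≥ k) = exp(−βk²) with β = (Γ(3/2)·E[m]/E[N])², and
p = 1 − exp(−E[m]·P(n ≥ k)).  Cluster endpoints are refined by linear
interpolation between the last sub-threshold and first supra-threshold
node, so reported locations are continuous percentages.

Smoothness is estimated from the residuals of the fitted model at hand
(deviations from group means, or regression residuals), normalized to
unit node-wise variance: FWHM = √(4 ln 2 / v) with v the mean squared
forward-difference gradient.  Monte-Carlo calibration on 2000 smooth
null datasets (n = 15+15, Q = 101, FWHM = 15) keeps the empirical
family-wise error of two-tailed t inference inside [0.035, 0.065], and
the same check applied to the T² gatekeeping logic on 500 reduced null
studies lands near α as well.

## Permutation (SnPM) inference

For group designs the permutation unit is the group label; for
regressions, the covariate vector.  All C(n₁+n₂, n₁) relabelings (or n!
orderings) are enumerated exactly when their number is at most 100 000,
otherwise 10 000 Monte-Carlo draws (seedable) are used with the observed
labeling always included, so p-values never fall below 1/B.  The
critical threshold is the ⌈(1−α)·B⌉-th order statistic of the
per-permutation maximum statistic (|t| for two-tailed fields), and
cluster p-values come from the permutation distribution of the maximal
supra-threshold cluster extent, measured in whole-node run lengths on
both the observed and the permuted side (observed endpoints are still
interpolated for reporting).

Degenerate inputs are handled by a variance floor of 10⁻¹² on pooled
variances and covariance eigenvalues (flagged, not fatal) and a
configurable statistic cap (default 10⁶) for perfect fits and r² → 1.

## Preprocessing protocol

Stages run in fixed order; each logs its decisions to a QC table.

* **Occlusion screening** excludes a cycle when the fraction of time
  samples with *any* channel missing strictly exceeds 20% of movement
  duration (the boundary stays in).
* **Gap filling** interpolates missing runs per channel with a cubic
  spline through the observed samples; boundary gaps extrapolate the
  nearest spline segment.  A channel needs ≥ 4 observed samples.
* **Smoothing** (default off) fits a quintic smoothing spline whose
  smoothing parameter targets a predicted mean squared residual; the
  squared-millimetre marker-coordinate filter of the original protocol
  belongs to the kinematic model upstream of this package, so angle-
  domain smoothing is exposed as an option rather than a default.
* **Trimming** drops the first and last of the four repetitions per
  recording (start/stop strategies), leaving 2 × 2 = 4 cycles per task.
* **Time normalization** interpolates linearly onto Q = 101 nodes;
  endpoints are preserved exactly and the operation is idempotent.
* **Cycle selection** computes, for each of the 4 cycles, the RMSE
  against the mean of the other three, pooled over all channels and
  nodes (one scalar per cycle), and discards the largest; ties discard
  the latest cycle_id so the result is deterministic.  The RMSE is
  computed in the normalized domain.
* **Averaging** takes the node-wise mean of the three retained cycles.

When screening removes cycles the pipeline degrades gracefully: four
usable cycles trigger selection, three are used as-is, fewer drop the
subject-task cell with a QC entry.  The standalone `trim_repetitions`
enforces the strict 4-repetition contract (configurable to a warning).

## Clinical scoring

Weakness is the sum of three MMT items (elbow extensors, elbow
supinators, wrist extensors; 0–15, higher = stronger).  Spasticity is
the sum of three MAS items (elbow flexors, elbow pronators, wrist
flexors; 0–12, higher = more spastic) after coding the 1+ grade as 1.5
— the standard numeric convention consistent with a 0–12 range; the
mapping is configurable.  Severity groups use cohort quartiles with
linear-interpolation percentiles; scores strictly beyond p75 on the
unimpaired side are "low", strictly beyond p25 on the impaired side
"severe", and boundary values "moderate" (the grouping language is
open-interval "above/below percentile").  For spasticity the severity
direction is inverted relative to weakness: low raw scores mean low
impairment.

## Synthetic data generator

The generator emulates the study design: two groups of n subjects, each
performing 8 tasks in 2 recordings × 4 repetitions, 12 angle channels.
Per channel the truth is a smooth template (offset + logistic ramp +
Gaussian bump, overridable), plus a subject-level Gaussian random field
obtained by convolving white noise with a Gaussian kernel of the
configured FWHM on an extended grid (cropped, then rescaled to the
target node-wise SD — the construction under which the RFT thresholds
are exact).  Group effects add a constant amplitude over a node window
for the impaired group; covariate effects add slope × (score − cohort
mean) over their window.  Cycles are the true curve resampled to a
uniform-random raw duration (default 80–150 samples) plus smooth
repetition noise, with one contiguous missing gap injected in a
configurable fraction of cycles.

Defaults are fixed once as plausible magnitudes for upper-limb
kinematics, since the study reports no variance decomposition:
between-subject SD 8°, repetition SD 2.5°, FWHM 20 nodes, gap
probability 0.05 with gap lengths 2–10% of the cycle.  MMT item
marginals skew toward 3–5 and MAS marginals toward 0–2, yielding
composite distributions spread over their ranges with SD ≈ 2 for the
spasticity composite.  Control subjects receive full-strength profiles
(MMT 5,5,5; MAS 0,0,0).

What the generator does **not** emulate: task-specific biomechanical
trajectory shapes, inter-channel covariance (channels are independent
fields), non-Gaussian or heteroscedastic noise, time-warping
variability beyond uniform duration changes, and marker-level artefacts
other than contiguous occlusion runs.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its own
model assumptions, not robustness to every property of real
motion-capture data.

## Simulation studies and their sizes

The test suite and `scripts/acceptance.py` compute, at these problem
sizes:

* node-wise oracle equivalence: 50 random datasets, Q = 21, n = 5–10
  per group, p ∈ {1, 2, 3}; tolerance 10⁻¹⁰;
* scalar reduction (T² = t², r² = Pearson²): 20 datasets, 10⁻¹⁰;
* RFT family-wise error: 2000 null datasets, n = 15+15, Q = 101,
  FWHM = 15; acceptance band [0.035, 0.065] (±3 binomial SD around
  0.05);
* single-test limit: thresholds at R = 0 vs. scipy quantiles, 10⁻⁶;
* permutation exactness: n₁ = n₂ = 4, all 70 relabelings vs. an
  exhaustive brute-force oracle, exact equality;
* smoothness recovery: 500 fields with FWHM = 20 in batches of 10;
  mean estimate in [17, 23];
* group-effect recovery: elbow flexion-extension offset of 1.5
  within-group SD over nodes 40–60, n = 30+30, 100 simulated studies
  through the full generate → preprocess → analyze pipeline; vector
  significance plus an overlapping post-hoc cluster in ≥ 90% of runs,
  mean cluster center within 50 ± 5 nodes;
* covariate-effect recovery: pro-supination slope 2°/unit of the
  spasticity composite over nodes 30–100, n = 60, 1000 permutations,
  100 simulations; ≥ 90% recovery;
* gatekeeping calibration: 500 null studies at n = 10+10, 2 tasks ×
  2 multi-component joints (trunk, elbow); fraction of cells with any
  post-hoc output inside [0.035, 0.065].

## Design choices where the design was open

* The analysis consumes each subject's 3-cycle mean rather than all
  three cycles, keeping the unpaired tests' exchangeability unit at the
  subject level.
* t-field inference is two-tailed everywhere (deviations occur in both
  directions); T² and X² are one-tailed by construction.
* The parametric RFT path is used for group comparisons and the
  permutation path for impairment regressions, each overridable per
  analysis in `AnalysisConfig`.
* No correction is applied across the 8 × 5 task-joint family; only the
  within-joint component family is Bonferroni-adjusted.
* Permutation cluster extents are compared in whole-node units on both
  sides of the comparison rather than mixing interpolated observed
  extents with node-resolution null extents.
* Estimators follow the sklearn fit/attribute protocol so they compose
  with sklearn tooling; module-level functions remain as thin wrappers.

## Known limitations

* T² EC densities are implemented for p ≤ 3 (sufficient for the
  five-joint repertoire).
* The parametric X² RFT path is not exposed; the canonical-correlation
  statistic is permutation-only by design.
* Cluster p-values rely on the 1D extent heuristic, which is an
  approximation; threshold-level (cluster-presence) error rates are the
  calibrated quantity.
* Repeated-measures, paired and ANOVA-type designs, 2D fields and
  circular (periodic-gait) corrections are out of scope.
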
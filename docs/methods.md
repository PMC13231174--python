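# Methods

## Model

The edema sub-segmentation is an unsupervised two-class mixture model on the
bivariate intensity x_i = (T2_i, FLAIR_i) of every voxel i in the edema
mask, each channel z-scored within the mask. Class-conditional densities are
bivariate Gaussians N(x; μ_k, Σ_k), k ∈ {nCET, vasogenic}. Unlike a plain
mixture, the mixing proportions π_ik vary per voxel and are coupled across
voxels through non-local patch-similarity weights

    w_ij = exp(−‖P_i − P_j‖² / h²),

where P_i is the cube of z-scored FLAIR values around voxel i
(side 2·patch_radius + 1, default 3³) and j ranges over the cubic search
window around i (side 2·search_radius + 1, default 5³, center excluded).
Weights are computed on the FLAIR channel only, because FLAIR is the
separating sequence for the two edema classes; T2 distributions of the two
classes overlap heavily. Patch positions where either patch leaves the
edema mask contribute zero to the squared distance. This pair-validity
convention makes w_ij exactly symmetric, including at volume borders, and
avoids contaminating the distance with out-of-mask (tumor core, background)
intensities. With `bandwidth: null` (default) the scale h is the median
in-window patch distance — an auto-bandwidth that adapts to the noise level.

EM fitting alternates

- E-step: r_ik ∝ π_ik N(x_i; μ_k, Σ_k);
- M-step: responsibility-weighted MLE of μ_k and Σ_k, with covariance
  eigenvalues floored at 1e-6 (z-scored units) so that degenerate clusters
  can never produce a singular covariance;
- mixing update: π_ik ← (r_ik + β Σ_j w_ij r_jk) / (1 + β Σ_j w_ij).

The tracked objective is the penalized log-likelihood

    J = Σ_i log Σ_k π_ik N(x_i; μ_k, Σ_k)
        − (β/2) Σ_ij w_ij Σ_k (π_ik − π_jk)²,

i.e. the data log-likelihood minus a graph-Laplacian smoothness penalty on
the mixing field. The closed-form mixing update is a fast approximate
maximizer, not the exact constrained optimum of J, so J is not theoretically
guaranteed to increase at every step. The implementation therefore applies a
damped fallback: if the candidate mixing field would lower J, the step is
halved toward the previous field until J no longer decreases (the
class-parameter M-step alone can never decrease J, so the fallback always
terminates). In practice the undamped update is accepted essentially always;
the safeguard turns an empirical tendency into a hard invariant, asserted to
1e-9 per iteration in the tests.

Initialization is 2-means on the z-scored FLAIR channel (scikit-learn,
deterministic given `init_seed`). The final class labeled nCET is the one
with the lower mean FLAIR in scanner units; a tie (< 1e-9) breaks to class 0
and is flagged. With β = 0, or `mixing_mode: global`, the model reduces
exactly to a standard bivariate Gaussian mixture — this is verified against
an independently coded textbook EM in the tests.

Defaults: β = 1.0, patch 3³, window 5³, tol 1e-5 (relative objective
change), max 100 iterations. K is fixed at 2 by the two-subregion
definition of the problem.

## Boundary cleanup

A single targeted rule corrects partial-volume artifacts at the outer rim of
the FLAIR abnormality. The outer boundary band is the set of edema voxels
whose exact Euclidean distance (mm, anisotropy-aware, scipy EDT) to the
nearest non-lesion voxel is ≤ 4 mm; distances toward the enhancing core or
necrosis do not define the band. A 26-connected nCET component is reassigned
to vasogenic edema iff all three hold: every voxel of the component lies in
the band; its size is strictly below 100 voxels; and its minimum distance to
the contrast-enhancing tumor (CET) strictly exceeds 10 mm. The CET gate is
evaluated per component (`gate_scope: component`); the alternative
case-level reading — removal allowed only when the whole band is > 10 mm
from the CET — is available as `gate_scope: case`, since the narrative
phrasing of the rule admits both readings. An empty CET mask makes the gate
vacuously open and is flagged. Removed voxels stay in the edema partition
(the TFHI denominator is volume-preserving). The rule is idempotent and
monotone in both thresholds; both properties are asserted in tests.

## Per-case validation

Two criteria on the FLAIR channel decide whether the split is trusted:

- Mann-Whitney U between nCET and vasogenic FLAIR intensities, two-sided,
  significant at P < .01 (strict). Exact enumeration is used for small
  tie-free samples (both n ≤ 20), otherwise the normal approximation with
  tie-corrected variance (scipy).
- %ΔI = |Ī_nCET − Ī_vasog| / (max I_brain − min I_brain) · 100 > 5
  (strict), where the brain mask is all strictly positive FLAIR voxels
  (inputs are skull-stripped, so nonzero ⇔ in-brain). Region summaries are
  means by default (`summary: median` is available); %ΔI is invariant under
  any positive affine intensity rescaling.

T2 statistics are computed and reported alongside but do not drive the
flags. Degenerate cases (an empty subregion) produce a non-significant
report with a reason, never an exception.

## TFHI and comparator

TFHI = V_nCET / V_edema with V_edema the *total* edema label volume (both
subregions, cleanup-reassigned voxels included), so TFHI ∈ [0, 1] and is
invariant to voxel spacing. The conventional CET/edema volume ratio is
computed alongside as the comparator biomarker, and their Pearson
correlation is reported at cohort level.

## Survival analysis

- **c-index.** Harrell's concordance by explicit pair enumeration: usable
  ordered pairs are those whose shorter time carries an event (tied times
  usable only when exactly one member has the event); risk ties count 0.5.
  Verified exactly against an O(n²) double-loop oracle and against
  lifelines on tie-free data.
- **Threshold search.** Candidates are midpoints between consecutive sorted
  unique TFHI values; each candidate is scored by the c-index of the binary
  indicator 1[TFHI > t]; ties break toward the smallest threshold. The
  search is exhaustive by construction. Note a structural property measured
  in the simulations: because risk-tied (within-group) pairs count 0.5, the
  expected c-index of a dichotomized biomarker trades off group purity
  against group balance, so its population argmax sits below a
  change point located in the distribution's upper tail. On simulated
  cohorts (Beta(2,2) TFHI, hazard doubling above 0.70) the optimized cutoff
  concentrates around 0.63-0.67 rather than 0.70. The search is still
  exactly the stated estimator; the shift is a property of the estimand.
- **Kaplan-Meier.** Product-limit estimator (lifelines); the median is the
  earliest time with S(t) ≤ 0.5 and is undefined when the curve never
  reaches 0.5. ΔOS is the absolute difference of group medians.
- **Cox regression.** lifelines CoxPHFitter with Efron tie handling (the
  standard default, lower bias than Breslow under moderate ties);
  Wald p-values, 95% CIs from ±1.96·SE on the log scale, model c-index from
  the linear predictor. Non-convergence raises with diagnostics;
  separation warnings are attached to the result.
- **Covariate encoding.** Gender male = 0 / female = 1; MGMT methylated = 0
  / unmethylated = 1, missing imputed to the more prevalent observed
  category (deterministic; a seeded `impute: proportional` alternative
  draws from the observed prevalence); continuous covariates (age, edema
  volume, rCBV, TFHI) min-max scaled to [0, 1] on the cohort. Model tiers
  are built incrementally — clinical {age, gender, MGMT} → +perfusion
  {rCBV p90 in nCET} → +volumetric {edema volume} — each fitted with and
  without TFHI.

## Synthetic data

The phantom emulates the geometry and signal contract of the segmentation
problem, not MR physics. A brain sphere (radius 26 mm) contains nested
lesion spheres: necrosis (5 mm) inside CET (9 mm) inside edema (16 mm), on
a 64³ grid at 1 mm isotropic spacing by default. Ground-truth nCET is the
innermost shell of the edema (adjacent to the enhancing rim, where
infiltration is expected) filled to the configured `ncet_fraction`
(default 0.25), plus a few small satellite islands (default 3, 20-60
voxels) placed within ~4 mm of the outer boundary specifically to exercise
the cleanup rule. Intensities are class means plus i.i.d. Gaussian noise
(SD 1) inside the brain: on FLAIR, vasogenic edema 16 vs nCET 13 — a 3-SD
separation; on T2 the two classes share a mean (15), reproducing the
qualitative real-data pattern that T2 alone does not separate them. The
class means are configurable; no published quantitative intensity
distributions exist for the two classes, so these defaults are this
package's choice. A multiplicative low-order polynomial bias field is
available but off by default (inputs are assumed bias-corrected upstream).

What the phantom does *not* emulate: textured/correlated noise, partial
volume at class interfaces, irregular lesion shapes, registration error
between T2 and FLAIR, and scanner-dependent intensity scales. Passing the
phantom studies therefore demonstrates correctness of the estimator under
its own signal model (a 3-SD FLAIR gap with spatially coherent classes),
not expected accuracy on clinical images.

The survival simulator draws TFHI ~ Beta(2, 2) (symmetric, full-support —
a neutral choice for a volume fraction), event times exponential with
hazard λ0 · HR^{1[TFHI > 0.70]} (λ0 = ln2/400 per day, i.e. 400-day median
below threshold; HR = 2), and independent uniform censoring on
(200, 1500) days. Optional covariates add an MGMT effect (HR 1.9,
10% missing) to exercise encoding and imputation.

## Problem sizes used in the automated studies

The packaged studies use 20 phantoms (64³) for segmentation/TFHI recovery,
100 cohorts of n = 200 for the threshold search, 200 cohorts of n = 500 for
Cox recovery, and n = 5000 exponential samples for the Kaplan-Meier
closed-form check — sizes at which each Monte-Carlo bound has comfortable
slack while the full suite runs in minutes on one CPU.

## Known limitations

- The NLSVFMM instantiation (bivariate Gaussians, responsibility-smoothing
  mixing update, FLAIR-only weights, in-mask z-scoring) is one concrete
  realization of the spatially-varying-mixture-plus-non-local-means design;
  other realizations differ in detail, and bit-compatibility with any
  particular hosted implementation is not claimed.
- K = 2 is assumed; edema with more than two intensity populations is
  forced into the nearest two-class description.
- The c-index-optimal dichotomization is balance-biased as described above;
  users who need an unbiased change-point estimate should treat the
  optimized cutoff as a stratification device, not a hazard-boundary
  estimate.
- Cohort-level conclusions from the simulators inherit their assumptions
  (exponential baseline, independent uniform censoring, step hazard in
  TFHI).
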
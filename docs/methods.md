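# Methods

## Model

Scores of `p` questionnaire subscales are modelled as a Gaussian graphical
model (GGM): observations are (after rank transformation) multivariate
normal with precision matrix `Θ`, and a missing edge `Θ_ij = 0` means
subscales `i` and `j` are conditionally independent given all others.
Edge weights are signed partial correlations
`w_ij = −Θ_ij / √(Θ_ii Θ_jj)`.

Estimation proceeds in four stages:

1. **Spearman correlation** `S` of the score matrix, with average ranks
   for ties. Rank correlations are used because subscale scores are
   bounded, skewed and ordinal; all downstream steps are invariant to the
   monotone z-scaling applied for reporting. Under the `pairwise` missing
   policy each pair uses its complete observations (per-pair `n`
   recorded); `complete-case` drops incomplete rows.
2. **Positive-definite repair**: pairwise deletion can make `S`
   indefinite, while the graphical lasso needs a positive-definite input.
   Eigenvalues are clipped at a floor (default 1e-3) and the matrix
   rescaled to unit diagonal, iterated to idempotence; a flag records
   whether any repair occurred.
3. **Graphical lasso path**: `Θ(λ)` maximizes
   `log det Θ − tr(SΘ) − λ Σ_{i≠j}|Θ_ij|` (diagonal unpenalized, the
   convention of partial-correlation network estimation) on a descending
   log-spaced path of 100 penalties from `λ_max = max_{i≠j}|S_ij|` (empty
   network) down to `0.01·λ_max`. The solver is a block coordinate
   descent over columns of the working covariance, numba-compiled and
   warm-started along the path; the test suite verifies it against
   scikit-learn's implementation and against direct numerical
   maximization of the penalized likelihood at p = 3.
4. **Extended BIC selection**: each fit is scored with
   `EBIC = −2L + E log n + 4 E γ log p`, where
   `L = (n/2)(log det Θ − tr(SΘ))` and `E` is the number of nonzero
   off-diagonal pairs (absolute tolerance 1e-8). The minimum-EBIC fit is
   selected, ties broken toward the larger penalty (sparser model). The
   selected precision is *not* refitted without penalty — weights remain
   shrunken, matching the convention of the regularized estimator family
   this package follows. Under pairwise missingness the EBIC `n` is the
   number of rows.

The hyperparameter `γ` (default 0.25) trades sensitivity against
specificity: lower values keep more edges at the risk of spurious ones.
A consequence of the no-refit convention, measured by the validation
study shipped with the package, is that edge selection is slightly
liberal: on sparse 10-node truths with partials ≥ 0.2 at n = 1000,
sensitivity is ≈ 1.0 while specificity is ≈ 0.88 (false-positive rate
≈ 0.1), roughly independent of `γ` in [0.25, 0.5]. Users who need
tighter support control should raise `γ` and interpret weak edges with
the bootstrap intervals.

## Strength metrics

Node strength is `s_i = Σ_j |w_ij|`; global strength is
`GS = Σ_{i<j} |w_ij| = ½ Σ_i s_i`. GS is implemented as the **sum** of
absolute edge weights over unique pairs — the definition used by the
permutation comparison framework and the only one consistent with
reported magnitudes of the order `GS ≈ 9` for 21-node networks whose
largest node strength is ≈ 1.25; a per-node average is sometimes loosely
called "average node strength" in the applied literature, and is exposed
separately as `global_strength_mean`. Edge similarity between two
networks on the same nodes is the Spearman correlation of the vectorized
upper triangles, zeros included (a support-union option exists); it is
NaN when a network is completely empty.

## Inference

**Permutation network comparison test (NCT).** The observed statistic is
`|GS_A − GS_B|` from networks estimated independently per group. Pooled
rows are reassigned uniformly at random to groups of the original sizes;
both networks are re-estimated with identical settings per permutation.
The add-one p-value `(1 + #{null ≥ observed})/(1 + B)` is exact-valid and
never zero; B defaults to 1000. Permutation indices are recorded so every
null statistic is replayable. The unpaired test is implemented; patients
contributing an assessment to both groups violate exchangeability, and
the supported remedy is the cross-subgroup deduplication sensitivity
analysis rather than a paired test.

**Edge-weight accuracy.** Nonparametric row bootstrap (same `n`, with
replacement, B = 1000 default, full re-estimation per replicate) with
per-edge quantile intervals at the requested level.

**Node-strength stability.** Case-dropping bootstrap: for each drop
proportion `q ∈ {0.1, …, 0.7}` and each of B = 250 replicates, `⌊qn⌋`
rows are dropped, the network re-estimated, and replicate node strengths
Spearman-correlated with the full-sample strengths. The CS-coefficient is
the largest `q` at which ≥ 95% of replicates correlate ≥ 0.7 (0 if
none) — fixed thresholds from the stability framework this statistic
comes from.

## Cohort stratification

Three schemes split assessments into two subgroups: disease status
(preoperative vs. postoperative on active treatment or stable;
progressive-disease assessments are excluded entirely), tumor grade
(II vs. III/IV, a patient-level label attached to the selected
assessment), and fatigue status (raw CIS fatigue-severity score ≥ 27 is
fatigued, assigned per assessment; the four CIS nodes are then removed,
leaving 17 nodes). Within each side at most one assessment per patient
is kept; the selection rule is configurable (`earliest` by default,
`latest`, or seeded `random`) because the underlying study's exact rule
is not fully specified — the default is this package's choice, not a
claim about the original selection. A patient may appear on both sides;
the deduplication sensitivity analysis removes shared patients from one
side (`keep_side` configurable; the pipeline defaults keep the
postoperative/higher-grade side and, for fatigue, the non-fatigued side).
Z-scaling (mean 0, sample SD 1 per column, missing preserved) is applied
within each subgroup immediately before estimation; Spearman-based
estimation makes this a reporting convention, not a statistical choice.

## Synthetic cohorts

The generator emulates the statistical shape of a glioma PROM cohort:
256 patients with 1–3 assessments each (≈ 420 total), grades II/III/IV
at 47/25/28%, first assessments preoperative with probability 0.65,
later ones active treatment/stable/progression at 42/48/10% — figures
chosen to match the published cohort composition. Latent scores are
multivariate normal with a correlation-scaled precision matrix whose
support is a random graph (default density 0.30, partial-correlation
magnitudes 0.05–0.35, random signs); positive definiteness is enforced by
adding `|min eigenvalue| + 0.1` to the diagonal when needed, then
rescaling (which preserves support and relative weights). Observed scores
are discretized to each instrument's bounded grid (CIS fatigue severity
8–56, CES-D 0–60, 0–100 scales elsewhere) by equal-probability standard
normal quantile cuts; with these grids roughly 60% of assessments exceed
the fatigue cut-off, matching the published proportion. A
`subgroup_effect` multiplier applies to the generating network of
postoperative (active treatment/stable) assessments, giving a known
global-strength ratio for power studies.

What the generator does **not** emulate: within-patient correlation
across timepoints (repeated assessments are sampled independently given
the patient's network — the estimators treat assessments
cross-sectionally, but real repeated measures are dependent), item-level
scoring, floor/ceiling pile-ups beyond what discretization induces, and
non-random missingness (only MCAR is available). Passing tests therefore
demonstrate correctness of the estimators and the stratification logic
under idealized sampling, not robustness to longitudinal dependence or
informative missingness.

## Numerical choices and problem sizes

Solver convergence: mean absolute off-diagonal change of the working
covariance below `tol · mean|S_offdiag|` (tol 1e-5, 500 sweeps max;
non-convergence raises). Edge tolerance 1e-8 on precision entries.
Degenerate inputs: an all-zero correlation matrix yields a single-point
path {0} with a warning; zero-variance columns and pairs with < 3
complete observations are errors naming the offender. Master-seed →
stage-seed derivation uses `SeedSequence([master, stage_tag, scheme_tag])`
with fixed documented tags, so adding a stage never perturbs earlier
draws.

The shipped validation studies use 40-penalty paths and B = 200
permutations (200 null replicates for type-I error, 50 for power against
a doubled-weight alternative; 20 truths for edge recovery) — sizes chosen
to characterize the estimator at desk scale; the end-user defaults remain
100 penalties and B = 1000.

## Known limitations

- No paired-sample comparison test; no edge-level or centrality
  difference tests.
- No polychoric/polyserial correlation option; ordinal scores enter via
  Spearman ranks only.
- The no-refit EBIC convention's liberal support (above) is inherited by
  every downstream statistic, though GS comparisons are insensitive to it
  because both groups share the convention.
- Plotting is a thin convenience at most; figure-quality layout is out of
  scope.
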
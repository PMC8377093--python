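# Methods

## Model and objective

The data model is a subjects-by-items table of non-negative, age-corrected
scaled test scores, held internally as an items × subjects matrix `X`
(p × n, p ≥ 2, n ≥ 3, complete cases only). OPNMF approximates `X` by the
non-negative projection `W Wᵀ X`, minimizing `f(W) = ‖X − W Wᵀ X‖²_F` over
`W ≥ 0` (p × k). At an exact optimum the columns of `W` are orthonormal and
`W Wᵀ` is a projector; the non-negativity constraint makes the columns'
supports nearly disjoint, which is what licenses reading the basis as an
item clustering. Items are assigned to the factor carrying their largest
basis coefficient, ties toward the lowest factor index, all-zero rows to
factor 0 with a warning.

The items × subjects orientation (the transpose of the conventional table
layout) is deliberate: it puts items on basis rows so the assignment rule is
a row argmax, and it makes `A = X Xᵀ` a cheap p × p matrix that is
precomputed once per fit.

## Optimization

The fit iterates the multiplicative update

```
W ← W ∘ (A W) ⊘ (W (Wᵀ A W) + ε),   A = X Xᵀ,  ε = 1e-16
```

from either a deterministic NNDSVD-a start (non-negative double SVD with
zeros replaced by the data mean; the default, so the headline pipeline is
fully reproducible without seeds) or a seeded uniform random start. Two
safeguards are layered on the bare update, which is a fixed-point heuristic
rather than a provably monotone scheme:

* **Backtracking damping.** If the full multiplicative step would increase
  the objective, the step is geometrically interpolated (`W ∘ ratio^γ`,
  γ = 1/2, 1/4, …) until it does not; if no damped step helps, the iteration
  stops. The recorded objective trace is therefore non-increasing by
  construction (relative increases bounded by 1e-12 per step).
* **Guarded sparsification.** Every 500 iterations, entries below 1e-3 of
  their column maximum are set to zero and columns are renormalized; the
  candidate is accepted only if the objective does not increase. Near an
  exactly sparse optimum the bare update only approaches zeros
  geometrically; this step lands on them, which is what lets noiseless
  block-structured data reach machine-precision reconstruction in ~10³
  iterations instead of ~10⁶. The renormalization matters because the slowly
  decaying near-zero entries compensate for column norms slightly below
  one — pruning without rescaling *increases* the objective.

Convergence is declared when the relative objective change drops below
`tol` (default 1e-5) or after `max_iter` (default 50,000) iterations; the
values are conventional for multiplicative NMF schemes. On finalization
columns are normalized to unit Euclidean norm (the scale is absorbed into
the loadings `H = Wᵀ X`) and put in canonical order: descending squared
column mass, ties by the row index of the column maximum.

## Split-half stability and rank selection

`make_splits` draws independent random half-splits (sizes differing by at
most one; optional stratification keeps each declared group balanced within
one subject, odd remainders alternating between halves). For each split and
each candidate rank both halves are fitted independently and compared on:

* **ARI** (Hubert–Arabie) and **VI** (natural-log entropies) of the two
  item partitions. Both are label-invariant, so no factor matching is
  needed; VI is bounded by ln p.
* **Concordance index**: basis columns are matched one-to-one by maximizing
  summed Pearson correlations (exact assignment via the Hungarian
  algorithm), then Lin's concordance correlation coefficient is computed
  per matched pair and averaged. Matching removes the column-order
  arbitrariness; CCC rather than plain correlation penalizes scale and
  location differences between the bases. Zero-variance columns yield CCC 1
  when identical, else 0 with a warning.
* **Transfer-error increase**: relative Frobenius reconstruction error of
  each half through the other half's basis, averaged over both directions,
  minus the average within-sample error. Symmetrizing removes the
  arbitrary direction of the projection.

Ranks are scored per criterion (maximize mean ARI and concordance, minimize
mean VI and error increase), each candidate gets the average of its four
criterion ranks, and the smallest k among the minimizers wins — parsimony
is the explicit tie-break. Summaries report mean, sd, and 5th/95th
percentile bands per rank.

The analysis default is 10,000 splits over ranks 2–9. The test suite and
the acceptance script use 20–50 splits and 20 replicates: at p = 17,
n = 334 the per-rank criterion means are already stable at that scale, and
the selection behavior (not the Monte-Carlo error of the curves) is what is
under test.

## PCA/EFA comparison arm

PCA loadings are eigenvectors of the item correlation matrix scaled by the
root eigenvalues, sign-fixed so each column's largest entry is positive.
EFA is a common-factor model fitted by profiling out the loadings: the
uniquenesses ψ are optimized (L-BFGS-B, bounds [1e-4, 1]) with conditionally
optimal loadings — top-k eigenpairs of `R − diag(ψ)` for minres, of
`Ψ^{-1/2} R Ψ^{-1/2}` for maximum likelihood — starting from
1 − squared multiple correlations. minres is the default extraction (the
common default of the standard GUI tools); ML is available. Unrotated
loadings are reported in the canonical orientation (`Λᵀ Ψ⁻¹ Λ` diagonal,
descending), which is what reference implementations print. Model fit uses
the ML discrepancy at the solution with Bartlett's correction,
`df = ((p−k)² − (p+k))/2`, the independence model `χ² = −c·ln det R` with
`df = p(p−1)/2`, and the Tucker–Lewis index computed from the two χ²/df
ratios (not clipped to [0, 1]). Communalities above 1 are flagged as
Heywood cases, not fatal. k is capped at the classic identifiability bound
`(2p + 1 − √(8p+1))/2`.

Promax follows the conventional recipe: Kaiser-normalized varimax
pre-rotation (SVD algorithm, relative stopping criterion 1e-5 matching the
canonical implementations), element-wise |loading|^κ target with signs
preserved (κ = 4 default), least-squares oblique target fit, and column
rescaling so the factor correlation matrix Φ has unit diagonal. Without
Kaiser normalization the identity `pattern = unrotated · T` holds exactly;
with it, both here and in the reference implementations, the identity holds
only up to the row rescaling.

Parallel analysis simulates standard-normal datasets of the observed shape
and retains the leading observed eigenvalues strictly above the
per-position 95th percentile (configurable) of the simulated ones, stopping
at the first failure. The eigenvalue basis is method-matched by default:
full correlation matrix for PCA, reduced correlation matrix (squared
multiple correlations on the diagonal) for EFA. This mirrors how the
standard tools implement the two variants and is what produces the
characteristic retention divergence on hierarchical data — the PCA variant
counts dominant variance directions, the EFA variant counts common factors.
A scree report with an advisory acceleration-factor elbow (largest second
difference) is provided; scree reading remains a manual judgment.

## Synthetic data generator

The generators emulate the statistical regime of an executive-function
battery, not its marginal distributions:

* **Planted basis**: items split across factors as evenly as possible
  (remainder to the lowest-index factors), primary loadings uniform on
  [0.6, 1], unit-norm columns. `overlap > 0` gives a random half of the
  items a secondary loading of that relative magnitude (< 1, so the home
  factor keeps the argmax).
* **Subject scores**: |N(0, 1)| by default; log-normal(0, 0.5) under the
  skew flag, reflecting that these methods are routinely applied to skewed
  score distributions. Defaults p = 17 (with the D-KEFS variable names as
  labels), n = 334, matching the sample regime the package targets.
* **Noise**: additive Gaussian, clipped at zero together with the signal —
  the simplest contract that preserves non-negativity; the choice is
  recorded in the generator metadata. Default sd 0.25 (flat) / 0.3
  (hierarchical), roughly half the typical signal amplitude per entry,
  which yields within-block item correlations around 0.4–0.5 — the
  moderate-correlation regime typical of test batteries.
* **Hierarchy**: fine-factor scores are `√w·g_parent + √(1−w)·e` with g, e
  half-normal, so fine factors under one coarse parent correlate at ≈ w
  (default 0.7) and are uncorrelated across parents. Shared variance is
  then dominated by the coarse split while item blocks follow the fine
  partition — the regime in which stability-based selection prefers the
  coarse model while EFA parallel analysis still counts the fine factors.
* **Subgroups**: drawn from one shared basis with optional per-group
  non-negative loading perturbations; labels are attached to subjects.
  **Null data**: i.i.d. normals shifted to non-negativity by the global
  minimum, which leaves correlations untouched.

Everything is deterministic given (parameters, seed). What passing tests on
these data do *not* show: robustness to the discreteness, floors/ceilings
and outliers of real scaled scores, to age-correction artifacts, or to
missing-data mechanisms (complete cases are assumed at load time).

## Numerical choices and degenerate inputs

Denominators in the multiplicative update carry an ε = 1e-16 guard.
All-zero data matrices are rejected; negative entries are rejected at
construction and at load time with the offending cell named. All-zero basis
rows are assigned to factor 0 with a warning. Zero-variance items make the
correlation matrix undefined and are rejected by name. The ML discrepancy
clips eigenvalues at 1e-12 before logs. JSON/TSV writers use sorted keys
and round-trip float formatting (`%.17g` out, `round_trip` parsing in), so
repeated pipeline runs with one config are byte-identical.

## Known limitations

* The OPNMF multiplicative update is a safeguarded heuristic: the objective
  trace is non-increasing by construction, but convergence to a global
  optimum is not guaranteed; the deterministic NNDSVD-a start makes runs
  reproducible, and random restarts are available where the landscape is in
  doubt.
* The concordance index is operationalized as Hungarian-matched mean Lin's
  CCC; other concordance formulations exist, and a Pearson-based variant is
  one flag away in the matching step.
* EFA fit statistics use the ML discrepancy even for minres solutions,
  as reference implementations do; for badly misspecified models the two
  can diverge.
* Subgroup analyses refit from scratch on each subgroup; no measurement-
  invariance testing across groups is attempted.
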
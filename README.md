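# opnmfkit

Latent-structure analysis of non-negative psychometric score batteries with
**orthonormal projective non-negative matrix factorization (OPNMF)** and
**split-half cross-validated rank selection**, alongside the traditional
**PCA/EFA** arm (promax oblique rotation, Horn's parallel analysis,
Tucker–Lewis index).

The package is aimed at researchers who factorize test batteries — the
running example is the 17 total-achievement scores of the Delis–Kaplan
Executive Function System (D-KEFS) — and want a factor solution selected for
*stability and out-of-sample generalizability* rather than by eigenvalue
heuristics alone, together with the standard exploratory baselines for
comparison.

## The method

Given a non-negative items × subjects matrix `X` (p × n), OPNMF solves

```
min_{W ≥ 0}  ‖ X − W Wᵀ X ‖²_F
```

for an items × k basis `W` with near-orthonormal, non-negative columns, via
the multiplicative update `W ← W ∘ (A W) ⊘ (W (Wᵀ A W))` with `A = X Xᵀ`.
The orthonormal-projective constraint drives each item's loadings toward a
single factor, so `W` doubles as a soft clustering; the hard partition is
the row-wise argmax. Subject loadings are `H = Wᵀ X`.

The number of factors k is chosen by repeated split-half cross-validation:
subjects are split into random halves, OPNMF is fitted on each half at every
k in a candidate range (default 2–9, default 10,000 splits), and the halves
are scored on

* **adjusted Rand index** and **variation of information** of the
  item-to-factor partitions (stability of the assignment),
* mean **Lin's concordance correlation** between optimally matched basis
  columns (stability of the whole basis),
* the increase of **out-of-sample reconstruction error** — each half
  reconstructed through the other half's basis — over within-sample error
  (generalizability).

The selected k has the best average criterion rank, ties going to the
smaller model. The comparison arm runs PCA and minres/ML exploratory factor
analysis on the item correlation matrix, with promax(κ=4) oblique rotation,
scree diagnostics, parallel analysis (PCA- or reduced-correlation-based),
and the Tucker–Lewis fit index.

A first-class synthetic-data module generates score batteries with planted
non-negative factor structure — flat k-factor layouts, five-fine-factors-in-
two-coarse hierarchies, labelled subgroups, and structureless null data — so
every stage of the pipeline is testable without any external data.

## Worked example

```python
from opnmfkit import generate_scores, run_stability, select_rank, opnmf_fit

sm, truth = generate_scores(p=17, k=2, n=334, noise_sd=0.3, seed=3)
result = run_stability(sm, ranks=range(2, 10), n_splits=50, seed=3)
k_star, table = select_rank(result)
print(table[["mean_ari", "mean_vi", "mean_concordance", "mean_err_increase"]].round(3))
```

prints

```
      mean_ari  mean_vi  mean_concordance  mean_err_increase
rank
2        1.000    0.000             0.985              0.005
3        0.587    0.648             0.519              0.012
4        0.340    1.086             0.368              0.017
...
9        0.078    1.221             0.513              0.027
```

At k = 2 the two halves always agree on the item partition (ARI 1.0, VI
0.0), the bases are nearly identical (concordance 0.99), and projecting one
half through the other half's basis costs almost nothing (error increase
0.005) — so `select_rank` returns 2, the planted rank. Fitting the full
sample at that rank (`opnmf_fit(sm, 2)`) splits the 17 items into the two
planted blocks exactly (ARI 1.0 against the ground truth).

The `examples/` directory has one short narrative script per capability:
data simulation, a single OPNMF fit, rank stability, the PCA/EFA arm, and
the full pipeline with subgroups. The same pipeline is also exposed as a
thin CLI (`opnmfkit simulate | opnmf | stability | baselines | run-all |
compare`) for use on CSV/TSV score tables.

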
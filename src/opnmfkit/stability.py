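"""Split-half cross-validated stability and rank selection for OPNMF.

Subjects are repeatedly split into random halves; OPNMF is fitted on each
half at every candidate rank, and the two half-fits are compared on

* partition agreement — adjusted Rand index (higher = more stable) and
  variation of information (lower = more stable) of the item-to-factor
  assignments;
* basis agreement — mean Lin's concordance correlation between optimally
  matched basis columns;
* generalizability — the increase of out-of-sample (transfer) reconstruction
  error over within-sample error, symmetrized over both directions.

The selected rank is the one with the best average criterion rank, ties
broken toward the smaller (more parsimonious) model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, mutual_info_score

from .opnmf import opnmf_fit, reconstruction_error
from .scores import ScoreMatrix

METRICS = ("ari", "vi", "concordance", "err_within", "err_transfer", "err_increase")


@dataclass
class SplitPlan:
    """Reproducible set of half-splits of n subjects."""

    n: int
    n_splits: int
    seed: int | None
    pairs: list[tuple[np.ndarray, np.ndarray]]
    stratify_by: str | None = None

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class StabilityResult:
    """Per-replicate stability metrics and per-rank summaries."""

    ranks: list[int]
    records: pd.DataFrame  # columns: replicate, rank, + METRICS
    n_splits: int
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        """Mean, sd and 5th/95th percentiles of every metric per rank."""
        g = self.records.groupby("rank")[list(METRICS)]
        parts = {
            "mean": g.mean(),
            "sd": g.std(ddof=1),
            "p05": g.quantile(0.05),
            "p95": g.quantile(0.95),
        }
        out = pd.concat(parts, axis=1)  # (stat, metric) columns
        return out.swaplevel(axis=1).sort_index(axis=1)

    def to_tidy(self) -> pd.DataFrame:
        return self.records.melt(
            id_vars=["replicate", "rank"], var_name="metric", value_name="value"
        )


def make_splits(
    n: int,
    n_splits: int,
    seed: int | None = None,
    stratify_by: dict | list | None = None,
    subject_ids: list[str] | None = None,
) -> SplitPlan:
    """Draw ``n_splits`` independent random half-splits of ``n`` subjects.

    Halves are disjoint, cover all subjects and differ in size by at most one.
    With ``stratify_by`` (a per-subject group label array, or a mapping from
    subject id when ``subject_ids`` is given) each group is split in half
    within one subject, odd remainders alternating between the two halves.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if n < 6:
        raise ValueError("need at least 6 subjects to split into analysable halves")
    rng = np.random.default_rng(seed)

    groups = None
    if stratify_by is not None:
        if isinstance(stratify_by, dict):
            if subject_ids is None:
                raise ValueError("subject_ids required when stratify_by is a mapping")
            groups = np.asarray([stratify_by[s] for s in subject_ids])
        else:
            groups = np.asarray(stratify_by)
            if groups.shape[0] != n:
                raise ValueError("stratify_by length does not match n")

    pairs = []
    for _ in range(n_splits):
        if groups is None:
            perm = rng.permutation(n)
            half = n // 2 + (n % 2)
            a, b = perm[:half], perm[half:]
        else:
            a_parts, b_parts = [], []
            toggle = 0
            for gval in sorted(pd.unique(groups), key=str):
                idx = np.flatnonzero(groups == gval)
                idx = rng.permutation(idx)
                size_a = len(idx) // 2
                if len(idx) % 2:
                    size_a += toggle
                    toggle = 1 - toggle
                a_parts.append(idx[:size_a])
                b_parts.append(idx[size_a:])
            a = np.concatenate(a_parts)
            b = np.concatenate(b_parts)
        pairs.append((np.sort(a), np.sort(b)))
    return SplitPlan(
        n=n,
        n_splits=n_splits,
        seed=seed,
        pairs=pairs,
        stratify_by=None if groups is None else "groups",
    )


def _check_partitions(p1, p2) -> tuple[np.ndarray, np.ndarray]:
    p1, p2 = np.asarray(p1), np.asarray(p2)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError("partitions must be 1-D and defined on the same item set")
    return p1, p2


def adjusted_rand_index(p1, p2) -> float:
    """Hubert–Arabie adjusted Rand index; 1 iff identical up to relabeling."""
    p1, p2 = _check_partitions(p1, p2)
    return float(adjusted_rand_score(p1, p2))


def variation_of_information(p1, p2) -> float:
    """VI = H(p1) + H(p2) - 2 I(p1; p2), natural-log entropies (>= 0,
    0 iff identical up to relabeling, bounded by ln(#items))."""
    p1, p2 = _check_partitions(p1, p2)

    def _entropy(p):
        _, counts = np.unique(p, return_counts=True)
        freq = counts / counts.sum()
        return float(-(freq * np.log(freq)).sum())

    mi = mutual_info_score(p1, p2)  # natural log
    vi = _entropy(p1) + _entropy(p2) - 2.0 * mi
    return float(max(vi, 0.0))


def _column_correlations(W_A: np.ndarray, W_B: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of W_A with every column of W_B;
    zero-variance columns yield 0 correlation."""
    A = W_A - W_A.mean(axis=0)
    B = W_B - W_B.mean(axis=0)
    sa = np.linalg.norm(A, axis=0)
    sb = np.linalg.norm(B, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (A.T @ B) / np.outer(sa, sb)
    return np.nan_to_num(C, nan=0.0)


def match_factors(W_A, W_B) -> np.ndarray:
    """Optimal one-to-one column matching of W_B to W_A.

    Solves the assignment problem maximizing the sum of matched-column
    Pearson correlations; returns ``perm`` such that column ``perm[j]`` of
    W_B matches column ``j`` of W_A.
    """
    W_A, W_B = np.asarray(W_A, float), np.asarray(W_B, float)
    if W_A.shape != W_B.shape:
        raise ValueError("bases must have identical shape to be matched")
    if W_A.shape[1] == 1:
        return np.array([0])
    C = _column_correlations(W_A, W_B)
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(W_A.shape[1], dtype=int)
    perm[rows] = cols
    return perm


def lins_ccc(a: np.ndarray, b: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(), b.var()
    if va == 0.0 and vb == 0.0:
        if np.allclose(a, b):
            return 1.0
        warnings.warn("zero-variance columns that differ: CCC set to 0", RuntimeWarning)
        return 0.0
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(2.0 * cov / (va + vb + (a.mean() - b.mean()) ** 2))


def concordance_index(W_A, W_B) -> float:
    """Mean Lin's CCC over optimally matched basis columns (in [-1, 1])."""
    W_A, W_B = np.asarray(W_A, float), np.asarray(W_B, float)
    perm = match_factors(W_A, W_B)
    return float(
        np.mean([lins_ccc(W_A[:, j], W_B[:, perm[j]]) for j in range(W_A.shape[1])])
    )


def out_of_sample_error_increase(X_A, X_B, W_A, W_B) -> tuple[float, float, float]:
    """Within/transfer reconstruction errors and their difference.

    err_within averages each half reconstructed by its own basis; err_transfer
    averages the two cross-directions (each half through the other half's
    basis); increase = err_transfer - err_within.
    """
    err_within = 0.5 * (reconstruction_error(X_A, W_A) + reconstruction_error(X_B, W_B))
    err_transfer = 0.5 * (reconstruction_error(X_B, W_A) + reconstruction_error(X_A, W_B))
    return err_within, err_transfer, err_transfer - err_within


def run_stability(
    X: ScoreMatrix,
    ranks=range(2, 10),
    plan: SplitPlan | None = None,
    n_splits: int = 10_000,
    seed: int | None = None,
    opnmf_params: dict | None = None,
) -> StabilityResult:
    """Evaluate every rank on every split-half replicate.

    With no explicit ``plan`` one is drawn from (n, n_splits, seed).  OPNMF is
    fitted with deterministic nndsvd-a initialization by default, so results
    are fully reproducible from the plan and parameters.
    """
    ranks = [int(k) for k in ranks]
    if not ranks:
        raise ValueError("ranks must be non-empty")
    if max(ranks) > X.n_items or min(ranks) < 1:
        raise ValueError(f"ranks must lie in [1, {X.n_items}]")
    if plan is None:
        plan = make_splits(X.n_subjects, n_splits, seed=seed)
    params = {"init": "nndsvd-a", "max_iter": 50_000, "tol": 1e-5}
    params.update(opnmf_params or {})

    rows = []
    for rep, (idx_a, idx_b) in enumerate(plan.pairs):
        if len(idx_a) < 3 or len(idx_b) < 3:
            raise ValueError("each half must contain at least 3 subjects")
        X_A = X.values[:, idx_a]
        X_B = X.values[:, idx_b]
        for k in ranks:
            sol_a = opnmf_fit(X_A, k, **params)
            sol_b = opnmf_fit(X_B, k, **params)
            ew, et, inc = out_of_sample_error_increase(X_A, X_B, sol_a.basis, sol_b.basis)
            rows.append(
                {
                    "replicate": rep,
                    "rank": k,
                    "ari": adjusted_rand_index(sol_a.partition, sol_b.partition),
                    "vi": variation_of_information(sol_a.partition, sol_b.partition),
                    "concordance": concordance_index(sol_a.basis, sol_b.basis),
                    "err_within": ew,
                    "err_transfer": et,
                    "err_increase": inc,
                }
            )
    records = pd.DataFrame(rows)
    return StabilityResult(ranks=ranks, records=records, n_splits=plan.n_splits, seed=plan.seed)


def select_rank(result: StabilityResult) -> tuple[int, pd.DataFrame]:
    """Pick the rank with the best average criterion rank.

    Criteria: maximize mean ARI, minimize mean VI, maximize mean concordance,
    minimize mean transfer-error increase.  Each candidate rank is ranked on
    each criterion (1 = best); the winner minimizes the average rank, ties
    broken toward the smaller k.
    """
    if len(result.ranks) < 2:
        raise ValueError("need at least 2 evaluated ranks to select one")
    means = result.records.groupby("rank")[["ari", "vi", "concordance", "err_increase"]].mean()
    table = pd.DataFrame(index=means.index)
    table["mean_ari"] = means["ari"]
    table["mean_vi"] = means["vi"]
    table["mean_concordance"] = means["concordance"]
    table["mean_err_increase"] = means["err_increase"]
    table["rank_ari"] = (-means["ari"]).rank(method="min")
    table["rank_vi"] = means["vi"].rank(method="min")
    table["rank_concordance"] = (-means["concordance"]).rank(method="min")
    table["rank_err_increase"] = means["err_increase"].rank(method="min")
    rank_cols = ["rank_ari", "rank_vi", "rank_concordance", "rank_err_increase"]
    table["avg_rank"] = table[rank_cols].mean(axis=1)
    best = table["avg_rank"].min()
    k_star = int(min(k for k in table.index if table.loc[k, "avg_rank"] == best))
    return k_star, table
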
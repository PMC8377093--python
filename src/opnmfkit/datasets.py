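"""Synthetic score-battery generators with planted non-negative factor structure.

These emulate the statistical regime of an executive-function battery: p
non-negative item scores (17 by default, labelled with the D-KEFS variables),
a few hundred subjects, a planted non-negative factor structure — either a
flat k-factor layout or five fine factors nested inside two coarse ones —
additive Gaussian noise clipped at zero, optionally skewed subject scores,
and labelled subgroups.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .scores import ScoreMatrix, default_item_labels


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic score matrix."""

    basis_true: np.ndarray  # p x k_true, non-negative, unit-norm columns
    scores_true: np.ndarray  # k_true x n, non-negative subject factor scores
    partition_true: np.ndarray  # item -> (fine) factor, row-argmax of basis_true
    noise_sd: float
    seed: int | None
    k_fine: int = 0
    k_coarse: int = 0
    nesting: np.ndarray | None = None  # fine factor -> coarse factor
    partition_coarse: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.basis_true, axis=0)
        if np.any(self.basis_true < 0) or not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("basis_true must be non-negative with unit-norm columns")
        if not np.array_equal(self.partition_true, np.argmax(self.basis_true, axis=1)):
            raise ValueError("partition_true must be the row-argmax of basis_true")
        if self.nesting is not None:
            if self.k_fine < self.k_coarse:
                raise ValueError("k_fine must be >= k_coarse when nesting is present")
            if len(self.nesting) != self.k_fine:
                raise ValueError("every fine factor must map to exactly one coarse factor")

    def to_dict(self) -> dict:
        d = {
            "basis_true": self.basis_true.tolist(),
            "partition_true": self.partition_true.tolist(),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "k_fine": self.k_fine,
            "k_coarse": self.k_coarse,
            "metadata": self.metadata,
        }
        if self.nesting is not None:
            d["nesting"] = self.nesting.tolist()
            d["partition_coarse"] = self.partition_coarse.tolist()
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _even_blocks(p: int, k: int) -> np.ndarray:
    """Assign p items to k factors as evenly as possible, remainder to the
    lowest-index factors; returns the item -> factor map."""
    base, rem = divmod(p, k)
    sizes = [base + (1 if j < rem else 0) for j in range(k)]
    return np.repeat(np.arange(k), sizes)


def generate_basis(p: int, k: int, overlap: float = 0.0, seed: int | None = None) -> np.ndarray:
    """Planted p x k non-negative basis with block simple structure.

    With ``overlap == 0`` each item loads on exactly one factor (disjoint
    support).  With ``overlap > 0`` a random half of the items receive a
    secondary loading on another factor with relative magnitude ``overlap``
    (< 1, so the argmax stays on the home factor).  Columns are normalized to
    unit Euclidean norm.
    """
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    rng = np.random.default_rng(seed)
    home = _even_blocks(p, k)
    B = np.zeros((p, k))
    primary = rng.uniform(0.6, 1.0, size=p)
    B[np.arange(p), home] = primary
    if overlap > 0 and k > 1:
        n_sec = p // 2
        chosen = rng.choice(p, size=n_sec, replace=False)
        for i in chosen:
            others = [j for j in range(k) if j != home[i]]
            j = others[rng.integers(len(others))]
            B[i, j] = overlap * primary[i]
    B /= np.linalg.norm(B, axis=0)
    return B


def _draw_scores(rng: np.random.Generator, k: int, n: int, skew: bool) -> np.ndarray:
    if skew:
        return rng.lognormal(mean=0.0, sigma=0.5, size=(k, n))
    return np.abs(rng.standard_normal((k, n)))


def generate_scores(
    p: int = 17,
    k: int = 2,
    n: int = 334,
    noise_sd: float = 0.25,
    overlap: float = 0.0,
    skew: bool = False,
    seed: int | None = None,
    item_labels: list[str] | None = None,
) -> tuple[ScoreMatrix, GroundTruth]:
    """Flat planted-factor score matrix: X = B S + E, clipped at zero.

    Subject scores are |N(0,1)| by default, log-normal(0, 0.5) with ``skew``;
    noise is additive Gaussian with sd ``noise_sd`` clipped at 0 together with
    the signal.  Item labels default to the 17 D-KEFS variables when p == 17.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    B = generate_basis(p, k, overlap=overlap, seed=rng.integers(2**31))
    S = _draw_scores(rng, k, n, skew)
    X = B @ S
    if noise_sd > 0:
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    X = np.clip(X, 0.0, None)
    truth = GroundTruth(
        basis_true=B,
        scores_true=S,
        partition_true=np.argmax(B, axis=1),
        noise_sd=noise_sd,
        seed=seed,
        metadata={
            "generator": "generate_scores",
            "score_distribution": "lognormal(0,0.5)" if skew else "|N(0,1)|",
            "noise_model": "additive Gaussian clipped at 0",
            "overlap": overlap,
            "p": p,
            "k": k,
            "n": n,
        },
    )
    labels = item_labels or default_item_labels(p)
    sm = ScoreMatrix(
        X, labels, [f"s{i:04d}" for i in range(n)], metadata=dict(truth.metadata)
    )
    return sm, truth


def generate_hierarchical(
    p: int = 17,
    k_fine: int = 5,
    k_coarse: int = 2,
    within_corr: float = 0.7,
    n: int = 334,
    noise_sd: float = 0.3,
    seed: int | None = None,
    item_labels: list[str] | None = None,
) -> tuple[ScoreMatrix, GroundTruth]:
    """Nested structure: fine item blocks whose subject scores share a coarse parent.

    Each fine factor f gets subject scores
    s_f = sqrt(w) g_parent(f) + sqrt(1-w) e_f with g, e half-normal, so two
    fine factors under the same parent correlate at ~``within_corr`` while
    factors under different parents are uncorrelated.  Shared variance is
    therefore dominated by the coarse split and item blocks by the fine one.
    """
    if not k_coarse <= k_fine <= p:
        raise ValueError("need k_coarse <= k_fine <= p")
    if not 0 < within_corr < 1:
        raise ValueError(f"within_corr must be in (0, 1), got {within_corr}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    B = generate_basis(p, k_fine, overlap=0.0, seed=rng.integers(2**31))
    nesting = _even_blocks(k_fine, k_coarse)
    G = np.abs(rng.standard_normal((k_coarse, n)))
    E = np.abs(rng.standard_normal((k_fine, n)))
    S = np.sqrt(within_corr) * G[nesting, :] + np.sqrt(1.0 - within_corr) * E
    X = B @ S
    if noise_sd > 0:
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    X = np.clip(X, 0.0, None)
    part_fine = np.argmax(B, axis=1)
    truth = GroundTruth(
        basis_true=B,
        scores_true=S,
        partition_true=part_fine,
        noise_sd=noise_sd,
        seed=seed,
        k_fine=k_fine,
        k_coarse=k_coarse,
        nesting=nesting,
        partition_coarse=nesting[part_fine],
        metadata={
            "generator": "generate_hierarchical",
            "within_corr": within_corr,
            "score_distribution": "half-normal mixture",
            "noise_model": "additive Gaussian clipped at 0",
            "p": p,
            "n": n,
        },
    )
    labels = item_labels or default_item_labels(p)
    sm = ScoreMatrix(
        X, labels, [f"s{i:04d}" for i in range(n)], metadata=dict(truth.metadata)
    )
    return sm, truth


def generate_subgroups(
    groups: list[tuple[str, int, float]],
    p: int = 17,
    k: int = 2,
    noise_sd: float = 0.25,
    overlap: float = 0.0,
    skew: bool = False,
    seed: int | None = None,
    item_labels: list[str] | None = None,
) -> tuple[ScoreMatrix, GroundTruth]:
    """Score matrix with labelled subgroups drawn from one shared basis.

    ``groups`` is a list of (label, size, perturbation_sd); each subgroup's
    effective basis is the shared basis plus a group-specific non-negative
    perturbation of the given magnitude (renormalized), so perturbation_sd=0
    means all groups share the identical generative structure.
    """
    labels_g = [g[0] for g in groups]
    if len(set(labels_g)) != len(labels_g):
        raise ValueError("duplicate group labels")
    for label, size, psd in groups:
        if size < 2:
            raise ValueError(f"group {label!r} must have at least 2 subjects")
        if psd < 0:
            raise ValueError(f"group {label!r} perturbation_sd must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    B = generate_basis(p, k, overlap=overlap, seed=rng.integers(2**31))

    blocks, ids, group_map = [], [], {}
    offset = 0
    for label, size, psd in groups:
        Bg = B
        if psd > 0:
            Bg = np.clip(B + rng.normal(scale=psd, size=B.shape), 0.0, None)
            norms = np.linalg.norm(Bg, axis=0)
            norms[norms == 0] = 1.0
            Bg = Bg / norms
        S = _draw_scores(rng, k, size, skew)
        Xg = Bg @ S
        if noise_sd > 0:
            Xg = Xg + rng.normal(scale=noise_sd, size=Xg.shape)
        blocks.append(np.clip(Xg, 0.0, None))
        for i in range(size):
            sid = f"s{offset + i:04d}"
            ids.append(sid)
            group_map[sid] = label
        offset += size
    X = np.concatenate(blocks, axis=1)
    truth = GroundTruth(
        basis_true=B,
        scores_true=np.zeros((k, 0)),
        partition_true=np.argmax(B, axis=1),
        noise_sd=noise_sd,
        seed=seed,
        metadata={
            "generator": "generate_subgroups",
            "groups": [list(g) for g in groups],
            "noise_model": "additive Gaussian clipped at 0",
        },
    )
    labels = item_labels or default_item_labels(p)
    sm = ScoreMatrix(X, labels, ids, group_labels=group_map, metadata=dict(truth.metadata))
    return sm, truth


def generate_null(p: int = 17, n: int = 334, seed: int | None = None) -> ScoreMatrix:
    """Structure-free scores: i.i.d. standard normals shifted to non-negativity.

    A global shift leaves the correlation structure untouched, so rank
    diagnostics should retain ~0 factors on this input.
    """
    if p < 2 or n < 3:
        raise ValueError("need p >= 2 and n >= 3")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((p, n))
    X = Z - Z.min()
    return ScoreMatrix(
        X,
        default_item_labels(p),
        [f"s{i:04d}" for i in range(n)],
        metadata={"generator": "generate_null", "seed": seed},
    )
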
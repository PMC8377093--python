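"""Orthonormal projective non-negative matrix factorization (OPNMF).

Approximates a non-negative items x subjects matrix X by a projection
X ~ W W' X, where W (items x k) is non-negative with (near-)orthonormal
columns.  Because each item ends up loading essentially on one column, the
basis doubles as a soft clustering of items; the hard partition is the
row-wise argmax.

The objective

    f(W) = || X - W W' X ||_F^2 ,   W >= 0,

is minimized with the multiplicative update

    W <- W * (A W) / (W (W' A W)),    A = X X',

damped by a backtracking safeguard so the recorded objective trace is
non-increasing (the bare multiplicative step is a heuristic and can, rarely,
overshoot near a stationary point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .scores import ScoreMatrix

EPS = 1e-16
_PRUNE_INTERVAL = 500


@dataclass
class FactorSolution:
    """A fitted OPNMF basis and its diagnostics.

    Attributes
    ----------
    basis : ndarray (p, k)
        Non-negative basis W with unit-norm columns after finalization.
    loadings : ndarray (k, n)
        Subject loadings H = W' X for the training data.
    k : int
        Number of factors.
    objective_trace : ndarray
        || X - W W' X ||_F^2 per iteration (non-increasing).
    converged : bool
    n_iter : int
    partition : ndarray (p,)
        Item -> factor assignment (row argmax of the basis).
    item_labels : list of str
    zero_rows : ndarray
        Indices of all-zero basis rows (assigned to factor 0 with a warning).
    init : str
    seed : int or None
    """

    basis: np.ndarray
    loadings: np.ndarray
    k: int
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    partition: np.ndarray
    item_labels: list[str] = field(default_factory=list)
    zero_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    init: str = "nndsvd-a"
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "basis": self.basis.tolist(),
            "partition": self.partition.tolist(),
            "item_labels": list(self.item_labels),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "final_objective": float(self.objective_trace[-1]),
            "init": self.init,
            "seed": self.seed,
        }


def _as_values(X) -> np.ndarray:
    if isinstance(X, ScoreMatrix):
        return X.values
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("data matrix must be non-negative")
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix must be finite")
    return X


def initialize_basis(X, k: int, method: str = "nndsvd-a", seed: int | None = None) -> np.ndarray:
    """Non-negative p x k starting basis.

    ``nndsvd-a``: non-negative double SVD (Boutsidis & Gallopoulos) with
    zeros replaced by the data mean — deterministic.  ``random``: i.i.d.
    uniform(0, 1] scaled to the data magnitude — deterministic given seed.
    """
    V = _as_values(X)
    p, n = V.shape
    if k < 1 or k > p:
        raise ValueError(f"k must be in [1, {p}], got {k}")

    if method == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(V.mean() / max(k, 1)) if V.mean() > 0 else 1.0
        W = (1.0 - rng.random((p, k))) * scale  # uniform on (0, 1]
        return W

    if method != "nndsvd-a":
        raise ValueError(f"unknown init method {method!r}")

    U, s, Vt = np.linalg.svd(V, full_matrices=False)
    r = s.size
    W = np.zeros((p, k))
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    for j in range(1, min(k, r)):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            col = up / n_up if n_up > 0 else up
        else:
            sigma = n_un * n_vn
            col = un / n_un if n_un > 0 else un
        W[:, j] = np.sqrt(s[j] * sigma) * col
    mean = V.mean()
    W[W <= 0] = mean if mean > 0 else EPS
    return W


def reconstruction_error(X, W) -> float:
    """Relative Frobenius error || X - W W' X ||_F / || X ||_F."""
    V = _as_values(X)
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != V.shape[0]:
        raise ValueError(
            f"basis shape {W.shape} does not match data with {V.shape[0]} items"
        )
    norm = np.linalg.norm(V)
    if norm == 0:
        raise ValueError("data matrix is identically zero")
    resid = V - W @ (W.T @ V)
    return float(np.linalg.norm(resid) / norm)


def _objective(A: np.ndarray, trA: float, W: np.ndarray) -> float:
    # ||X - WW'X||_F^2 = tr(A) - 2 tr(W'AW) + tr((W'W)(W'AW))
    AW = A @ W
    WtAW = W.T @ AW
    WtW = W.T @ W
    return float(trA - 2.0 * np.trace(WtAW) + np.sum(WtW * WtAW))


def opnmf_fit(
    X,
    k: int,
    init: str = "nndsvd-a",
    max_iter: int = 50_000,
    tol: float = 1e-5,
    seed: int | None = None,
    W0: np.ndarray | None = None,
) -> FactorSolution:
    """Fit OPNMF at rank k.

    Iterates the multiplicative update until the relative objective change
    drops below ``tol`` or ``max_iter`` is reached.  A backtracking damping
    step enforces a non-increasing objective trace.  The final basis is
    column-normalized and columns are put in canonical order (descending
    squared mass).
    """
    V = _as_values(X)
    labels = X.item_labels if isinstance(X, ScoreMatrix) else [
        f"item_{i:02d}" for i in range(V.shape[0])
    ]
    p, _ = V.shape
    if k < 1 or k > p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    if not np.any(V > 0):
        raise ValueError("degenerate input: data matrix is identically zero")

    W = initialize_basis(V, k, method=init, seed=seed) if W0 is None else np.array(W0, float)
    A = V @ V.T
    trA = float(np.trace(A))

    obj = _objective(A, trA, W)
    trace = [obj]
    converged = False
    scale = max(trA, EPS)
    for it in range(max_iter):
        if it and it % _PRUNE_INTERVAL == 0:
            # guarded sparsification: zero near-zero entries and renormalize
            # columns, accepted only when the objective does not increase.
            # Near an exactly-sparse optimum this lands on it in one step
            # instead of the multiplicative update's slow geometric tail.
            W_sp = W.copy()
            colmax = W_sp.max(axis=0, keepdims=True)
            W_sp[W_sp < 1e-3 * colmax] = 0.0
            norms = np.linalg.norm(W_sp, axis=0)
            if np.all(norms > 0):
                W_sp = W_sp / norms
                obj_sp = _objective(A, trA, W_sp)
                if obj_sp <= obj:
                    W, obj = W_sp, obj_sp
        AW = A @ W
        denom = W @ (W.T @ AW) + EPS
        ratio = AW / denom
        W_new = W * ratio
        obj_new = _objective(A, trA, W_new)
        if obj_new > obj + 1e-12 * scale:
            # damp: geometric interpolation toward the multiplicative step
            accepted = False
            gamma = 0.5
            for _ in range(20):
                W_try = W * ratio**gamma
                obj_try = _objective(A, trA, W_try)
                if obj_try <= obj + 1e-12 * scale:
                    W_new, obj_new = W_try, obj_try
                    accepted = True
                    break
                gamma *= 0.5
            if not accepted:
                converged = True
                break
        rel_change = abs(obj - obj_new) / max(obj, EPS)
        W, obj = W_new, obj_new
        trace.append(obj)
        if rel_change < tol:
            converged = True
            break

    W, order = order_basis_columns(W, return_order=True)
    norms = np.linalg.norm(W, axis=0)
    zero_cols = norms <= 0
    norms[zero_cols] = 1.0
    W = W / norms
    H = W.T @ V

    partition, zero_rows = assign_items(W, return_zero_rows=True)
    return FactorSolution(
        basis=W,
        loadings=H,
        k=k,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace) - 1,
        partition=partition,
        item_labels=list(labels),
        zero_rows=zero_rows,
        init=init,
        seed=seed,
    )


def project(X_new, W, item_labels: list[str] | None = None):
    """Project held-out data onto a fitted basis.

    Returns ``(loadings, out_of_sample_error)`` where loadings = W' X_new and
    the error is the relative Frobenius reconstruction error.  When both the
    basis provenance and the new data carry item labels they must agree in
    order (row alignment is by position, so a mismatch is an error, not a
    silent permutation).
    """
    if isinstance(X_new, ScoreMatrix) and item_labels is not None:
        if list(X_new.item_labels) != list(item_labels):
            raise ValueError("item labels of new data do not match the training items")
    V = _as_values(X_new)
    W = np.asarray(W, dtype=float)
    if W.shape[0] != V.shape[0]:
        raise ValueError("item count of new data does not match the basis")
    return W.T @ V, reconstruction_error(V, W)


def assign_items(W, return_zero_rows: bool = False):
    """Item -> factor partition: the column index of each row's largest entry.

    Ties break toward the lowest column index.  All-zero rows go to factor 0
    with a warning.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("basis must be non-negative")
    partition = np.argmax(W, axis=1)
    zero_rows = np.flatnonzero(~np.any(W > 0, axis=1))
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} all-zero basis row(s) assigned to factor 0",
            RuntimeWarning,
            stacklevel=2,
        )
        partition[zero_rows] = 0
    if return_zero_rows:
        return partition, zero_rows
    return partition


def order_basis_columns(W, H: np.ndarray | None = None, return_order: bool = False):
    """Canonical column order: descending squared column mass.

    Ties break by the smallest row index of the column's maximal entry.  The
    same permutation is applied to the loadings when given.
    """
    W = np.asarray(W, dtype=float)
    mass = np.sum(W**2, axis=0)
    argmax_row = np.argmax(W, axis=0)
    order = sorted(range(W.shape[1]), key=lambda j: (-mass[j], argmax_row[j], j))
    order = np.asarray(order)
    W_ord = W[:, order]
    out = [W_ord]
    if H is not None:
        out.append(np.asarray(H)[order, :])
    if return_order:
        out.append(order)
    return out[0] if len(out) == 1 else tuple(out)
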
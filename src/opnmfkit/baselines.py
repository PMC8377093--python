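"""PCA and exploratory factor analysis baselines.

Correlation-matrix factorizations with promax oblique rotation, scree
diagnostics, Horn's parallel analysis, and the Tucker–Lewis fit index.  EFA
extraction is minimum-residual (minres) by default with Gaussian maximum
likelihood optional; both optimize over the uniquenesses with conditionally
optimal loadings, the standard reduction for p-variable batteries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .scores import ScoreMatrix


@dataclass
class LoadingMatrix:
    """Signed loadings plus rotation and fit metadata."""

    loadings: np.ndarray  # items x k pattern matrix
    method: str  # pca | efa-minres | efa-ml
    rotation: str = "none"  # none | promax
    rotation_matrix: np.ndarray | None = None  # k x k, L_rot = L_unrot @ T
    factor_correlations: np.ndarray | None = None  # Phi, unit diagonal (oblique)
    communalities: np.ndarray | None = None
    uniquenesses: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    fit_stats: dict = field(default_factory=dict)
    heywood: bool = False
    item_labels: list[str] | None = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass
class RankDiagnostics:
    """Eigenvalue-based retention diagnostics (scree / parallel analysis)."""

    eigenvalues: np.ndarray  # descending
    pa_thresholds: np.ndarray | None = None
    k_parallel: int | None = None
    k_scree: int | None = None
    n_sim: int | None = None
    percentile: float | None = None
    seed: int | None = None
    basis: str | None = None


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, ScoreMatrix) else np.asarray(X, float)


def correlation_matrix(X) -> np.ndarray:
    """Pearson item-by-item correlations across subjects (p x p)."""
    V = _values(X)
    sd = V.std(axis=1)
    if np.any(sd == 0):
        labels = X.item_labels if isinstance(X, ScoreMatrix) else [
            str(i) for i in range(V.shape[0])
        ]
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance item(s): {bad}")
    R = np.corrcoef(V)
    np.fill_diagonal(R, 1.0)
    return R


def _check_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("not a valid correlation matrix (symmetry/unit diagonal)")
    return 0.5 * (R + R.T)


def _fix_signs(L: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-magnitude entry is positive."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def pca_loadings(R, k: int, item_labels: list[str] | None = None) -> LoadingMatrix:
    """Unrotated principal-component loadings: eigenvectors scaled by
    sqrt(eigenvalue) for the top-k eigenvalues of R."""
    R = _check_corr(R)
    p = R.shape[0]
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    L = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    return LoadingMatrix(
        loadings=_fix_signs(L),
        method="pca",
        eigenvalues=evals,
        communalities=np.sum(L**2, axis=1),
        item_labels=item_labels,
    )


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, 1 - 1/diag(R^-1); falls back to
    max |off-diagonal| per row for singular R."""
    try:
        inv = np.linalg.inv(R)
        smc = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        off = R - np.eye(R.shape[0])
        smc = np.max(np.abs(off), axis=1) ** 2
    return np.clip(smc, 0.0, 1.0 - 1e-4)


def _conditional_loadings_minres(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    evals, evecs = np.linalg.eigh(R - np.diag(psi))
    order = np.argsort(evals)[::-1][:k]
    lam = np.sqrt(np.maximum(evals[order], 0.0))
    return evecs[:, order] * lam


def _conditional_loadings_ml(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    sp = np.sqrt(psi)
    Rs = R / np.outer(sp, sp)
    evals, evecs = np.linalg.eigh(Rs)
    order = np.argsort(evals)[::-1][:k]
    lam = np.sqrt(np.maximum(evals[order] - 1.0, 0.0))
    return (evecs[:, order] * lam) * sp[:, None]


def _ml_discrepancy(R: np.ndarray, psi: np.ndarray, k: int) -> float:
    """Lawley ML fit function: sum over trailing eigenvalues of
    Psi^-1/2 R Psi^-1/2 of (lambda - log lambda - 1)."""
    sp = np.sqrt(psi)
    Rs = R / np.outer(sp, sp)
    evals = np.sort(np.linalg.eigvalsh(Rs))[::-1]
    tail = np.maximum(evals[k:], 1e-12)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _canonicalize(L: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Rotate to the canonical form with L' Psi^-1 L diagonal, descending
    (the factanal convention), then fix column signs."""
    if L.shape[1] == 1:
        return _fix_signs(L)
    M = L.T @ (L / psi[:, None])
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    return _fix_signs(L @ evecs[:, order])


def max_identifiable_factors(p: int) -> int:
    """Largest k with non-negative model degrees of freedom."""
    return int((2 * p + 1 - np.sqrt(8 * p + 1)) / 2)


def efa_fit(
    R,
    k: int,
    n_subjects: int,
    method: str = "minres",
    item_labels: list[str] | None = None,
) -> LoadingMatrix:
    """Common-factor solution by minres (default) or maximum likelihood.

    Optimizes the uniquenesses with conditionally optimal loadings; returns
    unrotated loadings in the canonical (L' Psi^-1 L diagonal) orientation,
    communalities, the model and null-model chi-squares (Bartlett-corrected),
    and the Tucker–Lewis index.  Heywood cases (communality > 1) are flagged,
    not fatal.
    """
    R = _check_corr(R)
    p = R.shape[0]
    kmax = max_identifiable_factors(p)
    if not 1 <= k <= kmax:
        raise ValueError(f"k must be in [1, {kmax}] for p={p} items, got {k}")
    if n_subjects <= p:
        raise ValueError("need more subjects than items for EFA fit statistics")
    if method not in ("minres", "ml"):
        raise ValueError(f"unknown EFA method {method!r}")

    lower, upper = 1e-4, 1.0

    if method == "minres":

        def objective(psi):
            L = _conditional_loadings_minres(R, psi, k)
            resid = R - L @ L.T
            np.fill_diagonal(resid, 0.0)
            return 0.5 * float(np.sum(resid**2))

    else:

        def objective(psi):
            return _ml_discrepancy(R, psi, k)

    psi0 = 1.0 - _smc(R)
    res = minimize(
        objective,
        np.clip(psi0, lower, upper),
        method="L-BFGS-B",
        bounds=[(lower, upper)] * p,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        raise RuntimeError(f"EFA optimization failed to converge: {res.message}")
    psi = np.clip(res.x, lower, upper)

    if method == "minres":
        L = _conditional_loadings_minres(R, psi, k)
    else:
        L = _conditional_loadings_ml(R, psi, k)
    L = _canonicalize(L, psi)
    comm = np.sum(L**2, axis=1)
    heywood = bool(np.any(comm > 1.0 + 1e-6))
    if heywood:
        warnings.warn("Heywood case: communality exceeds 1", RuntimeWarning)

    # chi-square fit statistics via the ML discrepancy at the solution,
    # with Bartlett's correction factor
    F = _ml_discrepancy(R, psi, k)
    df_model = ((p - k) ** 2 - (p + k)) / 2.0
    correction = n_subjects - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0
    chi_model = max(correction, 0.0) * F
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    chi_null = -(n_subjects - 1 - (2 * p + 5) / 6.0) * logdet
    df_null = p * (p - 1) / 2.0
    tli = tucker_lewis_index(max(chi_model, 1e-12), df_model, max(chi_null, 1e-12), df_null)

    return LoadingMatrix(
        loadings=L,
        method=f"efa-{method}",
        communalities=comm,
        uniquenesses=psi,
        heywood=heywood,
        fit_stats={
            "discrepancy": F,
            "chi_model": chi_model,
            "df_model": df_model,
            "chi_null": chi_null,
            "df_null": df_null,
            "tli": tli,
            "n_subjects": n_subjects,
        },
        item_labels=item_labels,
    )


def varimax(L: np.ndarray, normalize: bool = True, tol: float = 1e-5, max_iter: int = 1000):
    """Varimax orthogonal rotation (SVD algorithm), Kaiser-normalized by
    default.  The stopping rule (relative criterion increase < tol, default
    1e-5) matches the canonical implementations.  Returns (rotated loadings,
    rotation matrix)."""
    L = np.asarray(L, float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    if normalize:
        h = np.sqrt(np.sum(L**2, axis=1))
        h[h == 0] = 1.0
        A = L / h[:, None]
    else:
        A = L.copy()
    T = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = A @ T
        G = A.T @ (B**3 - B @ np.diag(np.mean(B**2, axis=0)))
        U, s, Vt = np.linalg.svd(G)
        T = U @ Vt
        d = np.sum(s)
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    B = A @ T
    if normalize:
        B = B * h[:, None]
    return B, T


def promax_rotate(
    L,
    kappa: float = 4.0,
    kaiser: bool = True,
    item_labels: list[str] | None = None,
) -> LoadingMatrix:
    """Promax oblique rotation.

    Varimax pre-rotation (Kaiser row-normalized by default, matching the
    conventional implementation), element-wise power-kappa target with signs
    preserved, least-squares oblique fit of the target, and column rescaling
    so the factor correlation matrix Phi has a unit diagonal.  Returns
    pattern loadings, the total rotation matrix and Phi.  k = 1 passes
    through with Phi = [[1]].  Without Kaiser normalization the identity
    pattern = unrotated @ rotation_matrix holds exactly.
    """
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if isinstance(L, LoadingMatrix):
        src, labels, method = L.loadings, L.item_labels or item_labels, L.method
    else:
        src, labels, method = np.asarray(L, float), item_labels, "unknown"
    p, k = src.shape
    if k == 1:
        return LoadingMatrix(
            loadings=src.copy(),
            method=method,
            rotation="promax",
            rotation_matrix=np.eye(1),
            factor_correlations=np.eye(1),
            communalities=np.sum(src**2, axis=1),
            item_labels=labels,
        )
    V, T_vmx = varimax(src, normalize=kaiser)
    target = V * np.abs(V) ** (kappa - 1)
    VtV = V.T @ V
    cond = np.linalg.cond(VtV)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular intermediate matrix in promax (condition number {cond:.3g})"
        )
    U = np.linalg.solve(VtV, V.T @ target)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)[None, :]
    pattern = V @ U
    phi = np.linalg.inv(U.T @ U)
    phi = 0.5 * (phi + phi.T)
    rotmat = T_vmx @ U
    return LoadingMatrix(
        loadings=pattern,
        method=method,
        rotation="promax",
        rotation_matrix=rotmat,
        factor_correlations=phi,
        communalities=np.sum((pattern @ phi) * pattern, axis=1),
        item_labels=labels,
    )


def _pa_eigenvalues(V: np.ndarray, basis: str) -> np.ndarray:
    R = np.corrcoef(V)
    np.fill_diagonal(R, 1.0)
    if basis == "efa-eigen":
        Rr = R.copy()
        np.fill_diagonal(Rr, _smc(R))
        evals = np.linalg.eigvalsh(Rr)
    else:
        evals = np.linalg.eigvalsh(R)
    return np.sort(evals)[::-1]


def parallel_analysis(
    X,
    n_sim: int = 1000,
    percentile: float = 95.0,
    basis: str = "pca-eigen",
    seed: int | None = None,
) -> RankDiagnostics:
    """Horn's parallel analysis.

    Simulates ``n_sim`` standard-normal datasets of the observed shape,
    takes the per-position ``percentile`` of their correlation eigenvalues as
    thresholds, and retains the leading observed eigenvalues that strictly
    exceed them, stopping at the first failure.  With ``basis='efa-eigen'``
    both observed and simulated eigenvalues come from the reduced correlation
    matrix (squared multiple correlations on the diagonal), the common-factor
    variant.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if basis not in ("pca-eigen", "efa-eigen"):
        raise ValueError(f"unknown parallel-analysis basis {basis!r}")
    V = _values(X)
    p, n = V.shape
    observed = _pa_eigenvalues(V, basis)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, p))
    for s in range(n_sim):
        Z = rng.standard_normal((p, n))
        sims[s] = _pa_eigenvalues(Z, basis)
    thresholds = np.percentile(sims, percentile, axis=0)
    k = 0
    for j in range(p):
        if observed[j] > thresholds[j]:
            k += 1
        else:
            break
    return RankDiagnostics(
        eigenvalues=observed,
        pa_thresholds=thresholds,
        k_parallel=k,
        n_sim=n_sim,
        percentile=percentile,
        seed=seed,
        basis=basis,
    )


def scree_eigenvalues(R) -> RankDiagnostics:
    """Descending eigenvalues of R plus an advisory acceleration-factor elbow
    (position of the largest second difference); scree reading remains a
    judgment call, the elbow is only a hint."""
    R = _check_corr(R)
    evals = np.sort(np.linalg.eigvalsh(R))[::-1]
    k_scree = None
    if evals.size >= 3:
        accel = evals[:-2] - 2 * evals[1:-1] + evals[2:]  # at positions 2..p-1
        if np.max(accel) > 1e-10:
            k_scree = int(np.argmax(accel) + 1)
    return RankDiagnostics(eigenvalues=evals, k_scree=k_scree)


def tucker_lewis_index(chi_model: float, df_model: float, chi_null: float, df_null: float) -> float:
    """TLI = ((chi_n/df_n) - (chi_m/df_m)) / ((chi_n/df_n) - 1); not clipped,
    values can fall outside [0, 1]."""
    if df_model <= 0 or df_null <= 0:
        raise ValueError("degrees of freedom must be positive")
    if chi_model < 0 or chi_null < 0:
        raise ValueError("chi-square values must be non-negative")
    null_ratio = chi_null / df_null
    if null_ratio == 1.0:
        raise ValueError("null-model chi-square/df equals 1: TLI undefined")
    return float((null_ratio - chi_model / df_model) / (null_ratio - 1.0))


def assign_items_from_loadings(L) -> np.ndarray:
    """Item -> factor partition by largest absolute pattern loading (ties to
    the lowest factor index; all-zero rows to factor 0 with a warning)."""
    A = np.abs(L.loadings if isinstance(L, LoadingMatrix) else np.asarray(L, float))
    partition = np.argmax(A, axis=1)
    zero_rows = np.flatnonzero(~np.any(A > 0, axis=1))
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} all-zero loading row(s) assigned to factor 0",
            RuntimeWarning,
            stacklevel=2,
        )
        partition[zero_rows] = 0
    return partition
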
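"""Nonparametric statistical machinery shared by all analysis modules.

The group comparisons throughout the package are covariate-adjusted
permutation tests: a Pillai-trace pseudo-F is computed from the full
(covariates + group) and reduced (covariates-only) linear models, and its
null distribution is obtained by Freedman–Lane permutation — residuals of
the reduced model are permuted, the fitted reduced part is added back, and
the statistic is recomputed on the reconstructed response.  For a
univariate response this reduces to the ordinary ANCOVA F test; for a
d-variate response (e.g. the three coordinates of a mesh vertex) it is a
permutation MANCOVA.  Multiple testing is controlled with the
Benjamini–Hochberg step-up FDR procedure, and brain–cognition associations
use partial Spearman correlations (rank-transform, residualize on
covariates, correlate residuals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDesignError, ValidationError

__all__ = [
    "StatResult",
    "PartialCorrelation",
    "validate_covariate_table",
    "covariate_matrix",
    "bh_fdr",
    "permutation_group_test",
    "batched_permutation_group_test",
    "pairwise_posthoc",
    "partial_spearman",
    "rank_group_tests",
]

#: Columns expected in a covariate table (besides subject_id).
COVARIATE_COLUMNS = ("age", "sex", "education", "center")


@dataclass
class StatResult:
    """Outcome of a single (possibly permutation-based) group test."""

    statistic: float
    p_raw: float
    p_fdr: float | None = None
    df_effect: int | None = None
    n_perm_used: int | None = None
    label: str | None = None


@dataclass
class PartialCorrelation:
    """Partial Spearman correlation between two variables given covariates."""

    rho: float
    p_raw: float
    n: int
    p_fdr: float | None = None


def validate_covariate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a covariate table: unique subject_id, no missing values.

    Sex and recruitment center are expected as 0/1 indicator codes.
    """
    if "subject_id" not in table.columns:
        raise ValidationError("covariate table needs a subject_id column")
    if table["subject_id"].duplicated().any():
        raise ValidationError("duplicate subject_ids in covariate table")
    missing = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"covariate table missing columns: {missing}")
    sub = table[list(COVARIATE_COLUMNS)]
    if sub.isna().any().any():
        raise ValidationError("covariate table contains missing values")
    return table


def covariate_matrix(covariates, n: int) -> np.ndarray:
    """Coerce covariates to an (n, k) float design block (no intercept).

    Accepts None (k = 0), an array, or a DataFrame (subject_id column, if
    present, is dropped; rows must already be aligned with the response).
    """
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, pd.DataFrame):
        cols = [c for c in covariates.columns if c != "subject_id"]
        mat = covariates[cols].to_numpy(dtype=float)
    else:
        mat = np.asarray(covariates, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
    if mat.shape[0] != n:
        raise ValidationError(
            f"covariates have {mat.shape[0]} rows, response has {n}"
        )
    if not np.all(np.isfinite(mat)):
        raise ValidationError("covariates must be finite")
    return mat


# ---------------------------------------------------------------------------
# Benjamini–Hochberg FDR
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original input order)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("bh_fdr expects a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Freedman–Lane permutation MANCOVA / ANCOVA
# ---------------------------------------------------------------------------

def _orthonormal_basis(mat: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    if mat.shape[1] == 0:
        return np.empty((mat.shape[0], 0))
    q, r = np.linalg.qr(mat)
    diag = np.abs(np.diag(r))
    keep = diag > max(mat.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    return q[:, keep]


def _group_dummies(group) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    codes, levels = pd.factorize(np.asarray(group))
    g = len(levels)
    if g < 2:
        raise ValidationError("need at least two groups")
    dummies = np.eye(g)[codes][:, 1:]  # reference-coded, intercept elsewhere
    return dummies, codes, np.asarray(levels)


def _permutation_schedule(n: int, n_perm: int, seed) -> tuple[np.ndarray, bool]:
    """Row-index permutations: exhaustive when n! <= n_perm, else sampled."""
    if n <= 12 and math.factorial(n) <= n_perm:
        perms = np.array(list(_iter_permutations(range(n))), dtype=np.intp)
        return perms, True
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)], dtype=np.intp)
    return perms, False


def _pillai_and_f(H: np.ndarray, E: np.ndarray, d: int, q: int, n: int,
                  k_full: int) -> tuple[np.ndarray, np.ndarray]:
    """Batched Pillai trace and pseudo-F from hypothesis/error SSCP stacks.

    H, E have shape (..., d, d).  Degenerate (constant-response) entries get
    statistic 0.
    """
    S = H + E
    tr = np.trace(S, axis1=-2, axis2=-1)
    scale = np.where(tr > 0, tr, 1.0)
    degenerate = tr <= 1e-12 * np.maximum(1.0, np.abs(scale))
    S_safe = np.where(degenerate[..., None, None], np.eye(d), S)
    # tiny symmetric ridge for numerical safety of the batched solve
    eps = 1e-12 * scale[..., None, None] * np.eye(d)
    pillai = np.trace(np.linalg.solve(S_safe + eps, H), axis1=-2, axis2=-1)
    pillai = np.clip(np.where(degenerate, 0.0, pillai), 0.0, None)
    s = min(d, q)
    m = (abs(d - q) - 1) / 2.0
    nn = (n - k_full - d - 1) / 2.0
    denom = np.maximum(s - pillai, 1e-12)
    f = ((2 * nn + s + 1) / (2 * m + s + 1)) * (pillai / denom)
    return pillai, f


def batched_permutation_group_test(
    response: np.ndarray,
    group,
    covariates=None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Freedman–Lane permutation MANCOVA over a batch of responses.

    Parameters
    ----------
    response
        Array of shape (n, V, d): V independent d-variate responses measured
        on the same n subjects (e.g. V mesh vertices with d = 3 coordinates,
        or V tract segments with d = 1).  A single shared permutation
        schedule is used for the whole batch, preserving exchangeability
        across the family.
    group
        Length-n group labels (two or more levels).
    covariates
        Optional (n, k) nuisance block; an intercept is always included.

    Returns
    -------
    (pseudo_f, p_raw, info) with arrays of length V.  ``info`` records the
    Pillai traces, effect df and the number of permutations actually used
    (exhaustive enumeration replaces sampling when n! <= n_perm).
    """
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 2:
        Y = Y[:, :, None]
    if Y.ndim != 3:
        raise ValidationError("response must have shape (n, V, d) or (n, V)")
    n, V, d = Y.shape
    if not np.all(np.isfinite(Y)):
        raise ValidationError("response must be finite")

    X, codes, levels = _group_dummies(group)
    if len(codes) != n:
        raise ValidationError("group labels not aligned with response rows")
    C = covariate_matrix(covariates, n)
    counts = np.bincount(codes)
    if np.any(counts < C.shape[1] + 1):
        raise DegenerateDesignError(
            "each group needs more subjects than covariates"
        )

    Z = np.column_stack([np.ones(n), C])            # nuisance (reduced model)
    Qz = _orthonormal_basis(Z)
    Xr = X - Qz @ (Qz.T @ X)                         # effect, ⟂ nuisance
    Qx = _orthonormal_basis(Xr)
    q = Qx.shape[1]
    if q == 0:
        raise DegenerateDesignError("group factor confounded with covariates")
    k_full = Qz.shape[1] + q

    Yf = Y.reshape(n, V * d)
    G0 = Qz.T @ Yf                                   # reduced-model fit
    R = Yf - Qz @ G0                                 # reduced-model residuals
    U0 = Qx.T @ Yf

    def _sscp(A):  # (k, V*d) -> (V, d, d) per-response cross-products
        Ar = A.reshape(-1, V, d)
        return np.einsum("kvi,kvj->vij", Ar, Ar)

    T_R = _sscp(R)                                   # permutation-invariant
    H0 = _sscp(U0)
    E0 = T_R - H0
    pillai0, f0 = _pillai_and_f(H0, E0, d, q, n, k_full)

    perms, exhaustive = _permutation_schedule(n, n_perm, seed)
    n_used = perms.shape[0]
    exceed = np.zeros(V, dtype=np.int64)
    chunk = max(1, int(2**24 // max(1, n * V * d)))
    for start in range(0, n_used, chunk):
        P = perms[start:start + chunk]
        Rp = R[P]                                    # (c, n, V*d)
        U = np.matmul(Qx.T, Rp)                      # Qx ⟂ Z ⇒ fit part drops
        Dz = np.matmul(Qz.T, Rp)
        Ur = U.reshape(len(P), -1, V, d)
        Dzr = Dz.reshape(len(P), -1, V, d)
        H = np.einsum("ckvi,ckvj->cvij", Ur, Ur)
        # E* = Y*'Y* - G*'G* - H; the reduced-model fit and its cross-terms
        # cancel exactly, leaving E* = R'R - Dz'Dz - H.
        DtD = np.einsum("ckvi,ckvj->cvij", Dzr, Dzr)
        E = T_R - DtD - H
        pil, _ = _pillai_and_f(H, E, d, q, n, k_full)
        exceed += np.sum(pil >= pillai0[None, :] - 1e-12, axis=0)

    if exhaustive:
        p_raw = exceed / n_used                      # identity perm included
    else:
        p_raw = (1 + exceed) / (1 + n_used)
    constant = np.trace(T_R, axis1=-2, axis2=-1) <= 1e-12
    p_raw = np.where(constant, 1.0, p_raw)
    f0 = np.where(constant, 0.0, f0)
    info = {
        "pillai": pillai0,
        "df_effect": q * d,
        "n_perm_used": n_used,
        "exhaustive": exhaustive,
        "levels": levels,
    }
    return f0, p_raw, info


def permutation_group_test(
    response,
    group,
    covariates=None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> StatResult:
    """Covariate-adjusted permutation group test for one response.

    ``response`` is (n,) for a univariate ANCOVA or (n, d) for a
    multivariate (Pillai-trace) MANCOVA.  See
    :func:`batched_permutation_group_test` for the permutation scheme.
    """
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    f, p, info = batched_permutation_group_test(
        Y[:, None, :], group, covariates, n_perm=n_perm, seed=seed
    )
    return StatResult(
        statistic=float(f[0]),
        p_raw=float(p[0]),
        df_effect=int(info["df_effect"]),
        n_perm_used=int(info["n_perm_used"]),
    )


def pairwise_posthoc(
    response,
    group,
    covariates=None,
    pairs=None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[StatResult]:
    """Two-group permutation tests for each pair, BH-FDR across the pairs.

    The caller is expected to have run (and found significant) the omnibus
    test first.  ``pairs`` defaults to all unordered pairs of observed
    group levels.
    """
    Y = np.asarray(response, dtype=float)
    labels = np.asarray(group)
    levels = pd.unique(labels)
    if pairs is None:
        pairs = list(combinations(levels, 2))
    if len(pairs) == 0:
        raise ValidationError("empty pair list")
    C = covariate_matrix(covariates, len(labels))
    results = []
    for i, (a, b) in enumerate(pairs):
        sel = (labels == a) | (labels == b)
        res = permutation_group_test(
            Y[sel], labels[sel], C[sel] if C.size else None,
            n_perm=n_perm, seed=None if seed is None else seed + i,
        )
        res.label = f"{a}/{b}"
        results.append(res)
    adj = bh_fdr([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_fdr = float(a)
    return results


# ---------------------------------------------------------------------------
# Partial Spearman correlation
# ---------------------------------------------------------------------------

def partial_spearman(x, y, covariates=None) -> PartialCorrelation:
    """Spearman correlation of x and y after removing covariate effects.

    Both variables are rank-transformed (average ranks for ties),
    residualized on [intercept, covariates] by least squares, and the
    residuals are Pearson-correlated.  The p-value uses the t
    approximation on n - 2 - k degrees of freedom.  With no covariates
    this is the ordinary Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and equally long")
    n = x.size
    C = covariate_matrix(covariates, n)
    k = C.shape[1]
    if n < k + 3:
        raise ValidationError("need at least covariates + 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDesignError("constant variable: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    Z = np.column_stack([np.ones(n), sps.rankdata(C, axis=0) if k else
                         np.empty((n, 0))])
    Qz = _orthonormal_basis(Z)
    ex = rx - Qz @ (Qz.T @ rx)
    ey = ry - Qz @ (Qz.T @ ry)
    denom = math.sqrt(float(ex @ ex) * float(ey @ ey))
    if denom == 0:
        raise DegenerateDesignError("residuals degenerate")
    rho = float(np.clip((ex @ ey) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return PartialCorrelation(rho=rho, p_raw=p, n=n)


# ---------------------------------------------------------------------------
# Rank-based group tests (cognitive / demographic tables)
# ---------------------------------------------------------------------------

def rank_group_tests(values, group) -> tuple[StatResult, list[StatResult]]:
    """Kruskal–Wallis omnibus plus Mann–Whitney post hocs (BH-FDR).

    Returns (omnibus, posthocs); posthocs cover all unordered group pairs
    regardless of omnibus significance so that callers can gate on it.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(group)
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    samples = [v[labels == lev] for lev in levels]
    if any(len(s) < 2 for s in samples):
        raise ValidationError("need at least two values per group")
    if np.ptp(v) == 0:
        omnibus = StatResult(statistic=0.0, p_raw=1.0, df_effect=len(levels) - 1)
        posthocs = []
        for a, b in combinations(levels, 2):
            posthocs.append(StatResult(statistic=float(
                len(v[labels == a]) * len(v[labels == b]) / 2), p_raw=1.0,
                p_fdr=1.0, label=f"{a}/{b}"))
        return omnibus, posthocs
    h, p = sps.kruskal(*samples)
    omnibus = StatResult(statistic=float(h), p_raw=float(p),
                         df_effect=len(levels) - 1)
    posthocs = []
    for a, b in combinations(levels, 2):
        u, pu = sps.mannwhitneyu(v[labels == a], v[labels == b],
                                 alternative="two-sided")
        posthocs.append(StatResult(statistic=float(u), p_raw=float(pu),
                                   label=f"{a}/{b}"))
    adj = bh_fdr([r.p_raw for r in posthocs])
    for r, a in zip(posthocs, adj):
        r.p_fdr = float(a)
    return omnibus, posthocs
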
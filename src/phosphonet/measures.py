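"""Pairwise association measures between rows of a data matrix.

Six measures are implemented, spanning linear correlation (Pearson),
rank correlation (Spearman, Kendall tau-b), information-theoretic
dependence on discretized data (plug-in mutual information), directional
functional dependence on discretized data (the functional chi-squared
statistic), and multivariate conditional dependence (shrinkage Gaussian
graphical model partial correlations).

Discretization for MI and FunChiSq uses globally optimal 1-D k-means
(dynamic programming over the sorted values, as in Ckmeans.1d.dp), with
the number of levels defaulting to min(ceil(sqrt(n)), 5).

Every measure is available in two forms: a 1:1 form on a single
variables x samples matrix, and a time-lagged form on an aligned
(leading, trailing) matrix pair in which entry (i, j) associates variable
i at times 1..n-1 with variable j at times 2..n and is interpreted as a
directed i -> j candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MEASURES",
    "AssociationMatrix",
    "score_matrix",
    "score_lagged",
    "pearson_matrix",
    "spearman_matrix",
    "kendall_matrix",
    "mutual_information_matrix",
    "funchisq_matrix",
    "ggm_matrix",
    "discretize_1d_kmeans",
    "default_levels",
    "funchisq_stat",
    "shrinkage_correlation",
]

MEASURES = ("pearson", "spearman", "kendall", "mi", "funchisq", "ggm")

#: measures whose score matrix is non-symmetric even in 1:1 mode
DIRECTED_MEASURES = ("funchisq",)


@dataclass
class AssociationMatrix:
    """Pairwise scores over a common variable space.

    ``directed`` is False when ``scores`` is symmetric by construction
    (then entry (i, j) belongs to the unordered pair), True when the score
    of (i, j) is the directed candidate i -> j.  The diagonal is NaN and
    is excluded from evaluation; zero-variance variables yield NaN rows.
    """

    scores: np.ndarray
    directed: bool
    measure_name: str
    variable_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValueError("scores must be a square matrix")


# ---------------------------------------------------------------------------
# helpers


def _as_matrix(X: np.ndarray, min_samples: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (variables x samples)")
    if X.shape[1] < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {X.shape[1]}")
    return X

def _mask_degenerate(scores: np.ndarray, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """NaN out rows/columns of constant variables and the diagonal (if square)."""
    scores[np.std(X, axis=1) == 0, :] = np.nan
    scores[:, np.std(Y, axis=1) == 0] = np.nan
    if scores.shape[0] == scores.shape[1]:
        np.fill_diagonal(scores, np.nan)
    return scores


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, X)


def _pearson_cross(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Cross-correlation matrix between rows of X and rows of Y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (Xc @ Yc.T) / np.outer(sx, sy)
    return np.clip(C, -1.0, 1.0)


# ---------------------------------------------------------------------------
# discretization


def default_levels(n_samples: int, cap: int = 5) -> int:
    """Default number of discretization levels: min(ceil(sqrt(n)), cap)."""
    return max(2, min(math.ceil(math.sqrt(n_samples)), cap))


def discretize_1d_kmeans(v: np.ndarray, k: int) -> np.ndarray:
    """Globally optimal 1-D k-means clustering into ``k`` levels.

    Dynamic programming over the sorted values minimises total
    within-cluster sum of squares exactly (the optimal clusters are
    contiguous in sorted order).  Labels are 0..k-1 ordered by cluster
    mean.  If fewer than ``k`` distinct values exist, k is reduced.
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, len(np.unique(v)))
    if k == 1:
        return np.zeros(n, dtype=int)

    order = np.argsort(v, kind="stable")
    x = v[order]
    # prefix sums for O(1) within-cluster SSE of x[i..j]
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:  # inclusive, 0-based
        s = csum[j + 1] - csum[i]
        q = csq[j + 1] - csq[i]
        m = j - i + 1
        return q - s * s / m

    INF = np.inf
    # D[c][j] = optimal cost of clustering x[0..j] into c+1 clusters
    D = np.full((k, n), INF)
    B = np.zeros((k, n), dtype=int)  # start index of the last cluster
    for j in range(n):
        D[0, j] = sse(0, j)
    for c in range(1, k):
        for j in range(c, n):
            best, arg = INF, c
            for i in range(c, j + 1):
                cost = D[c - 1, i - 1] + sse(i, j)
                if cost < best:
                    best, arg = cost, i
            D[c, j] = best
            B[c, j] = arg

    labels_sorted = np.empty(n, dtype=int)
    j = n - 1
    for c in range(k - 1, -1, -1):
        i = B[c, j] if c > 0 else 0
        labels_sorted[i : j + 1] = c
        j = i - 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def _discretize_rows(X: np.ndarray, levels: int | None) -> np.ndarray:
    r = levels if levels is not None else default_levels(X.shape[1])
    return np.vstack([discretize_1d_kmeans(row, r) for row in X])


# ---------------------------------------------------------------------------
# correlation measures


def pearson_matrix(X: np.ndarray) -> AssociationMatrix:
    """Pearson correlation between all row pairs."""
    X = _as_matrix(X, 3)
    C = _pearson_cross(X, X)
    return AssociationMatrix(_mask_degenerate(C, X, X), False, "pearson")


def spearman_matrix(X: np.ndarray) -> AssociationMatrix:
    """Spearman correlation: Pearson on midranks."""
    X = _as_matrix(X, 3)
    R = _rank_rows(X)
    C = _pearson_cross(R, R)
    return AssociationMatrix(_mask_degenerate(C, X, X), False, "spearman")


def _kendall_cross(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    nx, ny = X.shape[0], Y.shape[0]
    same = X is Y
    C = np.empty((nx, ny))
    for i in range(nx):
        j0 = i if same else 0
        for j in range(j0, ny):
            if same and i == j:
                C[i, j] = 1.0
                continue
            tau = stats.kendalltau(X[i], Y[j]).statistic
            C[i, j] = tau
            if same:
                C[j, i] = tau
    return C


def kendall_matrix(X: np.ndarray) -> AssociationMatrix:
    """Kendall rank correlation (tau-b tie correction) between row pairs."""
    X = _as_matrix(X, 2)
    C = _kendall_cross(X, X)
    return AssociationMatrix(_mask_degenerate(C, X, X), False, "kendall")


# ---------------------------------------------------------------------------
# discretized measures


def _mi_from_labels(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (natural log) of two label vectors."""
    n = a.size
    joint = np.zeros((a.max() + 1, b.max() + 1))
    np.add.at(joint, (a, b), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


def mutual_information_matrix(X: np.ndarray, levels: int | None = None) -> AssociationMatrix:
    """Plug-in MI between row pairs after optimal 1-D k-means discretization."""
    X = _as_matrix(X, 2)
    L = _discretize_rows(X, levels)
    n = X.shape[0]
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = _mi_from_labels(L[i], L[j])
    return AssociationMatrix(_mask_degenerate(C, X, X), False, "mi")


def funchisq_stat(table: np.ndarray) -> tuple[float, int]:
    """Functional chi-squared statistic of a contingency table.

    Tests whether the column variable is a function of the row variable:
    the row-wise deviation from a uniform conditional distribution, minus
    the deviation of the column marginal from uniformity.  Returns
    (statistic, degrees of freedom (r-1)(s-1)).
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or (T < 0).any():
        raise ValueError("table must be a non-negative 2-D count matrix")
    n = T.sum()
    r, s = T.shape
    if n == 0 or r < 2 or s < 2:
        return float("nan"), (r - 1) * (s - 1)
    row_sums = T.sum(axis=1)
    col_sums = T.sum(axis=0)
    nz = row_sums > 0
    expected = row_sums[nz, None] / s
    row_term = ((T[nz] - expected) ** 2 / expected).sum()
    col_term = ((col_sums - n / s) ** 2 / (n / s)).sum()
    return float(row_term - col_term), (r - 1) * (s - 1)


def _funchisq_normalized(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized functional chi-squared of label vectors a -> b."""
    table = np.zeros((a.max() + 1, b.max() + 1))
    np.add.at(table, (a, b), 1.0)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return float("nan")
    chi2, df = funchisq_stat(table)
    return (chi2 - df) / math.sqrt(2.0 * df)


def funchisq_matrix(X: np.ndarray, levels: int | None = None) -> AssociationMatrix:
    """Normalized functional chi-squared for every ordered row pair i -> j."""
    X = _as_matrix(X, 2)
    L = _discretize_rows(X, levels)
    n = X.shape[0]
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                C[i, j] = _funchisq_normalized(L[i], L[j])
    return AssociationMatrix(_mask_degenerate(C, X, X), True, "funchisq")


# ---------------------------------------------------------------------------
# Gaussian graphical model


def shrinkage_correlation(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Schaefer-Strimmer shrinkage of the sample correlation matrix.

    The correlation matrix is shrunk toward the identity with the analytic
    optimal intensity lambda* = sum Var-hat(r_ij) / sum r_ij^2 (off-diagonal
    sums), clipped to [0, 1].  Returns (shrunk correlation, lambda).
    """
    X = _as_matrix(X, 3)
    p, n = X.shape
    sd = X.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant variables: cannot shrink a singular correlation")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    R = (Z @ Z.T) / (n - 1)
    # Var-hat(r_ij) = n / (n-1)^3 * sum_k (w_kij - mean_k w_kij)^2,
    # with w_kij = z_ki z_kj
    W_mean = R * (n - 1) / n
    sq = (Z**2) @ (Z**2).T  # sum_k z_ki^2 z_kj^2
    var_r = n / (n - 1.0) ** 3 * (sq - n * W_mean**2)
    off = ~np.eye(p, dtype=bool)
    denom = (R[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    R_star = (1.0 - lam) * R
    np.fill_diagonal(R_star, 1.0)
    return R_star, lam


def _partial_from_correlation(R: np.ndarray) -> np.ndarray:
    P = np.linalg.inv(R)
    d = np.sqrt(np.diag(P))
    rho = -P / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def ggm_matrix(X: np.ndarray, shrink: bool = True) -> AssociationMatrix:
    """Partial correlations from a (shrunk) Gaussian graphical model.

    rho_ik = -P_ik / sqrt(P_ii P_kk) with P the inverse of the shrinkage
    correlation matrix; measures the association of i and k conditional on
    all other variables.  ``shrink=False`` inverts the raw correlation
    matrix (only valid when samples comfortably exceed variables).
    """
    X = _as_matrix(X, 3)
    if shrink:
        R, _ = shrinkage_correlation(X)
    else:
        R = _pearson_cross(X, X)
    try:
        rho = _partial_from_correlation(R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"correlation matrix singular: {exc}") from exc
    return AssociationMatrix(_mask_degenerate(rho, X, X), False, "ggm")


def _ggm_lagged(leading: np.ndarray, trailing: np.ndarray) -> np.ndarray:
    """Directed GGM scores: partial correlations between leading and trailing
    copies of the variables, estimated jointly on the stacked 2p matrix."""
    p = leading.shape[0]
    stacked = np.vstack([leading, trailing])
    sd = stacked.std(axis=1)
    ok = sd > 0
    scores = np.full((p, p), np.nan)
    if ok.sum() < 2:
        return scores
    R, _ = shrinkage_correlation(stacked[ok])
    rho_ok = _partial_from_correlation(R)
    idx = np.flatnonzero(ok)
    pos = {v: i for i, v in enumerate(idx)}
    for i in range(p):
        for j in range(p):
            if i in pos and (j + p) in pos:
                scores[i, j] = rho_ok[pos[i], pos[j + p]]
    return scores


# ---------------------------------------------------------------------------
# dispatchers


def score_matrix(X: np.ndarray, measure: str, levels: int | None = None) -> AssociationMatrix:
    """Score all row pairs of ``X`` with the named measure (1:1 mode)."""
    if measure == "pearson":
        return pearson_matrix(X)
    if measure == "spearman":
        return spearman_matrix(X)
    if measure == "kendall":
        return kendall_matrix(X)
    if measure == "mi":
        return mutual_information_matrix(X, levels)
    if measure == "funchisq":
        return funchisq_matrix(X, levels)
    if measure == "ggm":
        return ggm_matrix(X)
    raise ValueError(f"unknown measure {measure!r}")


def score_lagged(
    leading: np.ndarray,
    trailing: np.ndarray,
    measure: str,
    levels: int | None = None,
) -> AssociationMatrix:
    """Directed scores between leading (i, times 1..n-1) and trailing
    (j, times 2..n) variables; entry (i, j) is the i -> j candidate."""
    leading = np.asarray(leading, dtype=float)
    trailing = np.asarray(trailing, dtype=float)
    if leading.shape != trailing.shape:
        raise ValueError("leading and trailing matrices must be aligned")
    if measure == "pearson":
        C = _pearson_cross(leading, trailing)
    elif measure == "spearman":
        C = _pearson_cross(_rank_rows(leading), _rank_rows(trailing))
    elif measure == "kendall":
        C = _kendall_cross(leading, trailing)
    elif measure in ("mi", "funchisq"):
        La = _discretize_rows(leading, levels)
        Lb = _discretize_rows(trailing, levels)
        n = leading.shape[0]
        C = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if measure == "mi":
                    C[i, j] = _mi_from_labels(La[i], Lb[j])
                else:
                    C[i, j] = _funchisq_normalized(La[i], Lb[j])
    elif measure == "ggm":
        C = _ggm_lagged(leading, trailing)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    C = _mask_degenerate(C, leading, trailing)
    return AssociationMatrix(C, True, measure)
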
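"""Association measures against hand computations and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from phosphonet import measures as M

# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())


def spearman_oracle(x, y):
    return pearson_oracle(stats.rankdata(x), stats.rankdata(y))


def kendall_oracle(x, y):
    """tau-b by full pair enumeration with tie corrections."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))


def mi_oracle(a, b):
    """Plug-in MI from explicit joint frequencies, natural log."""
    n = len(a)
    total = 0.0
    for va in set(a):
        for vb in set(b):
            pxy = sum(1 for u, v in zip(a, b) if u == va and v == vb) / n
            if pxy == 0:
                continue
            px = sum(1 for u in a if u == va) / n
            py = sum(1 for v in b if v == vb) / n
            total += pxy * math.log(pxy / (px * py))
    return total


def funchisq_oracle(table):
    """Published functional chi-squared, written out longhand."""
    T = np.asarray(table, float)
    n = T.sum()
    r, s = T.shape
    first = 0.0
    for i in range(r):
        ni = T[i].sum()
        if ni == 0:
            continue
        for j in range(s):
            first += (T[i, j] - ni / s) ** 2 / (ni / s)
    second = sum((T[:, j].sum() - n / s) ** 2 / (n / s) for j in range(s))
    return first - second


def kmeans1d_oracle(v, k):
    """Optimal 1-D k-means by enumerating contiguous partitions of sorted v."""
    x = np.sort(np.asarray(v, float))
    n = len(x)
    best, best_bounds = np.inf, None
    for bounds in itertools.combinations(range(1, n), k - 1):
        cuts = (0, *bounds, n)
        cost = sum(
            ((x[a:b] - x[a:b].mean()) ** 2).sum() for a, b in zip(cuts, cuts[1:])
        )
        if cost < best:
            best, best_bounds = cost, cuts
    return best, best_bounds


# ---------------------------------------------------------------------------
# hand-computed examples


@pytest.mark.parametrize(
    "fn,x,y,expected",
    [
        (M.pearson_matrix, [1, 2, 3], [2, 4, 6], 1.0),
        (M.pearson_matrix, [1, 2, 3], [6, 4, 2], -1.0),
        (M.pearson_matrix, [1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        (M.spearman_matrix, [1, 2, 3], [1, 8, 27], 1.0),
        (M.spearman_matrix, [1, 2, 3], [27, 8, 1], -1.0),
        (M.spearman_matrix, [1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        (M.kendall_matrix, [1, 2, 3], [10, 20, 30], 1.0),
        (M.kendall_matrix, [1, 2, 3], [30, 20, 10], -1.0),
        (M.kendall_matrix, [1, 2, 3], [1, 3, 2], 1 / 3),
    ],
)
def test_correlation_examples(fn, x, y, expected):
    am = fn(np.array([x, y], dtype=float))
    assert am.scores[0, 1] == pytest.approx(expected, abs=1e-12)
    assert am.scores[1, 0] == pytest.approx(expected, abs=1e-12)


def test_mi_identical_balanced_levels_is_ln2():
    x = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
    am = M.mutual_information_matrix(np.array([x, x]), levels=2)
    assert am.scores[0, 1] == pytest.approx(math.log(2), abs=1e-12)


def test_mi_exact_product_joint_is_zero():
    # joint counts equal the product of the marginals -> MI 0
    x = np.array([0, 0, 0, 0, 5, 5, 5, 5], dtype=float)
    y = np.array([0, 0, 5, 5, 0, 0, 5, 5], dtype=float)
    am = M.mutual_information_matrix(np.array([x, y]), levels=2)
    assert am.scores[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_funchisq_diagonal_table():
    chi2, df = M.funchisq_stat([[3, 0], [0, 3]])
    assert chi2 == pytest.approx(6.0)
    assert df == 1


def test_funchisq_uniform_table_is_zero():
    chi2, _ = M.funchisq_stat([[2, 2], [2, 2]])
    assert chi2 == pytest.approx(0.0)


def test_funchisq_directionality_values():
    # [[2,2],[4,0]]: row->column reads 2, transposed direction 8/3, per the
    # published statistic (the column-marginal penalty differs by direction)
    fwd, _ = M.funchisq_stat([[2, 2], [4, 0]])
    rev, _ = M.funchisq_stat(np.array([[2, 2], [4, 0]]).T)
    assert fwd == pytest.approx(2.0)
    assert rev == pytest.approx(8 / 3)


def test_funchisq_prefers_functional_direction():
    # square table, y = f(x) exactly (many-to-one), x = f(y) not:
    # the normalized statistic must score X->Y above Y->X
    table = np.array([[4, 0, 0], [0, 4, 0], [4, 0, 0]])
    fwd, dff = M.funchisq_stat(table)
    rev, dfr = M.funchisq_stat(table.T)
    assert (fwd - dff) / math.sqrt(2 * dff) > (rev - dfr) / math.sqrt(2 * dfr)


def test_ggm_two_variables_equals_pearson(rng):
    X = rng.normal(size=(2, 40))
    am = M.ggm_matrix(X, shrink=False)
    assert am.scores[0, 1] == pytest.approx(pearson_oracle(X[0], X[1]), abs=1e-10)


def test_ggm_chain_partial_correlation_vanishes():
    # population covariance of A -> B -> C with unit innovations:
    # B = 2A + e, C = 3B + e  =>  analytic 3x3 covariance; rho_AC|B = 0
    a, b = 2.0, 3.0
    cov = np.array(
        [
            [1.0, a, a * b],
            [a, a**2 + 1.0, b * (a**2 + 1.0)],
            [a * b, b * (a**2 + 1.0), b**2 * (a**2 + 1.0) + 1.0],
        ]
    )
    d = np.sqrt(np.diag(cov))
    R = cov / np.outer(d, d)
    P = np.linalg.inv(R)
    rho_ac_given_b = -P[0, 2] / math.sqrt(P[0, 0] * P[2, 2])
    assert rho_ac_given_b == pytest.approx(0.0, abs=1e-12)
    # and the sample-based estimator approaches the analytic values:
    # rho_AB|C = a / sqrt((1+a^2)(1+b^2)) from the precision matrix
    rng = np.random.default_rng(5)
    A = rng.normal(size=20000)
    B = a * A + rng.normal(size=20000)
    C = b * B + rng.normal(size=20000)
    am = M.ggm_matrix(np.array([A, B, C]))
    assert abs(am.scores[0, 2]) < 0.05
    assert am.scores[0, 1] == pytest.approx(a / math.sqrt((1 + a**2) * (1 + b**2)), abs=0.05)


def test_ggm_diagonal_covariance_gives_zero_partials(rng):
    X = rng.normal(size=(4, 20000))
    am = M.ggm_matrix(X)
    off = am.scores[~np.isnan(am.scores)]
    assert np.all(np.abs(off) < 0.05)


# ---------------------------------------------------------------------------
# brute-force agreement on random small matrices


def test_measures_agree_with_oracles_on_random_matrices(rng):
    X = rng.normal(size=(6, 10))
    P = M.pearson_matrix(X).scores
    S = M.spearman_matrix(X).scores
    K = M.kendall_matrix(X).scores
    L = np.vstack([M.discretize_1d_kmeans(row, 3) for row in X])
    MI = M.mutual_information_matrix(X, levels=3).scores
    F = M.funchisq_matrix(X, levels=3).scores
    for i, j in itertools.combinations(range(6), 2):
        assert P[i, j] == pytest.approx(pearson_oracle(X[i], X[j]), abs=1e-10)
        assert S[i, j] == pytest.approx(spearman_oracle(X[i], X[j]), abs=1e-10)
        assert K[i, j] == pytest.approx(kendall_oracle(X[i], X[j]), abs=1e-10)
        assert MI[i, j] == pytest.approx(mi_oracle(list(L[i]), list(L[j])), abs=1e-10)
        table = np.zeros((3, 3))
        np.add.at(table, (L[i], L[j]), 1)
        chi2 = funchisq_oracle(table)
        df = 4
        assert F[i, j] == pytest.approx((chi2 - df) / math.sqrt(2 * df), abs=1e-10)


def test_ggm_matches_direct_inversion_when_n_large(rng):
    # with samples >> variables the shrinkage intensity is tiny and the
    # partial correlations approach the plain inverse-correlation estimate
    X = rng.normal(size=(4, 5000))
    X[1] += 0.5 * X[0]
    X[2] += 0.3 * X[1]
    shrunk = M.ggm_matrix(X, shrink=True).scores
    direct = M.ggm_matrix(X, shrink=False).scores
    mask = ~np.isnan(shrunk)
    assert np.allclose(shrunk[mask], direct[mask], atol=1e-2)


# ---------------------------------------------------------------------------
# discretization


@pytest.mark.parametrize(
    "v,k,expected_labels",
    [
        ([1, 1, 1, 10, 10, 10], 2, [0, 0, 0, 1, 1, 1]),
        ([0, 1, 2, 100], 2, [0, 0, 0, 1]),
        ([5, 5, 5], 1, [0, 0, 0]),
    ],
)
def test_kmeans_examples(v, k, expected_labels):
    assert list(M.discretize_1d_kmeans(np.array(v, float), k)) == expected_labels


def test_kmeans_reduces_k_when_few_distinct_values():
    labels = M.discretize_1d_kmeans(np.array([1.0, 1.0, 2.0, 2.0]), 4)
    assert set(labels) == {0, 1}


def test_kmeans_matches_enumeration_oracle(rng):
    for k in (2, 3, 4):
        v = rng.normal(size=12)
        labels = M.discretize_1d_kmeans(v, k)
        cost = sum(
            ((v[labels == c] - v[labels == c].mean()) ** 2).sum() for c in range(k)
        )
        best, _ = kmeans1d_oracle(v, k)
        assert cost == pytest.approx(best, abs=1e-9)


def test_kmeans_labels_ordered_by_cluster_mean(rng):
    v = rng.normal(size=30)
    labels = M.discretize_1d_kmeans(v, 4)
    means = [v[labels == c].mean() for c in range(labels.max() + 1)]
    assert means == sorted(means)


# ---------------------------------------------------------------------------
# invariants


@pytest.mark.parametrize("measure", M.MEASURES)
def test_bounds_and_permutation_invariance(measure, rng):
    X = rng.normal(size=(5, 12))
    am = M.score_matrix(X, measure)
    vals = am.scores[~np.isnan(am.scores)]
    if measure == "mi":
        assert np.all(vals >= 0)
    elif measure != "funchisq":
        assert np.all(np.abs(vals) <= 1 + 1e-12)
    perm = np.array([3, 0, 4, 1, 2])
    am_p = M.score_matrix(X[perm], measure)
    assert np.allclose(
        am_p.scores, am.scores[np.ix_(perm, perm)], equal_nan=True, atol=1e-12
    )


@pytest.mark.parametrize("measure", M.MEASURES)
def test_lagged_api_shapes_and_directedness(measure, rng):
    X = rng.normal(size=(5, 15))
    lead, trail = X[:, :-1], X[:, 1:]
    am = M.score_lagged(lead, trail, measure)
    assert am.directed
    assert am.scores.shape == (5, 5)
    assert np.isnan(np.diag(am.scores)).all()


def test_symmetric_measures_are_symmetric(rng):
    X = rng.normal(size=(6, 9))
    for measure in ("pearson", "spearman", "kendall", "mi", "ggm"):
        S = M.score_matrix(X, measure).scores
        assert np.allclose(S, S.T, equal_nan=True)


def test_zero_variance_rows_are_na(rng):
    X = rng.normal(size=(3, 10))
    X[1] = 2.5
    am = M.pearson_matrix(X)
    assert np.isnan(am.scores[1, :]).all()
    assert np.isnan(am.scores[:, 1]).all()
    assert np.isfinite(am.scores[0, 2])


def test_too_few_samples_rejected():
    with pytest.raises(ValueError):
        M.pearson_matrix(np.zeros((3, 1)))
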
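"""Evaluation metrics against enumeration oracles and calibration checks."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from phosphonet import evaluate as ev
from phosphonet.gold_networks import LabelMatrix
from phosphonet.measures import AssociationMatrix

# ---------------------------------------------------------------------------
# oracles


def auroc_oracle(scores, labels):
    """Brute-force count over all TP x TN pairs; ties score 0.5."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def fisher_tail_oracle(a, b, c, d):
    """One-sided hypergeometric tail P(X >= a) for the 2x2 table [[a,b],[c,d]]."""
    n, K, N = a + b + c + d, a + b, a + c  # draws of size N from K successes
    return sum(
        math.comb(K, x) * math.comb(n - K, N - x) / math.comb(n, N)
        for x in range(a, min(K, N) + 1)
    )


# ---------------------------------------------------------------------------
# TP gate


@pytest.mark.parametrize("n_tp,passes", [(5, True), (4, False), (0, False)])
def test_tp_gate(n_tp, passes):
    labels = np.zeros(20)
    labels[:n_tp] = 1
    assert ev.tp_gate(labels, min_tp=5) is passes


# ---------------------------------------------------------------------------
# compute_metrics


def test_perfect_separation_metrics():
    scores = np.concatenate([np.full(2, 5.0), np.full(18, 1.0)])
    labels = np.concatenate([np.ones(2), np.zeros(18)])
    res = ev.compute_metrics(scores, labels)
    assert res.auroc == 1.0
    assert res.baseline == pytest.approx(0.1)
    assert res.log10_auprc_ratio == pytest.approx(1.0)  # AUPRC 1, baseline 0.1


def test_constant_scores_are_chance():
    scores = np.full(30, 0.7)
    labels = np.concatenate([np.ones(10), np.zeros(20)])
    res = ev.compute_metrics(scores, labels)
    assert res.auroc == pytest.approx(0.5)


def test_auroc_matches_pairwise_count_oracle(rng):
    for _ in range(5):
        scores = rng.choice(np.arange(10) / 10.0, size=60)  # many ties
        labels = rng.integers(0, 2, size=60).astype(float)
        if labels.sum() in (0, 60):
            continue
        assert ev.auroc(scores, labels) == pytest.approx(
            auroc_oracle(scores, labels), abs=1e-12
        )


def test_fisher_top2_of_10_example():
    # 10 pairs, 2 TPs; both land in the top-2 by score.  The one-sided
    # Fisher p equals 1 / C(10,2) = 1/45 by hypergeometric enumeration.
    scores = np.array([0.99, 0.95, 0.5, 0.45, 0.4, 0.35, 0.3, 0.25, 0.2, 0.15])
    labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    res = ev.compute_metrics(scores, labels)
    assert res.top20_fisher_p == pytest.approx(1 / 45)
    assert res.top20_fisher_p == pytest.approx(fisher_tail_oracle(2, 0, 0, 8))


def test_fisher_matches_hypergeometric_oracle(rng):
    for _ in range(5):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.3).astype(float)
        if labels.sum() < 1 or labels.sum() > 39:
            continue
        res = ev.compute_metrics(scores, labels)
        k = math.ceil(0.2 * 40)
        order = np.lexsort((np.arange(40), -np.abs(scores)))
        top = np.zeros(40, dtype=bool)
        top[order[:k]] = True
        a = int((labels[top] == 1).sum())
        b = int((labels[top] == 0).sum())
        c = int((labels[~top] == 1).sum())
        d = int((labels[~top] == 0).sum())
        assert res.top20_fisher_p == pytest.approx(
            fisher_tail_oracle(a, b, c, d), rel=1e-9
        )


def test_odds_ratio_zero_cell_correction():
    scores = np.array([0.9, 0.8, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
    labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    res = ev.compute_metrics(scores, labels)
    # top-2 = both TPs -> b = 0 and c = 0: Haldane-Anscombe reported OR
    assert res.top20_odds_ratio == pytest.approx((2.5 * 8.5) / (0.5 * 0.5))


def test_single_class_rejected():
    with pytest.raises(ValueError):
        ev.compute_metrics(np.ones(5), np.ones(5))


def test_absolute_ranking_treats_negative_scores_as_informative():
    scores = np.array([-0.95, 0.9, 0.05, -0.1, 0.2, 0.01])
    labels = np.array([1, 1, 0, 0, 0, 0], dtype=float)
    assert ev.compute_metrics(scores, labels).auroc == 1.0
    assert ev.compute_metrics(scores, labels, absolute=False).auroc < 1.0


def test_label_shuffle_calibration(rng):
    # over many shuffles the mean AUROC sits at chance
    scores = rng.normal(size=200)
    labels = np.concatenate([np.ones(40), np.zeros(160)])
    aucs = [ev.auroc(scores, rng.permutation(labels)) for _ in range(1000)]
    assert abs(np.mean(aucs) - 0.5) < 0.02


# ---------------------------------------------------------------------------
# permutation p-value


def test_permutation_p_arithmetic():
    # the p-value is the fraction of null AUCs strictly above the observed:
    # 123 exceedances out of 10,000 -> 0.0123
    assert 123 / 10_000 == pytest.approx(0.0123)
    rng = np.random.default_rng(0)
    scores = rng.normal(size=50)
    labels = (rng.random(50) < 0.3).astype(float)
    res = ev.permutation_pvalue(scores, labels, n_perm=400, seed=1)
    assert res.p_value == pytest.approx(
        (res.null_aucs > res.observed_auc).sum() / 400
    )
    assert res.null_aucs.shape == (400,)


def test_permutation_p_zero_for_maximal_auc():
    # observed AUROC 1 with distinct scores: no shuffle can strictly beat it
    scores = np.array([5.0, 4.0, 3.0, 0.2, 0.1, 0.05, 0.04, 0.03])
    labels = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
    res = ev.permutation_pvalue(scores, labels, n_perm=500, seed=3)
    assert res.observed_auc == 1.0
    assert res.p_value == 0.0


def test_permutation_deterministic_under_seed(rng):
    scores = rng.normal(size=40)
    labels = (rng.random(40) < 0.4).astype(float)
    r1 = ev.permutation_pvalue(scores, labels, n_perm=200, seed=9)
    r2 = ev.permutation_pvalue(scores, labels, n_perm=200, seed=9)
    assert np.array_equal(r1.null_aucs, r2.null_aucs)


def test_permutation_p_uniform_under_null(rng):
    # scores independent of labels: p-values approximately U[0,1]
    labels = np.concatenate([np.ones(15), np.zeros(45)])
    pvals = []
    for _ in range(300):
        scores = rng.normal(size=60)
        pvals.append(ev.permutation_pvalue(scores, labels, n_perm=200, seed=int(rng.integers(2**31))).p_value)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_permutation_requires_at_least_one():
    with pytest.raises(ValueError):
        ev.permutation_pvalue(np.ones(4), np.array([1.0, 0, 0, 1]), n_perm=0)


# ---------------------------------------------------------------------------
# kinase ranking


def rank_fixture(rng, informative=True):
    n_kin, n_sub = 10, 30
    S = rng.normal(size=(n_kin, n_sub))
    L = np.zeros((n_kin, n_sub))
    true_kin = rng.integers(0, n_kin, size=n_sub)
    for j, k in enumerate(true_kin):
        L[k, j] = 1.0
        if informative:
            S[k, j] = 5.0 + rng.normal()
    assoc = AssociationMatrix.__new__(AssociationMatrix)
    assoc.scores = S
    assoc.directed = True
    assoc.measure_name = "pearson"
    assoc.variable_labels = None
    labels = LabelMatrix(
        labels=L,
        row_ids=[f"K{i}" for i in range(n_kin)],
        col_ids=[f"S{j}" for j in range(n_sub)],
        mode="KS_direct",
    )
    return assoc, labels


def test_true_kinase_ranked_first_when_dominant(rng):
    assoc, labels = rank_fixture(rng, informative=True)
    ranks, p = ev.kinase_rank_test(assoc, labels, n_random=50, seed=0)
    assert np.all(ranks == 0.0)  # normalised rank 0 = top
    assert p < 1e-6


def test_randomised_scores_rank_uniform(rng):
    assoc, labels = rank_fixture(rng, informative=False)
    ranks, p = ev.kinase_rank_test(assoc, labels, n_random=100, seed=1)
    assert abs(ranks.mean() - 0.5) < 0.15
    assert p > 1e-3  # no decisive prioritisation signal


def test_discretized_measures_rejected(rng):
    assoc, labels = rank_fixture(rng)
    assoc.measure_name = "mi"
    with pytest.raises(ValueError, match="continuous"):
        ev.kinase_rank_test(assoc, labels)
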
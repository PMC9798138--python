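"""Evaluation of association scores against gold-standard labels.

Scored candidate pairs are ranked (by absolute score by default, since a
strong negative correlation is as informative an association as a strong
positive one) and compared with {1, 0} labels using three metrics:

* AUROC via the rank-sum (Mann-Whitney) identity with midranks for ties;
* the area under the precision-recall curve, reported as
  log10(AUPRC / baseline) where baseline is the positive prevalence, so 0
  is chance;
* enrichment of true positives in the top 20% of predictions, as a
  one-sided Fisher's exact test with the odds ratio of the 2x2
  (top vs rest) x (TP vs TN) table.

Datasets contribute to evaluation only when they carry at least
``min_tp`` (default 5) true positives.  Significance of an observed AUROC
is assessed with a permutation null: the score column of the candidate
edge list is shuffled without replacement n times (default 10,000) and
p = #(null AUC > observed) / n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score

from .gold_networks import LabelMatrix
from .measures import AssociationMatrix

__all__ = [
    "EvalResult",
    "PermutationResult",
    "auroc",
    "flatten_pairs",
    "tp_gate",
    "compute_metrics",
    "permutation_pvalue",
    "kinase_rank_test",
]


@dataclass
class EvalResult:
    auroc: float
    auprc: float
    baseline: float
    log10_auprc_ratio: float
    top20_odds_ratio: float
    top20_fisher_p: float
    n_tp: int
    n_tn: int
    permutation_p: float | None = None


@dataclass
class PermutationResult:
    observed_auc: float
    null_aucs: np.ndarray
    p_value: float


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC by the rank-sum identity; ties receive midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both positive and negative labels")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _ranking_scores(scores: np.ndarray, absolute: bool) -> np.ndarray:
    return np.abs(scores) if absolute else scores


def flatten_pairs(
    assoc: AssociationMatrix, labels: LabelMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (scores, labels) vectors over evaluable candidate pairs.

    Pairs with NA labels or NaN scores are dropped.  For an undirected
    association matrix with symmetric labels only the upper triangle is
    used; otherwise every ordered pair enters once.
    """
    S = assoc.scores
    L = labels.labels
    if S.shape != L.shape:
        raise ValueError(f"score shape {S.shape} != label shape {L.shape}")
    if not assoc.directed and labels.symmetric:
        mask = np.triu(np.ones_like(L, dtype=bool), k=1)
    else:
        mask = ~np.eye(L.shape[0], dtype=bool) if L.shape[0] == L.shape[1] else np.ones_like(L, dtype=bool)
    ok = mask & ~np.isnan(L) & ~np.isnan(S)
    return S[ok], L[ok]


def tp_gate(labels: LabelMatrix | np.ndarray, min_tp: int = 5) -> bool:
    """True iff the label set holds at least ``min_tp`` positives."""
    L = labels.labels if isinstance(labels, LabelMatrix) else np.asarray(labels, dtype=float)
    return int(np.nansum(L == 1)) >= min_tp


def _top20_table(scores: np.ndarray, labels: np.ndarray, fraction: float) -> np.ndarray:
    n = scores.size
    k = max(1, int(np.ceil(fraction * n)))
    # deterministic split: stable sort by (score desc, index asc)
    order = np.lexsort((np.arange(n), -scores))
    top = np.zeros(n, dtype=bool)
    top[order[:k]] = True
    tp_top = int((labels[top] == 1).sum())
    tn_top = int((labels[top] == 0).sum())
    tp_rest = int((labels[~top] == 1).sum())
    tn_rest = int((labels[~top] == 0).sum())
    return np.array([[tp_top, tn_top], [tp_rest, tn_rest]])


def compute_metrics(
    scores: np.ndarray | AssociationMatrix,
    labels: np.ndarray | LabelMatrix,
    *,
    absolute: bool = True,
    top_fraction: float = 0.2,
) -> EvalResult:
    """All three evaluation metrics for one scored candidate set.

    Accepts either aligned 1-D (scores, labels) vectors or an
    (AssociationMatrix, LabelMatrix) pair, which is flattened with
    :func:`flatten_pairs` first.
    """
    if isinstance(scores, AssociationMatrix):
        scores, labels = flatten_pairs(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    n_tp = int((labels == 1).sum())
    n_tn = int((labels == 0).sum())
    if n_tp == 0 or n_tn == 0:
        raise ValueError("need both classes to evaluate")

    r = _ranking_scores(scores, absolute)
    auc = auroc(r, labels)
    auprc = float(average_precision_score(labels, r))
    baseline = n_tp / (n_tp + n_tn)
    log10_ratio = float(np.log10(auprc / baseline))

    table = _top20_table(r, labels, top_fraction)
    _, fisher_p = stats.fisher_exact(table, alternative="greater")
    # Haldane-Anscombe correction for a reportable odds ratio with zero cells
    a, b = table[0]
    c, d = table[1]
    if 0 in (a, b, c, d):
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)

    return EvalResult(
        auroc=auc,
        auprc=auprc,
        baseline=baseline,
        log10_auprc_ratio=log10_ratio,
        top20_odds_ratio=float(odds),
        top20_fisher_p=float(fisher_p),
        n_tp=n_tp,
        n_tn=n_tn,
    )


def permutation_pvalue(
    scores: np.ndarray | AssociationMatrix,
    labels: np.ndarray | LabelMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
    *,
    absolute: bool = True,
) -> PermutationResult:
    """Permutation null for the observed AUROC.

    The score column of the candidate edge list is sampled without
    replacement ``n_perm`` times; each shuffle yields a null AUROC and
    p = #(null > observed) / n_perm (strict inequality).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(scores, AssociationMatrix):
        scores, labels = flatten_pairs(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    r = _ranking_scores(scores, absolute)
    observed = auroc(r, labels)

    # Shuffling scores against fixed labels is equivalent to drawing the
    # positives' rank sum from the fixed midrank vector without replacement.
    ranks = stats.rankdata(r)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = ranks.size - n1
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    chunk = max(1, int(2e6 // max(ranks.size, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(ranks, (m, ranks.size)), axis=1)
        null[done : done + m] = (perm[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
        done += m
    p = float((null > observed).sum() / n_perm)
    return PermutationResult(observed_auc=observed, null_aucs=null, p_value=p)


def kinase_rank_test(
    assoc: AssociationMatrix,
    labels: LabelMatrix,
    n_random: int = 100,
    seed: int | None = None,
    *,
    absolute: bool = True,
) -> tuple[np.ndarray, float]:
    """Rank of each substrate's true kinase versus score-randomised ranks.

    For every substrate (column) with at least one known kinase and at
    least two candidate kinases, the best true kinase's rank among all
    candidate kinases (1 = highest score) is normalised to [0, 1]
    ((rank-1)/(m-1)).  The observed normalised ranks are compared with
    ranks from ``n_random`` score-shuffled replicates using a one-sided
    Wilcoxon rank-sum test (observed ranks smaller = true kinase
    prioritised).  Only continuous-scored measures (Pearson, GGM) are
    accepted: rank-based and discretized measures produce heavily tied
    scores whose ranks are not meaningful here.

    Returns (observed normalised ranks, rank-sum p-value).
    """
    if assoc.measure_name not in ("pearson", "ggm"):
        raise ValueError(
            f"kinase ranking requires a continuous measure (pearson or ggm), "
            f"got {assoc.measure_name!r}"
        )
    S = _ranking_scores(assoc.scores, absolute)
    L = labels.labels
    if S.shape != L.shape:
        raise ValueError("score/label shape mismatch")
    rng = np.random.default_rng(seed)

    def column_ranks(scores_matrix: np.ndarray) -> list[float]:
        out = []
        for j in range(L.shape[1]):
            cand = ~np.isnan(L[:, j]) & ~np.isnan(scores_matrix[:, j])
            m = int(cand.sum())
            if m < 2 or not (L[cand, j] == 1).any():
                continue
            col = scores_matrix[cand, j]
            ranks = stats.rankdata(-col)  # 1 = best
            best_true = ranks[L[cand, j] == 1].min()
            out.append((best_true - 1.0) / (m - 1.0))
        return out

    observed = np.array(column_ranks(S))
    if observed.size == 0:
        raise ValueError("no substrate with a known kinase and >=2 candidates")
    null: list[float] = []
    for _ in range(n_random):
        null.extend(column_ranks(rng.permuted(S, axis=0)))
    stat = stats.mannwhitneyu(observed, np.array(null), alternative="less")
    return observed, float(stat.pvalue)
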
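"""Phosphopeptide sequence-similarity filtering of association networks.

Kinases recognise substrate phosphosites through sequence motifs around
the modified residue, so substrates of the same kinase tend to share
sequence context.  This module scores the similarity of 15-residue
peptide windows centred on phosphosites by Smith-Waterman local alignment
with the BLOSUM62 substitution matrix (gap open 10, extend 4), normalised
to [0, 1] as

    sim(a, b) = score(a, b) / sqrt(score(a, a) * score(b, b)).

A dataset-specific threshold is derived by sampling pairs of interactome
substrates that share a kinase (true positives) and random non-shared
pairs (true negatives), after removing the dataset's own phosphosites
from the pool; the threshold is the median TP similarity.  Candidate
pairs whose windows align below the threshold have their association
score forced to 0 and are treated as predicted negatives.  The
filter-only predictor uses the thresholded similarity itself as a binary
score, with no association measure at all.

Windows near protein termini are padded with 'X', which scores 0 against
every residue.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .gold_networks import KSRecord, PhosphoSite
from .measures import AssociationMatrix

__all__ = [
    "PeptideWindow",
    "SimilarityThreshold",
    "extract_window",
    "peptide_similarity",
    "similarity_matrix",
    "compute_threshold",
    "apply_similarity_filter",
    "filter_only_predictor",
]

logger = logging.getLogger(__name__)

PAD = "X"
WINDOW = 15
_FLANK = WINDOW // 2


@dataclass(frozen=True)
class PeptideWindow:
    """A 15-mer around a phosphosite (modified residue at centre)."""

    site: PhosphoSite
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW:
            raise ValueError(f"window must be {WINDOW} residues")
        if self.sequence[_FLANK] not in "STY":
            raise ValueError("window centre must be S, T or Y")


@dataclass
class SimilarityThreshold:
    dataset_id: str
    threshold: float
    n_tp_sampled: int
    n_tn_sampled: int
    seed: int | None
    tn_median: float | None = None


def extract_window(protein_sequence: str, site: PhosphoSite) -> PeptideWindow:
    """15-mer at positions [pos-7, pos+7], 'X'-padded at the termini."""
    seq = protein_sequence.upper()
    pos = site.position  # 1-based
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside protein of length {len(seq)}")
    if seq[pos - 1] != site.residue:
        raise ValueError(
            f"sequence has {seq[pos - 1]} at position {pos}, site claims {site.residue}"
        )
    lo, hi = pos - 1 - _FLANK, pos + _FLANK
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    window = PAD * left_pad + seq[max(lo, 0) : min(hi, len(seq))] + PAD * right_pad
    return PeptideWindow(site=site, sequence=window)


def _aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load("BLOSUM62")
    arr = np.array(matrix)
    xi = matrix.alphabet.index(PAD)
    arr[xi, :] = 0.0  # pad character is neutral against everything
    arr[:, xi] = 0.0
    neutral = substitution_matrices.Array(alphabet=matrix.alphabet, data=arr)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = neutral
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


class _SimilarityScorer:
    """Caches the aligner and self-alignment scores."""

    def __init__(self, gap_open: float = 10.0, gap_extend: float = 4.0) -> None:
        self.aligner = _aligner(gap_open, gap_extend)
        self._self_scores: dict[str, float] = {}

    def self_score(self, seq: str) -> float:
        s = self._self_scores.get(seq)
        if s is None:
            s = float(self.aligner.score(seq, seq))
            self._self_scores[seq] = s
        return s

    def similarity(self, a: str, b: str) -> float:
        if not a or not b:
            raise ValueError("empty sequence")
        sa, sb = self.self_score(a), self.self_score(b)
        if sa <= 0 or sb <= 0:
            return 0.0
        raw = float(self.aligner.score(a, b))
        return max(raw, 0.0) / np.sqrt(sa * sb)


_DEFAULT_SCORER: _SimilarityScorer | None = None


def _default_scorer() -> _SimilarityScorer:
    global _DEFAULT_SCORER
    if _DEFAULT_SCORER is None:
        _DEFAULT_SCORER = _SimilarityScorer()
    return _DEFAULT_SCORER


def peptide_similarity(
    a: PeptideWindow | str,
    b: PeptideWindow | str,
    scorer: _SimilarityScorer | None = None,
) -> float:
    """Normalised Smith-Waterman/BLOSUM62 similarity of two windows, in [0, 1]."""
    scorer = scorer or _default_scorer()
    sa = a.sequence if isinstance(a, PeptideWindow) else a
    sb = b.sequence if isinstance(b, PeptideWindow) else b
    return scorer.similarity(sa, sb)


def similarity_matrix(
    windows: dict[str, PeptideWindow | str], ids: list[str]
) -> np.ndarray:
    """Pairwise similarity over ``ids``; NaN where a window is missing."""
    scorer = _default_scorer()
    n = len(ids)
    S = np.full((n, n), np.nan)
    seqs = []
    for sid in ids:
        w = windows.get(sid)
        seqs.append(w.sequence if isinstance(w, PeptideWindow) else w)
    for i in range(n):
        if seqs[i] is None:
            continue
        S[i, i] = 1.0
        for j in range(i + 1, n):
            if seqs[j] is None:
                continue
            S[i, j] = S[j, i] = scorer.similarity(seqs[i], seqs[j])
    return S


def _pair_from_index(counts: list[int], offsets: np.ndarray, flat: int) -> tuple[int, int, int]:
    """Map a flat index over sum_k C(m_k, 2) to (kinase index, a, b)."""
    k = int(np.searchsorted(offsets, flat, side="right") - 1)
    r = flat - offsets[k]
    # unrank pair r within combinations(m, 2) in lexicographic order
    m = counts[k]
    a = 0
    block = m - 1
    while r >= block:
        r -= block
        a += 1
        block -= 1
    return k, a, a + 1 + int(r)


def compute_threshold(
    records: list[KSRecord],
    dataset_sites: list[PhosphoSite],
    windows: dict[str, str | PeptideWindow],
    n_sample: int = 100_000,
    seed: int | None = None,
    dataset_id: str = "dataset",
) -> SimilarityThreshold:
    """Dataset-specific similarity threshold: the TP-median of sampled pairs.

    The dataset's own phosphosites are removed from the interactome
    substrate pool first, so the threshold is independent of the sites
    being filtered.  Up to ``n_sample`` true-positive (shared-kinase)
    pairs are drawn uniformly without replacement from the enumerable pair
    space (all pairs are used when fewer exist), and as many true-negative
    pairs are sampled at random from non-shared-kinase combinations.
    """
    rng = np.random.default_rng(seed)
    scorer = _default_scorer()
    dataset_keys = {s.key for s in dataset_sites}

    def seq_of(site: PhosphoSite) -> str | None:
        w = windows.get(str(site))
        if w is None and site.peptide_window is not None:
            return site.peptide_window
        return w.sequence if isinstance(w, PeptideWindow) else w

    by_kinase: dict[str, list[PhosphoSite]] = {}
    kinases_of: dict[tuple, set[str]] = {}
    pool: dict[tuple, PhosphoSite] = {}
    for r in records:
        s = r.substrate_site
        if s.key in dataset_keys or seq_of(s) is None:
            continue
        bucket = by_kinase.setdefault(r.kinase_accession, [])
        if s.key not in {x.key for x in bucket}:
            bucket.append(s)
        kinases_of.setdefault(s.key, set()).add(r.kinase_accession)
        pool[s.key] = s

    counts = [len(v) for v in by_kinase.values()]
    kin_list = list(by_kinase.values())
    pair_counts = [m * (m - 1) // 2 for m in counts]
    total_tp = int(sum(pair_counts))
    if total_tp < 2:
        raise ValueError("fewer than 2 enumerable true-positive pairs")

    if total_tp <= n_sample:
        tp_pairs = [
            (a, b)
            for bucket in kin_list
            for a, b in itertools.combinations(bucket, 2)
        ]
    else:
        offsets = np.concatenate([[0], np.cumsum(pair_counts)])
        flat = rng.choice(total_tp, size=n_sample, replace=False)
        tp_pairs = []
        for f in flat:
            k, a, b = _pair_from_index(counts, offsets, int(f))
            tp_pairs.append((kin_list[k][a], kin_list[k][b]))

    tp_sims = np.array(
        [scorer.similarity(seq_of(a), seq_of(b)) for a, b in tp_pairs]
    )

    pool_sites = list(pool.values())
    n_tn_target = min(n_sample, len(tp_pairs))
    tn_sims: list[float] = []
    if len(pool_sites) >= 2:
        attempts = 0
        while len(tn_sims) < n_tn_target and attempts < 20 * n_tn_target:
            attempts += 1
            i, j = rng.choice(len(pool_sites), size=2, replace=False)
            a, b = pool_sites[i], pool_sites[j]
            if kinases_of.get(a.key, set()) & kinases_of.get(b.key, set()):
                continue
            tn_sims.append(scorer.similarity(seq_of(a), seq_of(b)))

    return SimilarityThreshold(
        dataset_id=dataset_id,
        threshold=float(np.median(tp_sims)),
        n_tp_sampled=len(tp_sims),
        n_tn_sampled=len(tn_sims),
        seed=seed,
        tn_median=float(np.median(tn_sims)) if tn_sims else None,
    )


def apply_similarity_filter(
    assoc: AssociationMatrix,
    windows: dict[str, PeptideWindow | str],
    thr: SimilarityThreshold,
    similarity: np.ndarray | None = None,
) -> AssociationMatrix:
    """Zero out associations between dissimilar peptide pairs.

    Pairs with similarity strictly below the threshold get score 0 and are
    thereby evaluated as predicted negatives; others are unchanged.  Pairs
    missing a window become NA with a warning.  Pass a precomputed
    ``similarity`` matrix (from :func:`similarity_matrix`) to avoid
    realigning when filtering several measures over the same sites.
    """
    ids = assoc.variable_labels
    if ids is None:
        raise ValueError("association matrix lacks variable labels")
    S = similarity if similarity is not None else similarity_matrix(windows, ids)
    if S.shape != assoc.scores.shape:
        raise ValueError("similarity matrix shape mismatch")
    scores = assoc.scores.copy()
    missing = np.isnan(S) & ~np.isnan(scores)
    np.fill_diagonal(missing, False)
    if missing.any():
        logger.warning(
            "similarity filter: %d scored pairs lack a peptide window; set to NA",
            int(missing.sum()),
        )
        scores[missing] = np.nan
    below = S < thr.threshold
    scores[below & ~np.isnan(scores)] = 0.0
    return AssociationMatrix(
        scores, assoc.directed, assoc.measure_name + "+seqfilter", ids
    )


def filter_only_predictor(
    windows: dict[str, PeptideWindow | str],
    thr: SimilarityThreshold,
    ids: list[str],
    similarity: np.ndarray | None = None,
) -> AssociationMatrix:
    """Binary predictor from the similarity filter alone: 1 iff the pair's
    window similarity reaches the threshold, with no association measure."""
    S = similarity if similarity is not None else similarity_matrix(windows, ids)
    scores = np.where(S >= thr.threshold, 1.0, 0.0)
    scores[np.isnan(S)] = np.nan
    np.fill_diagonal(scores, np.nan)
    return AssociationMatrix(scores, False, "seqfilter_only", list(ids))
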
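# Methods

This note documents the models, numerical choices and known limitations
behind the benchmark, in the order the pipeline uses them.

## Network simulation (simnet)

Synthetic time-series are drawn from a first-order linear-Gaussian
autoregression on a fixed directed network (default: the 11-node,
19-edge Raf pathway consensus, bundled as `data/raf_edges.tsv`):

    X_i(t) = Σ_{k ∈ parents(i)} ω_ik X_k(t−1) + ε_i(t),  ε_i ~ N(0, σ²)

with |ω_ik| ~ U[0.5, 2] and independent random sign, σ = 1 by default.
Two readings of this generative family are implemented, because they
behave very differently under the sampling manipulations the benchmark
studies:

* **lagged (default)** — the sum runs over the parents only, so on a DAG
  the transition matrix is nilpotent and the process is stationary at
  full weight strength with no rescaling. All cross-variable dependence
  is carried by short lags (at most the network depth). Optional
  autoregressive self-weights ω_ii can be switched on
  (`include_self_weights=True`); the full weight matrix is then rescaled
  to spectral radius 0.95 (configurable) to preserve stationarity. A
  burn-in of 50 steps precedes recording. σ only sets the overall scale
  in the default model (every node is a linear mix of innovations), so
  correlations are σ-invariant.
* **instantaneous** — each timepoint is an independent draw obtained by
  propagating innovations through the DAG in topological order within a
  single timepoint (a Gaussian structural-equation model). Here the
  same-time joint distribution is Markov with respect to the graph, so
  partial correlations align with direct edges and the sample count is
  the only thing subsampling changes.

The two modes bound the plausible readings of the generating process,
and the benchmark's findings split cleanly across them: the sample-size
dependence of recovery (AUROC rising with series length, with the GGM
clearly ahead once conditioning pays off) appears in instantaneous mode,
while the degradation under intermittent sampling and the failure of
time-lagged scoring appear in lagged mode, where skipping timepoints
skips the lag-1 dependencies themselves. No stationary autoregression
can show both at once: with strong autocorrelation the same-time
covariance — and hence 1:1 recovery — is invariant to the sampling
interval, and with short-lag dependence the conditional-independence
structure that privileges the GGM is absent from the same-time law.
The residual margin above AUROC 0.5 at large sampling intervals comes
from same-time covariance between nodes that share an upstream regulator
at equal path length; it cannot be removed by subsampling.

Evaluation in the sweeps is over all ordered node pairs (diagonal
excluded) against the directed edge set; symmetric measures fill both
orientations with the same score, which caps their directed AUROC below
1 (ties on the two orientations of each true edge).

## Association measures

* **Pearson / Spearman / Kendall** follow the standard formulas;
  Spearman is Pearson on midranks, Kendall uses the tau-b tie
  correction (real phosphodata contains ties). Zero-variance variables
  score NA against everything.
* **Discretization** for MI and FunChiSq is globally optimal 1-D k-means:
  dynamic programming over the sorted values (optimal clusters are
  contiguous in sorted order) minimising within-cluster sum of squares
  exactly, labels ordered by cluster mean. The level count defaults to
  r = min(⌈√n⌉, 5), shared by both measures; k is reduced when fewer
  distinct values exist.
* **Mutual information** is the plug-in estimator on the discretized
  joint, natural log. It is biased upward for small n — a property the
  benchmark deliberately exposes rather than corrects, since the
  measures are compared as commonly used.
* **FunChiSq** builds the r×s contingency table of each ordered pair and
  computes the functional chi-squared statistic (row-conditional
  deviation from uniformity minus the column-marginal deviation),
  normalised as (χ²_f − df)/√(2·df) with df = (r−1)(s−1) for ranking.
  It is the only non-symmetric 1:1 measure. With equal level counts on
  both axes the statistic prefers the functional (many-to-one)
  direction; with unequal level counts the df-normalisation does not
  fully remove the scale asymmetry between directions, so the pipeline
  always discretizes both variables to the same r.
* **GGM** shrinks the sample correlation matrix toward the identity with
  the analytic Schäfer–Strimmer intensity
  λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij² (clipped to [0, 1]) and reports
  partial correlations ρ_ik = −P_ik/√(P_ii P_kk) from the inverse P of
  the shrunk matrix. The conventional minus sign is used; ranking is by
  absolute value, which makes the sign choice inert. `shrink=False`
  inverts the raw correlation matrix (valid only for n ≫ p, used as the
  oracle cross-check in tests).
* **Time-lagged mode**: every measure accepts the aligned
  (leading, trailing) matrices over t = 1..n−1 and t = 2..n and fills a
  directed matrix; entry (i, j) is the i → j candidate. The lagged GGM
  stacks the leading and trailing copies into a 2p-variable matrix,
  applies the same shrinkage partial-correlation estimator, and reads
  the leading-to-trailing block.

Ranking for evaluation uses |score| by default: a strong negative
correlation is as informative an association as a strong positive one.
This is configurable (`absolute=False`) for signed ranking.

## Gold standards

Interactome tables (kinase, substrate, residue, position) are validated
per row (residue ∈ {S,T,Y}, position ≥ 1), deduplicated, and isoform
suffixes are stripped so site identity is accession + residue +
position. ML prediction tables join above a strict probability cutoff
(> 0.5), with database precedence on duplicates; augmentation can only
add positives.

KS labels: rows are measured phosphosites on annotated kinase proteins
(one row per specificity class; dual-specificity kinases contribute a
row per class), columns are all measured sites. 1 = recorded relation,
0 = residue class matches the kinase's specificity but no record,
NA = class mismatch, self pair, or unannotated kinase. SS labels: a
symmetric matrix over S/T sites, 1 iff two sites share a recorded
kinase, diagonal NA. The S/T restriction follows the observation that
only S/T kinases show the sequence-specificity shift the filter relies
on; it can be overridden.

## Sequence-similarity filter

15-mer windows centred on the phosphosite (positions pos−7..pos+7,
termini padded with 'X', which scores 0 against every residue) are
compared by Smith–Waterman local alignment with BLOSUM62, gap open 10 /
extend 4 (the cited implementation's defaults; configurable), and
normalised as score(a,b)/√(score(a,a)·score(b,b)) ∈ [0, 1].

The dataset-specific threshold is the median similarity of up to
100,000 true-positive (shared-kinase) pairs sampled uniformly without
replacement from the interactome after removing the dataset's own
phosphosites; true-negative pairs are sampled for reporting the
distribution shift. Candidate pairs below the threshold have their
association score set to 0 and are evaluated as predicted negatives;
the filter-only predictor scores 1/0 by the same threshold with no
abundance data at all. Because the threshold is the TP median, the
filter deliberately sacrifices ~half of the true positives to remove a
larger share of negatives — it helps exactly when the unfiltered
association signal is weak (the regime real panels are in), and can
hurt when associations are already clean.

## Evaluation

Metrics are computed over candidate pairs with non-NA labels and non-NaN
scores (upper triangle only when both the measure and the label space
are symmetric). AUROC uses the rank-sum identity with midranks; AUPRC is
the step-integrated precision–recall area (`average_precision_score`),
reported as log₁₀(AUPRC/baseline) with baseline = positive prevalence;
the top-20 % split is deterministic (stable sort by |score| descending,
then index) and feeds a one-sided Fisher exact test, with a
Haldane–Anscombe +0.5 correction applied to the reported odds ratio only
(never to the p-value). Datasets enter evaluation only with ≥ 5 true
positives. The permutation null shuffles the score column over the
labeled edge list (equivalently: redraws the positives' ranks without
replacement), 10,000 times by default, with p = #(null AUC > observed)/n
under strict inequality. The kinase-prioritisation test ranks each
substrate's best known kinase among all candidate kinases (normalised
(rank−1)/(m−1)) and compares against score-shuffled replicates by a
one-sided Wilcoxon rank-sum test; it accepts only continuous-scored
measures (Pearson, GGM) — rank-based and discretized measures produce
heavily tied scores whose per-column ranks are not meaningful.

## Synthetic phosphoproteome worlds

A world has 8 kinases × 10 substrates plus 24 background substrates by
default. Kinase motifs are position-weight profiles over the 15-mer
(per flanking position, one preferred residue carries 0.35 excess
probability over a uniform background; the centre is fixed S/T at 70/30).
Substrate windows are drawn from the regulating kinase's motif,
background windows from uniform residue frequencies. This sharpness
yields a modest TP/TN similarity shift (medians ≈ 0.16 vs ≈ 0.13), of
the same scale as real S/T interactomes — detectable but far from
separable.

Signals are activity-driven: each kinase follows a random sum of 1–3
logistic ramps (standardized), its substrates follow g_s·a(t) with
signed gains |g_s| ~ U[0.5, 2], and each kinase contributes its own
phosphosite row tracking a(t), so KS candidate rows exist in the matrix.
Perturbation panels (48 conditions by default) inhibit a random ~30 %
kinase subset per condition; substrate log2FC is −g_s under inhibition,
and a per-site p-value table (two-sided z-test against the noise level)
accompanies the matrix. The default noise level (σ = 1.5) is calibrated
so unfiltered SS/KS recovery sits near AUROC 0.6, the regime reported
for real phosphoproteome panels; this is the regime in which the
similarity filter's benefit is testable.

What the worlds do **not** emulate: missing values, multi-kinase
regulation of one site, kinase cascades (kinase activities are mutually
independent), batch effects, and intensity-dependent noise. Passing
tests therefore demonstrate correctness of the pipeline's logic and the
direction of its qualitative findings, not performance on real data.

## Pipeline

`run_benchmark` evaluates every (dataset × measure × {direct, lagged} ×
{unfiltered, similarity-filtered} × {KS, SS}) combination plus the
measure-independent filter-only predictor, skips lagged mode for
condition-labeled (perturbation) panels, logs TP-gate failures with
reasons, and emits a manifest (seeds, thresholds, version) sufficient to
reproduce a run bit-for-bit. Similarity thresholds for synthetic
datasets use a disjoint world generated from a derived seed as the
leave-dataset-out interactome stand-in.

## Problem sizes

Replicate counts are chosen for single-CPU runs: sweeps in the test
suite use 200 replicate datasets per grid point (70 per interval for the
lagged sweep), the synthetic-recovery suite uses 50 worlds, and the
reproduction script uses 500 replicates for the interval-4 grand mean
and 100 per interval for the lagged mean. The original study used
10,000 replicate datasets; means are stable well before that (Monte
Carlo SE of a sweep mean at 200 replicates is ≈ 0.005 AUROC).
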
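# phosphonet

Benchmarking pairwise association measures for data-driven
kinase–substrate network inference from global phosphoproteomics data.

## The problem

Mass-spectrometry phosphoproteomics measures the abundance of tens of
thousands of phosphosites per sample, but the kinase responsible for most
sites is unknown. A tempting shortcut is to infer kinase–substrate (KS)
relationships directly from the data: if a kinase's phosphosite and a
substrate's phosphosite co-vary across timepoints or perturbations, maybe
the kinase regulates the substrate. This package implements a complete,
tested benchmark of that idea for the six pairwise association measures
that underpin most network-inference methods:

| measure | type | directed |
|---|---|---|
| Pearson correlation | linear, continuous | no |
| Spearman correlation | rank (Pearson on midranks) | no |
| Kendall tau-b | rank, pair concordance | no |
| Mutual information | plug-in estimate on discretized levels | no |
| Functional chi-squared (FunChiSq) | functional dependence on discretized levels | yes |
| Gaussian graphical model (GGM) | shrinkage partial correlation ρᵢₖ = −Pᵢₖ/√(PᵢᵢPₖₖ), P = C*⁻¹ | no |

where C* is the Schäfer–Strimmer shrinkage correlation matrix
C* = λI + (1−λ)C with the analytic optimal intensity λ*, so the GGM stays
well-conditioned when variables outnumber samples. MI and FunChiSq
discretize each variable by globally optimal 1-D k-means (dynamic
programming, r = min(⌈√n⌉, 5) levels).

The benchmark covers every stage of the published evaluation protocol:

* **simnet** — a linear-Gaussian VAR(1) simulator on the 11-node, 19-edge
  Raf signalling pathway, Xᵢ(t) = Σₖ∈parents ωᵢₖXₖ(t−1) + εᵢ(t) with
  |ωᵢₖ| ~ U[0.5, 2] and random sign, plus intermittent subsampling,
  time-lagged sample pairs (t = 1..n−1 vs t = 2..n) and AUROC sweeps;
* **measures** — the six scores in 1:1 and time-lagged (directed) form;
* **gold_networks** — interactome TSV parsing, ML-prediction augmentation
  (probability > 0.5), and KS / substrate–substrate (SS) label matrices
  in {1, 0, NA} with the residue-class rules (S/T kinases pair with S/T
  sites, Y with Y, everything else NA);
* **preprocess** — TMT / ratio-to-control / phospho-over-proteome
  normalization and the regulated-site filters (|log₂FC| > 2, adjusted
  p < 0.05; perturbation rule: ≥20 % significant conditions and ≥2 large
  fold changes);
* **seqfilter** — 15-mer phosphopeptide windows, Smith–Waterman/BLOSUM62
  similarity normalised by the geometric mean of self-scores,
  dataset-specific TP-median thresholds, network filtering and the
  filter-only predictor;
* **evaluate** — AUROC (rank-sum with midranks), log₁₀(AUPRC/baseline),
  one-sided Fisher enrichment of true positives in the top 20 % of
  predictions, a 10,000-shuffle permutation null, the ≥5-TP gate and the
  kinase-prioritisation rank test;
* **synthetic_phospho** — synthetic phosphoproteome worlds (kinase motifs,
  substrate peptides, activity-driven time-series and perturbation
  panels, and a matching gold interactome) so the entire pipeline runs
  and is tested without any download;
* **pipeline** — orchestration of datasets × measures × modes × filters,
  with a skip log and a reproducibility manifest.

## Worked example

`examples/04_sequence_filter.py` demonstrates the package's central
finding on one synthetic world:

```
similarity(identical)    = 1.000
similarity(one mismatch) = 0.931
similarity(unrelated)    = 0.151

dataset threshold = 0.159 (TP median over 360 sampled shared-kinase pairs; TN median 0.130)

SS AUROC, Pearson unfiltered : 0.587
SS AUROC, Pearson + filter   : 0.621
SS AUROC, filter only        : 0.613
```

Shared-kinase substrate pairs are slightly more similar in sequence
(median 0.159) than random pairs (0.130), because kinases recognise
motifs. Zeroing the association score of dissimilar pairs — and counting
them as predicted negatives — lifts SS recovery from 0.587 to 0.621
AUROC, and the thresholded similarity *alone* (no abundance data at all)
already reaches 0.613. The other examples walk through the simulation
study, the measures, gold-label construction and the full benchmark
grid; each prints a short interpretation of its numbers.

A thin CLI wraps the same functions:

```bash
phosphonet-bench sweep --mode interval --reps 200 --seed 0 --out sweep.tsv
phosphonet-bench run --config cfg.yaml --out results/
phosphonet-bench synth-world --seed 1 --out world/
```

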
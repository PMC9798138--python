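"""Benchmark orchestration: datasets x measures x modes x filters.

``run_benchmark`` evaluates every requested association measure on every
dataset in a configuration, in direct (1:1) and - for time-series data -
time-lagged mode, against kinase-substrate (KS) and substrate-substrate
(SS) gold labels, optionally with the sequence-similarity filter and the
filter-only predictor in SS mode, and optionally against an ML-augmented
gold set.  Datasets (or candidate spaces) with fewer than ``min_tp`` true
positives are recorded in a skip log instead of the results table.

Configurations are plain dicts (or YAML files with the same structure):

```yaml
datasets:
  - id: world0            # synthetic world
    kind: synthetic_timeseries   # or synthetic_perturbation
    n_kinases: 8
    n_substrates_per_kinase: 10
    n_background: 24
    n_timepoints: 8       # or n_conditions for perturbation panels
measures: [pearson, ggm]
modes: [KS, SS]
lagged: true
similarity_filter: true
n_permutations: 0         # >0 adds a permutation p-value per row
threshold_sample: 2000    # TP/TN pairs sampled for the similarity threshold
seed: 0
min_tp: 5
```
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import measures as M
from . import evaluate as E
from . import seqfilter as SF
from .gold_networks import LabelMatrix, build_ks_labels, build_ss_labels
from .simnet import TimeSeriesDataset, make_lagged_pairs
from .synthetic_phospho import (
    SyntheticWorld,
    generate_perturbation,
    generate_timeseries,
    generate_world,
)

__all__ = ["run_benchmark", "align_scores"]


def align_scores(assoc: M.AssociationMatrix, labels: LabelMatrix) -> np.ndarray:
    """Extract the score submatrix aligned to a label matrix.

    Association matrices are indexed by site identifiers; label rows may
    carry a ``|class`` suffix (kinase rows) which is stripped for lookup.
    """
    if assoc.variable_labels is None:
        raise ValueError("association matrix lacks variable labels")
    pos = {v: i for i, v in enumerate(assoc.variable_labels)}
    rows = [pos[r.split("|")[0]] for r in labels.row_ids]
    cols = [pos[c] for c in labels.col_ids]
    return assoc.scores[np.ix_(rows, cols)]


def _ks_eval_arrays(
    assoc: M.AssociationMatrix, labels: LabelMatrix
) -> tuple[np.ndarray, np.ndarray]:
    S = align_scores(assoc, labels)
    ok = ~np.isnan(S) & ~np.isnan(labels.labels)
    return S[ok], labels.labels[ok]


def _make_dataset(spec: dict, seed: int) -> tuple[SyntheticWorld, TimeSeriesDataset, str]:
    kind = spec.get("kind", "synthetic_timeseries")
    world = generate_world(
        n_kinases=spec.get("n_kinases", 8),
        n_substrates_per_kinase=spec.get("n_substrates_per_kinase", 10),
        n_background=spec.get("n_background", 24),
        noise_sd=spec.get("noise_sd", 0.5),
        seed=seed,
    )
    if kind == "synthetic_timeseries":
        ds = generate_timeseries(world, spec.get("n_timepoints", 8), seed=seed + 1)
    elif kind == "synthetic_perturbation":
        ds, _ = generate_perturbation(world, spec.get("n_conditions", 48), seed=seed + 1)
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")
    return world, ds, kind


def _eval_row(scores: np.ndarray, labels: np.ndarray, n_perm: int, seed: int) -> dict:
    res = E.compute_metrics(scores, labels)
    row = asdict(res)
    if n_perm > 0:
        row["permutation_p"] = E.permutation_pvalue(
            scores, labels, n_perm=n_perm, seed=seed
        ).p_value
    return row


def run_benchmark(
    config: dict[str, Any] | str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full benchmark described by ``config``.

    Returns ``(results, skipped, manifest)``: a tidy results frame with
    one row per (dataset, mode, measure, filter) combination and the
    EvalResult fields, a skip log with reasons, and a reproducibility
    manifest (seeds, thresholds, package version).
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())

    measures = config.get("measures", list(M.MEASURES))
    for m in measures:
        if m not in M.MEASURES:
            raise ValueError(f"unknown measure {m!r}")
    modes = config.get("modes", ["KS", "SS"])
    for mode in modes:
        if mode not in ("KS", "SS"):
            raise ValueError(f"unknown mode {mode!r}")
    use_lagged = bool(config.get("lagged", False))
    use_filter = bool(config.get("similarity_filter", True))
    n_perm = int(config.get("n_permutations", 0))
    min_tp = int(config.get("min_tp", 5))
    thr_sample = int(config.get("threshold_sample", 2000))
    base_seed = int(config.get("seed", 0))

    results: list[dict] = []
    skipped: list[dict] = []
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": base_seed,
        "measures": measures,
        "modes": modes,
        "lagged": use_lagged,
        "similarity_filter": use_filter,
        "n_permutations": n_perm,
        "min_tp": min_tp,
        "thresholds": {},
    }

    for d_idx, spec in enumerate(config.get("datasets", [])):
        ds_id = str(spec.get("id", f"dataset{d_idx}"))
        ds_seed = base_seed + 1000 * d_idx
        world, ds, kind = _make_dataset(spec, ds_seed)
        records = world.records()
        sites = world.sites
        ids = [str(s) for s in sites]

        label_sets: dict[str, LabelMatrix] = {}
        if "KS" in modes:
            label_sets["KS"] = build_ks_labels(records, sites, world.kinase_classes())
        if "SS" in modes:
            label_sets["SS"] = build_ss_labels(records, sites)

        thr = None
        sim = None
        if use_filter and "SS" in modes:
            # threshold from a leave-dataset-out interactome: a disjoint
            # world generated from a derived seed stands in for the rest
            # of the interactome
            ref_world = generate_world(
                n_kinases=spec.get("n_kinases", 8),
                n_substrates_per_kinase=spec.get("n_substrates_per_kinase", 10),
                n_background=spec.get("n_background", 24),
                noise_sd=world.noise_sd,
                seed=ds_seed + 500,
            )
            thr = SF.compute_threshold(
                ref_world.records(),
                sites,
                ref_world.windows,
                n_sample=thr_sample,
                seed=ds_seed + 501,
                dataset_id=ds_id,
            )
            manifest["thresholds"][ds_id] = thr.threshold
            sim = SF.similarity_matrix(world.windows, ids)

        variants: list[tuple[str, str | None]] = [("direct", None)]
        if use_lagged and ds.sample_kind == "timepoint":
            variants.append(("lagged", None))

        for variant, _ in variants:
            if variant == "lagged":
                lead, trail = make_lagged_pairs(ds)
            for measure in measures:
                if variant == "lagged":
                    am = M.score_lagged(lead, trail, measure)
                else:
                    am = M.score_matrix(ds.values, measure)
                am.variable_labels = ids

                for mode, labels in label_sets.items():
                    if not E.tp_gate(labels, min_tp):
                        skipped.append(
                            {
                                "dataset": ds_id,
                                "mode": mode,
                                "measure": measure,
                                "variant": variant,
                                "reason": f"fewer than {min_tp} true positives",
                            }
                        )
                        continue
                    combos: list[tuple[str, M.AssociationMatrix]] = [("none", am)]
                    if mode == "SS" and thr is not None:
                        combos.append(
                            (
                                "similarity",
                                SF.apply_similarity_filter(am, world.windows, thr, sim),
                            )
                        )
                    for filt, fam in combos:
                        if mode == "KS":
                            s, y = _ks_eval_arrays(fam, labels)
                        else:
                            s, y = E.flatten_pairs(fam, labels)
                        if (y == 1).sum() < min_tp or (y == 0).sum() == 0:
                            skipped.append(
                                {
                                    "dataset": ds_id,
                                    "mode": mode,
                                    "measure": measure,
                                    "variant": variant,
                                    "reason": "too few evaluable pairs after filtering",
                                }
                            )
                            continue
                        row = {
                            "dataset": ds_id,
                            "kind": kind,
                            "mode": mode,
                            "variant": variant,
                            "measure": measure,
                            "filter": filt,
                        }
                        row.update(_eval_row(s, y, n_perm, ds_seed + 7))
                        results.append(row)

                # the filter-only predictor is measure-independent
            if thr is not None and "SS" in modes and E.tp_gate(label_sets["SS"], min_tp):
                fam = SF.filter_only_predictor(world.windows, thr, ids, sim)
                s, y = E.flatten_pairs(fam, label_sets["SS"])
                row = {
                    "dataset": ds_id,
                    "kind": kind,
                    "mode": "SS",
                    "variant": variant,
                    "measure": "seqfilter_only",
                    "filter": "similarity",
                }
                row.update(_eval_row(s, y, n_perm, ds_seed + 7))
                results.append(row)

    return pd.DataFrame(results), pd.DataFrame(skipped), manifest


def write_outputs(
    outdir: str | Path,
    results: pd.DataFrame,
    skipped: pd.DataFrame,
    manifest: dict,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    skipped.to_csv(out / "skipped.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
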
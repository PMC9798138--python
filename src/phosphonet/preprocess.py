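"""Normalization and regulated-phosphosite filtering of abundance matrices.

Matrices are pandas DataFrames with phosphosite identifiers as the index
and samples as columns.  Three normalization conventions are supported:

* ``tmt_median_mean`` - subtract column medians, then row means (log-scale
  TMT intensities; removes per-channel loading and per-site baseline);
* ``ratio_to_control`` - divide every column by a designated control
  column (SILAC-style ratios);
* ``phospho_over_proteome`` - divide each phosphosite row by its parent
  protein's abundance row, so late-timepoint signals reflect
  phosphorylation rather than protein-level change.

Regulation filters keep only actively changing sites before association
scoring: time-series matrices of log2 ratios to t=0 require at least one
timepoint with |log2FC| > 2 (strict) and, when adjusted p-values from an
upstream differential-expression fit are supplied, adjusted p < 0.05;
perturbation panels require >= 20% of conditions significant at p < 0.05
and >= 2 conditions with |log2FC| > 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "normalize_matrix",
    "average_replicates",
    "filter_timeseries",
    "filter_perturbation",
]

NORMALIZATION_MODES = ("tmt_median_mean", "ratio_to_control", "phospho_over_proteome")


@dataclass
class FilterReport:
    rule_name: str
    sites_in: int
    sites_kept: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sites_kept > self.sites_in:
            raise ValueError("sites_kept cannot exceed sites_in")

    def to_dict(self) -> dict:
        return {
            "rule_name": self.rule_name,
            "sites_in": self.sites_in,
            "sites_kept": self.sites_kept,
            "thresholds": self.thresholds,
        }


def normalize_matrix(
    X: pd.DataFrame,
    mode: str,
    control: str | None = None,
    proteome: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply one of the supported normalization conventions (see module doc)."""
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "tmt_median_mean":
        out = X - X.median(axis=0)
        return out.sub(out.mean(axis=1), axis=0)
    if mode == "ratio_to_control":
        if control is None or control not in X.columns:
            raise ValueError("ratio_to_control requires a control column present in X")
        ctrl = X[control]
        if (ctrl == 0).any():
            raise ValueError("control column contains zeros")
        return X.div(ctrl, axis=0)
    # phospho_over_proteome
    if proteome is None:
        raise ValueError("phospho_over_proteome requires a proteome matrix")
    missing = X.index.difference(proteome.index)
    if len(missing):
        raise ValueError(f"proteome rows missing for {len(missing)} phosphosites")
    prot = proteome.loc[X.index, X.columns]
    if (prot == 0).any().any():
        raise ValueError("proteome matrix contains zeros")
    return X / prot


def average_replicates(X: pd.DataFrame, replicate_of: dict[str, str]) -> pd.DataFrame:
    """Average replicate columns; ``replicate_of`` maps column -> sample id."""
    groups = X.columns.to_series().map(replicate_of)
    if groups.isna().any():
        raise ValueError("every column needs a sample assignment")
    return X.T.groupby(groups).mean().T


def filter_timeseries(
    X: pd.DataFrame,
    pvalues: pd.Series | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep regulated sites of a time-series log2-ratio matrix.

    A site passes when max_t |log2FC| strictly exceeds ``fc_threshold``
    and, if per-site adjusted p-values are given, adjusted p < ``p_threshold``.
    """
    keep = X.abs().max(axis=1) > fc_threshold
    thresholds = {"abs_log2fc_gt": fc_threshold}
    if pvalues is not None:
        pv = pvalues.reindex(X.index)
        if pv.isna().any():
            raise ValueError("p-values missing for some sites")
        keep &= pv < p_threshold
        thresholds["adj_p_lt"] = p_threshold
    report = FilterReport("timeseries_regulated", len(X), int(keep.sum()), thresholds)
    return X.loc[keep], report


def filter_perturbation(
    X: pd.DataFrame,
    pvalues: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    p_fraction: float = 0.2,
    min_fc_conditions: int = 2,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep regulated sites of a perturbation log2-ratio panel.

    A site passes when at least ``p_fraction`` (inclusive) of its
    conditions have p < 0.05 and at least ``min_fc_conditions`` conditions
    show |log2FC| > ``fc_threshold``.  The condition-count reading of the
    fold-change clause is used: the filter acts per site, so the "2 or
    more" requirement is interpreted over that site's conditions.
    """
    if pvalues.shape != X.shape:
        raise ValueError("p-value table must match the data matrix shape")
    pv = pvalues.reindex(index=X.index, columns=X.columns)
    frac_sig = (pv < p_threshold).sum(axis=1) / X.shape[1]
    n_fc = (X.abs() > fc_threshold).sum(axis=1)
    keep = (frac_sig >= p_fraction) & (n_fc >= min_fc_conditions)
    report = FilterReport(
        "perturbation_regulated",
        len(X),
        int(keep.sum()),
        {
            "p_lt": p_threshold,
            "min_p_fraction": p_fraction,
            "abs_log2fc_gt": fc_threshold,
            "min_fc_conditions": min_fc_conditions,
        },
    )
    return X.loc[keep], report
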
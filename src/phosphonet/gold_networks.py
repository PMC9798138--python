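"""Gold-standard label construction for kinase-substrate evaluation.

Known kinase-substrate relations are read from a phosphosite-resolved
interactome table (the export dialect of PhosphoSitePlus / Omnipath /
Phospho.ELM-style TSVs: columns ``kinase``, ``substrate``, ``residue``,
``position``).  Machine-learning prediction tables carrying probability
scores can augment the database records above a probability cutoff
(strictly greater than 0.5 by default).

Two label spaces are built over the phosphosites measured in a dataset:

* KS (kinase-substrate): rows are measured phosphosites on proteins
  annotated as kinases, columns are measured substrate phosphosites.  An
  entry is 1 when the interactome links the row kinase to the column
  site, 0 when the column site's residue matches the kinase's specificity
  class (S/T kinases pair with S/T sites, Y kinases with Y sites) but no
  record exists, and NA otherwise - residue-class mismatches and pairs of
  non-kinase proteins never enter evaluation.

* SS (substrate-substrate): a symmetric space over substrate sites of one
  residue class (S/T by default) where a pair is 1 when some kinase is
  known to regulate both sites and 0 otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhosphoSite",
    "KSRecord",
    "LabelMatrix",
    "read_interactome",
    "build_ks_labels",
    "build_ss_labels",
    "augment_with_ml",
]

logger = logging.getLogger(__name__)

_VALID_RESIDUES = frozenset("STY")


def _strip_isoform(accession: str) -> str:
    """Site identity uses the canonical accession: isoform suffixes dropped."""
    acc = str(accession).strip()
    base, sep, suffix = acc.partition("-")
    return base if sep and suffix.isdigit() else acc


@dataclass(frozen=True)
class PhosphoSite:
    """One phosphorylatable residue on a protein."""

    protein_accession: str
    residue: str
    position: int
    peptide_window: str | None = None

    def __post_init__(self) -> None:
        if self.residue not in _VALID_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.peptide_window is not None:
            if len(self.peptide_window) != 15:
                raise ValueError("peptide window must be 15 residues")
            if self.peptide_window[7] != self.residue:
                raise ValueError("window center must be the modified residue")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.protein_accession, self.residue, self.position)

    def __str__(self) -> str:
        return f"{self.protein_accession}_{self.residue}{self.position}"


@dataclass(frozen=True)
class KSRecord:
    """A kinase -> substrate-site relation."""

    kinase_accession: str
    substrate_site: PhosphoSite
    source: str = "database"
    probability: float | None = None

    def __post_init__(self) -> None:
        if self.source not in ("database", "ml_prediction"):
            raise ValueError(f"unknown source {self.source!r}")
        if (self.probability is not None) != (self.source == "ml_prediction"):
            raise ValueError("probability present iff source is ml_prediction")


@dataclass
class LabelMatrix:
    """Candidate-pair gold labels in {1, 0, NA} (NA encoded as NaN)."""

    labels: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    mode: str  # KS_direct, KS_lagged or SS
    residue_class: str = "ST"
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("label shape does not match identifier lists")

    @property
    def n_positive(self) -> int:
        return int(np.nansum(self.labels == 1))

    @property
    def n_negative(self) -> int:
        return int(np.nansum(self.labels == 0))


def _row_to_record(row: Mapping, source: str = "database") -> KSRecord | None:
    residue = str(row["residue"]).strip().upper()
    if residue not in _VALID_RESIDUES:
        return None
    try:
        position = int(row["position"])
    except (TypeError, ValueError):
        return None
    if position < 1:
        return None
    prob = None
    if source == "ml_prediction":
        try:
            prob = float(row["probability"])
        except (TypeError, ValueError, KeyError):
            return None
        if not 0.0 <= prob <= 1.0:
            return None
    site = PhosphoSite(_strip_isoform(row["substrate"]), residue, position)
    return KSRecord(_strip_isoform(row["kinase"]), site, source=source, probability=prob)


def read_interactome(path: str | Path | pd.DataFrame) -> list[KSRecord]:
    """Read and validate a kinase-substrate interactome TSV.

    Expected columns: ``kinase``, ``substrate``, ``residue``, ``position``.
    Malformed rows (bad residue letter or position) are rejected
    per-row with a logged count; duplicates collapse to a single record.
    """
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, sep="\t")
    missing = {"kinase", "substrate", "residue", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"interactome table lacks columns: {sorted(missing)}")
    records: dict[tuple, KSRecord] = {}
    n_rejected = 0
    for _, row in df.iterrows():
        rec = _row_to_record(row)
        if rec is None:
            n_rejected += 1
            continue
        records.setdefault((rec.kinase_accession, rec.substrate_site.key), rec)
    if n_rejected:
        logger.warning("read_interactome: rejected %d malformed rows", n_rejected)
    return list(records.values())


def augment_with_ml(
    records: Sequence[KSRecord],
    ml_tables: Iterable[pd.DataFrame],
    cutoff: float = 0.5,
) -> list[KSRecord]:
    """Union of database records and ML predictions above ``cutoff``.

    Predictions require probability strictly greater than the cutoff.
    A prediction duplicating a database record collapses onto the database
    record (source precedence).  Probabilities outside [0, 1] reject the row.
    """
    merged: dict[tuple, KSRecord] = {
        (r.kinase_accession, r.substrate_site.key): r for r in records
    }
    n_rejected = 0
    for table in ml_tables:
        for _, row in table.iterrows():
            rec = _row_to_record(row, source="ml_prediction")
            if rec is None:
                n_rejected += 1
                continue
            if rec.probability <= cutoff:
                continue
            merged.setdefault((rec.kinase_accession, rec.substrate_site.key), rec)
    if n_rejected:
        logger.warning("augment_with_ml: rejected %d malformed rows", n_rejected)
    return list(merged.values())


def _class_of(residue: str) -> str:
    return "Y" if residue == "Y" else "ST"


def build_ks_labels(
    records: Sequence[KSRecord],
    dataset_sites: Sequence[PhosphoSite],
    kinase_classes: Mapping[str, str | Sequence[str]],
    mode: str = "KS_direct",
) -> LabelMatrix:
    """Kinase-substrate gold labels over measured phosphosites.

    ``kinase_classes`` maps kinase accessions to "ST", "Y", or a sequence
    of both for dual-specificity kinases (such kinases contribute one row
    per class).  Rows are the measured phosphosites residing on annotated
    kinase proteins; kinases with no class annotation yield all-NA rows
    with a warning.  Columns are all measured sites.
    """
    by_kinase: dict[str, set[tuple]] = {}
    for r in records:
        by_kinase.setdefault(r.kinase_accession, set()).add(r.substrate_site.key)

    col_sites = list(dataset_sites)
    kinase_site_rows: list[tuple[PhosphoSite, str | None]] = []
    for site in col_sites:
        if site.protein_accession in kinase_classes:
            classes = kinase_classes[site.protein_accession]
            if isinstance(classes, str):
                classes = [classes]
            for cls in classes:
                kinase_site_rows.append((site, cls))
        elif site.protein_accession in by_kinase:
            logger.warning(
                "kinase %s has interactome records but no class annotation; row is NA",
                site.protein_accession,
            )
            kinase_site_rows.append((site, None))

    n_rows, n_cols = len(kinase_site_rows), len(col_sites)
    L = np.full((n_rows, n_cols), np.nan)
    for i, (ksite, cls) in enumerate(kinase_site_rows):
        if cls is None:
            continue
        substrates = by_kinase.get(ksite.protein_accession, set())
        for j, s in enumerate(col_sites):
            if s.key == ksite.key:
                continue  # a site is not its own candidate substrate
            if _class_of(s.residue) != cls:
                continue  # residue-class mismatch stays NA
            L[i, j] = 1.0 if s.key in substrates else 0.0

    row_ids = [f"{site}|{cls or 'NA'}" for site, cls in kinase_site_rows]
    return LabelMatrix(
        labels=L,
        row_ids=row_ids,
        col_ids=[str(s) for s in col_sites],
        mode=mode,
        residue_class="mixed",
        symmetric=False,
    )


def build_ss_labels(
    records: Sequence[KSRecord],
    dataset_sites: Sequence[PhosphoSite],
    residue_class: str = "ST",
) -> LabelMatrix:
    """Substrate-substrate gold labels: 1 iff two measured sites share a
    regulating kinase.  Symmetric with an NA diagonal; restricted to one
    residue class (S/T by default, where kinase motif specificity makes
    shared regulation detectable)."""
    sites = [s for s in dataset_sites if _class_of(s.residue) == residue_class]
    kinases_of: dict[tuple, set[str]] = {s.key: set() for s in sites}
    for r in records:
        if r.substrate_site.key in kinases_of:
            kinases_of[r.substrate_site.key].add(r.kinase_accession)

    n = len(sites)
    L = np.zeros((n, n))
    np.fill_diagonal(L, np.nan)
    for i, j in itertools.combinations(range(n), 2):
        if kinases_of[sites[i].key] & kinases_of[sites[j].key]:
            L[i, j] = L[j, i] = 1.0
    ids = [str(s) for s in sites]
    return LabelMatrix(
        labels=L,
        row_ids=ids,
        col_ids=ids,
        mode="SS",
        residue_class=residue_class,
        symmetric=True,
    )
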
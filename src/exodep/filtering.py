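"""Scaffold-style evidence filtering.

Peptide-spectrum records exported from a search/validation tool are
retained only when they clear peptide-level rules (minimum length,
no singly-charged precursors, peptide probability) and protein-level
rules (>=2 distinct peptides, protein probability, protein FDR).
Retained records are tallied into a raw spectral-count matrix: one
count per retained record, per protein, per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .matrix import SpectralCountMatrix


class EvidenceError(ValueError):
    """Raised for malformed or inconsistent evidence records."""


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide-spectrum match from an evidence export."""

    sample_id: str
    protein_id: str
    peptide_seq: str
    charge_state: int
    peptide_prob: float
    protein_prob: float
    protein_fdr: float

    def validate(self, row: int | None = None) -> None:
        where = "" if row is None else f" (row {row})"
        if not self.peptide_seq or not str(self.peptide_seq).isalpha():
            raise EvidenceError(f"peptide_seq must be a non-empty amino-acid string{where}: {self.peptide_seq!r}")
        if int(self.charge_state) < 1:
            raise EvidenceError(f"charge_state must be >= 1{where}: {self.charge_state}")
        for name in ("peptide_prob", "protein_prob"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise EvidenceError(f"{name} must lie in [0, 1]{where}: {v}")
        if not 0.0 <= float(self.protein_fdr) <= 1.0:
            raise EvidenceError(f"protein_fdr must lie in [0, 1]{where}: {self.protein_fdr}")


@dataclass(frozen=True)
class FilterThresholds:
    """Retention cutoffs, defaulting to the published Scaffold settings.

    Peptide length and probabilities are strict (``>``) comparisons;
    protein FDR is strict ``<``.
    """

    min_peptide_length_exclusive: int = 5
    forbid_charge_one: bool = True
    min_peptide_prob: float = 0.80
    min_peptides_per_protein: int = 2
    min_protein_prob: float = 0.99
    max_protein_fdr: float = 0.01
    peptides_per_protein_scope: str = "experiment"  # or "sample"

    def __post_init__(self) -> None:
        if self.min_peptide_length_exclusive < 0:
            raise ValueError("min_peptide_length_exclusive must be >= 0")
        for name in ("min_peptide_prob", "min_protein_prob", "max_protein_fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_peptides_per_protein < 1:
            raise ValueError("min_peptides_per_protein must be >= 1")
        if self.peptides_per_protein_scope not in ("experiment", "sample"):
            raise ValueError("peptides_per_protein_scope must be 'experiment' or 'sample'")

    def to_dict(self) -> dict:
        return asdict(self)


def _passes_peptide_rules(rec: PeptideRecord, t: FilterThresholds) -> bool:
    if len(rec.peptide_seq) <= t.min_peptide_length_exclusive:
        return False
    if t.forbid_charge_one and int(rec.charge_state) == 1:
        return False
    return float(rec.peptide_prob) > t.min_peptide_prob


def filter_peptides(
    records: Iterable[PeptideRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[PeptideRecord]:
    """Keep records clearing the peptide-level rules; order is preserved."""
    out = []
    for i, rec in enumerate(records):
        rec.validate(row=i)
        if _passes_peptide_rules(rec, thresholds):
            out.append(rec)
    return out


def assemble_protein_counts(
    records: Iterable[PeptideRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    samples: Sequence[str] | None = None,
    group_map: Mapping[str, str] | None = None,
) -> pd.DataFrame | SpectralCountMatrix:
    """Apply protein-level rules and tally retained records into counts.

    The peptide filter is re-applied defensively. A protein is retained
    iff it has >= ``min_peptides_per_protein`` distinct retained peptide
    sequences (per experiment by default), a protein probability above
    ``min_protein_prob`` and a protein FDR below ``max_protein_fdr``.
    Cell (i, j) is the number of retained records of protein i in sample
    j (total spectra, not distinct peptides).

    Returns a plain DataFrame, or a :class:`SpectralCountMatrix` when a
    ``group_map`` is supplied.
    """
    kept = filter_peptides(records, thresholds)
    sample_order = list(samples) if samples is not None else sorted({r.sample_id for r in kept})

    by_protein: dict[str, list[PeptideRecord]] = {}
    for rec in kept:
        by_protein.setdefault(rec.protein_id, []).append(rec)

    rows: dict[str, dict[str, int]] = {}
    for pid in sorted(by_protein):
        recs = by_protein[pid]
        probs = {float(r.protein_prob) for r in recs}
        if len(probs) > 1:
            raise EvidenceError(f"conflicting protein_prob values for protein {pid!r}: {sorted(probs)}")
        fdrs = {float(r.protein_fdr) for r in recs}
        if len(fdrs) > 1:
            raise EvidenceError(f"conflicting protein_fdr values for protein {pid!r}: {sorted(fdrs)}")
        if thresholds.peptides_per_protein_scope == "experiment":
            n_peptides = len({r.peptide_seq for r in recs})
        else:
            per_sample: dict[str, set[str]] = {}
            for r in recs:
                per_sample.setdefault(r.sample_id, set()).add(r.peptide_seq)
            n_peptides = max((len(v) for v in per_sample.values()), default=0)
        if n_peptides < thresholds.min_peptides_per_protein:
            continue
        if not probs.pop() > thresholds.min_protein_prob:
            continue
        if not fdrs.pop() < thresholds.max_protein_fdr:
            continue
        counts: dict[str, int] = {s: 0 for s in sample_order}
        for r in recs:
            if r.sample_id not in counts:  # sample not declared up-front
                counts[r.sample_id] = 0
                sample_order.append(r.sample_id)
            counts[r.sample_id] += 1
        rows[pid] = counts

    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=sample_order).fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame(index=pd.Index([], name="protein_id"), columns=sample_order, dtype=int)
    df.index.name = "protein_id"
    if group_map is not None:
        return SpectralCountMatrix(df, group_map, flavor="raw")
    return df


EVIDENCE_COLUMNS = [
    "sample_id",
    "protein_id",
    "peptide_seq",
    "charge",
    "peptide_prob",
    "protein_prob",
    "protein_fdr",
]


def read_evidence(path: str | Path) -> list[PeptideRecord]:
    """Read an evidence TSV with the canonical header."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise EvidenceError(f"{path}: missing evidence columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = PeptideRecord(
            sample_id=str(row.sample_id),
            protein_id=str(row.protein_id),
            peptide_seq=str(row.peptide_seq),
            charge_state=int(row.charge),
            peptide_prob=float(row.peptide_prob),
            protein_prob=float(row.protein_prob),
            protein_fdr=float(row.protein_fdr),
        )
        rec.validate(row=i)
        records.append(rec)
    return records


def write_evidence(records: Iterable[PeptideRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.sample_id, r.protein_id, r.peptide_seq, r.charge_state, r.peptide_prob, r.protein_prob, r.protein_fdr)
            for r in records
        ],
        columns=EVIDENCE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
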
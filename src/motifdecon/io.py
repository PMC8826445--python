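"""Readers and writers for the plain-text formats the tool touches.

Formats: peptide lists (one per line), FASTA, tab-separated sample sheets,
long-format prediction tables (so externally computed predictions can drive
the deconvolution), and the assignment/score output tables.

Validation is total: every input row is either accepted or produces a
logged, row-addressed rejection; accepted + rejected always equals the
input row count.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .constants import TRASH, is_canonical
from .datamodel import (
    MhcClass,
    PredictionRecord,
    RankTable,
    unique_in_order,
    validate_allele_name,
)

logger = logging.getLogger("motifdecon")

__all__ = [
    "SampleSheetRow",
    "read_peptide_input",
    "read_sample_sheet",
    "read_prediction_table",
    "write_assignment_table",
    "merge_peptide_lists",
]


@dataclass
class SampleSheetRow:
    """One sample-sheet row: id, class, alleles, and its peptide-file path."""

    sample_id: str
    mhc_class: MhcClass
    alleles: list[str]
    peptide_file: str


@dataclass
class PeptideInput:
    """Peptides read from disk plus the rejection bookkeeping."""

    peptides: list[str]
    n_skipped: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)


def _parse_list(handle) -> Iterable[tuple[int, str]]:
    for lineno, line in enumerate(handle, start=1):
        seq = line.strip()
        if seq:
            yield lineno, seq


def _parse_fasta(handle) -> Iterable[tuple[int, str]]:
    for recno, rec in enumerate(SeqIO.parse(handle, "fasta"), start=1):
        yield recno, str(rec.seq)


def read_peptide_input(path_or_stream, format: str = "list") -> PeptideInput:
    """Read peptides from a list file (one per line) or FASTA.

    Peptides are upper-cased and returned in input order with duplicates
    retained (deduplication happens later in the pipeline and is logged
    there).  Entries containing residues outside the 20 canonical one-letter
    codes (B, J, O, U, X, Z, ...) are excluded and counted.
    """
    if format not in ("list", "fasta"):
        raise ValueError(f"unknown peptide input format {format!r}")
    if hasattr(path_or_stream, "read"):
        handle = path_or_stream
        close = False
    else:
        handle = open(path_or_stream)
        close = True
    try:
        rows = _parse_list(handle) if format == "list" else _parse_fasta(handle)
        out = PeptideInput(peptides=[])
        for rowno, seq in rows:
            seq = seq.upper()
            if is_canonical(seq):
                out.peptides.append(seq)
            else:
                out.n_skipped += 1
                out.skipped.append((rowno, seq))
                logger.info("skipped row %d: non-canonical residue in %r", rowno, seq)
    finally:
        if close:
            handle.close()
    if not out.peptides:
        raise ValueError("no peptides in input")
    return out


def read_sample_sheet(path) -> list[SampleSheetRow]:
    """Read the tab-separated sample sheet.

    Header row ``sample_id  mhc_class  alleles  peptide_file``; alleles are
    comma-separated HLA names (null-allele suffix "N" accepted verbatim).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "mhc_class", "alleles", "peptide_file"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing column(s) {missing}")
    rows: list[SampleSheetRow] = []
    seen: set[str] = set()
    for i, rec in df.iterrows():
        sid = str(rec["sample_id"]).strip()
        if sid in seen:
            raise ValueError(f"row {i + 2}: duplicate sample_id {sid!r}")
        seen.add(sid)
        try:
            alleles = [validate_allele_name(a) for a in str(rec["alleles"]).split(",")]
        except ValueError as exc:
            raise ValueError(f"row {i + 2} (sample {sid!r}): {exc}") from None
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"row {i + 2} (sample {sid!r}): duplicate allele")
        rows.append(
            SampleSheetRow(
                sample_id=sid,
                mhc_class=MhcClass.parse(rec["mhc_class"]),
                alleles=alleles,
                peptide_file=str(rec["peptide_file"]).strip(),
            )
        )
    return rows


_PRED_COLUMNS = [
    "sample_id",
    "peptide",
    "allele",
    "raw_score",
    "rank_percent",
    "core",
    "core_offset",
]


def read_prediction_table(path) -> RankTable:
    """Read a long-format prediction TSV into a validated :class:`RankTable`.

    Columns: sample_id, peptide, allele, raw_score, rank_percent, core,
    core_offset (core columns may be empty).  The table must be complete:
    one row for every (peptide, allele) pair of each sample.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "core": str})
    missing = [c for c in _PRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction table missing column(s) {missing}")
    records = []
    for i, rec in df.iterrows():
        core = rec["core"] if isinstance(rec["core"], str) and rec["core"] else None
        off = rec["core_offset"]
        offset = None if pd.isna(off) else int(off)
        try:
            records.append(
                PredictionRecord(
                    sample_id=str(rec["sample_id"]),
                    peptide=str(rec["peptide"]),
                    allele=str(rec["allele"]),
                    raw_score=float(rec["raw_score"]),
                    rank_percent=float(rec["rank_percent"]),
                    core=core,
                    core_offset=offset,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i + 2}: {exc}") from None
    table = RankTable(records)
    table.validate()
    return table


def write_assignment_table(result, outdir) -> tuple[Path, Path]:
    """Write the two output TSVs of a deconvolution run.

    (a) ``scores.tsv``: the full peptide x allele table (raw and rank score
    and 9-mer core per combination); (b) ``assignments.tsv``: per-peptide
    assignment (allele or TRASH) with best rank and core.  Column order is
    fixed; ranks are printed with 4 decimals.
    """
    if not result.assignments:
        raise ValueError("empty deconvolution result")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    score_path = outdir / "scores.tsv"
    rows = [
        {
            "sample_id": r.sample_id,
            "peptide": r.peptide,
            "allele": r.allele,
            "raw_score": f"{r.raw_score:.6g}",
            "rank_percent": f"{r.rank_percent:.4f}",
            "core": r.core or "",
            "core_offset": "" if r.core_offset is None else r.core_offset,
        }
        for r in result.rank_table
    ]
    pd.DataFrame(rows, columns=_PRED_COLUMNS).to_csv(score_path, sep="\t", index=False)

    assign_path = outdir / "assignments.tsv"
    arows = [
        {
            "sample_id": a.sample_id,
            "peptide": a.peptide,
            "assigned": a.assigned,
            "best_rank": f"{a.best_rank:.4f}",
            "best_core": "" if a.assigned == TRASH else (a.best_core or ""),
        }
        for a in result.assignments
    ]
    pd.DataFrame(
        arows, columns=["sample_id", "peptide", "assigned", "best_rank", "best_core"]
    ).to_csv(assign_path, sep="\t", index=False)
    return score_path, assign_path


def merge_peptide_lists(lists: Sequence[Sequence[str]]) -> dict:
    """Merge several samples' peptide lists, reporting both counts.

    Returns ``{"total": ..., "unique": ..., "peptides": [...]}`` where
    ``total`` counts every entry across lists and ``unique`` counts distinct
    sequences after the merge.
    """
    merged: list[str] = []
    for lst in lists:
        merged.extend(lst)
    uniq = unique_in_order(merged)
    return {"total": len(merged), "unique": len(uniq), "peptides": uniq}
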
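"""Core domain types for multi-allelic immunopeptidome deconvolution.

The central objects are :class:`PeptidomeSample` (a peptide list plus the
HLA alleles of its source cell line), :class:`RankTable` (every
peptide x allele prediction: raw score, percentile rank and 9-mer binding
core) and :class:`Assignment` (the per-peptide deconvolution outcome: one
allele or the TRASH sentinel).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .constants import CORE_LENGTH, TRASH, is_canonical

__all__ = [
    "MhcClass",
    "PeptidomeSample",
    "PredictionRecord",
    "RankTable",
    "Assignment",
]


class MhcClass(enum.Enum):
    """MHC class: class I (HLA-A/B/C, short peptides) or class II (HLA-DR/DQ/DP)."""

    I = "I"
    II = "II"

    @classmethod
    def parse(cls, text: str) -> "MhcClass":
        t = str(text).strip().upper()
        if t in ("I", "1"):
            return cls.I
        if t in ("II", "2"):
            return cls.II
        raise ValueError(f"unknown MHC class {text!r} (expected 'I' or 'II')")


# Allele-name syntax: locus (letters/digits, optional "HLA-" prefix), "*",
# two colon-separated numeric fields, optional expression suffix such as the
# null-allele "N" (e.g. "HLA-A*02:02", "DRB1*13:01", "DRB4*01:03N").
_ALLELE_RE = re.compile(r"^(HLA-)?[A-Z]+[0-9]*\*\d+:\d+[A-Z]?$")


def validate_allele_name(name: str) -> str:
    """Validate HLA allele-name syntax, returning the name unchanged."""
    name = name.strip()
    if not _ALLELE_RE.match(name):
        raise ValueError(f"malformed allele name {name!r}")
    return name


@dataclass
class PeptidomeSample:
    """A sample: its identifier, peptides, expressed alleles, and MHC class.

    Peptides are kept in input order with duplicates retained; deduplication
    happens downstream (and is logged there).
    """

    sample_id: str
    peptides: list[str]
    alleles: list[str]
    mhc_class: MhcClass

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"sample {self.sample_id!r} declares no alleles")
        if len(set(self.alleles)) != len(self.alleles):
            seen: set[str] = set()
            dup = next(a for a in self.alleles if a in seen or seen.add(a))
            raise ValueError(f"sample {self.sample_id!r}: duplicate allele {dup!r}")
        for a in self.alleles:
            validate_allele_name(a)
        bad = [p for p in self.peptides if not is_canonical(p)]
        if bad:
            raise ValueError(
                f"sample {self.sample_id!r}: {len(bad)} peptide(s) with "
                f"non-canonical residues (first: {bad[0]!r}); filter upstream"
            )

    @property
    def unique_peptides(self) -> list[str]:
        """Unique peptides in first-occurrence order."""
        return list(dict.fromkeys(self.peptides))


@dataclass(frozen=True)
class PredictionRecord:
    """One peptide x allele prediction.

    ``rank_percent`` is the percentile rank in [0, 100] (0 best: the raw
    score beats every random natural peptide).  ``core`` is the best-scoring
    9-mer window, ``core_offset`` its 0-based start; both are ``None`` when
    no core is defined (peptide shorter than 9).
    """

    sample_id: str
    peptide: str
    allele: str
    raw_score: float
    rank_percent: float
    core: str | None = None
    core_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.rank_percent <= 100.0):
            raise ValueError(
                f"rank_percent {self.rank_percent} outside [0, 100] "
                f"({self.sample_id}/{self.peptide}/{self.allele})"
            )
        if self.core is not None:
            if self.core_offset is None:
                raise ValueError("core given without core_offset")
            if len(self.core) != CORE_LENGTH:
                raise ValueError(f"core {self.core!r} is not a 9-mer")
            if len(self.peptide) >= CORE_LENGTH:
                window = self.peptide[self.core_offset : self.core_offset + CORE_LENGTH]
                if window != self.core:
                    raise ValueError(
                        f"core {self.core!r} is not the substring of "
                        f"{self.peptide!r} at offset {self.core_offset}"
                    )


@dataclass
class RankTable:
    """All peptide x allele predictions for one or more samples.

    Invariant (checked by :meth:`validate`): within each sample there is
    exactly one record for every (peptide, allele) pair — peptides are
    predicted against *all* alleles the sample expresses.
    """

    records: list[PredictionRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[PredictionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(r.sample_id for r in self.records))

    def alleles(self, sample_id: str | None = None) -> list[str]:
        return list(
            dict.fromkeys(
                r.allele
                for r in self.records
                if sample_id is None or r.sample_id == sample_id
            )
        )

    def peptides(self, sample_id: str | None = None) -> list[str]:
        return list(
            dict.fromkeys(
                r.peptide
                for r in self.records
                if sample_id is None or r.sample_id == sample_id
            )
        )

    def for_sample(self, sample_id: str) -> "RankTable":
        return RankTable([r for r in self.records if r.sample_id == sample_id])

    def lookup(self, sample_id: str, peptide: str, allele: str) -> PredictionRecord:
        for r in self.records:
            if r.sample_id == sample_id and r.peptide == peptide and r.allele == allele:
                return r
        raise KeyError((sample_id, peptide, allele))

    def validate(self) -> None:
        """Enforce completeness: one record per (peptide, allele) per sample."""
        for sid in self.sample_ids():
            recs = [r for r in self.records if r.sample_id == sid]
            alleles = list(dict.fromkeys(r.allele for r in recs))
            peptides = list(dict.fromkeys(r.peptide for r in recs))
            seen: dict[tuple[str, str], int] = {}
            for r in recs:
                key = (r.peptide, r.allele)
                seen[key] = seen.get(key, 0) + 1
            dups = [k for k, v in seen.items() if v > 1]
            if dups:
                raise ValueError(
                    f"sample {sid!r}: duplicate prediction rows, first {dups[0]}"
                )
            missing = [
                (p, a) for p in peptides for a in alleles if (p, a) not in seen
            ]
            if missing:
                raise ValueError(
                    f"sample {sid!r}: rank table incomplete, missing "
                    f"{len(missing)} (peptide, allele) pair(s), "
                    f"first {missing[0]}"
                )


@dataclass(frozen=True)
class Assignment:
    """Per-peptide deconvolution outcome: one allele name or TRASH.

    ``best_rank`` is the minimum percentile rank over the sample's alleles
    (recorded for TRASH too); ``best_core`` is the corresponding binding
    core, reported only for allele assignments.
    """

    sample_id: str
    peptide: str
    assigned: str
    best_rank: float
    best_core: str | None = None

    @property
    def is_trash(self) -> bool:
        return self.assigned == TRASH


def unique_in_order(items: Iterable[str]) -> list[str]:
    """Deduplicate preserving first-occurrence order."""
    return list(dict.fromkeys(items))
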
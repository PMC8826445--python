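"""The core deconvolution pipeline.

A multi-allelic peptide set is partitioned among the sample's declared
alleles by best percentile rank: each peptide goes to the allele with the
lowest rank, unless every rank exceeds the trash threshold (default 20%),
in which case the peptide is a presumed co-immunoprecipitated contaminant
and lands in the TRASH cluster.  The module also implements the length
prefilter, the class I contaminant prefilter for class II runs, cluster
contribution summaries, and pairwise repertoire-overlap analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .constants import TRASH
from .datamodel import Assignment, MhcClass, RankTable, unique_in_order

__all__ = [
    "DeconvolutionConfig",
    "DeconvolutionResult",
    "prepare_peptides",
    "assign_peptides",
    "exclude_class_i_binders",
    "contribution_summary",
    "repertoire_overlap",
    "round_half_up",
]

#: Default length windows per MHC class (inclusive).
DEFAULT_LENGTH_RANGE = {MhcClass.I: (8, 14), MhcClass.II: (13, 21)}


@dataclass
class DeconvolutionConfig:
    """Run parameters.

    trash_threshold is a percentile rank: a peptide whose best rank is
    strictly above it is a contaminant.  Setting it to 101 disables the
    trash cluster entirely.  class_i_prefilter_threshold is the binder rank
    used when stripping class I restricted peptides from class II data.
    """

    mhc_class: MhcClass = MhcClass.II
    length_min: int | None = None
    length_max: int | None = None
    trash_threshold: float = 20.0
    min_logo_peptides: int = 10
    class_i_prefilter_threshold: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = DEFAULT_LENGTH_RANGE[self.mhc_class]
        if self.length_min is None:
            self.length_min = lo
        if self.length_max is None:
            self.length_max = hi
        if self.length_min > self.length_max or self.length_min < 1:
            raise ValueError(
                f"bad length range {self.length_min}-{self.length_max}"
            )
        if not (0 < self.trash_threshold <= 101):
            raise ValueError("trash_threshold must be in (0, 101]")


@dataclass
class FilterReport:
    """Bookkeeping of the length/dedup prefilter."""

    n_input: int = 0
    n_removed_length: int = 0
    n_duplicates_collapsed: int = 0
    n_retained: int = 0


@dataclass
class DeconvolutionResult:
    """Assignments plus per-cluster counts for one sample.

    Cluster counts always partition the filtered unique peptide set:
    the allele counts and the TRASH count sum to the number of peptides
    that entered the assignment step.
    """

    assignments: list[Assignment]
    cluster_counts: dict[str, int]
    config: DeconvolutionConfig
    rank_table: RankTable
    log: list[str] = field(default_factory=list)

    @property
    def sample_id(self) -> str:
        return self.assignments[0].sample_id if self.assignments else ""

    def peptides_in(self, cluster: str) -> list[str]:
        if cluster not in self.cluster_counts:
            raise KeyError(f"unknown cluster {cluster!r}")
        return [a.peptide for a in self.assignments if a.assigned == cluster]

    def cores_in(self, cluster: str) -> list[str]:
        """Best 9-mer cores of a cluster's peptides (for motif building)."""
        return [
            a.best_core
            for a in self.assignments
            if a.assigned == cluster and a.best_core is not None
        ]


def prepare_peptides(
    peptides: list[str], config: DeconvolutionConfig
) -> tuple[list[str], FilterReport]:
    """Length-filter and deduplicate the input peptides.

    Retains peptides with length_min <= len <= length_max, then collapses
    duplicates (first occurrence kept); the report counts what each rule
    removed.
    """
    report = FilterReport(n_input=len(peptides))
    in_range = [
        p for p in peptides if config.length_min <= len(p) <= config.length_max
    ]
    report.n_removed_length = len(peptides) - len(in_range)
    uniq = unique_in_order(in_range)
    report.n_duplicates_collapsed = len(in_range) - len(uniq)
    report.n_retained = len(uniq)
    if not uniq:
        raise ValueError(
            f"no peptides left after length filter "
            f"{config.length_min}-{config.length_max}"
        )
    return uniq, report


def assign_peptides(
    rank_table: RankTable, config: DeconvolutionConfig
) -> DeconvolutionResult:
    """Assign every peptide to its best-rank allele or to TRASH.

    A peptide goes to the allele with the minimum percentile rank when that
    rank is <= trash_threshold; if every rank is strictly above the
    threshold the peptide is a contaminant and goes to TRASH.  Equal best
    ranks break toward the lexicographically first allele name, so the
    result is independent of input order.
    """
    from .estimators import MotifDeconvolver  # thin wrapper over the estimator

    rank_table.validate()
    assignments: list[Assignment] = []
    counts: dict[str, int] = {}
    for sid in rank_table.sample_ids():
        recs = [r for r in rank_table.records if r.sample_id == sid]
        alleles = sorted(set(r.allele for r in recs))
        for a in alleles:
            counts.setdefault(a, 0)
        counts.setdefault(TRASH, 0)
        peptides = rank_table.peptides(sid)
        by_pair = {(r.peptide, r.allele): r for r in recs}
        ranks = pd.DataFrame(
            [[by_pair[(p, a)].rank_percent for a in alleles] for p in peptides],
            index=peptides,
            columns=alleles,
        )
        labels = MotifDeconvolver(config.trash_threshold).fit_predict(ranks)
        for pep, label in zip(peptides, labels):
            # best-rank record: min by (rank, allele) = lexicographic tie-break
            best = min(
                (by_pair[(pep, a)] for a in alleles),
                key=lambda r: (r.rank_percent, r.allele),
            )
            assignments.append(
                Assignment(sid, pep, str(label), best.rank_percent, best.core)
            )
            counts[str(label)] += 1
    n_peptides = sum(len(rank_table.peptides(s)) for s in rank_table.sample_ids())
    assert sum(counts.values()) == n_peptides, "cluster counts must partition"
    return DeconvolutionResult(
        assignments=assignments,
        cluster_counts=counts,
        config=config,
        rank_table=rank_table,
        log=[f"assigned {n_peptides} peptides over {len(counts)} clusters"],
    )


def exclude_class_i_binders(
    peptides: list[str],
    class_i_rank_table: RankTable,
    threshold: float = 2.0,
) -> tuple[list[str], list[str]]:
    """Strip peptides with predicted class I restriction from class II data.

    A peptide is a class I binder when its best rank over the sample's
    class I alleles is <= threshold (default 2%).  Returns (retained,
    excluded); every input peptide must have class I predictions.
    """
    if not class_i_rank_table.records:
        raise ValueError("class I rank table is empty")
    best: dict[str, float] = {}
    for r in class_i_rank_table.records:
        best[r.peptide] = min(best.get(r.peptide, math.inf), r.rank_percent)
    missing = [p for p in peptides if p not in best]
    if missing:
        raise ValueError(
            f"{len(missing)} peptide(s) lack class I predictions, "
            f"first {missing[0]!r}"
        )
    retained = [p for p in peptides if best[p] > threshold]
    excluded = [p for p in peptides if best[p] <= threshold]
    return retained, excluded


def round_half_up(x: float) -> int:
    """Round to the nearest integer with .5 rounding away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def contribution_summary(result: DeconvolutionResult) -> dict:
    """Per-cluster peptide counts and percent contributions.

    Two denominators are reported: all assigned peptides including TRASH
    (``percent_total``) and the allele-annotated (non-trash) peptides only
    (``percent_assigned``).  Display percentages round half-up to the
    nearest integer; the exact values are kept alongside.  A zero
    denominator yields ``None`` (undefined), never 0.
    """
    counts = result.cluster_counts
    if not counts:
        raise ValueError("empty deconvolution result")
    total = sum(counts.values())
    non_trash = total - counts.get(TRASH, 0)
    out: dict[str, dict] = {}
    for cluster, n in counts.items():
        pct_total = 100.0 * n / total if total else None
        pct_assigned = (
            100.0 * n / non_trash if (non_trash and cluster != TRASH) else None
        )
        out[cluster] = {
            "count": n,
            "percent_total": pct_total,
            "percent_total_display": (
                None if pct_total is None else round_half_up(pct_total)
            ),
            "percent_assigned": pct_assigned,
            "percent_assigned_display": (
                None if pct_assigned is None else round_half_up(pct_assigned)
            ),
        }
    return {"clusters": out, "total": total, "total_assigned": non_trash}


def repertoire_overlap(
    rank_table: RankTable,
    allele_a: str,
    allele_b: str,
    binder_threshold: float = 1.0,
) -> dict:
    """Classify each peptide as binder of a, b, both, or neither.

    A peptide binds an allele when its rank for that allele is <= the
    binder threshold (default 1% rank); peptides binding both molecules
    are the repertoire overlap.
    """
    alleles = set(r.allele for r in rank_table.records)
    for a in (allele_a, allele_b):
        if a not in alleles:
            raise KeyError(f"allele {a!r} not in rank table")
    rank_a: dict[str, float] = {}
    rank_b: dict[str, float] = {}
    for r in rank_table.records:
        if r.allele == allele_a:
            rank_a[r.peptide] = r.rank_percent
        elif r.allele == allele_b:
            rank_b[r.peptide] = r.rank_percent
    unique_a, unique_b, overlap, neither = [], [], [], []
    for pep in rank_table.peptides():
        a_bind = rank_a[pep] <= binder_threshold
        b_bind = rank_b[pep] <= binder_threshold
        if a_bind and b_bind:
            overlap.append(pep)
        elif a_bind:
            unique_a.append(pep)
        elif b_bind:
            unique_b.append(pep)
        else:
            neither.append(pep)
    return {
        "unique_a": len(unique_a),
        "unique_b": len(unique_b),
        "overlap": len(overlap),
        "neither": len(neither),
        "peptides": {
            "unique_a": unique_a,
            "unique_b": unique_b,
            "overlap": overlap,
            "neither": neither,
        },
    }
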
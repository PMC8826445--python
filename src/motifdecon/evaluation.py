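"""Benchmarking of deconvolution against known peptide restrictions.

Given per-peptide true labels (the single-allele dataset each benchmark
peptide was drawn from) and cluster assignments, this module builds the
true x assigned confusion matrix (with a TRASH column), maps anonymous
clusters to alleles by the majority rule, computes a Matthews correlation
coefficient per allele and its median, and attaches bootstrap percentile
confidence intervals.

Per allele X with mapped cluster C_X:
  TP = peptides of X assigned to C_X;
  FP = peptides of other alleles assigned to C_X (the trash cluster is
       never a mapped cluster, so trash contributes no FP);
  FN = peptides of X assigned elsewhere, trash included;
  TN = peptides of other alleles not assigned to C_X, trash included.
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with the
standard zero-denominator convention MCC = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import TRASH

__all__ = [
    "ConfusionMatrix",
    "MccReport",
    "confusion_matrix",
    "map_clusters_to_alleles",
    "mcc_from_counts",
    "mcc_scores",
    "bootstrap_median_mcc",
]


@dataclass
class ConfusionMatrix:
    """True-label x assigned-cluster counts (TRASH column included)."""

    true_labels: list[str]
    clusters: list[str]
    counts: np.ndarray  # shape (len(true_labels), len(clusters))

    def row(self, label: str) -> np.ndarray:
        return self.counts[self.true_labels.index(label)]

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MccReport:
    """Per-allele MCC, the median, and an optional bootstrap CI."""

    per_allele: dict[str, float]
    median: float
    bootstrap_ci: tuple[float, float] | None = None
    bootstrap_medians: np.ndarray | None = None
    n_boot: int | None = None
    seed: int | None = None


def confusion_matrix(true_labels, assignments) -> ConfusionMatrix:
    """Tally peptides by (true allele of origin, assigned cluster).

    Both arguments are per-peptide label sequences of equal length;
    assigned clusters may be allele names, anonymous cluster ids, or TRASH.
    """
    true_labels = list(true_labels)
    assignments = list(assignments)
    if len(true_labels) != len(assignments):
        raise ValueError(
            f"{len(true_labels)} true labels vs {len(assignments)} assignments"
        )
    labels = sorted(set(true_labels))
    clusters = sorted(set(assignments) - {TRASH}) + [TRASH]
    li = {l: i for i, l in enumerate(labels)}
    ci = {c: j for j, c in enumerate(clusters)}
    counts = np.zeros((len(labels), len(clusters)), dtype=np.int64)
    for t, a in zip(true_labels, assignments):
        counts[li[t], ci[a]] += 1
    return ConfusionMatrix(true_labels=labels, clusters=clusters, counts=counts)


def map_clusters_to_alleles(cm: ConfusionMatrix) -> dict[str, str | None]:
    """Map each true allele to the cluster holding the majority of its peptides.

    For supervised assignments the mapping is identity-like; for anonymous
    clusterings each allele claims the (non-trash) cluster containing most
    of its peptides.  Conflicts resolve deterministically: alleles are
    processed by descending dataset size (lexicographic on ties) and a
    claimed cluster falls through to the best remaining one; an allele left
    without a cluster maps to None.
    """
    non_trash = [c for c in cm.clusters if c != TRASH]
    if len(non_trash) > len(cm.true_labels):
        raise ValueError(
            f"{len(non_trash)} non-trash clusters for {len(cm.true_labels)} alleles"
        )
    # descending dataset size, then lexicographic
    order = sorted(
        cm.true_labels, key=lambda l: (-int(cm.row(l).sum()), l)
    )
    mapping: dict[str, str | None] = {}
    claimed: set[str] = set()
    for allele in order:
        row = cm.row(allele)
        candidates = [c for c in non_trash if c not in claimed]
        if not candidates:
            mapping[allele] = None
            continue
        # best remaining cluster by count; ties lexicographic on cluster name
        best = sorted(
            candidates,
            key=lambda c: (-int(row[cm.clusters.index(c)]), c),
        )[0]
        mapping[allele] = best
        claimed.add(best)
    return mapping


def mcc_from_counts(tp: float, fp: float, fn: float, tn: float) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def mcc_scores(
    cm: ConfusionMatrix, mapping: dict[str, str | None] | None = None
) -> MccReport:
    """Per-allele MCC and the median across alleles."""
    if mapping is None:
        mapping = map_clusters_to_alleles(cm)
    per: dict[str, float] = {}
    total = cm.total()
    for allele in cm.true_labels:
        cluster = mapping.get(allele)
        row = cm.row(allele)
        row_sum = int(row.sum())
        if cluster is None:
            tp = fp = 0
        else:
            j = cm.clusters.index(cluster)
            tp = int(row[j])
            fp = int(cm.counts[:, j].sum()) - tp
        fn = row_sum - tp
        tn = total - row_sum - fp
        per[allele] = mcc_from_counts(tp, fp, fn, tn)
    return MccReport(per_allele=per, median=float(np.median(list(per.values()))))


def bootstrap_median_mcc(
    true_labels,
    assignments,
    n_boot: int = 100,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> MccReport:
    """Bootstrap the median per-allele MCC.

    Peptides are resampled with replacement ``n_boot`` times; each
    replicate rebuilds the confusion matrix, the cluster mapping and the
    per-allele MCCs, and records the median.  The CI is the 2.5/97.5
    percentile interval of the replicate medians by default.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    true_labels = list(true_labels)
    assignments = list(assignments)
    if len(true_labels) < 2:
        raise ValueError("need at least 2 peptides to bootstrap")
    point = mcc_scores(confusion_matrix(true_labels, assignments))
    rng = np.random.default_rng(seed)
    n = len(true_labels)
    medians = np.empty(n_boot)
    tl = np.asarray(true_labels, dtype=object)
    asg = np.asarray(assignments, dtype=object)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rep = mcc_scores(confusion_matrix(tl[idx], asg[idx]))
        medians[b] = rep.median
    lo, hi = np.percentile(medians, ci)
    return MccReport(
        per_allele=point.per_allele,
        median=point.median,
        bootstrap_ci=(float(lo), float(hi)),
        bootstrap_medians=medians,
        n_boot=n_boot,
        seed=seed,
    )
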
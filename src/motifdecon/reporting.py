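"""Motif summaries: core frequency matrices, KL information logos, length
distributions and cross-sample motif consistency.

Per-position information is the Kullback-Leibler divergence (bits) of the
observed core residue frequencies from a background distribution; letter
heights are frequency-weighted information (the non-negative rendering of
the classic p-weighted KL logo).  Motif similarity between samples is the
Pearson correlation of the flattened 9x20 frequency matrices (180-vectors,
position-major order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import AA_INDEX, AMINO_ACIDS, CORE_LENGTH, UNIFORM_BACKGROUND
from .deconvolution import DeconvolutionResult

__all__ = [
    "MotifSummary",
    "ConsistencyMatrix",
    "core_frequency_matrix",
    "kl_logo_data",
    "length_distribution",
    "consistency_matrix",
    "motif_summary",
    "flatten_freq",
]


@dataclass
class MotifSummary:
    """One cluster's motif: core frequencies, information, length histogram.

    ``logo_suppressed`` marks clusters below the minimum peptide count for
    logo rendering (counts are still reported).
    """

    allele: str
    n_peptides: int
    freq: np.ndarray  # 9x20, rows sum to 1 when n_peptides > 0
    info: np.ndarray  # 9-vector, bits
    length_hist: dict[int, int]
    logo_suppressed: bool = False


@dataclass
class ConsistencyMatrix:
    """Pairwise motif PCC for one allele across samples."""

    allele: str
    sample_ids: list[str]
    pcc: np.ndarray  # symmetric, diagonal 1; NaN where undefined
    mean_pcc: float  # mean over defined off-diagonal upper-triangle entries


def core_frequency_matrix(cores: list[str]) -> np.ndarray:
    """Position x residue frequency matrix of a set of 9-mer binding cores.

    Raw relative counts: no pseudocounts, no sequence weighting;
    zero-count cells are exactly 0.
    """
    if not cores:
        raise ValueError("no cores")
    counts = np.zeros((CORE_LENGTH, 20))
    for core in cores:
        if len(core) != CORE_LENGTH:
            raise ValueError(f"core {core!r} is not a 9-mer")
        for i, aa in enumerate(core):
            counts[i, AA_INDEX[aa]] += 1
    return counts / len(cores)


def kl_logo_data(
    freq: np.ndarray, background: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-position KL information and per-letter heights.

    info_i = sum_a p_ia * log2(p_ia / q_a) with 0*log(0) = 0;
    height_ia = p_ia * info_i.  Returns a plot-ready long table with
    columns (position, residue, freq, info, height); position is 1-based
    (P1..P9).
    """
    q = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if np.any(q <= 0):
        raise ValueError("background must be strictly positive")
    p = np.asarray(freq, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q[None, :]), 0.0)
    info = terms.sum(axis=1)
    heights = p * info[:, None]
    rows = [
        {
            "position": i + 1,
            "residue": AMINO_ACIDS[a],
            "freq": p[i, a],
            "info": info[i],
            "height": heights[i, a],
        }
        for i in range(p.shape[0])
        for a in range(20)
    ]
    return pd.DataFrame(rows)


def kl_information(freq: np.ndarray, background: np.ndarray | None = None) -> np.ndarray:
    """Just the per-position KL information vector (bits)."""
    df = kl_logo_data(freq, background)
    return df.groupby("position")["info"].first().to_numpy()


def length_distribution(
    result: DeconvolutionResult, cluster: str
) -> dict[int, int]:
    """Peptide-length histogram of one cluster over the configured range.

    Every integer length in [length_min, length_max] appears, with zero
    counts for empty lengths; an empty cluster yields the all-zero
    histogram, not an error.
    """
    peptides = result.peptides_in(cluster)  # raises on unknown cluster
    cfg = result.config
    hist = {L: 0 for L in range(cfg.length_min, cfg.length_max + 1)}
    for p in peptides:
        hist[len(p)] = hist.get(len(p), 0) + 1
    return hist


def flatten_freq(freq: np.ndarray) -> np.ndarray:
    """Flatten a 9x20 frequency matrix position-major to a 180-vector."""
    arr = np.asarray(freq, dtype=float)
    if arr.shape != (CORE_LENGTH, 20):
        raise ValueError(f"expected 9x20 matrix, got {arr.shape}")
    return arr.reshape(-1)


def consistency_matrix(
    summaries: dict[str, MotifSummary], allele: str
) -> ConsistencyMatrix:
    """Pairwise Pearson correlation of one allele's motif across samples.

    Each sample's 9x20 frequency matrix is flattened to a 180-vector and
    correlated pairwise.  A constant vector makes the PCC undefined for its
    pairs; those entries are NaN and excluded from the mean.
    """
    if len(summaries) < 2:
        raise ValueError("need motif summaries from at least 2 samples")
    sample_ids = list(summaries)
    vecs = np.stack([flatten_freq(summaries[s].freq) for s in sample_ids])
    n = len(sample_ids)
    pcc = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vi, vj = vecs[i], vecs[j]
            if np.ptp(vi) == 0 or np.ptp(vj) == 0:  # constant vector: PCC undefined
                pcc[i, j] = pcc[j, i] = np.nan
            else:
                pcc[i, j] = pcc[j, i] = float(np.corrcoef(vi, vj)[0, 1])
    upper = pcc[np.triu_indices(n, k=1)]
    defined = upper[~np.isnan(upper)]
    mean_pcc = float(defined.mean()) if defined.size else float("nan")
    return ConsistencyMatrix(
        allele=allele, sample_ids=sample_ids, pcc=pcc, mean_pcc=mean_pcc
    )


def motif_summary(
    result: DeconvolutionResult,
    cluster: str,
    background: np.ndarray | None = None,
    min_logo_peptides: int | None = None,
) -> MotifSummary:
    """Build the motif summary (frequencies, information, lengths) of a cluster.

    The logo is suppressed (but counts still reported) when the cluster
    holds fewer than ``min_logo_peptides`` peptides (config default 10).
    """
    if min_logo_peptides is None:
        min_logo_peptides = result.config.min_logo_peptides
    cores = result.cores_in(cluster)
    n = result.cluster_counts[cluster]
    hist = length_distribution(result, cluster)
    if not cores:
        freq = np.zeros((CORE_LENGTH, 20))
        info = np.zeros(CORE_LENGTH)
    else:
        freq = core_frequency_matrix(cores)
        df = kl_logo_data(freq, background)
        info = df.groupby("position")["info"].first().to_numpy()
    return MotifSummary(
        allele=cluster,
        n_peptides=n,
        freq=freq,
        info=info,
        length_hist=hist,
        logo_suppressed=n < min_logo_peptides,
    )


def freq_matrix_frame(freq: np.ndarray) -> pd.DataFrame:
    """Frequency matrix as a DataFrame (rows P1..P9, canonical columns)."""
    return pd.DataFrame(
        np.asarray(freq, dtype=float),
        index=[f"P{i}" for i in range(1, CORE_LENGTH + 1)],
        columns=list(AMINO_ACIDS),
    )
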
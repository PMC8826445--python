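"""Ground-truth labeled synthetic immunopeptidomes.

Generates per-allele motif-driven eluted-ligand sets (9-mer binding core
plus background flanks for class II; middle deletion/insertion length
variants for class I), merges them into multi-allelic artificial benchmark
datasets with known single-allele origin and optional random contaminants,
and implements the k-mer overlap exclusion filter and the scrambled-peptide
contaminant null model.

Bundled presets mirror the published artificial benchmark designs:
``classI_paper`` merges 1000 ligands from each of four HLA-A/B-like alleles
with 200 from each of two weak-motif HLA-C-like alleles (A/B five times
more abundant than C, as in real surface expression), and ``classII_paper``
merges 800 ligands from each of four HLA-DR-like alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .constants import (
    AA_INDEX,
    AMINO_ACIDS,
    CONTAMINANT,
    CORE_LENGTH,
    NATURAL_BACKGROUND,
)
from .datamodel import MhcClass
from .predictor import AlleleModel

__all__ = [
    "MockAlleleSpec",
    "LabeledPeptidome",
    "make_mock_allele",
    "sample_peptidome",
    "build_artificial_benchmark",
    "benchmark_preset",
    "kmer_overlap_filter",
    "scramble_peptides",
    "DEFAULT_LENGTH_DIST",
]

#: Default class-specific peptide length distributions.  Class I peaks at
#: the canonical 9-mer over 8-14; class II peaks at 15-mers over 13-21,
#: the preference seen in eluted HLA-DR ligands.
DEFAULT_LENGTH_DIST: dict[MhcClass, dict[int, float]] = {
    MhcClass.I: {8: 0.10, 9: 0.55, 10: 0.18, 11: 0.10, 12: 0.04, 13: 0.02, 14: 0.01},
    MhcClass.II: {
        13: 0.06, 14: 0.12, 15: 0.22, 16: 0.18, 17: 0.14,
        18: 0.11, 19: 0.08, 20: 0.05, 21: 0.04,
    },
}


@dataclass
class MockAlleleSpec:
    """A mock binding motif: anchor positions with residue preferences.

    ``anchors`` maps 1-based core positions (P1..P9) to residue→frequency
    maps summing to 1; non-anchor positions follow the background.
    """

    allele: str
    anchors: dict[int, dict[str, float]]
    length_distribution: dict[int, float] | None = None

    def __post_init__(self) -> None:
        for pos, freq in self.anchors.items():
            if not (1 <= pos <= CORE_LENGTH):
                raise ValueError(f"anchor position {pos} outside 1..9")
            s = sum(freq.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.allele} P{pos}: anchor frequencies sum to {s}, not 1"
                )
            bad = [a for a in freq if a not in AA_INDEX]
            if bad:
                raise ValueError(f"{self.allele} P{pos}: unknown residue {bad[0]!r}")
        if not self.anchors:
            warnings.warn(
                f"{self.allele}: empty anchor set yields a flat motif", stacklevel=2
            )

    def target_frequencies(self, background: np.ndarray) -> np.ndarray:
        """9x20 per-position target residue frequencies (anchors over background)."""
        p = np.tile(np.asarray(background, float), (CORE_LENGTH, 1))
        for pos, freq in self.anchors.items():
            row = np.zeros(20)
            for aa, f in freq.items():
                row[AA_INDEX[aa]] = f
            p[pos - 1] = row
        return p


@dataclass
class LabeledPeptidome:
    """Peptides with their generating allele (or CONTAMINANT) as truth labels."""

    peptides: list[str]
    labels: list[str]
    alleles: list[str]
    mhc_class: MhcClass
    seed: int
    specs: dict[str, MockAlleleSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.peptides) != len(self.labels):
            raise ValueError("labels must cover all peptides")


def make_mock_allele(
    spec: MockAlleleSpec, background: np.ndarray | None = None
) -> AlleleModel:
    """Turn a mock motif spec into a log-odds scoring matrix.

    weights[i][a] = log2(p_target[i][a] / q_a), with target frequencies
    floored at 1e-3 before the log so zero-preference residues get a large
    finite penalty rather than -inf.
    """
    q = NATURAL_BACKGROUND if background is None else np.asarray(background, float)
    p = np.maximum(spec.target_frequencies(q), 1e-3)
    weights = np.log2(p / q[None, :])
    return AlleleModel(allele=spec.allele, weights=weights, background=q.copy())


def _draw_length(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lengths = np.array(sorted(dist))
    probs = np.array([dist[L] for L in lengths], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(lengths, p=probs))


def _draw_residues(rng: np.random.Generator, probs: np.ndarray, n: int) -> str:
    idx = rng.choice(20, size=n, p=probs / probs.sum())
    return "".join(AMINO_ACIDS[i] for i in idx)


def _draw_core(rng: np.random.Generator, p_target: np.ndarray) -> str:
    return "".join(
        AMINO_ACIDS[rng.choice(20, p=p_target[i] / p_target[i].sum())]
        for i in range(CORE_LENGTH)
    )


def sample_peptidome(
    spec: MockAlleleSpec,
    n: int,
    mhc_class: MhcClass,
    seed: int,
    background: np.ndarray | None = None,
) -> LabeledPeptidome:
    """Sample n motif-driven peptides from one mock allele.

    Each peptide draws a length from the class length distribution and a
    9-mer core positionwise from the spec's target frequencies.  Class II
    peptides pad the core with background flanks at a uniformly drawn
    offset.  Class I length variants use the middle bulge convention:
    8-mers delete core position 5; longer peptides insert background
    residues between core positions 5 and 6.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    q = NATURAL_BACKGROUND if background is None else np.asarray(background, float)
    dist = spec.length_distribution or DEFAULT_LENGTH_DIST[mhc_class]
    if mhc_class is MhcClass.I and min(dist) < CORE_LENGTH - 1:
        raise ValueError("class I lengths below 8 are not supported")
    if mhc_class is MhcClass.II and min(dist) < CORE_LENGTH:
        raise ValueError("class II peptides must fit the 9-mer core")
    rng = np.random.default_rng(seed)
    p_target = spec.target_frequencies(q)
    peptides = []
    for _ in range(n):
        L = _draw_length(rng, dist)
        core = _draw_core(rng, p_target)
        if mhc_class is MhcClass.II:
            n_flank = L - CORE_LENGTH
            left = int(rng.integers(0, n_flank + 1))
            flanks = _draw_residues(rng, q, n_flank)
            pep = flanks[:left] + core + flanks[left:]
        else:
            if L == CORE_LENGTH:
                pep = core
            elif L == CORE_LENGTH - 1:
                pep = core[:4] + core[5:]  # drop core position 5
            else:
                pep = core[:5] + _draw_residues(rng, q, L - CORE_LENGTH) + core[5:]
        peptides.append(pep)
    return LabeledPeptidome(
        peptides=peptides,
        labels=[spec.allele] * n,
        alleles=[spec.allele],
        mhc_class=mhc_class,
        seed=seed,
        specs={spec.allele: spec},
    )


# ---------------------------------------------------------------------------
# Bundled benchmark presets.  Anchor maps are mock motifs: realistic anchor
# positions (class I P2/P9, class II P1/P4/P6/P9) with per-position disjoint
# residue preferences so cluster identifiability is controlled by design.
# The HLA-C-like alleles carry deliberately flat ("weak") anchor maps.
# Each spec also carries one weak full-alphabet auxiliary position (a mild
# power tilt of the natural background) — real motifs are never exactly
# background off-anchor, and it keeps the score distribution non-degenerate.


def background_tilt(power: float) -> dict[str, float]:
    """Weak full-alphabet preference: natural background raised to ``power``."""
    w = NATURAL_BACKGROUND**power
    w = w / w.sum()
    return {aa: float(w[i]) for i, aa in enumerate(AMINO_ACIDS)}


_CLASS_I_SPECS = [
    MockAlleleSpec("HLA-A*02:02", {
        2: {"L": 0.5, "M": 0.3, "I": 0.2},
        5: background_tilt(0.75),
        9: {"V": 0.5, "L": 0.3, "I": 0.2},
    }),
    MockAlleleSpec("HLA-A*11:02", {
        2: {"T": 0.4, "S": 0.35, "A": 0.25},
        5: background_tilt(0.85),
        9: {"K": 0.6, "R": 0.4},
    }),
    MockAlleleSpec("HLA-B*13:01", {
        2: {"Q": 0.5, "E": 0.3, "D": 0.2},
        5: background_tilt(1.15),
        9: {"W": 0.4, "F": 0.4, "Y": 0.2},
    }),
    MockAlleleSpec("HLA-B*49:01", {
        2: {"G": 0.45, "P": 0.35, "N": 0.2},
        5: background_tilt(1.25),
        9: {"M": 0.5, "A": 0.3, "C": 0.2},
    }),
    MockAlleleSpec("HLA-C*07:02", {
        2: {"Y": 0.3, "F": 0.3, "H": 0.2, "W": 0.2},
        5: background_tilt(0.8),
        9: {"T": 0.3, "S": 0.3, "G": 0.2, "P": 0.2},
    }),
    MockAlleleSpec("HLA-C*14:03", {
        2: {"C": 0.35, "V": 0.25, "K": 0.2, "R": 0.2},
        5: background_tilt(1.2),
        9: {"H": 0.35, "N": 0.25, "Q": 0.25, "D": 0.15},
    }),
]

_CLASS_II_SPECS = [
    MockAlleleSpec("DRB1*04:03", {
        1: {"F": 0.4, "Y": 0.4, "W": 0.2},
        4: {"D": 0.5, "E": 0.4, "N": 0.1},
        5: background_tilt(0.8),
        6: {"T": 0.5, "S": 0.4, "A": 0.1},
        9: {"E": 0.5, "D": 0.3, "Q": 0.2},
    }),
    MockAlleleSpec("DRB1*08:03", {
        1: {"L": 0.4, "I": 0.3, "V": 0.3},
        4: {"K": 0.5, "R": 0.4, "H": 0.1},
        5: background_tilt(0.9),
        6: {"G": 0.5, "P": 0.3, "C": 0.2},
        9: {"L": 0.5, "M": 0.3, "F": 0.2},
    }),
    MockAlleleSpec("DRB3*02:02", {
        1: {"W": 0.4, "H": 0.3, "M": 0.3},
        4: {"N": 0.5, "Q": 0.4, "G": 0.1},
        5: background_tilt(1.1),
        6: {"V": 0.5, "I": 0.3, "L": 0.2},
        9: {"K": 0.5, "R": 0.4, "H": 0.1},
    }),
    MockAlleleSpec("DRB5*01:02", {
        1: {"T": 0.4, "S": 0.3, "A": 0.3},
        4: {"F": 0.4, "Y": 0.4, "W": 0.2},
        5: background_tilt(1.2),
        6: {"D": 0.5, "E": 0.4, "N": 0.1},
        9: {"Y": 0.5, "W": 0.3, "F": 0.2},
    }),
]

#: Preset merge designs: (specs, per-allele counts, MHC class).
_PRESETS: dict[str, tuple[list[MockAlleleSpec], dict[str, int], MhcClass]] = {
    # 4 x 1000 HLA-A/B + 2 x 200 HLA-C: A/B five times more abundant than C.
    "classI_paper": (
        _CLASS_I_SPECS,
        {
            "HLA-A*02:02": 1000,
            "HLA-A*11:02": 1000,
            "HLA-B*13:01": 1000,
            "HLA-B*49:01": 1000,
            "HLA-C*07:02": 200,
            "HLA-C*14:03": 200,
        },
        MhcClass.I,
    ),
    # 800 unique 13-21mers per DR allele.
    "classII_paper": (
        _CLASS_II_SPECS,
        {s.allele: 800 for s in _CLASS_II_SPECS},
        MhcClass.II,
    ),
}


def benchmark_preset(name: str):
    """Return (specs, per-allele counts, mhc_class) of a bundled preset."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(_PRESETS)}")
    specs, counts, cls = _PRESETS[name]
    return list(specs), dict(counts), cls


def build_artificial_benchmark(
    per_allele_counts: Mapping[str, int],
    contaminant_n: int = 0,
    seed: int = 1,
    specs: Mapping[str, MockAlleleSpec] | None = None,
    mhc_class: MhcClass = MhcClass.II,
    background: np.ndarray | None = None,
    preset: str | None = None,
) -> LabeledPeptidome:
    """Merge per-allele synthetic peptidomes into one labeled benchmark.

    Either give ``preset`` (``classI_paper`` / ``classII_paper``) or
    explicit specs and counts.  ``contaminant_n`` random background
    peptides (class length distribution, CONTAMINANT label) are mixed in;
    the merged list is shuffled deterministically from ``seed``.
    """
    q = NATURAL_BACKGROUND if background is None else np.asarray(background, float)
    if preset is not None:
        preset_specs, preset_counts, mhc_class = benchmark_preset(preset)
        specs = {s.allele: s for s in preset_specs}
        counts = dict(preset_counts)
        counts.update(per_allele_counts)
    else:
        counts = dict(per_allele_counts)
        specs = dict(specs or {})
    if any(n < 0 for n in counts.values()):
        raise ValueError("per-allele counts must be >= 0")
    missing = [a for a, n in counts.items() if n > 0 and a not in specs]
    if missing:
        raise KeyError(f"no MockAlleleSpec for {missing}")

    rng = np.random.default_rng(seed)
    peptides: list[str] = []
    labels: list[str] = []
    for allele in sorted(counts):
        n = counts[allele]
        if n == 0:
            continue
        sub = sample_peptidome(
            specs[allele], n, mhc_class,
            seed=int(rng.integers(0, 2**31 - 1)), background=q,
        )
        peptides.extend(sub.peptides)
        labels.extend(sub.labels)
    if contaminant_n:
        dist = DEFAULT_LENGTH_DIST[mhc_class]
        for _ in range(contaminant_n):
            L = _draw_length(rng, dist)
            peptides.append(_draw_residues(rng, q, L))
            labels.append(CONTAMINANT)
    order = rng.permutation(len(peptides))
    return LabeledPeptidome(
        peptides=[peptides[i] for i in order],
        labels=[labels[i] for i in order],
        alleles=sorted(a for a, n in counts.items() if n > 0),
        mhc_class=mhc_class,
        seed=seed,
        specs=dict(specs),
    )


def kmer_overlap_filter(
    peptides: Sequence[str], exclusion_set: Sequence[str], k: int
) -> tuple[list[str], list[str]]:
    """Remove peptides sharing a contiguous k-mer with the exclusion set.

    Mirrors benchmark construction hygiene: candidate benchmark peptides
    sharing a k-residue stretch (8 for class I, 9 for class II) with a
    predictor's training data are dropped.  Returns (retained, removed).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    index: set[str] = set()
    for pep in exclusion_set:
        for i in range(len(pep) - k + 1):
            index.add(pep[i : i + k])
    if exclusion_set and not index:
        warnings.warn(
            f"k={k} exceeds every exclusion peptide length; nothing removed",
            stacklevel=2,
        )
    retained, removed = [], []
    for pep in peptides:
        hit = any(pep[i : i + k] in index for i in range(len(pep) - k + 1))
        (removed if hit else retained).append(pep)
    return retained, removed


@dataclass
class ScrambleResult:
    """Scrambled-peptide null set with per-source best ranks."""

    scrambled: list[str]  # all n_peptides * n_scrambles permutations
    source_index: np.ndarray  # which input peptide each scramble came from
    best_rank_per_scramble: np.ndarray
    best_rank_per_source: np.ndarray  # min over that source's scrambles
    subsample: list[str]  # length-matched to the original dataset
    subsample_best_rank: np.ndarray


def scramble_peptides(
    peptides: Sequence[str],
    rank_fn: Callable[[str], Sequence[float] | float],
    n_scrambles: int = 100,
    seed: int = 0,
) -> ScrambleResult:
    """Build the scrambled-peptide null model.

    Each peptide is scrambled ``n_scrambles`` times (uniform random
    permutations of its residues, so amino-acid composition and length are
    preserved); each scramble is ranked against the sample's alleles via
    ``rank_fn`` and the best (lowest) rank over alleles is kept.  A random
    subsample matching the original length histogram exactly (per-length
    without replacement when possible) is returned as the null dataset.
    """
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    rng = np.random.default_rng(seed)
    scrambled: list[str] = []
    src: list[int] = []
    for i, pep in enumerate(peptides):
        letters = np.array(list(pep))
        for _ in range(n_scrambles):
            scrambled.append("".join(letters[rng.permutation(len(letters))]))
            src.append(i)
    best = np.array([float(np.min(rank_fn(s))) for s in scrambled])
    per_source = np.full(len(peptides), np.inf)
    for j, i in enumerate(src):
        per_source[i] = min(per_source[i], best[j])

    # per-length subsample matching the original histogram exactly
    want: dict[int, int] = {}
    for pep in peptides:
        want[len(pep)] = want.get(len(pep), 0) + 1
    pool_by_len: dict[int, list[int]] = {}
    for j, s in enumerate(scrambled):
        pool_by_len.setdefault(len(s), []).append(j)
    chosen: list[int] = []
    for L in sorted(want):
        pool = pool_by_len.get(L, [])
        k = want[L]
        if len(pool) >= k:
            chosen.extend(rng.choice(pool, size=k, replace=False))
        else:
            chosen.extend(rng.choice(pool, size=k, replace=True))
    return ScrambleResult(
        scrambled=scrambled,
        source_index=np.array(src),
        best_rank_per_scramble=best,
        best_rank_per_source=per_source,
        subsample=[scrambled[j] for j in chosen],
        subsample_best_rank=best[np.array(chosen, dtype=int)],
    )
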
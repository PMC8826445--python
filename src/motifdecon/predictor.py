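"""Built-in PSSM scoring backend with empirical percentile-rank calibration.

The external neural eluted-ligand predictors are deliberately not
reimplemented: the deconvolution only requires a backend honouring the
contract *raw score + percentile rank + 9-mer binding core* per
peptide x allele.  Here that backend is a 9x20 log-odds position-specific
scoring matrix (:class:`AlleleModel`), scored by maximising the window sum
over all contiguous 9-mers of a peptide, with ranks calibrated empirically
against random natural peptides (:class:`CalibrationCurve`): the rank of a
score is the percentage of random-peptide scores at least as large, so 0 is
the strongest possible score and 100 the weakest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import (
    AMINO_ACIDS,
    CORE_LENGTH,
    NATURAL_BACKGROUND,
    encode_peptide,
)
from .datamodel import PeptidomeSample, PredictionRecord, RankTable

__all__ = [
    "AlleleModel",
    "CalibrationCurve",
    "score_peptide",
    "score_peptides",
    "calibrate_ranks",
    "rank_of",
    "predict_sample",
    "sample_background_peptides",
    "save_models",
    "load_models",
]


@dataclass
class AlleleModel:
    """A named 9x20 log-odds matrix (bits) plus background frequencies.

    Rows are core positions P1..P9; columns follow the canonical
    amino-acid order ``ACDEFGHIKLMNPQRSTVWY``.
    """

    allele: str
    weights: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: NATURAL_BACKGROUND.copy()
    )

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.weights.shape != (CORE_LENGTH, 20):
            raise ValueError(
                f"weights must be {CORE_LENGTH}x20, got {self.weights.shape}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.background.shape != (20,):
            raise ValueError("background must be a 20-vector")
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be strictly positive")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    def implied_frequencies(self) -> np.ndarray:
        """Target residue frequencies implied by the log-odds weights.

        Inverts ``w = log2(p/q)`` positionwise and renormalises; used for
        motif-vs-motif similarity of models.
        """
        p = (2.0 ** self.weights) * self.background[None, :]
        return p / p.sum(axis=1, keepdims=True)

    def to_dict(self) -> dict:
        return {
            "allele": self.allele,
            "weights": self.weights.tolist(),
            "background": self.background.tolist(),
            "alphabet": AMINO_ACIDS,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AlleleModel":
        if d.get("alphabet", AMINO_ACIDS) != AMINO_ACIDS:
            raise ValueError("model file uses a non-canonical alphabet order")
        return cls(
            allele=d["allele"],
            weights=np.asarray(d["weights"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
        )


@dataclass
class CalibrationCurve:
    """Sorted raw scores of random natural peptides for one allele.

    The percentile rank of a query score is
    ``100 * #{background >= score} / n_bg``.
    """

    allele: str
    background_scores: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.background_scores = np.sort(
            np.asarray(self.background_scores, dtype=float)
        )
        if self.background_scores.size < 1000:
            raise ValueError("calibration needs at least 1000 background scores")

    @property
    def n_bg(self) -> int:
        return int(self.background_scores.size)


def _window_scores(weights: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Scores of every 9-mer window of one encoded peptide."""
    n_win = encoded.size - CORE_LENGTH + 1
    offsets = np.arange(n_win)[:, None] + np.arange(CORE_LENGTH)[None, :]
    return weights[np.arange(CORE_LENGTH)[None, :], encoded[offsets]].sum(axis=1)


def _deletion_scores(weights: np.ndarray, enc8: np.ndarray) -> np.ndarray:
    """Scores of an 8-mer under every single-position deletion register.

    An 8-residue class I ligand occupies the groove with one core position
    bulged out; register g skips core position g (0-based) and the gap
    contributes 0 (background log-odds).  Returns the 9 register scores.
    """
    scores = np.empty(CORE_LENGTH)
    for g in range(CORE_LENGTH):
        pos = np.delete(np.arange(CORE_LENGTH), g)
        scores[g] = weights[pos, enc8].sum()
    return scores


def score_peptide(
    model: AlleleModel, peptide: str
) -> tuple[float, str | None, int | None]:
    """Score one peptide: max 9-mer window sum, plus the argmax core.

    Ties are broken toward the leftmost window.  Length-8 peptides are
    scored over the 9 single-position deletion registers (no 9-mer core is
    reported); peptides shorter than 8 cannot occupy the groove and get raw
    score ``-inf`` with no core.
    """
    encoded = encode_peptide(peptide)
    if encoded.size == CORE_LENGTH - 1:
        return float(_deletion_scores(model.weights, encoded).max()), None, None
    if encoded.size < CORE_LENGTH:
        return float("-inf"), None, None
    scores = _window_scores(model.weights, encoded)
    off = int(np.argmax(scores))  # argmax returns the first (leftmost) max
    return float(scores[off]), peptide[off : off + CORE_LENGTH], off


def score_peptides(
    model: AlleleModel, peptides: Sequence[str]
) -> tuple[np.ndarray, list[str | None], list[int | None]]:
    """Vectorised :func:`score_peptide` over many peptides.

    Peptides are grouped by length so each group scores as one strided
    numpy reduction; order of the output matches the input.
    """
    n = len(peptides)
    raw = np.full(n, -np.inf)
    cores: list[str | None] = [None] * n
    offs: list[int | None] = [None] * n

    by_len: dict[int, list[int]] = {}
    for i, p in enumerate(peptides):
        by_len.setdefault(len(p), []).append(i)

    for length, idx in by_len.items():
        if length == CORE_LENGTH - 1:
            enc = np.stack([encode_peptide(peptides[i]) for i in idx])
            reg = np.zeros((len(idx), CORE_LENGTH))
            for g in range(CORE_LENGTH):
                pos = np.delete(np.arange(CORE_LENGTH), g)
                reg[:, g] = model.weights[pos[None, :], enc].sum(axis=1)
            raw[idx] = reg.max(axis=1)
            continue
        if length < CORE_LENGTH:
            continue
        enc = np.stack([encode_peptide(peptides[i]) for i in idx])
        n_win = length - CORE_LENGTH + 1
        win = np.zeros((len(idx), n_win))
        for j in range(CORE_LENGTH):
            win += model.weights[j, enc[:, j : j + n_win]]
        best = win.argmax(axis=1)
        raw[idx] = win[np.arange(len(idx)), best]
        for k, i in enumerate(idx):
            o = int(best[k])
            offs[i] = o
            cores[i] = peptides[i][o : o + CORE_LENGTH]
    return raw, cores, offs


def sample_background_peptides(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    bg_frequencies: np.ndarray,
) -> list[str]:
    """Draw random natural peptides: residues i.i.d. from the background,
    lengths uniform over ``length_range`` (inclusive)."""
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError(f"bad length range {length_range}")
    q = np.asarray(bg_frequencies, dtype=float)
    if np.any(q <= 0) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("background frequencies must be positive and sum to 1")
    lengths = rng.integers(lo, hi + 1, size=n)
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    out = []
    for L in lengths:
        out.append(bytes(aas[rng.choice(20, size=L, p=q)]).decode())
    return out


def calibrate_ranks(
    model: AlleleModel,
    n_bg: int = 100_000,
    length_range: tuple[int, int] = (8, 14),
    bg_frequencies: np.ndarray | None = None,
    seed: int = 0,
) -> CalibrationCurve:
    """Build the empirical rank calibration for one allele.

    Scores ``n_bg`` random natural peptides (residues i.i.d. from
    ``bg_frequencies``, lengths pooled uniformly over ``length_range``)
    and stores the sorted scores.  Fully reproducible from ``seed``.
    """
    if n_bg < 1000:
        raise ValueError("n_bg must be >= 1000")
    q = model.background if bg_frequencies is None else np.asarray(bg_frequencies)
    rng = np.random.default_rng(seed)
    peptides = sample_background_peptides(rng, n_bg, length_range, q)
    raw, _, _ = score_peptides(model, peptides)
    return CalibrationCurve(allele=model.allele, background_scores=raw, seed=seed)


def rank_of(curve: CalibrationCurve, raw_score: float) -> float:
    """Percentile rank: 100 x fraction of background scores >= ``raw_score``.

    Total and monotonically non-increasing in the raw score; 0 means the
    score beats every random natural peptide, 100 that none scores below it.
    """
    n_ge = curve.n_bg - np.searchsorted(
        curve.background_scores, raw_score, side="left"
    )
    return 100.0 * float(n_ge) / curve.n_bg


def ranks_of(curve: CalibrationCurve, raw_scores: np.ndarray) -> np.ndarray:
    """Vectorised :func:`rank_of`."""
    raw = np.asarray(raw_scores, dtype=float)
    n_ge = curve.n_bg - np.searchsorted(curve.background_scores, raw, side="left")
    return 100.0 * n_ge.astype(float) / curve.n_bg


def predict_sample(
    sample: PeptidomeSample,
    models: Mapping[str, AlleleModel],
    curves: Mapping[str, CalibrationCurve],
) -> RankTable:
    """Predict every unique peptide of a sample against all its alleles.

    Duplicate peptides are collapsed before prediction; the table holds one
    record per unique peptide x allele.  Sub-core peptides (< 9 residues)
    get rank 100 and no core.
    """
    missing = [a for a in sample.alleles if a not in models or a not in curves]
    if missing:
        raise KeyError(
            f"sample {sample.sample_id!r}: no model/calibration for {missing}"
        )
    peptides = sample.unique_peptides
    records: list[PredictionRecord] = []
    for allele in sample.alleles:
        raw, cores, offs = score_peptides(models[allele], peptides)
        finite = np.isfinite(raw)
        ranks = np.full(raw.size, 100.0)
        ranks[finite] = ranks_of(curves[allele], raw[finite])
        for i, pep in enumerate(peptides):
            records.append(
                PredictionRecord(
                    sample_id=sample.sample_id,
                    peptide=pep,
                    allele=allele,
                    raw_score=float(raw[i]) if finite[i] else float("-inf"),
                    rank_percent=float(ranks[i]),
                    core=cores[i],
                    core_offset=offs[i],
                )
            )
    table = RankTable(records)
    table.validate()
    return table


def save_models(models: Iterable[AlleleModel], path) -> None:
    """Write allele models to a JSON file (list of model objects)."""
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=1)


def load_models(path) -> dict[str, AlleleModel]:
    """Read allele models from JSON, keyed by allele name."""
    with open(path) as fh:
        data = json.load(fh)
    models = [AlleleModel.from_dict(d) for d in data]
    return {m.allele: m for m in models}
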
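"""Scikit-learn-style estimators for the score → rank → assign core.

:class:`PSSMRankScorer` is a transformer: ``fit`` runs the empirical
percentile-rank calibration for every allele model, ``transform`` maps
peptides to a peptide x allele rank matrix.  :class:`MotifDeconvolver` is a
classifier over that matrix: ``predict`` returns the best-rank allele per
peptide, or TRASH when every rank exceeds the trash threshold.  The two
compose in an sklearn ``Pipeline``; the module-level functions in
:mod:`motifdecon.predictor` and :mod:`motifdecon.deconvolution` are thin
wrappers over these classes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .constants import TRASH
from .datamodel import PeptidomeSample, RankTable
from .predictor import AlleleModel, calibrate_ranks
from .predictor import predict_sample as _predict_sample

__all__ = ["PSSMRankScorer", "MotifDeconvolver"]


class PSSMRankScorer(BaseEstimator, TransformerMixin):
    """Peptides -> percentile-rank matrix, one column per allele model.

    Parameters
    ----------
    models : mapping or sequence of AlleleModel
        The per-allele 9x20 log-odds matrices.
    n_bg : int
        Number of random natural peptides per allele used to calibrate the
        empirical rank curve.
    length_range : (int, int)
        Inclusive length range of the calibration peptides; should match
        the length window of the peptides being scored (class I 8-14,
        class II 13-21).
    background : 20-vector or None
        Residue frequencies of the random natural peptides; each model's
        own background when None.
    seed : int
        Seed for the calibration draws (one derived stream per allele).

    Attributes
    ----------
    curves_ : dict allele -> CalibrationCurve
    alleles_ : list of allele names (model order)
    """

    def __init__(
        self,
        models: Mapping[str, AlleleModel] | Sequence[AlleleModel] = (),
        n_bg: int = 100_000,
        length_range: tuple[int, int] = (8, 14),
        background=None,
        seed: int = 0,
    ):
        self.models = models
        self.n_bg = n_bg
        self.length_range = length_range
        self.background = background
        self.seed = seed

    def _model_dict(self) -> dict[str, AlleleModel]:
        if isinstance(self.models, Mapping):
            return dict(self.models)
        return {m.allele: m for m in self.models}

    def fit(self, X=None, y=None) -> "PSSMRankScorer":
        """Calibrate the rank curve of every allele model (X is ignored)."""
        models = self._model_dict()
        if not models:
            raise ValueError("no allele models supplied")
        root = np.random.SeedSequence(self.seed)
        self.alleles_ = list(models)
        self.curves_ = {}
        for allele, child in zip(self.alleles_, root.spawn(len(models))):
            self.curves_[allele] = calibrate_ranks(
                models[allele],
                n_bg=self.n_bg,
                length_range=tuple(self.length_range),
                bg_frequencies=self.background,
                seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            )
        return self

    def transform(self, X: Sequence[str]) -> pd.DataFrame:
        """Rank matrix for peptides ``X`` (rows follow input order)."""
        check_is_fitted(self, "curves_")
        sample = PeptidomeSample(
            sample_id="_transform",
            peptides=list(dict.fromkeys(X)),
            alleles=self.alleles_,
            mhc_class=_guess_class(X),
        )
        table = _predict_sample(sample, self._model_dict(), self.curves_)
        ranks = {a: {} for a in self.alleles_}
        for r in table.records:
            ranks[r.allele][r.peptide] = r.rank_percent
        return pd.DataFrame(
            [[ranks[a][p] for a in self.alleles_] for p in X],
            index=list(X),
            columns=self.alleles_,
        )

    def rank_table(self, sample: PeptidomeSample) -> RankTable:
        """Full :class:`RankTable` (raw scores, ranks, cores) for a sample."""
        check_is_fitted(self, "curves_")
        return _predict_sample(sample, self._model_dict(), self.curves_)


def _guess_class(peptides: Sequence[str]):
    from .datamodel import MhcClass

    lens = [len(p) for p in peptides]
    return MhcClass.II if lens and np.median(lens) >= 12 else MhcClass.I


class MotifDeconvolver(BaseEstimator):
    """Best-rank allele assignment with a trash cluster.

    ``predict`` assigns each peptide (a row of the rank matrix) to the
    allele with the minimum percentile rank, breaking exact ties toward
    the lexicographically first allele name, or to TRASH when every rank
    is strictly above ``trash_threshold``.  ``trash_threshold=101``
    disables the trash cluster.
    """

    def __init__(self, trash_threshold: float = 20.0):
        self.trash_threshold = trash_threshold

    def fit(self, X: pd.DataFrame, y=None) -> "MotifDeconvolver":
        if not (0 < self.trash_threshold <= 101):
            raise ValueError("trash_threshold must be in (0, 101]")
        X = self._as_frame(X)
        self.alleles_ = list(X.columns)
        self.classes_ = np.array(self.alleles_ + [TRASH], dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "alleles_")
        X = self._as_frame(X)
        cols = sorted(X.columns)  # lexicographic order -> leftmost-min tie-break
        vals = X[cols].to_numpy(dtype=float)
        best_idx = vals.argmin(axis=1)
        best_rank = vals[np.arange(len(vals)), best_idx]
        labels = np.array([cols[j] for j in best_idx], dtype=object)
        labels[best_rank > self.trash_threshold] = TRASH
        return labels

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).predict(X)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        raise TypeError(
            "MotifDeconvolver expects a peptide x allele rank DataFrame "
            "(allele names as columns)"
        )
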
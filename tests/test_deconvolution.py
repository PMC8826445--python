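"""Length filtering, best-rank assignment with trash, contributions, overlap."""

import numpy as np
import pytest

from motifdecon.constants import TRASH
from motifdecon.datamodel import MhcClass, PredictionRecord, RankTable
from motifdecon.deconvolution import (
    DeconvolutionConfig,
    assign_peptides,
    contribution_summary,
    exclude_class_i_binders,
    prepare_peptides,
    repertoire_overlap,
    round_half_up,
)


def make_table(rank_map, sample_id="s"):
    """rank_map: {peptide: {allele: rank}} -> complete RankTable."""
    records = []
    for pep, per_allele in rank_map.items():
        for allele, rank in per_allele.items():
            core = pep[:9] if len(pep) >= 9 else None
            records.append(
                PredictionRecord(
                    sample_id, pep, allele, -rank, rank,
                    core, 0 if core else None,
                )
            )
    return RankTable(records)


class TestPreparePeptides:
    def test_class_ii_default_window(self):
        cfg = DeconvolutionConfig(mhc_class=MhcClass.II)
        assert (cfg.length_min, cfg.length_max) == (13, 21)
        kept, rep = prepare_peptides(["A" * 12, "C" * 15], cfg)
        assert kept == ["C" * 15]
        assert rep.n_removed_length == 1

    def test_class_i_default_window(self):
        cfg = DeconvolutionConfig(mhc_class=MhcClass.I)
        assert (cfg.length_min, cfg.length_max) == (8, 14)
        kept, _ = prepare_peptides(["A" * 7, "C" * 9], cfg)
        assert kept == ["C" * 9]

    def test_duplicates_collapsed_and_counted(self):
        cfg = DeconvolutionConfig(mhc_class=MhcClass.I)
        kept, rep = prepare_peptides(["KLMNPQRST"] * 2, cfg)
        assert kept == ["KLMNPQRST"]
        assert rep.n_duplicates_collapsed == 1

    def test_empty_after_filter_is_error(self):
        cfg = DeconvolutionConfig(mhc_class=MhcClass.II)
        with pytest.raises(ValueError, match="no peptides"):
            prepare_peptides(["A" * 9], cfg)


class TestAssignPeptides:
    CFG = DeconvolutionConfig(mhc_class=MhcClass.I, trash_threshold=20.0)

    def test_argmin_allele_wins(self):
        table = make_table({"KLMNPQRST": {"HLA-A*01:01": 0.5, "HLA-B*08:01": 10.0}})
        res = assign_peptides(table, self.CFG)
        assert res.assignments[0].assigned == "HLA-A*01:01"
        assert res.assignments[0].best_rank == 0.5

    def test_all_ranks_above_threshold_goes_to_trash(self):
        table = make_table({"KLMNPQRST": {"HLA-A*01:01": 25.0, "HLA-B*08:01": 30.0}})
        res = assign_peptides(table, self.CFG)
        assert res.assignments[0].assigned == TRASH

    def test_threshold_boundary_is_inclusive(self):
        # only a rank strictly higher than the threshold is trash
        table = make_table({"KLMNPQRST": {"HLA-A*01:01": 20.0, "HLA-B*08:01": 50.0}})
        res = assign_peptides(table, self.CFG)
        assert res.assignments[0].assigned == "HLA-A*01:01"

    def test_tie_breaks_lexicographically(self):
        table = make_table({"KLMNPQRST": {"HLA-B*08:01": 1.0, "HLA-A*01:01": 1.0}})
        res = assign_peptides(table, self.CFG)
        assert res.assignments[0].assigned == "HLA-A*01:01"

    def test_threshold_101_disables_trash(self):
        cfg = DeconvolutionConfig(mhc_class=MhcClass.I, trash_threshold=101.0)
        table = make_table({"KLMNPQRST": {"HLA-A*01:01": 99.9}})
        res = assign_peptides(table, cfg)
        assert res.assignments[0].assigned == "HLA-A*01:01"

    def test_partition_property_on_random_tables(self):
        rng = np.random.default_rng(10)
        alleles = ["HLA-A*01:01", "HLA-B*08:01", "HLA-C*07:02"]
        for trial in range(100):
            n = int(rng.integers(1, 40))
            peps = {f"{'ACDEFGHIK'[:8]}{chr(65 + i % 26)}": None for i in range(n)}
            table = make_table(
                {
                    p: {a: float(rng.uniform(0, 100)) for a in alleles}
                    for p in list(peps)
                }
            )
            res = assign_peptides(table, self.CFG)
            assert sum(res.cluster_counts.values()) == len(table.peptides())

    def test_raising_threshold_never_adds_trash(self):
        rng = np.random.default_rng(20)
        alleles = ["HLA-A*01:01", "HLA-B*08:01"]
        table = make_table(
            {
                f"KLMNPQRS{chr(65 + i)}": {
                    a: float(rng.uniform(0, 100)) for a in alleles
                }
                for i in range(25)
            }
        )
        trash_at = {}
        for thr in (5.0, 20.0, 50.0, 101.0):
            cfg = DeconvolutionConfig(mhc_class=MhcClass.I, trash_threshold=thr)
            res = assign_peptides(table, cfg)
            trash_at[thr] = {
                a.peptide for a in res.assignments if a.assigned == TRASH
            }
        assert trash_at[101.0] <= trash_at[50.0] <= trash_at[20.0] <= trash_at[5.0]

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(30)
        alleles = ["HLA-A*01:01", "HLA-B*08:01"]
        rank_map = {
            f"KLMNPQRS{chr(65 + i)}": {a: float(rng.uniform(0, 100)) for a in alleles}
            for i in range(15)
        }
        res1 = assign_peptides(make_table(rank_map), self.CFG)
        reversed_map = dict(reversed(list(rank_map.items())))
        res2 = assign_peptides(make_table(reversed_map), self.CFG)
        a1 = {a.peptide: a.assigned for a in res1.assignments}
        a2 = {a.peptide: a.assigned for a in res2.assignments}
        assert a1 == a2

    def test_incomplete_table_rejected(self):
        records = [
            PredictionRecord("s", "KLMNPQRST", "HLA-A*01:01", 0.0, 1.0),
            PredictionRecord("s", "KLMNPQRST", "HLA-B*08:01", 0.0, 1.0),
            PredictionRecord("s", "CDEFGHIKL", "HLA-A*01:01", 0.0, 1.0),
        ]
        with pytest.raises(ValueError, match="incomplete"):
            assign_peptides(RankTable(records), self.CFG)


class TestClassIPrefilter:
    def test_binder_excluded_at_2_percent(self):
        ci = make_table({"KLMNPQRST": {"HLA-A*01:01": 1.5}})
        kept, dropped = exclude_class_i_binders(["KLMNPQRST"], ci, threshold=2.0)
        assert dropped == ["KLMNPQRST"] and kept == []

    def test_nonbinder_retained(self):
        ci = make_table({"KLMNPQRST": {"HLA-A*01:01": 10.0}})
        kept, dropped = exclude_class_i_binders(["KLMNPQRST"], ci, threshold=2.0)
        assert kept == ["KLMNPQRST"] and dropped == []

    def test_empty_class_i_table_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            exclude_class_i_binders(["KLMNPQRST"], RankTable([]), threshold=2.0)

    def test_missing_predictions_is_error(self):
        ci = make_table({"KLMNPQRST": {"HLA-A*01:01": 10.0}})
        with pytest.raises(ValueError, match="lack class I"):
            exclude_class_i_binders(["KLMNPQRST", "CDEFGHIKL"], ci)


class TestContributionSummary:
    @staticmethod
    def _result_with_counts(counts):
        from motifdecon.deconvolution import DeconvolutionResult

        return DeconvolutionResult(
            assignments=[None] * 0 or [],
            cluster_counts=counts,
            config=DeconvolutionConfig(mhc_class=MhcClass.II),
            rank_table=RankTable([]),
        )

    def test_half_up_display_rounding(self):
        assert round_half_up(49.8) == 50
        assert round_half_up(63.9) == 64
        assert round_half_up(2.04) == 2
        assert round_half_up(2.5) == 3

    def test_drb5_contributions(self):
        # 1490 of 2991 DR peptides -> 50%; 1010 of 1580 -> 64%
        res = self._result_with_counts({"DRB5*01:01": 1490, "DRB1*15:01": 1501})
        got = contribution_summary(res)
        assert got["clusters"]["DRB5*01:01"]["percent_total_display"] == 50
        res = self._result_with_counts({"DRB5*02:02": 1010, "DRB1*16:01": 570})
        got = contribution_summary(res)
        assert got["clusters"]["DRB5*02:02"]["percent_total_display"] == 64

    def test_null_allele_contribution(self):
        # 53 of 2597 DR-annotated peptides -> 2%
        res = self._result_with_counts({"DRB4*01:03N": 53, "DRB1*04:01": 2544})
        got = contribution_summary(res)
        assert got["clusters"]["DRB4*01:03N"]["percent_total_display"] == 2

    def test_all_trash(self):
        res = self._result_with_counts({"DRB1*04:01": 0, TRASH: 7})
        got = contribution_summary(res)
        assert got["clusters"][TRASH]["percent_total_display"] == 100
        assert got["clusters"]["DRB1*04:01"]["percent_total_display"] == 0
        # percent of assigned undefined when nothing is assigned
        assert got["clusters"]["DRB1*04:01"]["percent_assigned"] is None


class TestRepertoireOverlap:
    def test_four_quadrants(self):
        table = make_table(
            {
                "KLMNPQRSTAAAA": {"DRB1*15:01": 0.5, "DRB5*01:01": 0.5},
                "CDEFGHIKLAAAA": {"DRB1*15:01": 0.5, "DRB5*01:01": 2.0},
                "MNPQRSTVWAAAA": {"DRB1*15:01": 2.0, "DRB5*01:01": 0.5},
                "ACDEFGHIKAAAA": {"DRB1*15:01": 2.0, "DRB5*01:01": 2.0},
            }
        )
        got = repertoire_overlap(table, "DRB1*15:01", "DRB5*01:01")
        assert (got["overlap"], got["unique_a"], got["unique_b"], got["neither"]) == (
            1, 1, 1, 1,
        )

    def test_binder_threshold_is_1_percent(self):
        table = make_table({"KLMNPQRSTAAAA": {"DRB1*15:01": 0.5, "DRB5*01:01": 0.8}})
        got = repertoire_overlap(table, "DRB1*15:01", "DRB5*01:01")
        assert got["overlap"] == 1

    def test_unknown_allele_rejected(self):
        table = make_table({"KLMNPQRST": {"DRB1*15:01": 0.5, "DRB5*01:01": 0.8}})
        with pytest.raises(KeyError):
            repertoire_overlap(table, "DRB1*15:01", "DRB1*99:99")
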
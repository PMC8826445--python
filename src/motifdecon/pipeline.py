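"""End-to-end orchestration: filter -> rank -> assign -> report.

`deconvolute_sample` runs one sample through the full pipeline using
either the built-in PSSM backend (allele models, calibrated on the fly)
or an externally supplied prediction table.  `write_sample_outputs`
emits the standard output files of a run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .datamodel import PeptidomeSample, RankTable
from .deconvolution import (
    DeconvolutionConfig,
    DeconvolutionResult,
    FilterReport,
    assign_peptides,
    contribution_summary,
    exclude_class_i_binders,
    prepare_peptides,
)
from .estimators import PSSMRankScorer
from .io import write_assignment_table
from .predictor import AlleleModel
from .reporting import freq_matrix_frame, kl_logo_data, motif_summary

__all__ = ["deconvolute_sample", "write_sample_outputs"]


def _fmt(value) -> str:
    """Integer-percent display; undefined percentages print empty, not 0."""
    return "" if value is None else str(int(value))


def deconvolute_sample(
    sample: PeptidomeSample,
    config: DeconvolutionConfig,
    models: Mapping[str, AlleleModel] | None = None,
    rank_table: RankTable | None = None,
    class_i_rank_table: RankTable | None = None,
    n_bg: int = 100_000,
    seed: int = 0,
) -> tuple[DeconvolutionResult, FilterReport]:
    """Run the full deconvolution for one sample.

    Exactly one of ``models`` (built-in PSSM backend) or ``rank_table``
    (external predictions) must be given.  When ``class_i_rank_table`` is
    supplied for a class II run, peptides with predicted class I
    restriction (best class I rank <= the prefilter threshold) are removed
    before assignment.
    """
    if (models is None) == (rank_table is None):
        raise ValueError("give exactly one of models= or rank_table=")
    peptides, report = prepare_peptides(sample.peptides, config)
    if class_i_rank_table is not None:
        peptides, excluded = exclude_class_i_binders(
            peptides, class_i_rank_table, config.class_i_prefilter_threshold
        )
        report.n_retained = len(peptides)
        if not peptides:
            raise ValueError("no peptides left after class I prefilter")
    filtered = PeptidomeSample(
        sample_id=sample.sample_id,
        peptides=peptides,
        alleles=list(sample.alleles),
        mhc_class=sample.mhc_class,
    )
    if models is not None:
        scorer = PSSMRankScorer(
            models={a: models[a] for a in sample.alleles},
            n_bg=n_bg,
            length_range=(config.length_min, config.length_max),
            seed=seed,
        ).fit()
        table = scorer.rank_table(filtered)
    else:
        keep = set(peptides)
        table = RankTable(
            [
                r
                for r in rank_table.records
                if r.sample_id == sample.sample_id and r.peptide in keep
            ]
        )
        table.validate()
        missing = keep - set(table.peptides())
        if missing:
            raise ValueError(
                f"prediction table lacks {len(missing)} filtered peptide(s), "
                f"first {sorted(missing)[0]!r}"
            )
    result = assign_peptides(table, config)
    result.log.append(
        f"filter: {report.n_input} in, {report.n_removed_length} off-length, "
        f"{report.n_duplicates_collapsed} duplicates, {report.n_retained} kept"
    )
    return result, report


def write_sample_outputs(result: DeconvolutionResult, outdir) -> None:
    """Write the per-sample output files.

    scores.tsv / assignments.tsv (via :func:`write_assignment_table`),
    clusters.tsv (count and percent contributions per cluster), one
    frequency-matrix and logo-data TSV per cluster with enough peptides,
    length_distributions.tsv, and run_log.txt.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_assignment_table(result, outdir)

    summary = contribution_summary(result)
    rows = [
        {
            "cluster": cluster,
            "count": d["count"],
            "percent_total": _fmt(d["percent_total_display"]),
            "percent_assigned": _fmt(d["percent_assigned_display"]),
        }
        for cluster, d in summary["clusters"].items()
    ]
    pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    lrows = []
    for cluster in result.cluster_counts:
        ms = motif_summary(result, cluster)
        for L, c in ms.length_hist.items():
            lrows.append({"cluster": cluster, "length": L, "count": c})
        if not ms.logo_suppressed and ms.n_peptides > 0:
            safe = cluster.replace("*", "").replace(":", "")
            freq_matrix_frame(ms.freq).to_csv(outdir / f"freq_{safe}.tsv", sep="\t")
            kl_logo_data(ms.freq).to_csv(
                outdir / f"logo_{safe}.tsv", sep="\t", index=False
            )
    pd.DataFrame(lrows).to_csv(
        outdir / "length_distributions.tsv", sep="\t", index=False
    )
    (outdir / "run_log.txt").write_text("\n".join(result.log) + "\n")
    (outdir / "config.json").write_text(
        json.dumps(
            {
                "mhc_class": result.config.mhc_class.value,
                "length_min": result.config.length_min,
                "length_max": result.config.length_max,
                "trash_threshold": result.config.trash_threshold,
                "min_logo_peptides": result.config.min_logo_peptides,
            },
            indent=1,
        )
    )
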
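"""End-to-end orchestration of the episplicing analysis.

Thin glue over the stage modules: annotation preparation, per-comparison
DEU/DHM annotation and epispliced-gene calling, cross-comparison flank
consolidation, and the per-mark classification / attribution workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation_io import (
    ExonRecord,
    FlankRecord,
    TSSRecord,
    collect_flanks,
    exclude_tss_proximal,
    load_annotation,
)
from .classify_interpret import (
    ClassifierConfig,
    ClassifierReport,
    RBPSelection,
    select_rbps,
    shap_attribution,
    train_evaluate,
)
from .deu_flanks import (
    annotate_flanks_with_deu,
    assign_deu_scores,
    load_deu_table,
    min_read_filter,
)
from .dhm_flanks import annotate_flanks_with_dhm, load_dhm_peaks, peak_leak_filter
from .episplicing_caller import (
    ComparisonFlankSets,
    EpispliceCall,
    GeneScoreTable,
    build_gene_tables,
    call_epispliced,
    consolidate_flank_sets,
    flank_sets_from_calls,
)
from .rbp_matrix import BindingMatrix, build_feature_matrix, default_rbp_panel


@dataclass
class AnnotationBundle:
    """Prepared annotation: all supported exons, TSS set, candidates, flanks."""

    exons_all: list[ExonRecord]
    tss: list[TSSRecord]
    candidates: list[ExonRecord]
    flanks: list[FlankRecord]
    tss_window: int
    flank_size: int


def prepare_annotation(
    gff3_path: str | Path,
    tsl_max: int = 3,
    tss_window: int = 200,
    flank_size: int = 200,
) -> AnnotationBundle:
    """Load a GFF3 and derive TSS-filtered candidate exons and their flanks."""
    exons, tss = load_annotation(gff3_path, tsl_max=tsl_max)
    candidates = exclude_tss_proximal(exons, tss, window=tss_window)
    flanks = collect_flanks(candidates, flank_size=flank_size)
    return AnnotationBundle(
        exons_all=exons,
        tss=tss,
        candidates=candidates,
        flanks=flanks,
        tss_window=tss_window,
        flank_size=flank_size,
    )


@dataclass
class ComparisonResult:
    """Everything one pairwise comparison produced."""

    calls: list[EpispliceCall]
    tables: dict[tuple[str, str], GeneScoreTable]
    flank_sets: dict[str, ComparisonFlankSets] = field(default_factory=dict)


def run_comparison(
    bundle: AnnotationBundle,
    deu_paths: Sequence[str | Path],
    dhm_paths: Mapping[str, str | Path],
    deu_threshold: float = 0.2,
    fdr_max: float = 0.05,
    min_reads: int | None = None,
    min_cover_frac: float = 0.5,
    r_min: float = 0.5,
    min_flanks: int = 3,
) -> ComparisonResult:
    """Annotate flanks with DEU and per-mark DHM scores and call genes.

    ``deu_paths`` may mix SE and MXE tables; ``dhm_paths`` maps each histone
    mark to its MANorm-style peak table.  ``min_reads`` enables the
    junction-read support filter used in the validation workflow.
    """
    records = []
    for path in deu_paths:
        records.extend(load_deu_table(path))
    if min_reads is not None:
        records = min_read_filter(records, min_reads)
    score_map = assign_deu_scores(
        bundle.candidates, records, deu_threshold=deu_threshold, fdr_max=fdr_max
    )
    deu_ann = annotate_flanks_with_deu(bundle.flanks, score_map, deu_threshold)

    tables: dict[tuple[str, str], GeneScoreTable] = {}
    for mark, path in dhm_paths.items():
        peaks = load_dhm_peaks(path, mark, fdr_max=fdr_max)
        eligible = peak_leak_filter(
            peaks,
            bundle.exons_all,
            bundle.tss,
            window=bundle.tss_window,
            min_cover_frac=min_cover_frac,
        )
        dhm_ann = annotate_flanks_with_dhm(
            [a.flank for a in deu_ann], eligible, mark
        )
        for gene, table in build_gene_tables(deu_ann, dhm_ann, mark).items():
            tables[(gene, mark)] = table

    calls = call_epispliced(
        tables, r_min=r_min, fdr_max=fdr_max, min_flanks=min_flanks
    )
    marks = sorted({mark for _, mark in tables})
    flank_sets = {
        mark: flank_sets_from_calls(calls, tables, mark) for mark in marks
    }
    return ComparisonResult(calls=calls, tables=tables, flank_sets=flank_sets)


def consolidate_mark(
    results: Sequence[ComparisonResult],
    mark: str,
    control_frac: float = 0.7,
) -> tuple[set[str], set[str]]:
    """Epispliced and control flank sets for one mark across comparisons."""
    per_comp = [
        r.flank_sets.get(mark, ComparisonFlankSets(set(), set(), set()))
        for r in results
    ]
    return consolidate_flank_sets(per_comp, control_frac=control_frac)


@dataclass
class MarkClassification:
    """Classifier, attribution and RBP selection output for one mark."""

    matrix: BindingMatrix
    report: ClassifierReport
    shap_values: pd.DataFrame
    shap_summary: pd.DataFrame
    selection: RBPSelection


def classify_mark(
    events,
    epi_flanks: set[str],
    control_flanks: set[str],
    mark: str = "",
    rbp_panel: Sequence[str] | None = None,
    config: ClassifierConfig | None = None,
    z_min: float = 2.0,
    top_k: int = 10,
    expansion_r_min: float = 0.7,
    fdr_max: float = 0.05,
) -> MarkClassification:
    """Build the matrix, train/evaluate, attribute, and select RBP sets."""
    config = config or ClassifierConfig()
    panel = list(rbp_panel) if rbp_panel is not None else default_rbp_panel()
    matrix = build_feature_matrix(events, epi_flanks, control_flanks, panel, z_min=z_min)
    report = train_evaluate(matrix, config, keep_models=True)
    shap_values, shap_summary = shap_attribution(report, matrix)
    selection = select_rbps(
        shap_summary,
        matrix,
        mark=mark,
        top_k=top_k,
        r_min=expansion_r_min,
        fdr_max=fdr_max,
    )
    return MarkClassification(
        matrix=matrix,
        report=report,
        shap_values=shap_values,
        shap_summary=shap_summary,
        selection=selection,
    )
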
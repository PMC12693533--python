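"""Gene-wise DEU-DHM correlation and epispliced-gene calling.

For every gene with at least one qualifying splicing event, the absolute DEU
and DHM scores of its candidate-exon flanks (zero-imputed DHM included) are
Pearson-correlated per histone mark.  Genes with R >= 0.5 at BH-FDR < 0.05,
whose differential peaks sit only on alternative-exon flanks, are
"epispliced"; genes with alternative exons but no differential peak on any
mark are "non-epispliced"; everything else is unclassified.  Flank sets from
several pairwise comparisons are consolidated into one epispliced class and
one control class (flanks non-epispliced in at least 70% of the comparisons
in which their gene was testable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import exon_id_of_flank
from .deu_flanks import DEUAnnotation
from .dhm_flanks import DHMAnnotation

logger = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.5
DEFAULT_FDR_MAX = 0.05
DEFAULT_MIN_FLANKS = 3
DEFAULT_CONTROL_FRAC = 0.7

LABEL_EPISPLICED = "epispliced"
LABEL_NON_EPISPLICED = "non_epispliced"
LABEL_UNCLASSIFIED = "unclassified"


@dataclass
class GeneScoreTable:
    """Ordered per-gene flank score vectors for one histone mark.

    ``flanks`` holds (flank_id, abs_deu, abs_dhm) triples; scores are
    absolute values, with zero-imputed DHM entries included.
    """

    gene_id: str
    mark: str
    flanks: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if not self.flanks:
            raise ValueError("GeneScoreTable requires at least one flank")
        for _, deu, dhm in self.flanks:
            if deu < 0 or dhm < 0:
                raise ValueError("scores must be absolute values")

    @property
    def abs_deu(self) -> np.ndarray:
        return np.array([f[1] for f in self.flanks], dtype=float)

    @property
    def abs_dhm(self) -> np.ndarray:
        return np.array([f[2] for f in self.flanks], dtype=float)


@dataclass
class GeneCorrelation:
    gene_id: str
    mark: str
    n_flanks: int
    pearson_r: float = math.nan
    p_raw: float = math.nan
    excluded_reason: str | None = None


@dataclass
class EpispliceCall:
    """Per-(gene, mark) episplicing decision."""

    gene_id: str
    mark: str
    pearson_r: float
    p_raw: float
    p_fdr: float
    label: str
    epispliced_exon_ids: set[str] = field(default_factory=set)
    n_flanks: int = 0
    excluded_reason: str | None = None


def build_gene_tables(
    deu_annotations: Sequence[DEUAnnotation],
    dhm_annotations: Sequence[DHMAnnotation],
    mark: str,
) -> dict[str, GeneScoreTable]:
    """Assemble per-gene score tables for one mark from flank annotations.

    The flank universe is every DEU-annotated, non-clipped flank; DHM scores
    default to 0 for flanks missing from ``dhm_annotations``.
    """
    dhm_by_flank = {a.flank.flank_id: a.dhm_score for a in dhm_annotations}
    per_gene: dict[str, list[tuple[str, float, float]]] = {}
    for ann in deu_annotations:
        if ann.flank.clipped:
            continue
        fid = ann.flank.flank_id
        per_gene.setdefault(ann.flank.exon.gene_id, []).append(
            (fid, abs(ann.deu_score), abs(dhm_by_flank.get(fid, 0.0)))
        )
    return {
        gene: GeneScoreTable(gene_id=gene, mark=mark, flanks=sorted(rows))
        for gene, rows in per_gene.items()
    }


def gene_correlation(
    table: GeneScoreTable, min_flanks: int = DEFAULT_MIN_FLANKS
) -> GeneCorrelation:
    """Pearson correlation of a gene's |DEU| and |DHM| flank vectors.

    Genes with fewer than ``min_flanks`` flanks, or zero variance in either
    vector, are excluded with a reason instead of propagating NaN.
    """
    n = len(table.flanks)
    out = GeneCorrelation(gene_id=table.gene_id, mark=table.mark, n_flanks=n)
    if n < min_flanks:
        out.excluded_reason = "too_few_flanks"
        return out
    x, y = table.abs_deu, table.abs_dhm
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        out.excluded_reason = "zero_variance"
        return out
    r, p = stats.pearsonr(x, y)
    out.pearson_r, out.p_raw = float(r), float(p)
    return out


def call_epispliced(
    tables: Mapping[tuple[str, str], GeneScoreTable],
    r_min: float = DEFAULT_R_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_flanks: int = DEFAULT_MIN_FLANKS,
    all_marks_clear: bool = True,
) -> list[EpispliceCall]:
    """Label every (gene, mark) of one pairwise comparison.

    ``tables`` maps (gene_id, mark) to the gene's score table for that mark;
    BH-FDR runs per mark across the tested genes of the comparison.  A gene
    is epispliced for a mark when R >= ``r_min``, adjusted p < ``fdr_max``
    and every flank with a non-zero DHM score also has a non-zero DEU score
    (differential peaks confined to alternative-exon flanks).  A gene with
    at least one alternative exon whose flanks carry no DHM score - across
    all marks when ``all_marks_clear``, else for the mark at hand - is
    non-epispliced; the rest are unclassified.
    """
    by_mark: dict[str, list[GeneScoreTable]] = {}
    for (gene, mark), table in tables.items():
        if gene != table.gene_id or mark != table.mark:
            raise ValueError("tables key does not match table identity")
        by_mark.setdefault(mark, []).append(table)

    # gene-level facts used by the non-epispliced rule
    genes = sorted({g for g, _ in tables})
    has_alt = {g: False for g in genes}
    dhm_clear: dict[str, dict[str, bool]] = {g: {} for g in genes}
    for (gene, mark), table in tables.items():
        if any(deu > 0 for _, deu, _ in table.flanks):
            has_alt[gene] = True
        dhm_clear[gene][mark] = all(dhm == 0 for _, _, dhm in table.flanks)

    calls: list[EpispliceCall] = []
    for mark in sorted(by_mark):
        mark_tables = sorted(by_mark[mark], key=lambda t: t.gene_id)
        corrs = [gene_correlation(t, min_flanks) for t in mark_tables]
        tested = [c for c in corrs if c.excluded_reason is None]
        p_fdr: dict[str, float] = {}
        if tested:
            adjusted = multipletests([c.p_raw for c in tested], method="fdr_bh")[1]
            p_fdr = {c.gene_id: float(q) for c, q in zip(tested, adjusted)}

        for table, corr in zip(mark_tables, corrs):
            gene = table.gene_id
            clear = (
                all(dhm_clear[gene].values())
                if all_marks_clear
                else dhm_clear[gene].get(mark, True)
            )
            q = p_fdr.get(gene, math.nan)
            alt_only = all(deu > 0 for _, deu, dhm in table.flanks if dhm > 0)
            if (
                corr.excluded_reason is None
                and corr.pearson_r >= r_min
                and q < fdr_max
                and alt_only
                and not dhm_clear[gene][mark]
            ):
                label = LABEL_EPISPLICED
            elif has_alt[gene] and clear:
                label = LABEL_NON_EPISPLICED
            else:
                label = LABEL_UNCLASSIFIED
            exon_ids: set[str] = set()
            if label in (LABEL_EPISPLICED, LABEL_NON_EPISPLICED):
                exon_ids = {
                    exon_id_of_flank(fid) for fid, deu, _ in table.flanks if deu > 0
                }
            calls.append(
                EpispliceCall(
                    gene_id=gene,
                    mark=mark,
                    pearson_r=corr.pearson_r,
                    p_raw=corr.p_raw,
                    p_fdr=q,
                    label=label,
                    epispliced_exon_ids=exon_ids,
                    n_flanks=corr.n_flanks,
                    excluded_reason=corr.excluded_reason,
                )
            )
    return calls


@dataclass
class ComparisonFlankSets:
    """Flank classes produced by one pairwise comparison for one mark.

    ``testable`` is the set of flank ids of genes that entered the analysis
    in this comparison; when omitted it defaults to ``epispliced | control``.
    """

    epispliced: set[str]
    non_epispliced: set[str]
    testable: set[str] | None = None

    def testable_set(self) -> set[str]:
        return self.testable if self.testable is not None else self.epispliced | self.non_epispliced


def flank_sets_from_calls(
    calls: Sequence[EpispliceCall],
    tables: Mapping[tuple[str, str], GeneScoreTable],
    mark: str,
    alternative_only: bool = True,
) -> ComparisonFlankSets:
    """Extract per-comparison flank classes for one mark from caller output.

    Alternative-exon flanks (non-zero DEU) of epispliced/non-epispliced genes
    form the two classes; every flank of a gene present in the comparison is
    testable.
    """
    epi: set[str] = set()
    nonepi: set[str] = set()
    testable: set[str] = set()
    for call in calls:
        if call.mark != mark:
            continue
        table = tables.get((call.gene_id, mark))
        if table is None:
            continue
        fids = [
            fid for fid, deu, _ in table.flanks if (deu > 0 or not alternative_only)
        ]
        testable.update(fid for fid, _, _ in table.flanks)
        if call.label == LABEL_EPISPLICED:
            epi.update(fids)
        elif call.label == LABEL_NON_EPISPLICED:
            nonepi.update(fids)
    return ComparisonFlankSets(epispliced=epi, non_epispliced=nonepi, testable=testable)


def consolidate_flank_sets(
    comparisons: Sequence[ComparisonFlankSets],
    control_frac: float = DEFAULT_CONTROL_FRAC,
) -> tuple[set[str], set[str]]:
    """Merge per-comparison flank classes into disjoint epi/control sets.

    The epispliced set is the union over comparisons; a control flank must
    be called non-epispliced in at least ceil(control_frac * n_testable)
    of the comparisons in which its gene was testable.  Overlap is resolved
    in favor of the epispliced class.
    """
    if not comparisons:
        raise ValueError("at least one comparison is required")
    if not 0 < control_frac <= 1:
        raise ValueError("control_frac must be in (0, 1]")
    epi: set[str] = set()
    nonepi_counts: dict[str, int] = {}
    testable_counts: dict[str, int] = {}
    for comp in comparisons:
        epi |= comp.epispliced
        for fid in comp.non_epispliced:
            nonepi_counts[fid] = nonepi_counts.get(fid, 0) + 1
        for fid in comp.testable_set():
            testable_counts[fid] = testable_counts.get(fid, 0) + 1
    control = {
        fid
        for fid, n in nonepi_counts.items()
        if n >= math.ceil(control_frac * testable_counts.get(fid, len(comparisons)))
    }
    return epi, control - epi
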
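"""Differential exon usage (DEU) ingestion and flank scoring.

Consumes rMATS-style skipped-exon (SE) and mutually-exclusive-exon (MXE)
junction-count tables.  The DEU score of an exon is its inclusion-level
difference (delta PSI, in [-1, 1]); exons with |dPSI| >= 0.2 at FDR < 0.05
are alternative exons, all other candidate exons of the same genes score 0,
and exon scores are extrapolated onto both flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import ExonRecord, FlankRecord
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_DEU_THRESHOLD = 0.2
DEFAULT_FDR_MAX = 0.05
DEFAULT_MIN_READS = 10

_SE_COORD_COLS = ("exonStart_0base", "exonEnd")
_MXE_COORD_COLS = ("1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base", "2ndExonEnd")
_COUNT_COLS = ("IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2")


@dataclass(frozen=True)
class DEURecord:
    """One exon-level differential-usage event from an rMATS-style table."""

    exon_interval: GenomicInterval
    gene_id: str
    event_type: str  # "SE" | "MXE"
    delta_psi: float
    p_value: float
    fdr: float
    inc_reads: int
    skip_reads: int

    def __post_init__(self) -> None:
        if abs(self.delta_psi) > 1 + 1e-9:
            raise ValueError(f"|delta_psi| must be <= 1, got {self.delta_psi}")
        if self.inc_reads < 0 or self.skip_reads < 0:
            raise ValueError("junction read counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return self.inc_reads + self.skip_reads

    @property
    def key(self) -> tuple[str, int, int, str, str]:
        iv = self.exon_interval
        return (iv.chrom, iv.start, iv.end, iv.strand, self.gene_id)


@dataclass(frozen=True)
class DEUAnnotation:
    """A flank carrying the DEU score extrapolated from its exon."""

    flank: FlankRecord
    deu_score: float
    is_alternative: bool


def _sum_counts(cell: object) -> int:
    """Sum an rMATS comma-separated per-replicate count field."""
    if pd.isna(cell):
        return 0
    return sum(int(x) for x in str(cell).split(",") if x != "")


def load_deu_table(path: str | Path, event_type: str | None = None) -> list[DEURecord]:
    """Parse an rMATS SE/MXE junction-count table into DEU records.

    The dialect is auto-detected from the coordinate columns unless
    ``event_type`` is given.  rMATS coordinates (0-based start, 1-based end)
    already match the internal half-open convention and pass through.  MXE
    events expand into one record per constituent exon with opposite-signed
    delta PSI (the two exons' inclusion fractions are complementary).  Rows
    with zero supporting junction reads are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if event_type is None:
        if all(c in df.columns for c in _MXE_COORD_COLS):
            event_type = "MXE"
        elif all(c in df.columns for c in _SE_COORD_COLS):
            event_type = "SE"
        else:
            raise ValueError(f"unrecognized rMATS column layout in {path}")
    records: list[DEURecord] = []
    for idx, row in df.iterrows():
        inc = _sum_counts(row["IJC_SAMPLE_1"]) + _sum_counts(row["IJC_SAMPLE_2"])
        skip = _sum_counts(row["SJC_SAMPLE_1"]) + _sum_counts(row["SJC_SAMPLE_2"])
        if inc + skip == 0:
            logger.warning("row %s of %s has no supporting junction reads; dropped", idx, path)
            continue
        common = dict(
            gene_id=str(row["GeneID"]),
            event_type=event_type,
            p_value=float(row["PValue"]),
            fdr=float(row["FDR"]),
            inc_reads=inc,
            skip_reads=skip,
        )
        chrom = str(row["chr"])
        strand = str(row["strand"])
        dpsi = float(row["IncLevelDifference"])
        if event_type == "SE":
            records.append(
                DEURecord(
                    exon_interval=GenomicInterval(
                        chrom, int(row["exonStart_0base"]), int(row["exonEnd"]), strand
                    ),
                    delta_psi=dpsi,
                    **common,
                )
            )
        else:  # MXE: inclusion of the 1st exon implies exclusion of the 2nd
            records.append(
                DEURecord(
                    exon_interval=GenomicInterval(
                        chrom, int(row["1stExonStart_0base"]), int(row["1stExonEnd"]), strand
                    ),
                    delta_psi=dpsi,
                    **common,
                )
            )
            records.append(
                DEURecord(
                    exon_interval=GenomicInterval(
                        chrom, int(row["2ndExonStart_0base"]), int(row["2ndExonEnd"]), strand
                    ),
                    delta_psi=-dpsi,
                    **common,
                )
            )
    return records


def min_read_filter(
    records: Iterable[DEURecord], min_reads: int = DEFAULT_MIN_READS
) -> list[DEURecord]:
    """Keep events supported by at least ``min_reads`` junction reads in total."""
    return [r for r in records if r.total_reads >= min_reads]


def assign_deu_scores(
    candidates: Sequence[ExonRecord],
    records: Sequence[DEURecord],
    deu_threshold: float = DEFAULT_DEU_THRESHOLD,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> dict[tuple, float]:
    """Map candidate-exon keys to DEU scores.

    An exon matching a qualifying event (|dPSI| >= threshold, FDR < fdr_max)
    scores its delta PSI; the remaining candidate exons of the same genes
    score 0; exons of genes without any qualifying event are absent.
    Matching requires exact coordinate identity; +/-1 bp near-misses are
    rejected with a warning.  When several qualifying records hit one exon
    the maximum-|dPSI| record wins (ties logged, larger signed dPSI kept).
    """
    qualifying: dict[tuple, DEURecord] = {}
    for rec in records:
        if abs(rec.delta_psi) < deu_threshold or rec.fdr >= fdr_max:
            continue
        prev = qualifying.get(rec.key)
        if prev is None:
            qualifying[rec.key] = rec
        else:
            a, b = abs(rec.delta_psi), abs(prev.delta_psi)
            if a == b and rec.delta_psi != prev.delta_psi:
                logger.warning("conflicting equal-|dPSI| records for exon %s", rec.key)
            if (a, rec.delta_psi) > (b, prev.delta_psi):
                qualifying[rec.key] = rec

    candidate_keys = {e.key for e in candidates}
    all_record_keys = {r.key for r in records}
    matched_genes = {key[4] for key in qualifying if key in candidate_keys}

    scores: dict[tuple, float] = {}
    for exon in candidates:
        if exon.gene_id not in matched_genes:
            continue
        rec = qualifying.get(exon.key)
        if rec is not None:
            scores[exon.key] = rec.delta_psi
        else:
            c, s, e, st, g = exon.key
            for ds, de in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                if (c, s + ds, e + de, st, g) in all_record_keys:
                    logger.warning(
                        "exon %s near-misses a DEU record by 1 bp; not matched",
                        exon.exon_id,
                    )
                    break
            scores[exon.key] = 0.0
    return scores


def annotate_flanks_with_deu(
    flanks: Iterable[FlankRecord],
    score_map: Mapping[tuple, float],
    deu_threshold: float = DEFAULT_DEU_THRESHOLD,
) -> list[DEUAnnotation]:
    """Extrapolate exon DEU scores onto their flanks.

    Both flanks of a scored exon carry the exon's score; flanks of exons
    absent from ``score_map`` (genes without a qualifying event) are omitted.
    """
    annotations = []
    for flank in flanks:
        score = score_map.get(flank.exon.key)
        if score is None:
            continue
        annotations.append(
            DEUAnnotation(
                flank=flank,
                deu_score=score,
                is_alternative=abs(score) >= deu_threshold,
            )
        )
    return annotations
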
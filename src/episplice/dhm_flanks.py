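"""Differential histone modification (DHM) peaks and flank annotation.

Consumes MANorm-style differential-peak tables.  The DHM score of a peak is
its M-value (log2 fold change of normalized read density between the two
conditions).  Peaks common to both conditions are discarded, peaks must pass
the FDR cut, and "peak-leak" filtering removes (a) peaks touching any exon
within 200 bp of a TSS (treated as transcription-initiation signal) and
(b) peak-to-exon annotations where the peak covers less than half of the
exon.  Each flank then receives the M-value of the overlapping peak with the
largest |M|, or 0 when no peak remains (zero imputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotation_io import ExonRecord, FlankRecord, TSSRecord, tss_proximal_exons
from .intervals import GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)

HISTONE_MARKS = ("H3K27ac", "H3K27me3", "H3K36me3", "H3K9me3", "H3K4me3")

DEFAULT_FDR_MAX = 0.05
DEFAULT_MIN_COVER_FRAC = 0.5
DEFAULT_TSS_WINDOW = 200


@dataclass(frozen=True)
class DHMPeak:
    """One differential ChIP-seq peak with its M-value score."""

    interval: GenomicInterval
    mark: str
    m_value: float
    p_value: float
    fdr: float
    is_common: bool = False

    def __post_init__(self) -> None:
        if self.mark not in HISTONE_MARKS:
            raise ValueError(f"unknown histone mark {self.mark!r}")


@dataclass(frozen=True)
class DHMAnnotation:
    """A flank's DHM score for one mark (0 when no differential peak)."""

    flank: FlankRecord
    mark: str
    dhm_score: float


def load_dhm_peaks(
    path: str | Path,
    mark: str,
    fdr_max: float = DEFAULT_FDR_MAX,
    coords: str = "manorm",
) -> list[DHMPeak]:
    """Parse a MANorm-style peak table into filtered DHM peaks.

    Requires columns chr/start/end, m_value, p_value and a peak_group column
    whose value contains "common" for peaks present in both conditions.  An
    ``fdr`` column is used when present, otherwise p-values are BH-adjusted
    within the file.  Common peaks and peaks at FDR >= ``fdr_max`` are
    removed.  ``coords="manorm"`` treats start as 1-based closed (the MANorm
    .xls dialect); ``coords="bed"`` as 0-based half-open.
    """
    if mark not in HISTONE_MARKS:
        raise ValueError(f"unknown histone mark {mark!r}")
    if coords not in ("manorm", "bed"):
        raise ValueError("coords must be 'manorm' or 'bed'")
    df = pd.read_csv(path, sep="\t")
    required = {"chr", "start", "end", "m_value", "p_value", "peak_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} lacks columns {sorted(missing)}")
    if len(df) == 0:
        return []
    if "fdr" in df.columns:
        fdr = df["fdr"].to_numpy(float)
    else:
        fdr = multipletests(df["p_value"].to_numpy(float), method="fdr_bh")[1]
    offset = 1 if coords == "manorm" else 0
    peaks = []
    for i, row in enumerate(df.itertuples(index=False)):
        is_common = "common" in str(row.peak_group).lower()
        if is_common or fdr[i] >= fdr_max:
            continue
        peaks.append(
            DHMPeak(
                interval=GenomicInterval(str(row.chr), int(row.start) - offset, int(row.end)),
                mark=mark,
                m_value=float(row.m_value),
                p_value=float(row.p_value),
                fdr=float(fdr[i]),
                is_common=False,
            )
        )
    return peaks


def peak_leak_filter(
    peaks: Sequence[DHMPeak],
    exons: Sequence[ExonRecord],
    tss: Sequence[TSSRecord],
    window: int = DEFAULT_TSS_WINDOW,
    min_cover_frac: float = DEFAULT_MIN_COVER_FRAC,
) -> dict[tuple, list[DHMPeak]]:
    """Per-exon map of peaks eligible to annotate that exon's flanks.

    ``exons`` must include the TSS-proximal exons removed from the candidate
    set (they are needed to recognize transcription-initiation peaks).  A
    peak overlapping any exon within ``window`` bp of a TSS is discarded
    globally; a peak annotates a candidate exon's flanks only when its
    overlap with that exon covers at least ``min_cover_frac`` of the exon's
    length (inclusive).
    """
    proximal = tss_proximal_exons(exons, tss, window)
    proximal_idx = IntervalIndex((e.interval, e) for e in proximal)
    proximal_keys = {e.key for e in proximal}

    retained = [
        p for p in peaks if not p.is_common and not proximal_idx.query_interval(p.interval)
    ]
    peak_idx = IntervalIndex((p.interval, p) for p in retained)

    eligible: dict[tuple, list[DHMPeak]] = {}
    for exon in exons:
        if exon.key in proximal_keys:
            continue
        hits = []
        for peak in peak_idx.query_interval(exon.interval):
            cover = peak.interval.intersection_len(exon.interval)
            if cover >= min_cover_frac * exon.interval.length:
                hits.append(peak)
        eligible[exon.key] = sorted(hits, key=lambda p: (p.interval.start, p.interval.end))
    return eligible


def _best_peak(candidates: list[DHMPeak]) -> DHMPeak | None:
    """Max-|M| peak; ties broken by smaller FDR, then leftmost start."""
    if not candidates:
        return None
    return min(candidates, key=lambda p: (-abs(p.m_value), p.fdr, p.interval.start))


def annotate_flanks_with_dhm(
    flanks: Iterable[FlankRecord],
    peaks: Mapping[tuple, Sequence[DHMPeak]] | Sequence[DHMPeak],
    mark: str,
) -> list[DHMAnnotation]:
    """Score each flank with the strongest overlapping eligible peak.

    ``peaks`` is either the per-exon eligibility map from
    :func:`peak_leak_filter` or a flat peak list (applied to every flank).
    A peak must intersect the flank by >= 1 bp to contribute; flanks with no
    overlapping peak score 0.
    """
    if mark not in HISTONE_MARKS:
        raise ValueError(f"unknown histone mark {mark!r}")
    per_exon = isinstance(peaks, Mapping)
    flat_idx = None
    if not per_exon:
        flat_idx = IntervalIndex((p.interval, p) for p in peaks)

    annotations = []
    for flank in flanks:
        if per_exon:
            pool = [
                p
                for p in peaks.get(flank.exon.key, ())
                if p.interval.intersection_len(flank.interval) > 0
            ]
        else:
            pool = flat_idx.query_interval(flank.interval)
        best = _best_peak(pool)
        annotations.append(
            DHMAnnotation(flank=flank, mark=mark, dhm_score=best.m_value if best else 0.0)
        )
    return annotations
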
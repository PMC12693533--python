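"""Gene-annotation ingestion and candidate-exon selection.

Reads a Gencode-style GFF3, keeps exons of well-supported transcripts
(transcript support level, TSL, 1-3 by default), removes exons within a
fixed window of any annotated transcription start site (TSS, taken from
TSL 1-5 transcripts), and extracts the +/-200 bp flanks of the surviving
candidate exons.  TSS-proximal exons are excluded so that chromatin signal
tied to transcription initiation is not mistaken for splicing-associated
signal.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_TSL_MAX = 3
DEFAULT_TSS_WINDOW = 200
DEFAULT_FLANK_SIZE = 200

#: attribute keys probed for the transcript support level, in order
_TSL_KEYS = ("transcript_support_level", "tsl")


@dataclass(frozen=True)
class TSSRecord:
    """Strand-aware first transcribed base of a transcript (0-based)."""

    chrom: str
    pos: int
    transcript_id: str = ""


@dataclass(frozen=True)
class ExonRecord:
    """A deduplicated exon with its gene linkage and best support level."""

    interval: GenomicInterval
    gene_id: str
    transcript_ids: frozenset[str]
    tsl: int

    def __post_init__(self) -> None:
        if not 1 <= self.tsl <= 5:
            raise ValueError(f"tsl must be in 1..5, got {self.tsl}")
        if not self.transcript_ids:
            raise ValueError("exon must belong to at least one transcript")

    @property
    def key(self) -> tuple[str, int, int, str, str]:
        iv = self.interval
        return (iv.chrom, iv.start, iv.end, iv.strand, self.gene_id)

    @property
    def exon_id(self) -> str:
        iv = self.interval
        return f"{self.gene_id}|{iv.chrom}:{iv.start}-{iv.end}:{iv.strand}"


@dataclass(frozen=True)
class FlankRecord:
    """One fixed-width flank of a candidate exon.

    ``side`` is genomic orientation (left/right of the exon on the reference);
    ``side_tx`` is the transcriptional 5'/3' label derived from the strand.
    Flanks clipped at a contig edge are flagged and dropped from downstream
    scoring by default.
    """

    interval: GenomicInterval
    exon: ExonRecord
    side: str  # "left" | "right"
    side_tx: str  # "5prime" | "3prime"
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        adjacent = (
            self.interval.end == self.exon.interval.start
            if self.side == "left"
            else self.interval.start == self.exon.interval.end
        )
        if not adjacent:
            raise ValueError("flank must share one boundary with its exon")

    @property
    def flank_id(self) -> str:
        return f"{self.exon.exon_id}|{'L' if self.side == 'left' else 'R'}"


def exon_id_of_flank(flank_id: str) -> str:
    """Strip the side suffix from a flank id."""
    return flank_id.rsplit("|", 1)[0]


def _transcript_tsl(feature: gffutils.Feature) -> int | None:
    for key in _TSL_KEYS:
        if key in feature.attributes:
            raw = feature.attributes[key][0].split()[0]
            try:
                return int(raw)
            except ValueError:
                return None
    return None


def load_annotation(
    gff3_path: str | Path, tsl_max: int = DEFAULT_TSL_MAX
) -> tuple[list[ExonRecord], list[TSSRecord]]:
    """Parse a GFF3 into candidate exons and a TSS catalogue.

    Exons are kept when they belong to at least one transcript with
    TSL <= ``tsl_max`` and are deduplicated by (chrom, start, end, strand,
    gene_id); ``tsl`` is the minimum over all supporting transcripts.  The
    TSS list covers every transcript with TSL 1-5 regardless of ``tsl_max``.
    Transcripts without a parseable TSL attribute are skipped with a warning.
    """
    path = str(gff3_path)
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return [], []
    except Exception as exc:  # malformed file: surface the offending content
        raise ValueError(f"malformed GFF3 {path!r}: {exc}") from exc

    tsl_by_tx: dict[str, int] = {}
    gene_by_tx: dict[str, str] = {}
    tss: list[TSSRecord] = []
    seen_tss: set[tuple[str, int]] = set()
    for ftype in ("transcript", "mRNA"):
        for tx in db.features_of_type(ftype):
            tsl = _transcript_tsl(tx)
            if tsl is None or not 1 <= tsl <= 5:
                logger.warning(
                    "transcript %s has no usable TSL attribute; skipped", tx.id
                )
                continue
            tx_id = tx.attributes.get("transcript_id", [tx.id])[0]
            tsl_by_tx[tx_id] = tsl
            gene_by_tx[tx_id] = tx.attributes.get("gene_id", [""])[0]
            if tx.end < tx.start:
                raise ValueError(
                    f"malformed coordinates for transcript {tx.id} "
                    f"({tx.seqid}:{tx.start}-{tx.end})"
                )
            pos = tx.start - 1 if tx.strand != "-" else tx.end - 1
            if (tx.seqid, pos) not in seen_tss:
                seen_tss.add((tx.seqid, pos))
                tss.append(TSSRecord(chrom=tx.seqid, pos=pos, transcript_id=tx_id))

    merged: dict[tuple[str, int, int, str, str], tuple[set[str], int]] = {}
    for exon in db.features_of_type("exon"):
        if exon.end < exon.start:
            raise ValueError(
                f"malformed coordinates for exon {exon.id} "
                f"({exon.seqid}:{exon.start}-{exon.end})"
            )
        parents = exon.attributes.get("transcript_id", exon.attributes.get("Parent", []))
        supporters = [p for p in parents if p in tsl_by_tx]
        if not supporters:
            continue
        gene_id = exon.attributes.get("gene_id", [""])[0] or gene_by_tx[supporters[0]]
        key = (exon.seqid, exon.start - 1, exon.end, exon.strand or ".", gene_id)
        txs, best = merged.get(key, (set(), 6))
        txs.update(supporters)
        best = min(best, *(tsl_by_tx[p] for p in supporters))
        merged[key] = (txs, best)

    exons = [
        ExonRecord(
            interval=GenomicInterval(chrom=c, start=s, end=e, strand=st),
            gene_id=g,
            transcript_ids=frozenset(txs),
            tsl=best,
        )
        for (c, s, e, st, g), (txs, best) in sorted(merged.items())
        if best <= tsl_max
    ]
    return exons, tss


def exclude_tss_proximal(
    exons: Sequence[ExonRecord],
    tss: Sequence[TSSRecord],
    window: int = DEFAULT_TSS_WINDOW,
) -> list[ExonRecord]:
    """Drop exons with any base within ``window`` bp (inclusive) of a TSS.

    Distance is exon-boundary-to-TSS (0 when the TSS falls inside the exon);
    the window is symmetric around each TSS.  Idempotent and order-preserving.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_chrom: dict[str, list[int]] = {}
    for rec in tss:
        by_chrom.setdefault(rec.chrom, []).append(rec.pos)
    for positions in by_chrom.values():
        positions.sort()

    kept = []
    for exon in exons:
        iv = exon.interval
        positions = by_chrom.get(iv.chrom, [])
        # any TSS in [start - window, end - 1 + window]?
        lo = bisect_left(positions, iv.start - window)
        hi = bisect_right(positions, iv.end - 1 + window)
        if lo == hi:
            kept.append(exon)
    return kept


def tss_proximal_exons(
    exons: Sequence[ExonRecord],
    tss: Sequence[TSSRecord],
    window: int = DEFAULT_TSS_WINDOW,
) -> list[ExonRecord]:
    """Complement of :func:`exclude_tss_proximal` over the same input."""
    kept = {e.key for e in exclude_tss_proximal(exons, tss, window)}
    return [e for e in exons if e.key not in kept]


def extract_flanks(
    exon: ExonRecord, flank_size: int = DEFAULT_FLANK_SIZE
) -> tuple[FlankRecord | None, FlankRecord]:
    """Left and right flanks of an exon in genomic orientation.

    Left flank is [start - size, start), right flank is [end, end + size).
    Strand only relabels the transcriptional side (left is 5' on '+', 3' on
    '-'); coordinates are never strand-flipped.  A left flank truncated by
    the contig start is flagged ``clipped`` (``None`` when the exon starts at
    position 0 and no left flank exists at all).
    """
    if flank_size <= 0:
        raise ValueError("flank_size must be positive")
    iv = exon.interval
    left_start = max(0, iv.start - flank_size)
    clipped = left_start > iv.start - flank_size
    if iv.start == 0:
        logger.warning("exon %s starts at contig position 0; no left flank", exon.exon_id)
        left = None
    else:
        left = FlankRecord(
            interval=GenomicInterval(iv.chrom, left_start, iv.start, iv.strand),
            exon=exon,
            side="left",
            side_tx="5prime" if iv.strand != "-" else "3prime",
            clipped=clipped,
        )
        if clipped:
            logger.warning("left flank of %s clipped at contig start", exon.exon_id)
    right = FlankRecord(
        interval=GenomicInterval(iv.chrom, iv.end, iv.end + flank_size, iv.strand),
        exon=exon,
        side="right",
        side_tx="3prime" if iv.strand != "-" else "5prime",
        clipped=False,
    )
    return left, right


def collect_flanks(
    exons: Iterable[ExonRecord],
    flank_size: int = DEFAULT_FLANK_SIZE,
    drop_clipped: bool = True,
) -> list[FlankRecord]:
    """Flanks of all exons, dropping clipped ones by default."""
    flanks: list[FlankRecord] = []
    for exon in exons:
        for flank in extract_flanks(exon, flank_size):
            if flank is None or (drop_clipped and flank.clipped):
                continue
            flanks.append(flank)
    return flanks


def write_bed6(records: Iterable[FlankRecord | ExonRecord], path: str | Path) -> None:
    """Write exons or flanks as BED6 (name = gene_id|exon|side for flanks)."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, FlankRecord):
                iv, name = rec.interval, rec.flank_id
            else:
                iv, name = rec.interval, rec.exon_id
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
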
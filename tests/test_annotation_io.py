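"""Candidate-exon selection: TSL filtering, TSS exclusion, flank extraction."""

from __future__ import annotations

import numpy as np
import pytest

from episplice.annotation_io import (
    ExonRecord,
    TSSRecord,
    collect_flanks,
    exclude_tss_proximal,
    extract_flanks,
    load_annotation,
)
from episplice.intervals import GenomicInterval

# 1-based closed GFF3: 4 genes, mixed TSL, one transcript without a TSL
FIXTURE_GFF3 = "\n".join(
    [
        "##gff-version 3",
        "##sequence-region chrT 1 20000",
        "chrT\tt\tgene\t1001\t2300\t.\t+\t.\tID=G1;gene_id=G1",
        "chrT\tt\ttranscript\t1001\t2300\t.\t+\t.\tID=G1.t1;Parent=G1;gene_id=G1;transcript_id=G1.t1;transcript_support_level=1",
        "chrT\tt\texon\t1001\t1100\t.\t+\t.\tID=G1.t1.e1;Parent=G1.t1;gene_id=G1;transcript_id=G1.t1",
        "chrT\tt\texon\t1601\t1700\t.\t+\t.\tID=G1.t1.e2;Parent=G1.t1;gene_id=G1;transcript_id=G1.t1",
        "chrT\tt\texon\t2201\t2300\t.\t+\t.\tID=G1.t1.e3;Parent=G1.t1;gene_id=G1;transcript_id=G1.t1",
        # second transcript of G1: TSL 4, shares e2 and adds its own exon
        "chrT\tt\ttranscript\t1001\t2900\t.\t+\t.\tID=G1.t2;Parent=G1;gene_id=G1;transcript_id=G1.t2;transcript_support_level=4",
        "chrT\tt\texon\t1601\t1700\t.\t+\t.\tID=G1.t2.e1;Parent=G1.t2;gene_id=G1;transcript_id=G1.t2",
        "chrT\tt\texon\t2801\t2900\t.\t+\t.\tID=G1.t2.e2;Parent=G1.t2;gene_id=G1;transcript_id=G1.t2",
        "chrT\tt\tgene\t5001\t5700\t.\t-\t.\tID=G2;gene_id=G2",
        "chrT\tt\ttranscript\t5001\t5700\t.\t-\t.\tID=G2.t1;Parent=G2;gene_id=G2;transcript_id=G2.t1;transcript_support_level=3",
        "chrT\tt\texon\t5001\t5100\t.\t-\t.\tID=G2.t1.e1;Parent=G2.t1;gene_id=G2;transcript_id=G2.t1",
        "chrT\tt\texon\t5601\t5700\t.\t-\t.\tID=G2.t1.e2;Parent=G2.t1;gene_id=G2;transcript_id=G2.t1",
        # TSL 5: exons never candidates, TSS still counts
        "chrT\tt\tgene\t8001\t8700\t.\t+\t.\tID=G3;gene_id=G3",
        "chrT\tt\ttranscript\t8001\t8700\t.\t+\t.\tID=G3.t1;Parent=G3;gene_id=G3;transcript_id=G3.t1;transcript_support_level=5",
        "chrT\tt\texon\t8001\t8100\t.\t+\t.\tID=G3.t1.e1;Parent=G3.t1;gene_id=G3;transcript_id=G3.t1",
        # no TSL attribute: transcript skipped entirely
        "chrT\tt\tgene\t12001\t12100\t.\t+\t.\tID=G4;gene_id=G4",
        "chrT\tt\ttranscript\t12001\t12100\t.\t+\t.\tID=G4.t1;Parent=G4;gene_id=G4;transcript_id=G4.t1",
        "chrT\tt\texon\t12001\t12100\t.\t+\t.\tID=G4.t1.e1;Parent=G4.t1;gene_id=G4;transcript_id=G4.t1",
    ]
)


@pytest.fixture(scope="module")
def fixture_paths(tmp_path_factory):
    d = tmp_path_factory.mktemp("gff")
    path = d / "fixture.gff3"
    path.write_text(FIXTURE_GFF3 + "\n")
    empty = d / "empty.gff3"
    empty.write_text("##gff-version 3\n")
    return path, empty


class TestLoadAnnotation:
    def test_tsl_filter_and_dedup_match_hand_count(self, fixture_paths):
        """TSL<=3 exons: G1 has 3 (shared e2 merged, TSL4-only exon out), G2 has 2."""
        exons, tss = load_annotation(fixture_paths[0])
        assert len(exons) == 5
        by_gene = {}
        for e in exons:
            by_gene.setdefault(e.gene_id, []).append(e)
        assert len(by_gene["G1"]) == 3
        assert len(by_gene["G2"]) == 2
        assert "G3" not in by_gene
        # shared exon keeps both supporters and the minimum TSL
        shared = next(e for e in by_gene["G1"] if e.interval.start == 1600)
        assert shared.transcript_ids == {"G1.t1", "G1.t2"}
        assert shared.tsl == 1

    def test_tsl4_exons_excluded_but_tss_retained(self, fixture_paths):
        """Poorly supported transcripts still contribute transcription starts."""
        exons, tss = load_annotation(fixture_paths[0])
        positions = {(t.chrom, t.pos) for t in tss}
        assert ("chrT", 8000) in positions  # TSL 5 transcript's TSS
        assert not any(e.gene_id == "G3" for e in exons)
        # G2 is '-' stranded: TSS at its rightmost base (0-based 5699)
        assert ("chrT", 5699) in positions
        # transcript without a TSL contributes neither exons nor a TSS
        assert not any(e.gene_id == "G4" for e in exons)
        assert ("chrT", 12000) not in positions

    def test_empty_gff3_yields_empty_lists(self, fixture_paths):
        exons, tss = load_annotation(fixture_paths[1])
        assert exons == [] and tss == []

    def test_malformed_coordinates_raise(self, tmp_path):
        bad = tmp_path / "bad.gff3"
        bad.write_text("##gff-version 3\nchrT\tt\tgene\tnotanumber\t10\t.\t+\t.\tID=X\n")
        with pytest.raises(ValueError, match="malformed"):
            load_annotation(bad)


def _exon(chrom, start, end, strand="+", gene="G", tsl=1):
    return ExonRecord(
        interval=GenomicInterval(chrom, start, end, strand),
        gene_id=gene,
        transcript_ids=frozenset({"t"}),
        tsl=tsl,
    )


class TestTSSExclusion:
    def test_exon_on_tss_excluded_boundary_inclusive(self):
        exon = _exon("c", 1000, 1100)
        on_tss = [TSSRecord("c", 1000)]
        at_200 = [TSSRecord("c", 800)]  # distance from start exactly 200
        at_201 = [TSSRecord("c", 799)]
        assert exclude_tss_proximal([exon], on_tss) == []
        assert exclude_tss_proximal([exon], at_200) == []
        assert exclude_tss_proximal([exon], at_201) == [exon]

    def test_empty_tss_list_retains_all(self):
        exons = [_exon("c", i * 1000, i * 1000 + 100) for i in range(1, 6)]
        assert exclude_tss_proximal(exons, []) == exons

    def test_matches_brute_force_on_random_fixture(self):
        """50 exons / 5 TSS: retained set equals the all-pairs distance scan."""
        rng = np.random.default_rng(42)
        exons = []
        for _ in range(50):
            chrom = f"c{rng.integers(2)}"
            s = int(rng.integers(500, 50000))
            exons.append(_exon(chrom, s, s + int(rng.integers(50, 300))))
        tss = [
            TSSRecord(f"c{rng.integers(2)}", int(rng.integers(0, 50000))) for _ in range(5)
        ]
        got = exclude_tss_proximal(exons, tss, window=200)

        def dist(e, t):
            if e.interval.chrom != t.chrom:
                return float("inf")
            if e.interval.start <= t.pos < e.interval.end:
                return 0
            return min(abs(t.pos - e.interval.start), abs(t.pos - (e.interval.end - 1)))

        expected = [e for e in exons if all(dist(e, t) > 200 for t in tss)]
        assert got == expected

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(3)
        exons = [
            _exon("c", int(s), int(s) + 80)
            for s in rng.choice(np.arange(300, 30000, 100), 30, replace=False)
        ]
        tss = [TSSRecord("c", int(p)) for p in rng.integers(0, 30000, 4)]
        once = exclude_tss_proximal(exons, tss)
        assert exclude_tss_proximal(once, tss) == once
        reordered = exclude_tss_proximal(exons[::-1], tss)
        assert sorted(e.key for e in reordered) == sorted(e.key for e in once)


class TestFlanks:
    def test_plus_strand_coordinates(self):
        left, right = extract_flanks(_exon("c", 1000, 1100), 200)
        assert (left.interval.start, left.interval.end) == (800, 1000)
        assert (right.interval.start, right.interval.end) == (1100, 1300)
        assert left.side_tx == "5prime" and right.side_tx == "3prime"

    def test_minus_strand_same_intervals_swapped_labels(self):
        left, right = extract_flanks(_exon("c", 1000, 1100, strand="-"), 200)
        assert (left.interval.start, left.interval.end) == (800, 1000)
        assert left.side_tx == "3prime" and right.side_tx == "5prime"

    def test_clipped_left_flank_flagged_and_dropped(self):
        exon = _exon("c", 150, 300)
        left, right = extract_flanks(exon, 200)
        assert left.clipped and left.interval.start == 0
        assert collect_flanks([exon], 200) == [right]

    def test_flanks_adjacent_and_disjoint_from_exon(self):
        """Flank/exon union is contiguous; no flank overlaps its own exon."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            s = int(rng.integers(400, 10000))
            exon = _exon("c", s, s + int(rng.integers(30, 500)))
            left, right = extract_flanks(exon, 200)
            assert left.interval.intersection_len(exon.interval) == 0
            assert right.interval.intersection_len(exon.interval) == 0
            assert left.interval.end == exon.interval.start
            assert right.interval.start == exon.interval.end
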
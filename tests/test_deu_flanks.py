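"""DEU ingestion: rMATS dialects, score assignment, flank extrapolation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from episplice.annotation_io import ExonRecord, collect_flanks
from episplice.deu_flanks import (
    DEURecord,
    annotate_flanks_with_deu,
    assign_deu_scores,
    load_deu_table,
    min_read_filter,
)
from episplice.intervals import GenomicInterval


def _se_table(rows):
    cols = [
        "ID", "GeneID", "geneSymbol", "chr", "strand", "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
        "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
        "IncFormLen", "SkipFormLen", "PValue", "FDR",
        "IncLevel1", "IncLevel2", "IncLevelDifference",
    ]
    return pd.DataFrame(rows, columns=cols)


def _exon(start, end, gene="G1", strand="+"):
    return ExonRecord(
        interval=GenomicInterval("chr1", start, end, strand),
        gene_id=gene,
        transcript_ids=frozenset({"t"}),
        tsl=1,
    )


def _rec(start, end, dpsi, fdr=0.01, gene="G1", inc=20, skip=20, strand="+"):
    return DEURecord(
        exon_interval=GenomicInterval("chr1", start, end, strand),
        gene_id=gene,
        event_type="SE",
        delta_psi=dpsi,
        p_value=fdr / 2,
        fdr=fdr,
        inc_reads=inc,
        skip_reads=skip,
    )


class TestLoadTable:
    def test_se_coordinates_pass_through_as_half_open(self, tmp_path):
        df = _se_table(
            [[0, "G1", "G1", "chr1", "+", 999, 1100, 800, 900, 1300, 1400,
              "10,12", "5,6", "8,9", "9,8", 198, 98, 1e-5, 1e-4,
              "0.66,0.67", "0.47,0.53", 0.17]]
        )
        path = tmp_path / "SE.txt"
        df.to_csv(path, sep="\t", index=False)
        (rec,) = load_deu_table(path)
        assert (rec.exon_interval.start, rec.exon_interval.end) == (999, 1100)
        assert rec.event_type == "SE"
        assert rec.inc_reads == 10 + 12 + 8 + 9
        assert rec.skip_reads == 5 + 6 + 9 + 8

    def test_mxe_expands_to_opposite_signed_exons(self, tmp_path):
        """The two mutually exclusive exons' PSI values are complementary,
        so the inclusion difference of exon 2 is minus that of exon 1.

        Verified on a toy junction table: PSI = inc/(inc+skip) per exon, and
        the junction reads supporting inclusion of exon 1 are exactly those
        supporting exclusion of exon 2.
        """
        # toy counts, condition 1 vs 2: exon1 inc/skip = 30/10 vs 10/30
        psi1_c1, psi1_c2 = 30 / 40, 10 / 40
        dpsi1 = psi1_c1 - psi1_c2
        # exon2's inclusion reads are exon1's skip reads and vice versa
        psi2_c1, psi2_c2 = 10 / 40, 30 / 40
        assert psi2_c1 - psi2_c2 == pytest.approx(-dpsi1)

        cols = [
            "ID", "GeneID", "geneSymbol", "chr", "strand",
            "1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base", "2ndExonEnd",
            "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
            "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
            "IncFormLen", "SkipFormLen", "PValue", "FDR",
            "IncLevel1", "IncLevel2", "IncLevelDifference",
        ]
        df = pd.DataFrame(
            [[0, "G1", "G1", "chr1", "+", 1000, 1100, 2000, 2080, 500, 600,
              3000, 3100, "30", "10", "10", "30", 198, 178, 1e-6, 1e-5,
              "0.75", "0.25", round(dpsi1, 3)]],
            columns=cols,
        )
        path = tmp_path / "MXE.txt"
        df.to_csv(path, sep="\t", index=False)
        first, second = load_deu_table(path)
        assert first.delta_psi == pytest.approx(dpsi1, abs=1e-3)
        assert second.delta_psi == pytest.approx(-dpsi1, abs=1e-3)
        assert first.exon_interval.start == 1000
        assert second.exon_interval.start == 2000

    def test_empty_table_and_zero_read_rows(self, tmp_path):
        empty = tmp_path / "empty.txt"
        _se_table([]).to_csv(empty, sep="\t", index=False)
        assert load_deu_table(empty) == []
        zero = _se_table(
            [[0, "G1", "G1", "chr1", "+", 10, 20, 1, 5, 30, 40,
              "0,0", "0,0", "0,0", "0,0", 98, 98, 0.5, 0.9, "0,0", "0,0", 0.0]]
        )
        path = tmp_path / "zero.txt"
        zero.to_csv(path, sep="\t", index=False)
        assert load_deu_table(path) == []


class TestAssignScores:
    def test_qualifying_exon_scores_delta_psi(self):
        exon = _exon(100, 200)
        scores = assign_deu_scores([exon], [_rec(100, 200, 0.25, fdr=0.01)])
        assert scores == {exon.key: 0.25}

    def test_subthreshold_exon_in_qualifying_gene_scores_zero(self):
        alt, weak = _exon(100, 200), _exon(500, 600)
        scores = assign_deu_scores(
            [alt, weak], [_rec(100, 200, 0.25), _rec(500, 600, 0.10)]
        )
        assert scores[alt.key] == 0.25
        assert scores[weak.key] == 0.0

    def test_gene_without_qualifying_event_absent(self):
        exon = _exon(100, 200)
        assert assign_deu_scores([exon], [_rec(100, 200, 0.5, fdr=0.2)]) == {}
        assert assign_deu_scores([exon], [_rec(100, 200, 0.1, fdr=0.01)]) == {}

    def test_conflicting_records_keep_max_abs_dpsi(self):
        exon = _exon(100, 200)
        recs = [_rec(100, 200, 0.3), _rec(100, 200, -0.6)]
        assert assign_deu_scores([exon], recs)[exon.key] == -0.6
        assert assign_deu_scores([exon], recs[::-1])[exon.key] == -0.6

    def test_order_invariance_on_random_records(self):
        rng = np.random.default_rng(5)
        exons = [_exon(1000 * i, 1000 * i + 100, gene=f"G{i % 4}") for i in range(1, 20)]
        recs = []
        for e in exons:
            for _ in range(rng.integers(0, 3)):
                recs.append(
                    _rec(
                        e.interval.start,
                        e.interval.end,
                        float(rng.uniform(-0.9, 0.9)),
                        fdr=float(rng.choice([0.01, 0.2])),
                        gene=e.gene_id,
                    )
                )
        base = assign_deu_scores(exons, recs)
        perm = list(recs)
        rng.shuffle(perm)
        assert assign_deu_scores(exons, perm) == base


class TestReadFilterAndFlanks:
    @pytest.mark.parametrize(
        "inc,skip,kept", [(6, 4, True), (5, 4, False), (10, 0, True), (0, 9, False)]
    )
    def test_min_read_boundary(self, inc, skip, kept):
        rec = _rec(1, 2, 0.3, inc=inc, skip=skip)
        assert (min_read_filter([rec], 10) == [rec]) is kept

    def test_min_reads_zero_is_identity(self):
        recs = [_rec(1, 2, 0.3, inc=0, skip=1), _rec(5, 6, 0.4, inc=100, skip=0)]
        assert min_read_filter(recs, 0) == recs

    def test_extrapolation_copies_score_to_both_flanks(self):
        exons = [_exon(1000, 1100), _exon(2000, 2100)]
        flanks = collect_flanks(exons, 200)
        score_map = {exons[0].key: 0.25, exons[1].key: 0.0}
        anns = annotate_flanks_with_deu(flanks, score_map)
        assert len(anns) == 4  # 2n flanks for n scored exons
        by_exon = {}
        for a in anns:
            by_exon.setdefault(a.flank.exon.key, []).append(a)
        assert [a.deu_score for a in by_exon[exons[0].key]] == [0.25, 0.25]
        assert all(a.is_alternative for a in by_exon[exons[0].key])
        assert [a.deu_score for a in by_exon[exons[1].key]] == [0.0, 0.0]
        assert not any(a.is_alternative for a in by_exon[exons[1].key])

    def test_alternative_flank_count_is_twice_alternative_exons(self):
        rng = np.random.default_rng(9)
        exons = [_exon(2000 * i, 2000 * i + 100) for i in range(1, 30)]
        score_map = {
            e.key: float(rng.choice([0.0, 0.3, -0.5, 0.1])) for e in exons
        }
        anns = annotate_flanks_with_deu(collect_flanks(exons), score_map)
        n_alt_exons = sum(1 for v in score_map.values() if abs(v) >= 0.2)
        assert sum(a.is_alternative for a in anns) == 2 * n_alt_exons
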
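"""Synthetic upstream datasets with planted ground truth.

Emulates every file class the pipeline consumes - GFF3 annotation,
rMATS-style SE/MXE junction tables, MANorm-style differential-peak tables
per histone mark, RBPmap-style motif-hit tables and eCLIP peaks in
narrowPeak - on two synthetic contigs, with a manifest of planted truth:

* epispliced genes per mark: alternative exons (|dPSI| drawn >= 0.2, small
  FDR) whose flanks carry differential peaks with |M| proportional to
  |dPSI| plus Gaussian noise;
* non-epispliced genes: alternative exons and no differential peaks on any
  mark (plus mutually-exclusive-exon genes exercising the MXE dialect);
* distractors: common-only peaks, peaks failing the FDR cut, sub-threshold
  dPSI events, and peaks placed on non-alternative exons (which must leave
  the gene unclassified);
* transcription-initiation decoys: long peaks spanning a TSS-proximal exon,
  which the peak-leak filter must discard;
* constitutive exons with differential peaks (the ~DEU&DHM class);
* a planted discriminative RBP set whose motif-hit Z-scores are shifted by
  ``dz_plant`` on epispliced flanks, including one collinear pair to
  exercise correlation expansion, and eCLIP peaks at planted flanks over a
  uniform background.

Everything is deterministic per seed.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dhm_flanks import HISTONE_MARKS
from .rbp_matrix import MotifModel, default_rbp_panel

RNA = ("A", "C", "G", "U")

@dataclass(frozen=True)
class SceneConfig:
    """Scene parameters; defaults are the study conditions of the pipeline.

    Sized for single-CPU runs of a few minutes: 300 genes on 2 contigs,
    5 marks, a 160-RBP panel, ~2,500 candidate flanks.
    """

    n_genes: int = 300
    exons_per_gene: tuple[int, int] = (4, 7)
    seed: int = 17
    contigs: tuple[str, ...] = ("chrS1", "chrS2")
    gene_spacing: tuple[int, int] = (2000, 6000)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (600, 1500)
    flank_size: int = 200
    marks: tuple[str, ...] = HISTONE_MARKS
    focus_mark: str = "H3K36me3"
    comparisons: tuple[tuple[str, str], ...] = (
        ("H1", "mesoderm"),
        ("H1", "neuronal"),
        ("ectoderm", "mesoderm"),
    )
    # gene-class sizes
    n_epi_per_mark: int = 8
    n_nonepi: int = 50
    n_distractor_per_flavor: int = 6
    n_mxe: int = 4
    n_constitutive_dhm: int = 15
    n_low_tsl: int = 12
    n_tss_leak: int = 3
    alt_exons_per_gene: tuple[int, int] = (2, 3)
    # effect sizes and noise
    dpsi_range: tuple[float, float] = (0.25, 0.75)
    subthreshold_dpsi: tuple[float, float] = (0.04, 0.15)
    dhm_slope: float = 2.5
    dhm_noise_sd: float = 0.3
    peak_ext: int = 250
    # RBP binding
    n_rbps: int = 160
    n_planted_rbps: int = 10
    dz_plant: float = 2.0
    bg_z_mean: float = 1.5
    bg_z_sd: float = 0.8
    site_prob: float = 0.6
    max_sites: int = 3
    collinear_pair: bool = True
    # eCLIP
    n_eclip_background: int = 1500
    n_bg_peaks_per_mark: int = 40

@dataclass
class GeneTruth:
    """Planted structure and class of one synthetic gene."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, genomic order
    tsl: int
    second_tx: bool
    label: str = "null"
    mark: str | None = None
    alt_idx: tuple[int, ...] = ()
    offtarget_idx: int | None = None
    constit_idx: int | None = None
    tss_leak: bool = False
    decoy_idx: int | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss_exon_idx(self) -> int:
        return 0 if self.strand == "+" else len(self.exons) - 1

    def candidate_indices(self) -> list[int]:
        return [i for i in range(len(self.exons)) if i != self.tss_exon_idx]

    def exon_id(self, i: int) -> str:
        s, e = self.exons[i]
        return f"{self.gene_id}|{self.chrom}:{s}-{e}:{self.strand}"

    def flank_ids(self, i: int) -> tuple[str, str]:
        eid = self.exon_id(i)
        return f"{eid}|L", f"{eid}|R"

    def flank_coords(self, i: int, flank_size: int) -> dict[str, tuple[int, int]]:
        s, e = self.exons[i]
        return {"L": (s - flank_size, s), "R": (e, e + flank_size)}

@dataclass
class SyntheticTruth:
    """Manifest of everything planted; determines expected pipeline labels."""

    config: SceneConfig
    genes: dict[str, GeneTruth]
    contig_lengths: dict[str, int]
    epi_genes: dict[str, list[str]] = field(default_factory=dict)
    nonepi_genes: list[str] = field(default_factory=list)
    planted_rbps: list[str] = field(default_factory=list)
    collinear_pair: tuple[str, str] | None = None
    eclip_rbps: tuple[str, str] = ("", "")
    epi_flanks: dict[str, list[str]] = field(default_factory=dict)
    control_flanks: list[str] = field(default_factory=list)
    constitutive_flanks: list[str] = field(default_factory=list)
    events: dict[int, list[dict]] = field(default_factory=dict)
    eclip_truth: list[dict] = field(default_factory=list)

    @property
    def genome_bp(self) -> int:
        return sum(self.contig_lengths.values())

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "contig_lengths": self.contig_lengths,
            "genes": {g: asdict(t) for g, t in self.genes.items()},
            "epi_genes": self.epi_genes,
            "nonepi_genes": self.nonepi_genes,
            "planted_rbps": self.planted_rbps,
            "collinear_pair": self.collinear_pair,
            "eclip_rbps": list(self.eclip_rbps),
            "epi_flanks": self.epi_flanks,
            "control_flanks": self.control_flanks,
            "constitutive_flanks": self.constitutive_flanks,
            "events": {str(k): v for k, v in self.events.items()},
            "eclip_truth": self.eclip_truth,
        }
        return json.dumps(payload, indent=1, default=list)

# ---------------------------------------------------------------------------
# annotation

def generate_annotation(
    config: SceneConfig, seed: int | None = None
) -> tuple[str, dict[str, GeneTruth], dict[str, int]]:
    """Lay out non-overlapping genes on the synthetic contigs.

    Returns the GFF3 text (1-based closed, Gencode-style attributes), the
    per-gene truth skeleton, and the contig lengths.  Roughly one gene in
    five carries a second, poorly-supported (TSL 4) transcript over the same
    exons to exercise exon deduplication; ``n_low_tsl`` genes have only
    TSL 4-5 support and must never yield candidate exons.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = config.exons_per_gene
    cursors = {c: 1000 for c in config.contigs}
    genes: dict[str, GeneTruth] = {}
    low_tsl_ids = set(
        f"GENE{i:04d}" for i in rng.choice(config.n_genes, size=min(config.n_low_tsl, config.n_genes), replace=False)
    )
    for gi in range(config.n_genes):
        gene_id = f"GENE{gi:04d}"
        chrom = config.contigs[gi % len(config.contigs)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(lo, hi + 1))
        pos = cursors[chrom]
        exons = []
        for k in range(n_exons):
            length = int(rng.integers(*config.exon_len))
            exons.append((pos, pos + length))
            pos += length
            if k < n_exons - 1:
                pos += int(rng.integers(*config.intron_len))
        cursors[chrom] = pos + int(rng.integers(*config.gene_spacing))
        if gene_id in low_tsl_ids:
            tsl = int(rng.integers(4, 6))
            label = "low_tsl"
        else:
            tsl = int(rng.integers(1, 4))
            label = "null"
        genes[gene_id] = GeneTruth(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            tsl=tsl,
            second_tx=bool(rng.random() < 0.2),
            label=label,
        )
    contig_lengths = {c: cursors[c] + 1000 for c in config.contigs}

    lines = ["##gff-version 3"]
    for c in config.contigs:
        lines.append(f"##sequence-region {c} 1 {contig_lengths[c]}")
    for g in genes.values():
        attrs = f"ID={g.gene_id};gene_id={g.gene_id}"
        lines.append(
            f"{g.chrom}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        tx_specs = [(f"{g.gene_id}.t1", g.tsl)]
        if g.second_tx:
            tx_specs.append((f"{g.gene_id}.t2", 4))
        for tx_id, tsl in tx_specs:
            lines.append(
                f"{g.chrom}\tsynth\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tx_id};Parent={g.gene_id};gene_id={g.gene_id};"
                f"transcript_id={tx_id};transcript_support_level={tsl}"
            )
            for k, (s, e) in enumerate(g.exons):
                lines.append(
                    f"{g.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tx_id}.exon{k};Parent={tx_id};gene_id={g.gene_id};transcript_id={tx_id}"
                )
    return "\n".join(lines) + "\n", genes, contig_lengths

def _assign_classes(truth: SyntheticTruth, rng: np.random.Generator) -> None:
    config = truth.config
    k_lo, k_hi = config.alt_exons_per_gene
    eligible = sorted(
        g.gene_id
        for g in truth.genes.values()
        if g.label == "null" and len(g.candidate_indices()) >= 3
    )
    rng.shuffle(eligible)
    need = (
        config.n_epi_per_mark * len(config.marks)
        + config.n_nonepi
        + 4 * config.n_distractor_per_flavor
        + config.n_mxe
        + config.n_constitutive_dhm
    )
    if len(eligible) < need:
        raise ValueError(f"scene too small: {len(eligible)} eligible genes, need {need}")
    it = iter(eligible)

    def take(n: int) -> list[str]:
        return [next(it) for _ in range(n)]

    def set_alt(gene: GeneTruth, k_max_extra: int = 1) -> None:
        cand = gene.candidate_indices()
        k = int(rng.integers(k_lo, min(k_hi, len(cand) - k_max_extra) + 1))
        gene.alt_idx = tuple(sorted(rng.choice(cand, size=max(1, k), replace=False).tolist()))

    truth.epi_genes = {}
    for mark in config.marks:
        ids = take(config.n_epi_per_mark)
        truth.epi_genes[mark] = ids
        for gid in ids:
            gene = truth.genes[gid]
            gene.label = "epi"
            gene.mark = mark
            set_alt(gene)
            spare = [i for i in gene.candidate_indices() if i not in gene.alt_idx]
            if spare and rng.random() < 0.4:
                gene.decoy_idx = int(rng.choice(spare))
    truth.nonepi_genes = take(config.n_nonepi)
    for gid in truth.nonepi_genes:
        gene = truth.genes[gid]
        gene.label = "nonepi"
        set_alt(gene)
    for flavor in ("common", "highfdr", "subthresh", "offtarget"):
        for gid in take(config.n_distractor_per_flavor):
            gene = truth.genes[gid]
            gene.label = f"distractor_{flavor}"
            set_alt(gene)
            if flavor == "offtarget":
                spare = [i for i in gene.candidate_indices() if i not in gene.alt_idx]
                gene.offtarget_idx = int(spare[0]) if spare else None
    for gid in take(config.n_mxe):
        gene = truth.genes[gid]
        gene.label = "mxe"
        cand = gene.candidate_indices()
        gene.alt_idx = tuple(sorted(rng.choice(cand, size=2, replace=False).tolist()))
    for gid in take(config.n_constitutive_dhm):
        gene = truth.genes[gid]
        gene.label = "constitutive_dhm"
        gene.constit_idx = int(rng.choice(gene.candidate_indices()))
    focus_epi = truth.epi_genes[config.focus_mark]
    for gid in focus_epi[: config.n_tss_leak]:
        truth.genes[gid].tss_leak = True

    # flank universes derived from the planted classes
    truth.epi_flanks = {
        mark: sorted(
            fid
            for gid in ids
            for i in truth.genes[gid].alt_idx
            for fid in truth.genes[gid].flank_ids(i)
        )
        for mark, ids in truth.epi_genes.items()
    }
    control_labels = {"nonepi", "mxe", "distractor_common", "distractor_highfdr"}
    truth.control_flanks = sorted(
        fid
        for g in truth.genes.values()
        if g.label in control_labels
        for i in g.alt_idx
        for fid in g.flank_ids(i)
    )
    truth.constitutive_flanks = sorted(
        fid
        for g in truth.genes.values()
        if g.label == "constitutive_dhm"
        for fid in g.flank_ids(g.constit_idx)
    )

# ---------------------------------------------------------------------------
# DEU and DHM tables

def _psi_strings(psi: float, rng: np.random.Generator) -> tuple[str, list[int], list[int]]:
    incs, skips = [], []
    reps = []
    for _ in range(2):
        total = int(rng.integers(15, 60))
        inc = int(round(np.clip(psi + rng.normal(0, 0.02), 0, 1) * total))
        incs.append(inc)
        skips.append(total - inc)
        reps.append(inc / total if total else 0.0)
    return ",".join(f"{r:.3f}" for r in reps), incs, skips

def _se_row(
    gene: GeneTruth, i: int, dpsi: float, p: float, fdr: float, rng: np.random.Generator
) -> dict:
    s, e = gene.exons[i]
    up = gene.exons[i - 1] if i > 0 else (max(0, s - 500), max(1, s - 400))
    dn = gene.exons[i + 1] if i < len(gene.exons) - 1 else (e + 400, e + 500)
    psi1 = float(np.clip(0.5 + dpsi / 2, 0.02, 0.98))
    psi2 = float(np.clip(0.5 - dpsi / 2, 0.02, 0.98))
    lv1, inc1, skip1 = _psi_strings(psi1, rng)
    lv2, inc2, skip2 = _psi_strings(psi2, rng)
    return {
        "GeneID": gene.gene_id,
        "geneSymbol": gene.gene_id,
        "chr": gene.chrom,
        "strand": gene.strand,
        "exonStart_0base": s,
        "exonEnd": e,
        "upstreamES": up[0],
        "upstreamEE": up[1],
        "downstreamES": dn[0],
        "downstreamEE": dn[1],
        "IJC_SAMPLE_1": ",".join(map(str, inc1)),
        "SJC_SAMPLE_1": ",".join(map(str, skip1)),
        "IJC_SAMPLE_2": ",".join(map(str, inc2)),
        "SJC_SAMPLE_2": ",".join(map(str, skip2)),
        "IncFormLen": (e - s) + 98,
        "SkipFormLen": 98,
        "PValue": p,
        "FDR": fdr,
        "IncLevel1": lv1,
        "IncLevel2": lv2,
        "IncLevelDifference": round(dpsi, 3),
    }

def generate_deu_dhm(
    truth: SyntheticTruth, comparison: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate one pairwise comparison's rMATS SE/MXE and MANorm tables.

    Alternative-exon choices are fixed in the truth; effect sizes (dPSI, M)
    are redrawn per comparison.  Epispliced genes receive differential peaks
    only at their alternative exons with |M| = slope * |dPSI| + noise;
    distractor flavors receive common, high-FDR, off-target or long
    TSS-spanning peaks; intergenic background peaks cover no exon and must
    be discarded by the coverage rule.
    """
    config = truth.config
    rng = np.random.default_rng(seed)
    cells = config.comparisons[comparison]
    se_rows: list[dict] = []
    mxe_rows: list[dict] = []
    dhm_rows: dict[str, list[dict]] = {mark: [] for mark in config.marks}
    events: list[dict] = []

    def draw_dpsi() -> float:
        return float(rng.uniform(*config.dpsi_range) * (1 if rng.random() < 0.5 else -1))

    def small_p() -> tuple[float, float]:
        return float(rng.uniform(1e-8, 1e-4)), float(rng.uniform(1e-6, 1e-3))

    def peak_row(chrom: str, s: int, e: int, m: float, p: float, fdr: float, group: str) -> dict:
        return {
            "chr": chrom,
            "start": s + 1,  # MANorm dialect: 1-based closed
            "end": e,
            "summit": (s + e) // 2,
            "m_value": round(m, 4),
            "a_value": round(float(rng.uniform(2, 8)), 4),
            "p_value": p,
            "fdr": fdr,
            "peak_group": group,
        }

    for gene in sorted(truth.genes.values(), key=lambda g: g.gene_id):
        if gene.label in ("null", "low_tsl", "constitutive_dhm"):
            continue
        if gene.label == "mxe":
            dpsi = float(rng.uniform(0.3, 0.6) * (1 if rng.random() < 0.5 else -1))
            p, fdr = small_p()
            i, j = gene.alt_idx
            base = _se_row(gene, i, dpsi, p, fdr, rng)
            s1, e1 = gene.exons[i]
            s2, e2 = gene.exons[j]
            row = {
                k: v
                for k, v in base.items()
                if k not in ("exonStart_0base", "exonEnd")
            }
            row.update(
                {
                    "1stExonStart_0base": s1,
                    "1stExonEnd": e1,
                    "2ndExonStart_0base": s2,
                    "2ndExonEnd": e2,
                }
            )
            mxe_rows.append(row)
            events.append(
                {"gene": gene.gene_id, "exon_id": gene.exon_id(i), "dpsi": dpsi,
                 "deu_cell": cells[0] if dpsi > 0 else cells[1], "kind": "mxe"}
            )
            continue
        subthresh = gene.label == "distractor_subthresh"
        for i in gene.alt_idx:
            if subthresh:
                dpsi = float(
                    rng.uniform(*config.subthreshold_dpsi) * (1 if rng.random() < 0.5 else -1)
                )
            else:
                dpsi = draw_dpsi()
            p, fdr = small_p()
            se_rows.append(_se_row(gene, i, dpsi, p, fdr, rng))
            event = {
                "gene": gene.gene_id,
                "exon_id": gene.exon_id(i),
                "exon_idx": i,
                "dpsi": dpsi,
                "deu_cell": cells[0] if dpsi > 0 else cells[1],
                "kind": gene.label,
            }
            if gene.label == "epi":
                sign = 1 if rng.random() < 0.5 else -1
                m = sign * max(0.25, config.dhm_slope * abs(dpsi) + rng.normal(0, config.dhm_noise_sd))
                s, e = gene.exons[i]
                pp, pf = small_p()
                dhm_rows[gene.mark].append(
                    peak_row(
                        gene.chrom,
                        s - config.peak_ext,
                        e + config.peak_ext,
                        m,
                        pp,
                        pf,
                        f"{cells[0] if m > 0 else cells[1]}_unique",
                    )
                )
                event["m_value"] = m
                event["dhm_cell"] = cells[0] if m > 0 else cells[1]
                event["mark"] = gene.mark
            elif gene.label == "distractor_common":
                s, e = gene.exons[i]
                dhm_rows[config.focus_mark].append(
                    peak_row(gene.chrom, s - config.peak_ext, e + config.peak_ext,
                             float(rng.uniform(1, 3)), *small_p(), "common")
                )
            elif gene.label == "distractor_highfdr":
                s, e = gene.exons[i]
                pp = float(rng.uniform(0.05, 0.5))
                dhm_rows[config.focus_mark].append(
                    peak_row(gene.chrom, s - config.peak_ext, e + config.peak_ext,
                             float(rng.uniform(1, 3)), pp, float(rng.uniform(0.2, 0.8)),
                             f"{cells[0]}_unique")
                )
            events.append(event)
        if gene.decoy_idx is not None:
            p, fdr = small_p()
            dpsi = float(rng.uniform(0.03, 0.12) * (1 if rng.random() < 0.5 else -1))
            se_rows.append(_se_row(gene, gene.decoy_idx, dpsi, p, fdr, rng))
        if gene.label == "distractor_offtarget" and gene.offtarget_idx is not None:
            s, e = gene.exons[gene.offtarget_idx]
            dhm_rows[config.focus_mark].append(
                peak_row(gene.chrom, s - config.peak_ext, e + config.peak_ext,
                         float(rng.uniform(1.5, 3)), *small_p(), f"{cells[0]}_unique")
            )
        if gene.tss_leak:
            # long transcription-initiation peak spanning the TSS-proximal
            # exon and reaching over the neighboring candidate exon
            order = 1 if gene.strand == "+" else -1
            tss_i = gene.tss_exon_idx
            nb_i = tss_i + order
            lo = min(gene.exons[tss_i][0], gene.exons[nb_i][0]) - 100
            hi = max(gene.exons[tss_i][1], gene.exons[nb_i][1]) + config.peak_ext
            dhm_rows[config.focus_mark].append(
                peak_row(gene.chrom, lo, hi, float(rng.uniform(2, 4)), *small_p(),
                         f"{cells[0]}_unique")
            )

    for gene in sorted(truth.genes.values(), key=lambda g: g.gene_id):
        if gene.label != "constitutive_dhm":
            continue
        s, e = gene.exons[gene.constit_idx]
        m = float(rng.uniform(1, 3) * (1 if rng.random() < 0.5 else -1))
        dhm_rows[config.focus_mark].append(
            peak_row(gene.chrom, s - config.peak_ext, e + config.peak_ext, m,
                     *small_p(), f"{cells[0] if m > 0 else cells[1]}_unique")
        )

    # a zero-read decoy row on a null gene (loader must drop it)
    null_genes = [g for g in truth.genes.values() if g.label == "null"]
    if null_genes:
        g0 = null_genes[0]
        row = _se_row(g0, g0.candidate_indices()[0], 0.05, 0.5, 0.9, rng)
        for col in ("IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2"):
            row[col] = "0,0"
        se_rows.append(row)

    # intergenic background peaks: cover no exon, removed by the coverage rule
    for mark in config.marks:
        for _ in range(config.n_bg_peaks_per_mark):
            chrom = config.contigs[int(rng.integers(len(config.contigs)))]
            genes_on = [g for g in truth.genes.values() if g.chrom == chrom]
            g = genes_on[int(rng.integers(len(genes_on)))]
            s = g.end + 600 + int(rng.integers(0, 800))
            dhm_rows[mark].append(
                peak_row(chrom, s, s + int(rng.integers(150, 400)),
                         float(rng.uniform(-3, 3)), *small_p(), f"{cells[0]}_unique")
            )

    se_df = pd.DataFrame(se_rows)
    se_df.insert(0, "ID", range(len(se_df)))
    mxe_df = pd.DataFrame(mxe_rows)
    if len(mxe_df):
        mxe_df.insert(0, "ID", range(len(mxe_df)))
    dhm_dfs = {mark: pd.DataFrame(rows) for mark, rows in dhm_rows.items()}
    truth.events[comparison] = events
    return se_df, mxe_df, dhm_dfs

# ---------------------------------------------------------------------------
# RBP binding and eCLIP

def generate_binding_and_eclip(
    truth: SyntheticTruth,
    seed: int,
    n_rbps: int | None = None,
    dz_plant: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, MotifModel]]:
    """Motif-hit table, eCLIP peaks, and per-RBP motif models.

    Planted RBPs get per-site Z-scores shifted by ``dz_plant`` on the
    epispliced flanks of the focus mark (background Z ~ Normal(1.5, 0.8)
    truncated at 0); the last planted RBP's sites duplicate the first's
    (with small jitter) to create a collinear pair.  eCLIP peaks are placed
    at planted flanks (cells cycling through concordance patterns) plus a
    uniform genomic background.  Planted motifs are AU-rich, the rest drawn
    from a GC-leaning Dirichlet.
    """
    config = truth.config
    rng = np.random.default_rng(seed)
    n_rbps = config.n_rbps if n_rbps is None else n_rbps
    dz = config.dz_plant if dz_plant is None else dz_plant
    panel = default_rbp_panel(n_rbps)
    planted = sorted(rng.choice(panel, size=config.n_planted_rbps, replace=False).tolist())
    truth.planted_rbps = planted
    source, partner = (planted[0], planted[-1]) if config.collinear_pair else (None, None)
    truth.collinear_pair = (source, partner) if config.collinear_pair else None
    truth.eclip_rbps = (planted[0], planted[1])

    fs = config.flank_size
    flank_coords: dict[str, tuple[str, int, int]] = {}
    for g in truth.genes.values():
        for i in range(len(g.exons)):
            coords = g.flank_coords(i, fs)
            left, right = g.flank_ids(i)
            flank_coords[left] = (g.chrom, *coords["L"])
            flank_coords[right] = (g.chrom, *coords["R"])

    epi_focus = set(truth.epi_flanks[config.focus_mark])
    universe = sorted(set(truth.control_flanks) | epi_focus | set(truth.constitutive_flanks))

    hit_rows: list[dict] = []
    partner_cache: dict[str, list[tuple[int, float]]] = {}
    for fid in universe:
        chrom, start, end = flank_coords[fid]
        is_epi = fid in epi_focus
        for rbp in panel:
            if rbp == partner:
                continue
            if rng.random() >= config.site_prob:
                continue
            n_sites = int(rng.integers(1, config.max_sites + 1))
            sites = []
            for _ in range(n_sites):
                z = max(0.0, rng.normal(config.bg_z_mean, config.bg_z_sd))
                if is_epi and rbp in planted:
                    z += dz
                pos = int(rng.integers(start, end - 6))
                sites.append((pos, z))
                kmer = "".join(rng.choice(RNA, size=6))
                hit_rows.append(
                    {"rbp": rbp, "chrom": chrom, "start": pos, "end": pos + 6,
                     "kmer": kmer, "z_score": round(z, 4), "flank_id": fid}
                )
            if rbp == source:
                partner_cache[fid] = sites
    if partner is not None:
        for fid, sites in partner_cache.items():
            chrom, _, _ = flank_coords[fid]
            for pos, z in sites:
                hit_rows.append(
                    {"rbp": partner, "chrom": chrom, "start": pos, "end": pos + 6,
                     "kmer": "".join(rng.choice(RNA, size=6)),
                     "z_score": round(max(0.0, z + rng.normal(0, 0.05)), 4),
                     "flank_id": fid}
                )
    hits = pd.DataFrame(hit_rows).sort_values(["rbp", "chrom", "start"]).reset_index(drop=True)

    # eCLIP: peaks at planted epispliced flanks of the validation comparison,
    # cells cycling so that all three concordance cases arise
    cells = config.comparisons[0]
    eclip_rows: list[dict] = []
    focus_events = [
        ev for ev in truth.events.get(0, []) if ev.get("mark") == config.focus_mark
    ]
    for k, ev in enumerate(focus_events):
        gene = truth.genes[ev["gene"]]
        i = ev["exon_idx"]
        _, right = gene.flank_ids(i)
        chrom, rs, re_ = flank_coords[right]
        rbp = truth.eclip_rbps[k % 2]
        eclip_cell = ev["dhm_cell"] if k % 3 != 2 else (
            cells[0] if ev["dhm_cell"] == cells[1] else cells[1]
        )
        eclip_rows.append(
            {"chrom": chrom, "start": rs + 20, "end": rs + 90,
             "name": f"{rbp}_{eclip_cell}", "score": int(rng.integers(100, 1000)),
             "strand": gene.strand, "signal": round(float(rng.uniform(2, 10)), 3),
             "p": round(float(rng.uniform(3, 30)), 3), "q": round(float(rng.uniform(3, 30)), 3),
             "peak": 35}
        )
        truth.eclip_truth.append(
            {"gene": gene.gene_id, "exon_id": ev["exon_id"], "flank_id": right,
             "rbp": rbp, "eclip_cell": eclip_cell, "deu_cell": ev["deu_cell"],
             "dhm_cell": ev["dhm_cell"]}
        )
    contig_names = list(truth.contig_lengths)
    lengths = np.array([truth.contig_lengths[c] for c in contig_names], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(config.n_eclip_background):
        ci = int(rng.choice(len(contig_names), p=probs))
        chrom = contig_names[ci]
        s = int(rng.integers(0, truth.contig_lengths[chrom] - 60))
        rbp = truth.eclip_rbps[int(rng.integers(2))]
        cell = cells[int(rng.integers(2))]
        eclip_rows.append(
            {"chrom": chrom, "start": s, "end": s + 60, "name": f"{rbp}_{cell}",
             "score": int(rng.integers(100, 1000)), "strand": ".",
             "signal": round(float(rng.uniform(2, 10)), 3),
             "p": round(float(rng.uniform(3, 30)), 3),
             "q": round(float(rng.uniform(3, 30)), 3), "peak": 30}
        )
    # planted flank peaks first, uniform background after (order is part of
    # the manifest contract: truth.eclip_truth aligns with the leading rows)
    eclip = pd.DataFrame(eclip_rows)

    motifs: dict[str, MotifModel] = {}
    for rbp in panel:
        length = int(rng.integers(5, 8))
        if rbp in planted:
            alpha = np.array([4.0, 0.5, 0.5, 4.0])  # AU-rich
        else:
            alpha = np.array([0.7, 2.5, 2.5, 0.7])  # GC-leaning
        pwm = rng.dirichlet(alpha, size=length)
        motifs[rbp] = MotifModel(rbp=rbp, pwm=pwm)
    return hits, eclip, motifs

# ---------------------------------------------------------------------------
# scene orchestration

@dataclass
class SyntheticScene:
    """All generated tables of one scene, in memory, plus the truth manifest."""

    config: SceneConfig
    truth: SyntheticTruth
    gff3_text: str
    deu_se: dict[int, pd.DataFrame]
    deu_mxe: dict[int, pd.DataFrame]
    dhm: dict[int, dict[str, pd.DataFrame]]
    binding_hits: pd.DataFrame
    eclip: pd.DataFrame
    motifs: dict[str, MotifModel]

    def comparison_name(self, i: int) -> str:
        a, b = self.config.comparisons[i]
        return f"comp{i}_{a}_vs_{b}"

    def write(self, out_dir: str | Path) -> Path:
        """Write every file class plus the truth manifest under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "annotation.gff3").write_text(self.gff3_text)
        for i in range(len(self.config.comparisons)):
            comp_dir = out / self.comparison_name(i)
            comp_dir.mkdir(exist_ok=True)
            self.deu_se[i].to_csv(comp_dir / "SE.MATS.JC.txt", sep="\t", index=False)
            if len(self.deu_mxe[i]):
                self.deu_mxe[i].to_csv(comp_dir / "MXE.MATS.JC.txt", sep="\t", index=False)
            for mark, df in self.dhm[i].items():
                df.to_csv(comp_dir / f"dhm_{mark}.tsv", sep="\t", index=False)
        self.binding_hits.to_csv(out / "rbpmap_hits.tsv", sep="\t", index=False)
        with open(out / "eclip.narrowPeak", "w") as fh:
            for row in self.eclip.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.score}\t"
                    f"{row.strand}\t{row.signal}\t{row.p}\t{row.q}\t{row.peak}\n"
                )
        motif_dir = out / "motifs"
        motif_dir.mkdir(exist_ok=True)
        for rbp, model in self.motifs.items():
            with open(motif_dir / f"{rbp}.txt", "w") as fh:
                fh.write("Pos\tA\tC\tG\tU\n")
                for k, row in enumerate(model.pwm, start=1):
                    fh.write(f"{k}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        (out / "truth.json").write_text(self.truth.to_json())
        return out

def generate_scene(config: SceneConfig | None = None) -> SyntheticScene:
    """Generate the full scene deterministically from ``config.seed``."""
    config = config or SceneConfig()
    base = config.seed % (2**31)
    gff3_text, genes, contig_lengths = generate_annotation(config, seed=base)
    truth = SyntheticTruth(config=config, genes=genes, contig_lengths=contig_lengths)
    _assign_classes(truth, np.random.default_rng((base + 1) % (2**31)))
    deu_se, deu_mxe, dhm = {}, {}, {}
    for i in range(len(config.comparisons)):
        se_df, mxe_df, dhm_dfs = generate_deu_dhm(truth, i, seed=(base + 100 + i) % (2**31))
        deu_se[i], deu_mxe[i], dhm[i] = se_df, mxe_df, dhm_dfs
    hits, eclip, motifs = generate_binding_and_eclip(truth, seed=(base + 500) % (2**31))
    return SyntheticScene(
        config=config,
        truth=truth,
        gff3_text=gff3_text,
        deu_se=deu_se,
        deu_mxe=deu_mxe,
        dhm=dhm,
        binding_hits=hits,
        eclip=eclip,
        motifs=motifs,
    )

def binding_events_from_hits(hits: pd.DataFrame):
    """Convert a hit table with a flank_id column into binding events."""
    from .rbp_matrix import BindingEvent

    return [
        BindingEvent(rbp=str(r.rbp), flank_id=str(r.flank_id), z_score=float(r.z_score))
        for r in hits.itertuples(index=False)
    ]

def score_caller(
    calls_by_comparison: Sequence[Sequence],
    truth: SyntheticTruth,
) -> tuple[float, float]:
    """Sensitivity and specificity of epispliced calls against the truth.

    Positives are planted (gene, mark) pairs; negatives are every other
    tested (gene, mark) pair, pooled over comparisons.
    """
    positives = {
        (gid, mark) for mark, ids in truth.epi_genes.items() for gid in ids
    }
    tp = fn = fp = tn = 0
    for calls in calls_by_comparison:
        for call in calls:
            is_pos = (call.gene_id, call.mark) in positives
            is_called = call.label == "epispliced"
            if is_pos and is_called:
                tp += 1
            elif is_pos:
                fn += 1
            elif is_called:
                fp += 1
            else:
                tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec
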
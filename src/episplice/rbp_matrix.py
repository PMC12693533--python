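"""Flanks x RBPs binding-score feature matrix and motif composition.

Motif-scan hits (RBPmap-style, one Z-score per putative binding site) are
reduced to one value per (flank, RBP): the strongest site when its Z-score
reaches the binding threshold (Z >= 2 by default), else 0.  Sub-threshold
events are treated as non-binding; flanks with no predicted site for an RBP
are zero-imputed.  Rows carry the binary epispliced/control class label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import FlankRecord
from .intervals import IntervalIndex

logger = logging.getLogger(__name__)

DEFAULT_Z_MIN = 2.0
DEFAULT_PANEL_SIZE = 160
DEFAULT_EXPANSION_R_MIN = 0.7
DEFAULT_FDR_MAX = 0.05

RNA_ALPHABET = ("A", "C", "G", "U")


class BindingEvent(NamedTuple):
    """One predicted binding site of an RBP inside a flank."""

    rbp: str
    flank_id: str
    z_score: float


def default_rbp_panel(n: int = DEFAULT_PANEL_SIZE) -> list[str]:
    """Synthetic RBP panel names (the study's panel held 160 proteins)."""
    return [f"RBP{i:03d}" for i in range(1, n + 1)]


@dataclass
class BindingMatrix:
    """Thresholded binding scores (rows: flanks, columns: RBP panel).

    ``labels`` is a binary series aligned to the rows (1 = epispliced).
    """

    scores: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.scores.columns.duplicated().any():
            raise ValueError("RBP column names must be unique")
        if self.scores.isna().any().any():
            raise ValueError("matrix must be fully imputed (no missing values)")
        if not self.scores.index.equals(self.labels.index):
            raise ValueError("labels must align with matrix rows")

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())


def build_feature_matrix(
    events: Iterable[BindingEvent],
    epispliced_flanks: Iterable[str],
    control_flanks: Iterable[str],
    rbp_panel: Sequence[str] | None = None,
    z_min: float = DEFAULT_Z_MIN,
) -> BindingMatrix:
    """Reduce binding events to the strongest-site, thresholded matrix.

    Cell value = max Z over the (RBP, flank) events when that max reaches
    ``z_min``, else 0.  Rows are fixed to the labeled flank sets, columns to
    the configured panel, so matrices from different marks stay compatible.
    Events referencing unknown flanks or off-panel RBPs are skipped with a
    warning.
    """
    epi = sorted(set(epispliced_flanks))
    ctrl = sorted(set(control_flanks))
    overlap = set(epi) & set(ctrl)
    if overlap:
        raise ValueError(f"flanks in both classes: {sorted(overlap)[:3]}...")
    rows = epi + ctrl
    panel = list(rbp_panel) if rbp_panel is not None else default_rbp_panel()
    row_pos = {fid: i for i, fid in enumerate(rows)}
    col_pos = {rbp: j for j, rbp in enumerate(panel)}

    values = np.zeros((len(rows), len(panel)))
    n_unknown = 0
    for ev in events:
        i = row_pos.get(ev.flank_id)
        j = col_pos.get(ev.rbp)
        if i is None or j is None:
            n_unknown += 1
            continue
        if ev.z_score > values[i, j]:
            values[i, j] = ev.z_score
    if n_unknown:
        logger.warning("%d binding events referenced unknown flanks/RBPs; skipped", n_unknown)
    values[values < z_min] = 0.0

    scores = pd.DataFrame(values, index=pd.Index(rows, name="flank_id"), columns=panel)
    labels = pd.Series(
        [1] * len(epi) + [0] * len(ctrl), index=scores.index, name="epispliced"
    )
    return BindingMatrix(scores=scores, labels=labels)


def pairwise_pearson(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-pairwise Pearson r and two-sided p (t distribution, n-2 df).

    Constant columns yield NaN r and NaN p.
    """
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 rows for correlation")
    x = df.to_numpy(float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.isclose(np.abs(r), 1.0)] = 0.0
        p[np.isnan(r)] = np.nan
    cols = df.columns
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def rbp_correlation(
    matrix: BindingMatrix | pd.DataFrame,
    r_min: float = DEFAULT_EXPANSION_R_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> pd.DataFrame:
    """RBP-RBP correlation table with BH-FDR significance flags.

    One row per unordered column pair: (rbp_a, rbp_b, r, p, p_fdr,
    significant).  Pairs involving constant columns are never significant.
    BH adjustment runs over the defined p-values of the upper triangle.
    """
    df = matrix.scores if isinstance(matrix, BindingMatrix) else matrix
    r_mat, p_mat = pairwise_pearson(df)
    cols = list(df.columns)
    ia, ib = np.triu_indices(len(cols), k=1)
    rows = pd.DataFrame(
        {
            "rbp_a": [cols[i] for i in ia],
            "rbp_b": [cols[j] for j in ib],
            "r": r_mat.to_numpy()[ia, ib],
            "p": p_mat.to_numpy()[ia, ib],
        }
    )
    rows["p_fdr"] = np.nan
    defined = rows["p"].notna()
    if defined.any():
        rows.loc[defined, "p_fdr"] = multipletests(
            rows.loc[defined, "p"].to_numpy(), method="fdr_bh"
        )[1]
    rows["significant"] = (
        defined & (rows["r"] >= r_min) & (rows["p_fdr"] < fdr_max)
    )
    return rows


@dataclass
class MotifModel:
    """An RBP's RNA binding motif as a PWM and/or consensus string.

    ``pwm`` has shape (length, 4) over the A/C/G/U alphabet with rows
    summing to 1; T in consensus strings is read as U.
    """

    rbp: str
    pwm: np.ndarray | None = None
    consensus: str | None = None

    def __post_init__(self) -> None:
        if self.pwm is None and self.consensus is None:
            raise ValueError("motif needs a PWM or a consensus")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError("PWM must have shape (length, 4)")
            if (self.pwm < -1e-12).any() or (self.pwm > 1 + 1e-12).any():
                raise ValueError("PWM probabilities must lie in [0, 1]")
            if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("PWM rows must sum to 1")


def motif_composition(model: MotifModel) -> float:
    """AU fraction of a motif: mean over positions of P(A) + P(U).

    Falls back to consensus letter counts (T read as U) when no PWM exists.
    """
    if model.pwm is not None:
        return float(model.pwm[:, [0, 3]].sum(axis=1).mean())
    seq = model.consensus.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty consensus")
    return sum(1 for c in seq if c in "AU") / len(seq)


def load_cisbp_pwm(path: str | Path, rbp: str) -> MotifModel:
    """Read a cisBP-style tab PWM (columns Pos, A, C, G, U; T accepted)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().upper().replace("T", "U") for c in df.columns]
    pwm = df[["A", "C", "G", "U"]].to_numpy(float)
    return MotifModel(rbp=rbp, pwm=pwm)


def load_rbpmap_hits(path: str | Path, rbp: str | None = None) -> pd.DataFrame:
    """Read an RBPmap-style hit table (rbp, chrom, start, end, kmer, z_score).

    A missing ``rbp`` column is filled from the argument (per-protein files).
    """
    df = pd.read_csv(path, sep="\t")
    if "rbp" not in df.columns:
        if rbp is None:
            raise ValueError(f"{path} lacks an rbp column and no name was given")
        df = df.assign(rbp=rbp)
    required = {"rbp", "chrom", "start", "end", "z_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hit table {path} lacks columns {sorted(missing)}")
    return df


def map_hits_to_flanks(
    hits: pd.DataFrame, flanks: Sequence[FlankRecord]
) -> list[BindingEvent]:
    """Assign genomic motif hits to every flank they overlap (>= 1 bp)."""
    idx = IntervalIndex((f.interval, f.flank_id) for f in flanks)
    events = []
    for row in hits.itertuples(index=False):
        for fid in idx.query(str(row.chrom), int(row.start), int(row.end)):
            events.append(BindingEvent(rbp=str(row.rbp), flank_id=fid, z_score=float(row.z_score)))
    return events
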
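"""Domestication-selection statistics.

Windowed nucleotide diversity (pi) per group, the wild/cultivated ratio
pi_w/pi_c, top-5% sweep regions (optionally intersected with an external
statistic such as XP-CLR supplied as a per-window track), domestication-
associated SVs (dSVs, >50% overlap with sweeps), highly divergent SVs
(hdSVs, Fisher exact + BH FDR < 0.01), pi-ratio annotation (>= 3), and the
SV-to-expression screen (|log2 fold-change| >= 1.5 in at least one tissue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import Variant
from .simulate import GT_HET, GT_MISSING


@dataclass
class DiversityTrack:
    """Windowed pi for both groups plus the ratio (inf when pi_c == 0 < pi_w)."""

    windows: pd.DataFrame  # chrom, start, end, pi_wild, pi_cult, ratio

    def window_at(self, chrom: str, pos: int) -> Optional[pd.Series]:
        df = self.windows
        hit = df[(df["chrom"] == chrom) & (df["start"] <= pos) & (pos < df["end"])]
        if hit.empty:
            return None
        return hit.iloc[0]


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    n_windows: int


@dataclass
class DivergenceTest:
    sv_id: str
    carriers_wild: int
    non_wild: int
    carriers_cult: int
    non_cult: int
    p_value: float
    q_value: float = math.nan
    hdsv: bool = False


@dataclass
class ExpressionEffect:
    sv_id: str
    gene_id: str
    sv_context: str  # CDS | promoter
    log2_fc: Dict[str, float] = field(default_factory=dict)  # per tissue, cult vs wild
    flagged: bool = False


def _pi_per_site(hap: np.ndarray) -> np.ndarray:
    """Unbiased per-site diversity 2*p*q*n/(n-1) from a 0/1 haplotype matrix."""
    n = hap.shape[0]
    if n < 2:
        raise ValueError("need >= 2 haplotypes per group")
    p = hap.mean(axis=0)
    return 2.0 * p * (1.0 - p) * n / (n - 1)


def nucleotide_diversity(
    positions: np.ndarray,
    hap_wild: np.ndarray,
    hap_cult: np.ndarray,
    seq_length: int,
    window: int = 10_000,
    step: int = 10_000,
    chrom: str = "chr1",
) -> DiversityTrack:
    """Windowed pi for two groups of haplotypes at shared biallelic sites.

    Per-site contribution is 2*p*q*n/(n-1) (monomorphic sites contribute 0),
    summed per window and divided by window length.  Windows tile
    [0, seq_length) with the given step.
    """
    if window < step:
        raise ValueError("window must be >= step")
    positions = np.asarray(positions)
    pw = _pi_per_site(np.asarray(hap_wild))
    pc = _pi_per_site(np.asarray(hap_cult))
    rows = []
    start = 0
    while start < seq_length:
        end = min(start + window, seq_length)
        mask = (positions >= start) & (positions < end)
        length = end - start
        piw = float(pw[mask].sum()) / length
        pic = float(pc[mask].sum()) / length
        if pic > 0:
            ratio = piw / pic
        elif piw > 0:
            ratio = math.inf
        else:
            ratio = math.nan
        rows.append((chrom, start, end, piw, pic, ratio))
        start += step
    return DiversityTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "pi_wild", "pi_cult", "ratio"])
    )


def sweep_regions(
    track: DiversityTrack,
    top_fraction: float = 0.05,
    extra_stat: Optional[pd.Series] = None,
) -> List[SweepRegion]:
    """Windows in the top fraction of the ratio (and of extra_stat when given).

    The top set holds exactly floor(n * top_fraction) windows per statistic,
    ties broken toward the lower genomic coordinate; supplied statistics are
    intersected, and adjacent qualifying windows merge into one region.
    """
    df = track.windows.reset_index(drop=True)
    n = len(df)
    if n < 20:
        raise ValueError("need >= 20 windows for an empirical quantile")
    k = max(1, int(math.floor(n * top_fraction)))

    def top_idx(values: pd.Series) -> set:
        order = sorted(
            (i for i in range(n) if not math.isnan(values.iloc[i])),
            key=lambda i: (-values.iloc[i], df["chrom"].iloc[i], df["start"].iloc[i]),
        )
        return set(order[:k])

    chosen = top_idx(df["ratio"])
    if extra_stat is not None:
        chosen &= top_idx(pd.Series(np.asarray(extra_stat)))
    regions: List[SweepRegion] = []
    for i in sorted(chosen):
        row = df.iloc[i]
        if (
            regions
            and regions[-1].chrom == row["chrom"]
            and regions[-1].end >= row["start"]
        ):
            regions[-1].end = int(row["end"])
            regions[-1].n_windows += 1
        else:
            regions.append(SweepRegion(row["chrom"], int(row["start"]), int(row["end"]), 1))
    return regions


def call_dsv(
    svs: Sequence[Variant],
    sweeps: Sequence[SweepRegion],
    overlap_fraction: float = 0.5,
) -> Dict[str, bool]:
    """dSV flag: strictly more than ``overlap_fraction`` of the SV's reference
    extent falls inside a sweep.  Insertions (zero reference extent) count as
    inside iff their anchor position is inside a sweep."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for r in sweeps:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    flags: Dict[str, bool] = {}
    for v in svs:
        sid = v.id or f"{v.ref_chrom}:{v.ref_start}"
        intervals = by_chrom.get(v.ref_chrom, [])
        if v.ref_len == 0:
            flags[sid] = any(s <= v.ref_start < e for s, e in intervals)
            continue
        ov = sum(
            max(0, min(v.ref_end, e) - max(v.ref_start, s)) for s, e in intervals
        )
        flags[sid] = ov > overlap_fraction * v.ref_len
    return flags


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    t = np.asarray(table)
    if (t < 0).any():
        raise ValueError("negative counts")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-down: q_i = min_{j>=i} p_(j) m / j)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_hdsv(
    matrix: pd.DataFrame,
    groups: Dict[str, str],
    fdr_threshold: float = 0.01,
) -> List[DivergenceTest]:
    """Fisher exact test of carrier counts (wild vs cultivated) per SV site.

    ``matrix`` is sites x accessions with genotype codes (-1 missing, 0 ref,
    1 het, 2 alt); a carrier has at least one alternate allele.  Missing
    genotypes leave the margins.  BH correction runs across all testable
    SVs; hdSV means q < ``fdr_threshold``.  Sites with an empty group after
    missing-call removal are skipped (flagged with p = NaN).
    """
    wild = [a for a in matrix.columns if groups.get(a) == "wild"]
    cult = [a for a in matrix.columns if groups.get(a) == "cultivated"]
    tests: List[DivergenceTest] = []
    for sid, row in matrix.iterrows():
        gw = row[wild]
        gc = row[cult]
        gw = gw[gw != GT_MISSING]
        gc = gc[gc != GT_MISSING]
        cw = int((gw >= GT_HET).sum())
        cc = int((gc >= GT_HET).sum())
        nw, nc = len(gw) - cw, len(gc) - cc
        if len(gw) == 0 or len(gc) == 0:
            tests.append(DivergenceTest(str(sid), cw, nw, cc, nc, math.nan))
            continue
        p = fisher_exact([[cw, cc], [nw, nc]])
        tests.append(DivergenceTest(str(sid), cw, nw, cc, nc, p))
    testable = [t for t in tests if not math.isnan(t.p_value)]
    if testable:
        q = bh_fdr([t.p_value for t in testable])
        for t, qv in zip(testable, q):
            t.q_value = float(qv)
            t.hdsv = qv < fdr_threshold
    return tests


def carrier_frequencies(matrix: pd.DataFrame, groups: Dict[str, str]) -> pd.DataFrame:
    """Per-site carrier fraction per group (missing calls excluded)."""
    rows = []
    group_names = sorted(set(groups.values()))
    for sid, row in matrix.iterrows():
        rec = {"site_id": sid}
        for g in group_names:
            cols = [a for a in matrix.columns if groups.get(a) == g]
            vals = row[cols]
            vals = vals[vals != GT_MISSING]
            rec[g] = float((vals >= GT_HET).mean()) if len(vals) else math.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("site_id")


def annotate_pi_ratio(
    svs: Sequence[Variant],
    track: DiversityTrack,
    ratio_threshold: float = 3.0,
) -> Dict[str, Optional[bool]]:
    """Flag SVs whose midpoint window has pi_w/pi_c >= threshold.

    An undefined ratio with pi_c == 0 < pi_w is treated as +inf (flagged);
    SVs outside the track get None.
    """
    flags: Dict[str, Optional[bool]] = {}
    for v in svs:
        sid = v.id or f"{v.ref_chrom}:{v.ref_start}"
        mid = (v.ref_start + max(v.ref_end, v.ref_start + 1)) // 2
        row = track.window_at(v.ref_chrom, mid)
        if row is None:
            flags[sid] = None
        else:
            r = row["ratio"]
            flags[sid] = bool(r >= ratio_threshold) if not math.isnan(r) else False
    return flags


def expression_effect(
    links: Sequence[Tuple[str, str, str]],  # (sv_id, gene_id, context CDS|promoter)
    expr_wild: pd.DataFrame,
    expr_cult: pd.DataFrame,
    lfc_threshold: float = 1.5,
    pseudocount: float = 1.0,
) -> List[ExpressionEffect]:
    """Per-tissue log2((cult + pc) / (wild + pc)) for SV-linked genes.

    Only CDS- and promoter-context links are eligible; an effect is flagged
    when any tissue reaches |log2FC| >= lfc_threshold (inclusive).
    """
    if (expr_wild.values < 0).any() or (expr_cult.values < 0).any():
        raise ValueError("negative expression values")
    out = []
    for sv_id, gene_id, context in links:
        if context not in ("CDS", "promoter"):
            continue
        w = expr_wild.loc[gene_id]
        c = expr_cult.loc[gene_id]
        lfc = {
            t: float(np.log2((c[t] + pseudocount) / (w[t] + pseudocount)))
            for t in expr_wild.columns
        }
        flagged = any(abs(x) >= lfc_threshold for x in lfc.values())
        out.append(ExpressionEffect(sv_id, gene_id, context, lfc, flagged))
    return out
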
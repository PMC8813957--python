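"""Short-read support for large InDels via the read-depth (RD) rule.

A deletion is RD-supported when the mean coverage of its 1 kb flanks is
more than threefold the mean coverage of the deleted region AND the region
mean is below 3.  Insertions are evaluated by swapping the roles of the two
genomes — the insertion becomes a deletion on the carrier genome — since
assembly-derived SVs have precise breakpoints on both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    DELETION_CLASSES,
    INSERTION_CLASSES,
    Variant,
    VariantClass,
)
from .simulate import PairPlacement


@dataclass
class DepthTrack:
    """Per-position read depth per chromosome."""

    depths: Dict[str, np.ndarray]

    def mean(self, chrom: str, start: int, end: int) -> float:
        arr = self.depths[chrom]
        start = max(0, start)
        end = min(len(arr), end)
        if end <= start:
            return 0.0
        return float(arr[start:end].mean())


@dataclass
class SupportCall:
    variant_id: Optional[str]
    variant_class: VariantClass
    accession_id: str
    rd_supported: bool
    region_depth: float
    flank_depth: float

    @property
    def fold(self) -> float:
        if self.region_depth == 0:
            return math.inf
        return self.flank_depth / self.region_depth


def depth_profile(
    placements: Iterable[PairPlacement],
    chrom_lengths: Dict[str, int],
    min_map_q: int = 20,
    remove_duplicates: bool = True,
) -> DepthTrack:
    """Depth from read placements: mapq >= 20, PCR duplicates collapsed.

    Duplicates are pairs with identical placement (chromosome plus the full
    tuple of read intervals), counted once.
    """
    diff = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_lengths.items()}
    seen = set()
    for p in placements:
        if p.map_q < min_map_q:
            continue
        if remove_duplicates:
            key = (p.chrom, p.intervals)
            if key in seen:
                continue
            seen.add(key)
        arr = diff[p.chrom]
        n = len(arr) - 1
        for s, e in p.intervals:
            s = max(0, min(s, n))
            e = max(0, min(e, n))
            arr[s] += 1
            arr[e] -= 1
    return DepthTrack({c: np.cumsum(a[:-1]) for c, a in diff.items()})


def rd_support(
    deletion: Variant, depth: DepthTrack, flank: int = 1000
) -> SupportCall:
    """Apply the RD rule to one deletion (reference-genome coordinates).

    ``rd_supported = flank_mean > 3 x region_mean AND region_mean < 3``.
    Flanks truncated at chromosome ends are used at their reduced length.
    """
    if deletion.variant_class not in DELETION_CLASSES:
        raise ValueError("rd_support expects a deletion (CAN_DEL or COM_DEL)")
    s, e = deletion.ref_start, deletion.ref_end
    if e <= s:
        raise ValueError("zero-length deletion region")
    chrom = deletion.ref_chrom
    arr = depth.depths[chrom]
    region = depth.mean(chrom, s, e)
    left = arr[max(0, s - flank) : s]
    right = arr[e : e + flank]
    flank_positions = np.concatenate([left, right])
    flank_mean = float(flank_positions.mean()) if len(flank_positions) else 0.0
    supported = (flank_mean > 3.0 * region) and (region < 3.0)
    return SupportCall(
        deletion.id, deletion.variant_class, deletion.accession_id, supported, region, flank_mean
    )


_SWAP = {
    VariantClass.CAN_INS: VariantClass.CAN_DEL,
    VariantClass.CAN_DEL: VariantClass.CAN_INS,
    VariantClass.COM_INS: VariantClass.COM_DEL,
    VariantClass.COM_DEL: VariantClass.COM_INS,
}


def swap_reference(variant: Variant) -> Variant:
    """View an SV from the other genome: insertion <-> deletion.

    The returned variant spans the inserted sequence on the query genome
    (reference and query coordinate/allele roles exchanged).  The operation
    is an involution: ``swap_reference(swap_reference(v)) == v``.
    """
    if variant.qry_chrom is None or variant.qry_start is None or variant.qry_end is None:
        raise ValueError("swap_reference needs query coordinates")
    if variant.variant_class not in _SWAP:
        raise ValueError("swap_reference is defined for large InDels")
    return replace(
        variant,
        variant_class=_SWAP[variant.variant_class],
        ref_chrom=variant.qry_chrom,
        ref_start=variant.qry_start,
        ref_end=variant.qry_end,
        ref_allele=variant.alt_allele,
        alt_allele=variant.ref_allele,
        qry_chrom=variant.ref_chrom,
        qry_start=variant.ref_start,
        qry_end=variant.ref_end,
    )


def evaluate_deletions(
    deletions: Sequence[Variant], depth: DepthTrack, flank: int = 1000
) -> List[SupportCall]:
    return [rd_support(d, depth, flank) for d in deletions]


def support_summary(calls: Sequence[SupportCall]) -> pd.DataFrame:
    """Fraction of RD-supported SVs per (accession, class)."""
    rows = [
        {
            "accession_id": c.accession_id,
            "variant_class": c.variant_class.value,
            "rd_supported": c.rd_supported,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["accession_id", "variant_class", "n", "n_supported", "fraction"])
    g = df.groupby(["accession_id", "variant_class"])["rd_supported"]
    out = g.agg(n="count", n_supported="sum").reset_index()
    out["fraction"] = out["n_supported"] / out["n"]
    return out


def depth_from_sam(path: str, chrom_lengths: Dict[str, int], min_map_q: int = 20) -> DepthTrack:
    """Depth track from an external SAM/BAM, same filters as depth_profile."""
    import pysam

    diff = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_lengths.items()}
    with pysam.AlignmentFile(path) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_duplicate or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_map_q:
                continue
            if rec.reference_name not in diff:
                continue
            arr = diff[rec.reference_name]
            s = max(0, rec.reference_start)
            e = min(len(arr) - 1, rec.reference_end or s)
            arr[s] += 1
            arr[e] -= 1
    return DepthTrack({c: np.cumsum(a[:-1]) for c, a in diff.items()})
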
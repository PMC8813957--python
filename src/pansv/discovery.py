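"""Variant discovery from in-block alignments.

Differences are extracted from the unaligned gap pairs between exact
anchors inside collinear blocks, classified by the 50 bp size boundary
into SNPs, small InDels, canonical SVs (pure InDels with exact
breakpoints) and complex SVs (replacements of unequal length), refined by
1 kb flank re-alignment, and passed through the exclusion filters
(N-containing alleles, assembly self-inconsistency masking).  Deletion
breakpoints can be screened for microhomology, and variants annotated for
CDS/promoter overlap with coding consequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib

from ._seq import revcomp
from .model import (
    COMPLEX_CLASSES,
    ID_PREFIX,
    SV_CLASSES,
    SV_MIN_SIZE,
    Variant,
    VariantClass,
    left_align,
)
from .simulate import SimulatedGenome
from .wga import CollinearBlock, Rearrangement, align_genomes, detect_rearrangements

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def classify_variant(ref_len: int, alt_len: int, precise: bool) -> VariantClass:
    """Class from allele lengths and breakpoint precision.

    The 50 bp boundary belongs to the SV side.  Equal-length substitutions
    longer than 1 bp are rejected; callers decompose them into SNPs first.
    Replacements shorter than 50 bp fold into the small InDel classes.
    """
    if ref_len < 0 or alt_len < 0:
        raise ValueError("negative allele length")
    if ref_len == 0 and alt_len == 0:
        raise ValueError("both alleles empty")
    if ref_len == alt_len:
        if ref_len == 1:
            return VariantClass.SNP
        raise ValueError("equal-length substitution: decompose into SNPs first")
    size = max(ref_len, alt_len)
    if min(ref_len, alt_len) == 0:
        if size < SV_MIN_SIZE:
            return VariantClass.SMALL_INS if alt_len > ref_len else VariantClass.SMALL_DEL
        return VariantClass.CAN_INS if alt_len > ref_len else VariantClass.CAN_DEL
    if size < SV_MIN_SIZE:
        return VariantClass.SMALL_INS if alt_len > ref_len else VariantClass.SMALL_DEL
    return VariantClass.COM_INS if alt_len > ref_len else VariantClass.COM_DEL


# ---------------------------------------------------------------------------
# in-block diffing
# ---------------------------------------------------------------------------


@dataclass
class DiffPair:
    """A raw difference: ref segment replaced by qry segment."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int


def _parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _diff_aligned_pair(
    qry_seg: str,
    ref_seg: str,
    ref_off: int,
    qry_off: int,
    rchrom: str,
    qchrom: str,
    wordsize: int,
) -> List[DiffPair]:
    """Globally align a gap pair and split it at exact runs >= wordsize.

    Exact runs shorter than ``wordsize`` do not anchor (mirroring word-based
    diffing) and are absorbed into the flanking difference, which is what
    turns a divergent replacement into a single complex pair instead of a
    cloud of micro-calls.
    """
    if not ref_seg and not qry_seg:
        return []
    if not ref_seg or not qry_seg:
        return [
            DiffPair(
                rchrom,
                ref_off,
                ref_off + len(ref_seg),
                qchrom,
                qry_off,
                qry_off + len(qry_seg),
            )
        ]
    res = edlib.align(qry_seg, ref_seg, mode="NW", task="path")
    ops = _parse_cigar(res["cigar"])
    out: List[DiffPair] = []
    ri = qi = 0  # local coordinates
    diff_r0 = diff_q0 = None  # start of open difference
    for n, op in ops:
        if op == "=" and n >= wordsize:
            if diff_r0 is not None:
                out.append(
                    DiffPair(rchrom, ref_off + diff_r0, ref_off + ri, qchrom, qry_off + diff_q0, qry_off + qi)
                )
                diff_r0 = diff_q0 = None
            ri += n
            qi += n
            continue
        if diff_r0 is None:
            diff_r0, diff_q0 = ri, qi
        if op in ("=", "X"):
            ri += n
            qi += n
        elif op == "I":  # consumes query
            qi += n
        else:  # 'D' consumes target (reference)
            ri += n
    if diff_r0 is not None:
        out.append(
            DiffPair(rchrom, ref_off + diff_r0, ref_off + ri, qchrom, qry_off + diff_q0, qry_off + qi)
        )
    return out


def diff_block(
    block: CollinearBlock,
    ref_seqs: Dict[str, str],
    qry_seqs: Dict[str, str],
    wordsize: int = 10,
) -> List[DiffPair]:
    """Raw difference pairs inside one plus-strand collinear block.

    All differences live in the gap pairs between exact anchors (within
    segments) and between consecutive segments; matched anchors contribute
    nothing, so concatenating anchors and differences reconstructs both
    block sequences.  Minus-strand blocks are inversion material and are
    not diffed here.
    """
    if block.strand != "+":
        raise ValueError("diff_block expects a plus-strand block")
    rchrom, qchrom = block.ref_chrom, block.qry_chrom
    rseq, qseq = ref_seqs[rchrom], qry_seqs[qchrom]
    pairs: List[DiffPair] = []

    def do_gap(rs: int, re_: int, qs: int, qe: int) -> None:
        ref_seg = rseq[rs:re_]
        qry_seg = qseq[qs:qe]
        if ref_seg == qry_seg:
            return
        if set(ref_seg) <= {"N"} and set(qry_seg) <= {"N"}:
            return  # N-only content yields no calls
        pairs.extend(
            _diff_aligned_pair(qry_seg, ref_seg, rs, qs, rchrom, qchrom, wordsize)
        )

    for seg in block.segments:
        for g in seg.gaps:
            do_gap(g.ref_start, g.ref_end, g.qry_start, g.qry_end)
    for a, b in zip(block.segments, block.segments[1:]):
        do_gap(a.ref_end, b.ref_start, a.qry_end, b.qry_start)
    pairs.sort(key=lambda p: (p.ref_start, p.ref_end))
    return pairs


def _trim_common(ref_a: str, alt_a: str) -> Tuple[int, int]:
    """(prefix, suffix) lengths shared by the two alleles (prefix wins ties).

    Word-based diffing can absorb chance-matched flank bases into a
    difference pair; trimming restores the minimal representation, turning
    a replacement that is really a clean InDel back into one.
    """
    lim = min(len(ref_a), len(alt_a))
    p = 0
    while p < lim and ref_a[p] == alt_a[p]:
        p += 1
    s = 0
    while s < lim - p and ref_a[len(ref_a) - 1 - s] == alt_a[len(alt_a) - 1 - s]:
        s += 1
    return p, s


def variants_from_diffs(
    pairs: Iterable[DiffPair],
    ref_seqs: Dict[str, str],
    qry_seqs: Dict[str, str],
    accession_id: str = "",
) -> List[Variant]:
    """Typed variants from raw difference pairs.

    Alleles are trimmed to their minimal representation first; equal-length
    differences decompose into per-base SNPs; everything else goes through
    :func:`classify_variant`.  Pure InDels are left-normalized.
    """
    out: List[Variant] = []
    for raw in pairs:
        ref_full = ref_seqs[raw.ref_chrom][raw.ref_start : raw.ref_end]
        alt_full = qry_seqs[raw.qry_chrom][raw.qry_start : raw.qry_end]
        if len(ref_full) != len(alt_full):
            tp, ts = _trim_common(ref_full, alt_full)
        else:
            tp = ts = 0
        p = DiffPair(
            raw.ref_chrom,
            raw.ref_start + tp,
            raw.ref_end - ts,
            raw.qry_chrom,
            raw.qry_start + tp,
            raw.qry_end - ts,
        )
        ref_a = ref_full[tp : len(ref_full) - ts]
        alt_a = alt_full[tp : len(alt_full) - ts]
        if len(ref_a) == len(alt_a):
            if len(ref_a) >= SV_MIN_SIZE:
                mismatch = sum(x != y for x, y in zip(ref_a, alt_a))
                if mismatch > 0.5 * len(ref_a):
                    # unalignable equal-length pair (e.g. an undetected strand
                    # flip): not a SNP run, leave it uncalled
                    continue
            for i, (rb, qb) in enumerate(zip(ref_a, alt_a)):
                if rb != qb:
                    out.append(
                        Variant(
                            VariantClass.SNP,
                            p.ref_chrom,
                            p.ref_start + i,
                            p.ref_start + i + 1,
                            rb,
                            qb,
                            accession_id=accession_id,
                            qry_chrom=p.qry_chrom,
                            qry_start=p.qry_start + i,
                            qry_end=p.qry_start + i + 1,
                        )
                    )
            continue
        precise = min(len(ref_a), len(alt_a)) == 0
        vclass = classify_variant(len(ref_a), len(alt_a), precise)
        v = Variant(
            vclass,
            p.ref_chrom,
            p.ref_start,
            p.ref_end,
            ref_a,
            alt_a,
            accession_id=accession_id,
            qry_chrom=p.qry_chrom,
            qry_start=p.qry_start,
            qry_end=p.qry_end,
            precise=precise,
        )
        if precise:
            v = left_align(v, ref_seqs[p.ref_chrom])
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# breakpoint refinement
# ---------------------------------------------------------------------------


def refine_breakpoints(
    variant: Variant,
    ref_seqs: Dict[str, str],
    qry_seqs: Dict[str, str],
    flank: int = 1000,
) -> Variant:
    """Re-align 1 kb flanks of a complex call; promote to canonical if clean.

    A complex call whose flank re-alignment collapses to a single pure
    InDel between perfectly collinear flanks is re-emitted as canonical
    with updated coordinates; anything else is returned unchanged.
    Refining a canonical variant is a no-op.  Allele content is conserved:
    applying the refined variant to the reference yields the same query.
    """
    if variant.variant_class not in COMPLEX_CLASSES or variant.precise:
        return variant
    rseq = ref_seqs[variant.ref_chrom]
    qseq = qry_seqs[variant.qry_chrom]
    rs = max(0, variant.ref_start - flank)
    re_ = min(len(rseq), variant.ref_end + flank)
    qs = max(0, variant.qry_start - flank)
    qe = min(len(qseq), variant.qry_end + flank)
    diffs = _diff_aligned_pair(
        qseq[qs:qe], rseq[rs:re_], rs, qs, variant.ref_chrom, variant.qry_chrom, wordsize=20
    )
    if len(diffs) != 1:
        return variant
    d = diffs[0]
    ref_a = rseq[d.ref_start : d.ref_end]
    alt_a = qseq[d.qry_start : d.qry_end]
    tp, ts = _trim_common(ref_a, alt_a)
    ref_a = ref_a[tp : len(ref_a) - ts]
    alt_a = alt_a[tp : len(alt_a) - ts]
    if min(len(ref_a), len(alt_a)) != 0 or max(len(ref_a), len(alt_a)) == 0:
        return variant
    refined = replace(
        variant,
        variant_class=classify_variant(len(ref_a), len(alt_a), True),
        ref_start=d.ref_start + tp,
        ref_end=d.ref_end - ts,
        ref_allele=ref_a,
        alt_allele=alt_a,
        qry_start=d.qry_start + tp,
        qry_end=d.qry_end - ts,
        precise=True,
    )
    return left_align(refined, rseq)


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------


def filter_n_content(variants: Sequence[Variant]) -> Tuple[List[Variant], Dict[str, int]]:
    """Drop SVs whose ref or alt allele contains N; report removals per class."""
    kept: List[Variant] = []
    removed: Dict[str, int] = {}
    for v in variants:
        if v.is_sv and ("N" in v.ref_allele or "N" in v.alt_allele):
            removed[v.variant_class.value] = removed.get(v.variant_class.value, 0) + 1
        else:
            kept.append(v)
    return kept, removed


@dataclass(frozen=True)
class SelfCall:
    """A self-inconsistent position from mapping an accession's reads to its own assembly."""

    chrom: str
    pos: int  # 0-based, query-genome coordinates
    base_q: float
    map_q: float
    depth: float

    @property
    def qualifies(self) -> bool:
        return self.base_q > 20 and self.map_q > 30 and 2 < self.depth < 200


def mask_assembly_errors(
    variants: Sequence[Variant], self_calls: Sequence[SelfCall]
) -> List[Variant]:
    """Remove variants at positions with a quality-passing self-call.

    Positions are matched in query-genome coordinates (where the reads were
    mapped).  Self-calls failing any threshold (base quality > 20, mapping
    quality > 30, 2 < depth < 200) never mask.
    """
    qualifying: Dict[str, set] = {}
    for c in self_calls:
        if c.qualifies:
            qualifying.setdefault(c.chrom, set()).add(c.pos)
    out = []
    for v in variants:
        positions = qualifying.get(v.qry_chrom or "", ())
        if positions:
            qs = v.qry_start if v.qry_start is not None else 0
            qe = v.qry_end if v.qry_end is not None else qs
            span = range(qs, qe) if qe > qs else (qs,)
            if any(p in positions for p in span):
                continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# microhomology
# ---------------------------------------------------------------------------


@dataclass
class MicrohomologyReport:
    variant_id: Optional[str]
    homology_seq: str
    homology_len: int
    side: str  # left | right | both | none


def detect_microhomology(
    deletion: Variant, ref_seq: str, max_len: int = 25
) -> MicrohomologyReport:
    """Longest exact sequence shared by the two junctions of a deletion.

    Right homology: ref[start:start+k] == ref[end:end+k]; left homology:
    ref[start-k:start] == ref[end-k:end].  Both are capped at the deletion
    span and ``max_len``; the longer one is reported (``both`` when equal
    and identical in sequence; length 0 is allowed).
    """
    if deletion.variant_class not in (VariantClass.CAN_DEL, VariantClass.COM_DEL):
        raise ValueError("microhomology is defined for deletions")
    s, e = deletion.ref_start, deletion.ref_end
    span = e - s
    right_cap = min(max_len, span, len(ref_seq) - e)
    k_right = 0
    while k_right < right_cap and ref_seq[s + k_right] == ref_seq[e + k_right]:
        k_right += 1
    left_cap = min(max_len, span, s)
    k_left = 0
    while k_left < left_cap and ref_seq[s - 1 - k_left] == ref_seq[e - 1 - k_left]:
        k_left += 1
    if k_left == k_right == 0:
        return MicrohomologyReport(deletion.id, "", 0, "none")
    if k_right >= k_left:
        seq_r = ref_seq[s : s + k_right]
        if k_left == k_right and ref_seq[s - k_left : s] == seq_r:
            return MicrohomologyReport(deletion.id, seq_r, k_right, "both")
        return MicrohomologyReport(deletion.id, seq_r, k_right, "right")
    return MicrohomologyReport(deletion.id, ref_seq[s - k_left : s], k_left, "left")


# ---------------------------------------------------------------------------
# gene overlap / consequence annotation
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnot:
    """Minimal gene model for overlap annotation: gene span + CDS exons."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: List[Tuple[int, int]]  # sorted by coordinate

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GeneOverlap:
    variant_id: Optional[str]
    label: str  # CDS-SV | promoter-SV | intron-SV | intergenic
    gene_id: Optional[str]
    consequence: Optional[str]  # in_frame | frameshift | None
    aa_change: Optional[int]  # amino acids gained (+) or lost (-) for in_frame


def _cds_offset(gene: GeneAnnot, pos: int) -> Optional[int]:
    """Coding-strand offset of a genomic position inside the CDS, or None."""
    exons = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    off = 0
    for s, e in exons:
        if s <= pos < e:
            return off + (pos - s if gene.strand == "+" else e - 1 - pos)
        off += e - s
    return None


def annotate_gene_overlap(
    variants: Sequence[Variant],
    genes: Sequence[GeneAnnot],
    promoter_window: int = 3000,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> List[GeneOverlap]:
    """Label variants CDS-SV / promoter-SV / intron-SV / intergenic.

    For pure InDels overlapping CDS, a deletion (insertion) of length L
    fully inside one exon with L % 3 == 0 starting at a codon boundary is
    in-frame with L/3 amino acids lost (gained); anything else is a
    frameshift.
    """
    out: List[GeneOverlap] = []
    for v in variants:
        if chrom_lengths is not None:
            length = chrom_lengths.get(v.ref_chrom)
            if length is not None and (v.ref_end > length or v.ref_start < 0):
                raise ValueError(f"variant beyond chromosome bounds: {v.ref_chrom}:{v.ref_start}")
        vs, ve = v.ref_start, max(v.ref_end, v.ref_start + 1)  # insertions: anchor point
        label, gene_hit, consequence, aa = "intergenic", None, None, None
        for g in genes:
            if g.chrom != v.ref_chrom:
                continue
            cds_hit = any(vs < e and s < ve for s, e in g.cds)
            if cds_hit:
                label, gene_hit = "CDS-SV", g.gene_id
                indel = min(len(v.ref_allele), len(v.alt_allele)) == 0 and v.ref_allele != v.alt_allele
                if indel and v.variant_class is not VariantClass.SNP:
                    L = abs(len(v.ref_allele) - len(v.alt_allele))
                    inframe = False
                    if L % 3 == 0:
                        if v.ref_len > 0:  # deletion: fully inside one exon, codon-aligned
                            exon = next(((s, e) for s, e in g.cds if s <= vs and v.ref_end <= e), None)
                            if exon is not None:
                                first = vs if g.strand == "+" else v.ref_end - 1
                                off = _cds_offset(g, first)
                                inframe = off is not None and off % 3 == 0
                        else:  # insertion between vs-1 and vs
                            junction = vs if g.strand == "+" else vs - 1
                            off = _cds_offset(g, junction)
                            inframe = off is not None and off % 3 == 0
                    if inframe:
                        consequence = "in_frame"
                        aa = (L // 3) * (1 if len(v.alt_allele) > len(v.ref_allele) else -1)
                    else:
                        consequence = "frameshift"
                break
            if g.start <= vs < g.end or g.start < ve <= g.end:
                label, gene_hit = "intron-SV", g.gene_id
                break
            if g.strand == "+" and g.start - promoter_window <= vs < g.start:
                label, gene_hit = "promoter-SV", g.gene_id
                break
            if g.strand == "-" and g.end <= vs < g.end + promoter_window:
                label, gene_hit = "promoter-SV", g.gene_id
                break
        out.append(GeneOverlap(v.id, label, gene_hit, consequence, aa))
    return out


# ---------------------------------------------------------------------------
# end-to-end calling
# ---------------------------------------------------------------------------


def assign_ids(variants: Sequence[Variant]) -> List[Variant]:
    """SV_{TYPE}_{chrom}G{index}: index by reference-sorted order per chrom."""
    counters: Dict[str, int] = {}
    out = []
    for v in sorted(variants, key=lambda v: (v.ref_chrom, v.ref_start, v.ref_end)):
        if v.variant_class in SV_CLASSES:
            counters[v.ref_chrom] = counters.get(v.ref_chrom, 0) + 1
            chrom_token = v.ref_chrom.replace("chr", "")
            v.id = f"SV_{ID_PREFIX[v.variant_class]}_{chrom_token}G{counters[v.ref_chrom]:06d}"
        out.append(v)
    return out


@dataclass
class CallSet:
    variants: List[Variant]
    inversions: List[Rearrangement]
    translocations: List[Rearrangement]
    megabase_inversions: List[Rearrangement]
    removed_n: Dict[str, int]

    def by_class(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for v in self.variants:
            counts[v.variant_class.value] = counts.get(v.variant_class.value, 0) + 1
        return counts


def _suppressed_by_rearrangement(v: Variant, rearr: Sequence[Rearrangement]) -> bool:
    """Drop InDel calls shadowing a detected inversion or translocation.

    A translocation surfaces in the collinear blocks as a deletion at its
    source plus an insertion at its destination; an inversion surfaces as a
    garbled replacement.  Calls whose reference or query footprint lies
    mostly inside a reported rearrangement are artifacts of that event.
    """
    for r in rearr:
        if v.ref_chrom == r.ref_chrom and v.ref_start < r.ref_end and r.ref_start < v.ref_end:
            ov = min(v.ref_end, r.ref_end) - max(v.ref_start, r.ref_start)
            if ov > 0.5 * max(v.ref_len, 1):
                return True
        if (
            v.qry_chrom == r.qry_chrom
            and v.qry_start is not None
            and v.qry_start < r.qry_end
            and r.qry_start < v.qry_end
        ):
            ov = min(v.qry_end, r.qry_end) - max(v.qry_start, r.qry_start)
            if ov > 0.5 * max(v.qry_end - v.qry_start, 1):
                return True
    return False


def call_variants(
    ref_genome: SimulatedGenome,
    qry_genome: SimulatedGenome,
    accession_id: Optional[str] = None,
    min_anchor_len: int = 20,
    min_identity: float = 90.0,
    min_length: int = 200,
    max_block_gap: int = 50_000,
    wordsize: int = 10,
    flank: int = 1000,
    large_inv_threshold: int = 1_000_000,
    self_calls: Sequence[SelfCall] = (),
) -> CallSet:
    """Full assembly-vs-reference calling pipeline for one genome pair."""
    accession_id = accession_id or qry_genome.accession_id
    ref_seqs = ref_genome.seqs
    qry_seqs = qry_genome.seqs
    blocks = align_genomes(
        ref_genome,
        qry_genome,
        min_anchor_len=min_anchor_len,
        min_identity=min_identity,
        min_length=min_length,
        max_block_gap=max_block_gap,
    )
    inversions, translocations, megabase = detect_rearrangements(
        blocks, ref_seqs, large_inv_threshold
    )
    all_rearr = inversions + translocations + megabase

    variants: List[Variant] = []
    for block in blocks:
        if block.strand != "+":
            continue
        pairs = diff_block(block, ref_seqs, qry_seqs, wordsize)
        variants.extend(variants_from_diffs(pairs, ref_seqs, qry_seqs, accession_id))
    variants = [v for v in variants if not _suppressed_by_rearrangement(v, all_rearr)]
    variants = [refine_breakpoints(v, ref_seqs, qry_seqs, flank) for v in variants]
    variants, removed_n = filter_n_content(variants)
    if self_calls:
        variants = mask_assembly_errors(variants, self_calls)

    for r in inversions + megabase:
        seg = ref_seqs[r.ref_chrom][r.ref_start : r.ref_end]
        variants.append(
            Variant(
                VariantClass.INV,
                r.ref_chrom,
                r.ref_start,
                r.ref_end,
                seg,
                revcomp(seg),
                accession_id=accession_id,
                qry_chrom=r.qry_chrom,
                qry_start=r.qry_start,
                qry_end=r.qry_end,
                info={"low_confidence": r.low_confidence, "megabase": r.size >= large_inv_threshold},
            )
        )
    for r in translocations:
        variants.append(
            Variant(
                VariantClass.TRANS,
                r.ref_chrom,
                r.ref_start,
                r.ref_end,
                ref_seqs[r.ref_chrom][r.ref_start : r.ref_end],
                "",
                accession_id=accession_id,
                qry_chrom=r.qry_chrom,
                qry_start=r.qry_start,
                qry_end=r.qry_end,
                info={"kind": r.kind},
            )
        )
    # deduplicate identical calls from adjacent blocks
    seen = set()
    deduped = []
    for v in sorted(variants, key=lambda v: (v.ref_chrom, v.ref_start, v.ref_end)):
        key = (v.ref_chrom, v.ref_start, v.ref_end, v.alt_allele, v.variant_class)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(v)
    return CallSet(assign_ids(deduped), inversions, translocations, megabase, removed_n)
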
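"""Anchor-based whole-genome alignment and collinear block chaining.

The pipeline mirrors classic assembly-to-assembly comparison: seed with
maximal exact matches that are unique in the reference (MUM-like), extend
co-linear runs of anchors into scored alignment segments, keep a mutually
one-to-one segment set (identity >= 90%, length >= 200 bp by default), and
chain order-consistent segments into collinear blocks with a bounded
internal gap (50 kb by default).  Strand flips and order breaks between
blocks are reported as inversions and translocations.

Query coordinates of minus-strand features are always stored on the
forward query strand with a strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from ._seq import match_len_backward, match_len_forward, revcomp
from .simulate import SimulatedGenome

_AMBIG = -1
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match, unique in the reference."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class GapPair:
    """Unaligned region between two consecutive anchors of a segment.

    Coordinates are forward on the reference; query coordinates are in
    reverse-complement space for minus-strand segments (``rc_query``).
    """

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int


@dataclass
class AlignmentSegment:
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int  # forward query strand
    qry_end: int
    strand: str
    identity: float  # percent
    aligned_length: int  # alignment columns
    anchors: List[Anchor] = field(default_factory=list)
    gaps: List[GapPair] = field(default_factory=list)  # rc-space for '-'

    @property
    def weight(self) -> float:
        return self.identity * self.aligned_length


@dataclass
class CollinearBlock:
    segments: List[AlignmentSegment]
    max_internal_gap: int

    @property
    def ref_chrom(self) -> str:
        return self.segments[0].ref_chrom

    @property
    def qry_chrom(self) -> str:
        return self.segments[0].qry_chrom

    @property
    def strand(self) -> str:
        return self.segments[0].strand

    @property
    def ref_span(self) -> Tuple[int, int]:
        return (self.segments[0].ref_start, self.segments[-1].ref_end)

    @property
    def qry_span(self) -> Tuple[int, int]:
        qs = min(s.qry_start for s in self.segments)
        qe = max(s.qry_end for s in self.segments)
        return (qs, qe)


@dataclass
class Rearrangement:
    kind: str  # inversion | megabase_inversion | intra_translocation | inter_translocation
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    low_confidence: bool = False

    @property
    def size(self) -> int:
        return self.ref_end - self.ref_start


# ---------------------------------------------------------------------------
# anchor seeding
# ---------------------------------------------------------------------------


def _kmer_index(seqs: Dict[str, str], k: int):
    """2-bit rolling-code index kmer -> (chrom_idx, pos), AMBIG for repeats."""
    index: Dict[int, Tuple[int, int]] = {}
    mask = (1 << (2 * k)) - 1
    names = list(seqs)
    for ci, name in enumerate(names):
        seq = seqs[name]
        code = 0
        valid = 0  # how many consecutive coded bases end at current position
        for i, ch in enumerate(seq):
            b = _CODE.get(ch)
            if b is None:
                valid = 0
                code = 0
                continue
            code = ((code << 2) | b) & mask
            valid += 1
            if valid >= k:
                pos = i - k + 1
                prev = index.get(code)
                if prev is None:
                    index[code] = (ci, pos)
                elif prev != (_AMBIG, _AMBIG):
                    index[code] = (_AMBIG, _AMBIG)
    return index, names


def _scan_strand(
    index,
    ref_names: List[str],
    ref_seqs: Dict[str, str],
    qry_name: str,
    qseq: str,
    k: int,
    strand: str,
    out: List[Anchor],
) -> None:
    mask = (1 << (2 * k)) - 1
    n = len(qseq)
    qlen = n
    stride = max(1, k // 2)
    i = 0
    while i + k <= n:
        code = 0
        ok = True
        for t in range(k):
            b = _CODE.get(qseq[i + t])
            if b is None:
                ok = False
                i = i + t + 1  # skip past the N
                break
            code = ((code << 2) | b) & mask
        if not ok:
            continue
        hit = index.get(code)
        if hit is None or hit[0] == _AMBIG:
            i += stride
            continue
        ci, rpos = hit
        rseq = ref_seqs[ref_names[ci]]
        left = match_len_backward(rseq, qseq, rpos, i)
        right = match_len_forward(rseq, qseq, rpos + k, i + k)
        rs, re_ = rpos - left, rpos + k + right
        qs, qe = i - left, i + k + right
        if strand == "+":
            out.append(Anchor(ref_names[ci], rs, re_, qry_name, qs, qe, "+"))
        else:
            out.append(
                Anchor(ref_names[ci], rs, re_, qry_name, qlen - qe, qlen - qs, "-")
            )
        i = qe  # jump past the maximal match
    return


def find_anchors_genome(
    ref_genome: SimulatedGenome,
    qry_genome: SimulatedGenome,
    min_anchor_len: int = 20,
) -> List[Anchor]:
    """Maximal exact matches, unique in the (multi-chromosome) reference."""
    if min_anchor_len < 8:
        raise ValueError("min_anchor_len must be >= 8")
    ref_seqs = ref_genome.seqs
    index, names = _kmer_index(ref_seqs, min_anchor_len)
    anchors: List[Anchor] = []
    for qname, qseq in qry_genome.chromosomes:
        if not qseq:
            raise ValueError("empty query sequence")
        _scan_strand(index, names, ref_seqs, qname, qseq, min_anchor_len, "+", anchors)
        _scan_strand(
            index, names, ref_seqs, qname, revcomp(qseq), min_anchor_len, "-", anchors
        )
    # maximal extension from different seeds can rediscover the same match
    uniq = sorted(
        set(
            (a.ref_chrom, a.ref_start, a.ref_end, a.qry_chrom, a.qry_start, a.qry_end, a.strand)
            for a in anchors
        )
    )
    return [Anchor(*t) for t in uniq]


def find_anchors(ref_seq: str, qry_seq: str, min_anchor_len: int = 20) -> List[Anchor]:
    """Single sequence-pair convenience wrapper around the genome API."""
    ref = SimulatedGenome("ref", [("ref", ref_seq)])
    qry = SimulatedGenome("qry", [("qry", qry_seq)])
    return find_anchors_genome(ref, qry, min_anchor_len)


# ---------------------------------------------------------------------------
# segment building
# ---------------------------------------------------------------------------


def _edlib_stats(a: str, b: str) -> Tuple[int, int]:
    """(matches, columns) of a global alignment of a vs b."""
    if not a and not b:
        return 0, 0
    if not a or not b:
        return 0, max(len(a), len(b))
    res = edlib.align(a, b, mode="NW", task="distance")
    dist = res["editDistance"]
    # columns >= max(len); a banded estimate suffices for identity scoring:
    columns = max(len(a), len(b))
    matches = columns - dist if dist <= columns else 0
    return max(matches, 0), columns


def extend_and_score(
    anchors: Sequence[Anchor],
    ref_genome: SimulatedGenome,
    qry_genome: SimulatedGenome,
    max_anchor_gap: int = 1_500,
) -> List[AlignmentSegment]:
    """Merge co-linear anchors within ``max_anchor_gap`` and score the result.

    Identity is matches / alignment columns x 100 with inter-anchor gaps
    aligned globally (edlib); the gap pairs are retained on the segment so
    variant discovery can re-align them without recomputing anchors.
    """
    ref_seqs = ref_genome.seqs
    qry_seqs = qry_genome.seqs
    rc_cache: Dict[str, str] = {}

    def rc(qname: str) -> str:
        if qname not in rc_cache:
            rc_cache[qname] = revcomp(qry_seqs[qname])
        return rc_cache[qname]

    groups: Dict[Tuple[str, str, str], List[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.ref_chrom, a.qry_chrom, a.strand), []).append(a)

    segments: List[AlignmentSegment] = []
    for (rchrom, qchrom, strand), group in sorted(groups.items()):
        qlen = len(qry_seqs[qchrom])

        def q_interval(a: Anchor) -> Tuple[int, int]:
            # working coordinates: forward for '+', rc-space for '-'
            if strand == "+":
                return a.qry_start, a.qry_end
            return qlen - a.qry_end, qlen - a.qry_start

        group = sorted(group, key=lambda a: (a.ref_start, q_interval(a)[0]))
        chains: List[List[Tuple[Anchor, int, int, int, int]]] = []
        cur: List[Tuple[Anchor, int, int, int, int]] = []
        for a in group:
            qs, qe = q_interval(a)
            rs, re_ = a.ref_start, a.ref_end
            if cur:
                _, prs, pre, pqs, pqe = cur[-1]
                rg = rs - pre
                qg = qs - pqe
                trim = max(-min(rg, qg), 0)
                if trim > 0 and trim < (re_ - rs):
                    rs += trim
                    qs += trim
                    rg = rs - pre
                    qg = qs - pqe
                if 0 <= rg <= max_anchor_gap and 0 <= qg <= max_anchor_gap:
                    cur.append((a, rs, re_, qs, qe))
                    continue
                chains.append(cur)
                cur = []
            cur.append((a, a.ref_start, a.ref_end, qs, qe))
        if cur:
            chains.append(cur)

        qwork = qry_seqs[qchrom] if strand == "+" else rc(qchrom)
        rseq = ref_seqs[rchrom]
        for chain in chains:
            matches = 0
            columns = 0
            gaps: List[GapPair] = []
            for (_a, rs, re_, qs, qe) in chain:
                matches += re_ - rs
                columns += re_ - rs
            for (_a1, _rs1, pre, _qs1, pqe), (_a2, rs2, _re2, qs2, _qe2) in zip(
                chain, chain[1:]
            ):
                m, c = _edlib_stats(qwork[pqe:qs2], rseq[pre:rs2])
                matches += m
                columns += c
                if c:
                    gaps.append(GapPair(pre, rs2, pqe, qs2))
            rs0, re0 = chain[0][1], chain[-1][2]
            qs0, qe0 = chain[0][3], chain[-1][4]
            if strand == "+":
                fqs, fqe = qs0, qe0
            else:
                fqs, fqe = qlen - qe0, qlen - qs0
            segments.append(
                AlignmentSegment(
                    ref_chrom=rchrom,
                    ref_start=rs0,
                    ref_end=re0,
                    qry_chrom=qchrom,
                    qry_start=fqs,
                    qry_end=fqe,
                    strand=strand,
                    identity=100.0 * matches / columns if columns else 0.0,
                    aligned_length=columns,
                    anchors=[t[0] for t in chain],
                    gaps=gaps,
                )
            )
    segments.sort(key=lambda s: (s.ref_chrom, s.ref_start, s.qry_chrom, s.qry_start))
    return segments


# ---------------------------------------------------------------------------
# one-to-one filtering
# ---------------------------------------------------------------------------


def _overlap_len(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0])


def _conflicts(a: AlignmentSegment, b: AlignmentSegment, tol: int = 0) -> bool:
    """Overlap beyond ``tol`` bp on either genome axis.

    Maximal exact matches legitimately over-extend a few bases into junction
    homology, so adjacent segments may share a handful of positions without
    being true alternatives; ``tol`` keeps those out of the conflict graph
    (residual overlaps are trimmed after selection).
    """
    if a.ref_chrom == b.ref_chrom and _overlap_len(
        (a.ref_start, a.ref_end), (b.ref_start, b.ref_end)
    ) > tol:
        return True
    if a.qry_chrom == b.qry_chrom and _overlap_len(
        (a.qry_start, a.qry_end), (b.qry_start, b.qry_end)
    ) > tol:
        return True
    return False


def _best_consistent_subset(segs: List[AlignmentSegment], tol: int = 0) -> List[AlignmentSegment]:
    """Exact maximum-weight conflict-free subset (small component)."""
    n = len(segs)
    order = sorted(range(n), key=lambda i: (segs[i].ref_chrom, segs[i].ref_start))
    best: Tuple[float, Tuple] = (-1.0, ())
    suffix = [0.0] * (n + 1)
    for idx in range(n - 1, -1, -1):
        suffix[idx] = suffix[idx + 1] + segs[order[idx]].weight

    def rec(idx: int, chosen: List[int], weight: float) -> None:
        nonlocal best
        if weight + suffix[idx] < best[0]:
            return
        if idx == n:
            key = (weight, tuple(-i for i in chosen))
            if key > best:
                best = key
            return
        s = segs[order[idx]]
        if all(not _conflicts(s, segs[c], tol) for c in chosen):
            chosen.append(order[idx])
            rec(idx + 1, chosen, weight + s.weight)
            chosen.pop()
        rec(idx + 1, chosen, weight)

    rec(0, [], 0.0)
    return [segs[-i] for i in best[1]]


def _trim_front_ref(seg: AlignmentSegment, o: int) -> None:
    """Shift a segment's start ``o`` bp along the reference (diagonal trim)."""
    seg.ref_start += o
    if seg.strand == "+":
        seg.qry_start += o
    else:
        seg.qry_end -= o
    seg.aligned_length = max(seg.aligned_length - o, 1)


def _trim_front_qry(seg: AlignmentSegment, o: int) -> None:
    """Shift a segment's start ``o`` bp along the forward query strand."""
    seg.qry_start += o
    if seg.strand == "+":
        seg.ref_start += o
    else:
        seg.ref_end -= o
    seg.aligned_length = max(seg.aligned_length - o, 1)


def filter_one_to_one(
    segments: Sequence[AlignmentSegment],
    min_identity: float = 90.0,
    min_length: int = 200,
    overlap_tolerance: int = 30,
) -> List[AlignmentSegment]:
    """Identity/length filter, then resolve overlaps to a one-to-one set.

    Among conflicting alternatives the maximum-weight consistent subset
    (weight = identity x aligned length) is kept: exact search inside each
    conflict component up to 20 members, greedy by weight beyond that.
    Ties break toward the leftmost reference coordinate.  Overlaps up to
    ``overlap_tolerance`` bp (exact-match over-extension into junction
    homology) are not conflicts; they are trimmed afterwards so the
    retained set is strictly non-overlapping on both genomes.
    """
    kept = [
        s
        for s in segments
        if s.identity >= min_identity and s.aligned_length >= min_length
    ]
    tol = overlap_tolerance
    n = len(kept)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        if _conflicts(kept[i], kept[j], tol):
            parent[find(i)] = find(j)
    comps: Dict[int, List[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    out: List[AlignmentSegment] = []
    for members in comps.values():
        segs = [kept[i] for i in members]
        if len(segs) == 1:
            out.extend(segs)
        elif len(segs) <= 20:
            out.extend(_best_consistent_subset(segs, tol))
        else:
            chosen: List[AlignmentSegment] = []
            for s in sorted(segs, key=lambda s: (-s.weight, s.ref_chrom, s.ref_start)):
                if all(not _conflicts(s, c, tol) for c in chosen):
                    chosen.append(s)
            out.extend(chosen)

    # enforce strict one-to-one by trimming tolerated micro-overlaps
    out.sort(key=lambda s: (s.ref_chrom, s.ref_start, s.ref_end))
    for a, b in zip(out, out[1:]):
        if a.ref_chrom == b.ref_chrom:
            o = a.ref_end - b.ref_start
            if 0 < o < b.ref_end - b.ref_start:
                _trim_front_ref(b, o)
    out.sort(key=lambda s: (s.qry_chrom, s.qry_start, s.qry_end))
    for a, b in zip(out, out[1:]):
        if a.qry_chrom == b.qry_chrom:
            o = a.qry_end - b.qry_start
            if 0 < o < b.qry_end - b.qry_start:
                _trim_front_qry(b, o)
    out.sort(key=lambda s: (s.ref_chrom, s.ref_start, s.qry_chrom, s.qry_start))
    return out


# ---------------------------------------------------------------------------
# collinear blocks
# ---------------------------------------------------------------------------


def chain_collinear_blocks(
    segments: Sequence[AlignmentSegment], max_gap: int = 50_000
) -> List[CollinearBlock]:
    """Join same-strand, order-consistent segments with gaps <= max_gap."""
    groups: Dict[Tuple[str, str, str], List[AlignmentSegment]] = {}
    for s in segments:
        groups.setdefault((s.ref_chrom, s.qry_chrom, s.strand), []).append(s)
    blocks: List[CollinearBlock] = []
    for (_r, _q, strand), group in groups.items():
        group = sorted(group, key=lambda s: s.ref_start)
        cur: List[AlignmentSegment] = []
        for s in group:
            if cur:
                prev = cur[-1]
                rg = s.ref_start - prev.ref_end
                qg = (
                    s.qry_start - prev.qry_end
                    if strand == "+"
                    else prev.qry_start - s.qry_end
                )
                if 0 <= rg <= max_gap and 0 <= qg <= max_gap:
                    cur.append(s)
                    continue
                blocks.append(CollinearBlock(cur, max_gap))
                cur = []
            cur.append(s)
        if cur:
            blocks.append(CollinearBlock(cur, max_gap))
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_span[0]))
    return blocks


# ---------------------------------------------------------------------------
# rearrangements
# ---------------------------------------------------------------------------


def detect_rearrangements(
    blocks: Sequence[CollinearBlock],
    ref_seqs: Optional[Dict[str, str]] = None,
    large_inv_threshold: int = 1_000_000,
) -> Tuple[List[Rearrangement], List[Rearrangement], List[Rearrangement]]:
    """Classify strand flips and order breaks among collinear blocks.

    Returns (inversions < threshold, translocations, megabase inversions).
    A minus-strand block nested in same-chromosome plus-strand context on
    both sides is an inversion; unflanked terminal flips are reported with
    ``low_confidence=True``.  Plus-strand blocks that break reference/query
    order are intra-chromosomal translocations, blocks whose query lands on
    a different partner chromosome are inter-chromosomal.  Translocated
    segments containing N are excluded.
    """
    inversions: List[Rearrangement] = []
    megabase: List[Rearrangement] = []
    translocations: List[Rearrangement] = []

    by_ref: Dict[str, List[CollinearBlock]] = {}
    for b in blocks:
        by_ref.setdefault(b.ref_chrom, []).append(b)

    for rchrom, blist in sorted(by_ref.items()):
        blist = sorted(blist, key=lambda b: b.ref_span[0])
        span_by_qry: Dict[str, int] = {}
        for b in blist:
            span_by_qry[b.qry_chrom] = span_by_qry.get(b.qry_chrom, 0) + (
                b.ref_span[1] - b.ref_span[0]
            )
        dominant = max(span_by_qry, key=lambda q: span_by_qry[q])

        def has_n(b: CollinearBlock) -> bool:
            if ref_seqs is None:
                return False
            s, e = b.ref_span
            return "N" in ref_seqs[b.ref_chrom][s:e]

        plus = [b for b in blist if b.strand == "+" and b.qry_chrom == dominant]
        # maximum-span increasing run of query starts = the in-place backbone
        inplace = _weighted_lis(plus)
        inplace_set = set(id(b) for b in inplace)

        for b in blist:
            if b.qry_chrom != dominant:
                if not has_n(b):
                    translocations.append(
                        Rearrangement(
                            "inter_translocation",
                            rchrom,
                            *b.ref_span,
                            b.qry_chrom,
                            *b.qry_span,
                        )
                    )
                continue
            if b.strand == "-":
                s0, e0 = b.ref_span
                left_ok = any(x.ref_span[0] < s0 for x in inplace)
                right_ok = any(x.ref_span[1] > e0 for x in inplace)
                rearr = Rearrangement(
                    "inversion",
                    rchrom,
                    *b.ref_span,
                    b.qry_chrom,
                    *b.qry_span,
                    low_confidence=not (left_ok and right_ok),
                )
                if rearr.size >= large_inv_threshold:
                    rearr.kind = "megabase_inversion"
                    megabase.append(rearr)
                else:
                    inversions.append(rearr)
            elif id(b) not in inplace_set:
                if not has_n(b):
                    translocations.append(
                        Rearrangement(
                            "intra_translocation",
                            rchrom,
                            *b.ref_span,
                            b.qry_chrom,
                            *b.qry_span,
                        )
                    )
    return inversions, translocations, megabase


def _weighted_lis(blocks: List[CollinearBlock]) -> List[CollinearBlock]:
    """Maximum-total-ref-span subset with increasing query coordinates."""
    n = len(blocks)
    if n == 0:
        return []
    weight = [b.ref_span[1] - b.ref_span[0] for b in blocks]
    best = list(weight)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if blocks[j].qry_span[1] <= blocks[i].qry_span[0] and best[j] + weight[i] > best[i]:
                best[i] = best[j] + weight[i]
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    out = []
    while end != -1:
        out.append(blocks[end])
        end = prev[end]
    return out[::-1]


def align_genomes(
    ref_genome: SimulatedGenome,
    qry_genome: SimulatedGenome,
    min_anchor_len: int = 20,
    max_anchor_gap: int = 1_500,
    min_identity: float = 90.0,
    min_length: int = 200,
    max_block_gap: int = 50_000,
) -> List[CollinearBlock]:
    """Full anchor -> segment -> one-to-one -> block pipeline for a genome pair."""
    anchors = find_anchors_genome(ref_genome, qry_genome, min_anchor_len)
    segments = extend_and_score(anchors, ref_genome, qry_genome, max_anchor_gap)
    one = filter_one_to_one(segments, min_identity, min_length)
    return chain_collinear_blocks(one, max_block_gap)
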
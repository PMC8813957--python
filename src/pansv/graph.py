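"""SV-integrated variation graph with a preserved linear reference path.

The graph embeds large insertions, deletions, complex replacements and
inversions into the reference: reference nodes are split at every SV
boundary, deletions add a bypass edge, insertions and replacements add an
alternative-allele node, inversions reuse the reference segment with
reversed-orientation edges.  Concatenating the reference-path node
sequences reproduces the reference byte-for-byte.

Genotyping is allele-path re-alignment: for every site the ref and alt
allele spellings (with flanks) are indexed by their allele-distinguishing
k-mers; a read votes for the allele whose distinguishing k-mers it carries.
This is adequate for breakpoint-spanning short-read support and avoids a
universal graph mapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import revcomp
from .model import Variant, VariantClass
from .simulate import (
    GT_ALT,
    GT_HET,
    GT_MISSING,
    GT_REF,
    PopulationPanel,
    ReadSet,
    SimulatedGenome,
    site_key,
)

GRAPH_CLASSES = {
    VariantClass.CAN_INS,
    VariantClass.CAN_DEL,
    VariantClass.COM_INS,
    VariantClass.COM_DEL,
    VariantClass.INV,
}


@dataclass
class Node:
    node_id: int
    sequence: str
    ref_chrom: Optional[str] = None
    ref_start: Optional[int] = None

    @property
    def ref_interval(self) -> Optional[Tuple[str, int, int]]:
        if self.ref_chrom is None:
            return None
        return (self.ref_chrom, self.ref_start, self.ref_start + len(self.sequence))


OrientedNode = Tuple[int, str]  # (node_id, '+' | '-')
Edge = Tuple[int, str, int, str]


@dataclass
class Site:
    site_id: str
    chrom: str
    ref_start: int
    ref_end: int
    variant_class: VariantClass
    alt_allele: str
    ref_subpath: List[OrientedNode]
    alt_subpath: List[OrientedNode]


@dataclass
class VariationGraph:
    nodes: Dict[int, Node]
    edges: set  # of Edge
    ref_path: Dict[str, List[OrientedNode]]
    sites: Dict[str, Site] = field(default_factory=dict)

    def node_seq(self, oriented: OrientedNode) -> str:
        node_id, orient = oriented
        seq = self.nodes[node_id].sequence
        return seq if orient == "+" else revcomp(seq)

    def spell_path(self, path: Sequence[OrientedNode]) -> str:
        return "".join(self.node_seq(o) for o in path)

    def reference_seq(self, chrom: str) -> str:
        return self.spell_path(self.ref_path[chrom])


def build_graph(reference: SimulatedGenome, svs: Sequence[Variant]) -> VariationGraph:
    """Split the reference at SV boundaries and wire in alternative alleles.

    Accepts canonical/complex InDels and inversions (translocations are not
    part of the graph).  SVs must be deduplicated by (chrom, start, end, alt)
    beforehand; overlapping SVs are allowed and each becomes its own site
    with nodes split at the union of boundaries.
    """
    svs = [v for v in svs if v.variant_class in GRAPH_CLASSES]
    seqs = reference.seqs
    breakpoints: Dict[str, set] = {c: {0, len(s)} for c, s in reference.chromosomes}
    for v in svs:
        if v.ref_chrom not in seqs:
            raise ValueError(f"unknown chromosome {v.ref_chrom}")
        if v.ref_start < 0 or v.ref_end > len(seqs[v.ref_chrom]):
            raise ValueError(f"SV outside reference: {v.ref_chrom}:{v.ref_start}-{v.ref_end}")
        breakpoints[v.ref_chrom].add(v.ref_start)
        breakpoints[v.ref_chrom].add(v.ref_end)

    nodes: Dict[int, Node] = {}
    edges: set = set()
    ref_path: Dict[str, List[OrientedNode]] = {}
    start_node: Dict[Tuple[str, int], int] = {}  # node starting at ref pos
    end_node: Dict[Tuple[str, int], int] = {}  # node ending at ref pos
    nid = 0
    for chrom, seq in reference.chromosomes:
        bps = sorted(breakpoints[chrom])
        path: List[OrientedNode] = []
        prev: Optional[int] = None
        for s, e in zip(bps, bps[1:]):
            nid += 1
            nodes[nid] = Node(nid, seq[s:e], chrom, s)
            start_node[(chrom, s)] = nid
            end_node[(chrom, e)] = nid
            path.append((nid, "+"))
            if prev is not None:
                edges.add((prev, "+", nid, "+"))
            prev = nid
        ref_path[chrom] = path

    sites: Dict[str, Site] = {}
    # ref-path node ids per chrom in order, for subpath extraction
    order: Dict[str, List[int]] = {c: [n for n, _ in p] for c, p in ref_path.items()}
    pos_of: Dict[str, Dict[int, int]] = {
        c: {n: i for i, n in enumerate(lst)} for c, lst in order.items()
    }

    for v in svs:
        chrom = v.ref_chrom
        sid = site_key(v)
        if sid in sites:
            continue
        left = end_node.get((chrom, v.ref_start))
        right = start_node.get((chrom, v.ref_end))
        if left is None or right is None:
            # SV at a chromosome end: no flanking node on that side
            raise ValueError(f"SV touches chromosome end, unsupported: {sid}")
        i0, i1 = pos_of[chrom][left], pos_of[chrom][right]
        internal = order[chrom][i0 + 1 : i1]
        ref_subpath: List[OrientedNode] = [(left, "+")] + [(n, "+") for n in internal] + [(right, "+")]
        if v.variant_class is VariantClass.CAN_DEL or (
            v.variant_class is VariantClass.COM_DEL and not v.alt_allele
        ):
            edges.add((left, "+", right, "+"))
            alt_subpath: List[OrientedNode] = [(left, "+"), (right, "+")]
        elif v.variant_class is VariantClass.INV:
            alt_subpath = [(left, "+")] + [(n, "-") for n in reversed(internal)] + [(right, "+")]
            if internal:
                edges.add((left, "+", internal[-1], "-"))
                edges.add((internal[0], "-", right, "+"))
        else:  # insertion or replacement: one alternative node
            nid += 1
            nodes[nid] = Node(nid, v.alt_allele)
            edges.add((left, "+", nid, "+"))
            edges.add((nid, "+", right, "+"))
            alt_subpath = [(left, "+"), (nid, "+"), (right, "+")]
        sites[sid] = Site(
            sid, chrom, v.ref_start, v.ref_end, v.variant_class, v.alt_allele, ref_subpath, alt_subpath
        )
    return VariationGraph(nodes, edges, ref_path, sites)


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------


def write_gfa(graph: VariationGraph) -> str:
    """GFA 1.0 text: S lines (with SN/SO tags on reference nodes), L lines, P lines."""
    lines = ["H\tVN:Z:1.0"]
    for nid in sorted(graph.nodes):
        n = graph.nodes[nid]
        tags = ""
        if n.ref_chrom is not None:
            tags = f"\tSN:Z:{n.ref_chrom}\tSO:i:{n.ref_start}"
        lines.append(f"S\t{nid}\t{n.sequence}{tags}")
    for u, uo, v, vo in sorted(graph.edges):
        lines.append(f"L\t{u}\t{uo}\t{v}\t{vo}\t0M")
    for chrom in graph.ref_path:
        steps = ",".join(f"{n}{o}" for n, o in graph.ref_path[chrom])
        lines.append(f"P\t{chrom}\t{steps}\t*")
    return "\n".join(lines) + "\n"


def read_gfa(text: str) -> VariationGraph:
    """Parse GFA 1.0 written by :func:`write_gfa` (sites are not serialized)."""
    nodes: Dict[int, Node] = {}
    edges: set = set()
    ref_path: Dict[str, List[OrientedNode]] = {}
    for line in text.splitlines():
        if not line or line.startswith("H"):
            continue
        parts = line.split("\t")
        if parts[0] == "S":
            nid = int(parts[1])
            chrom = None
            so = None
            for tag in parts[3:]:
                if tag.startswith("SN:Z:"):
                    chrom = tag[5:]
                elif tag.startswith("SO:i:"):
                    so = int(tag[5:])
            nodes[nid] = Node(nid, parts[2], chrom, so)
        elif parts[0] == "L":
            edges.add((int(parts[1]), parts[2], int(parts[3]), parts[4]))
        elif parts[0] == "P":
            steps = [(int(s[:-1]), s[-1]) for s in parts[2].split(",")]
            ref_path[parts[1]] = steps
    return VariationGraph(nodes, edges, ref_path)


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------


@dataclass
class SiteGenotype:
    site_id: str
    accession_id: str
    ref_support: int
    alt_support: int
    genotype: int  # GT_* code
    quality: float

    @property
    def genotype_label(self) -> str:
        return {GT_REF: "ref/ref", GT_HET: "ref/alt", GT_ALT: "alt/alt", GT_MISSING: "missing"}[
            self.genotype
        ]


class SVGenotyper:
    """Allele-path k-mer genotyper over the sites of a variation graph.

    For each site, the ref and alt allele spellings (subpath sequence plus
    ``flank`` bp of reference-path context on both sides) are compared; the
    k-mers private to one spelling distinguish the alleles.  A read supports
    an allele when it carries at least one distinguishing k-mer of that
    allele and none of the other.  Reads not spanning a breakpoint carry no
    distinguishing k-mer and are uninformative.
    """

    def __init__(self, graph: VariationGraph, k: int = 31, flank: int = 160, stride: int = 7):
        self.graph = graph
        self.k = k
        self.stride = stride
        self.flank = flank
        self.kmer_index: Dict[str, List[Tuple[str, int]]] = {}
        chrom_seqs = {c: graph.reference_seq(c) for c in graph.ref_path}
        for sid, site in graph.sites.items():
            seq = chrom_seqs[site.chrom]
            lf = seq[max(0, site.ref_start - flank) : site.ref_start]
            rf = seq[site.ref_end : site.ref_end + flank]
            ref_sp = lf + seq[site.ref_start : site.ref_end] + rf
            alt_core = graph.spell_path(site.alt_subpath[1:-1])
            alt_sp = lf + alt_core + rf
            ref_kmers = _kmer_set(ref_sp, k)
            alt_kmers = _kmer_set(alt_sp, k)
            for km in ref_kmers - alt_kmers:
                self.kmer_index.setdefault(km, []).append((sid, 0))
            for km in alt_kmers - ref_kmers:
                self.kmer_index.setdefault(km, []).append((sid, 1))

    def count_support(
        self, reads: Iterable, min_map_q: int = 5, min_base_q: int = 5
    ) -> Dict[str, List[int]]:
        """Per-site [ref_support, alt_support] over a read set."""
        support: Dict[str, List[int]] = {sid: [0, 0] for sid in self.graph.sites}
        k, stride = self.k, self.stride
        index = self.kmer_index
        for pair in reads:
            if pair.map_q < min_map_q or pair.base_q < min_base_q:
                continue
            for seq in (pair.seq1, pair.seq2):
                votes: Dict[str, set] = {}
                for oriented in (seq, revcomp(seq)):
                    n = len(oriented) - k
                    if n < 0:
                        continue
                    positions = list(range(0, n + 1, stride))
                    if positions[-1] != n:
                        positions.append(n)
                    for i in positions:
                        hits = index.get(oriented[i : i + k])
                        if hits:
                            for sid, allele in hits:
                                votes.setdefault(sid, set()).add(allele)
                for sid, alleles in votes.items():
                    if len(alleles) == 1:
                        support[sid][alleles.pop()] += 1
        return support

    def genotype(
        self,
        reads: Iterable,
        accession_id: str,
        min_map_q: int = 5,
        min_base_q: int = 5,
        min_support: int = 3,
        hom_threshold: float = 0.8,
    ) -> List[SiteGenotype]:
        support = self.count_support(reads, min_map_q, min_base_q)
        out = []
        for sid in self.graph.sites:
            r, a = support[sid]
            total = r + a
            if total < min_support:
                gt, qual = GT_MISSING, 0.0
            else:
                frac = a / total
                if frac >= hom_threshold:
                    gt = GT_ALT
                elif frac <= 1.0 - hom_threshold:
                    gt = GT_REF
                else:
                    gt = GT_HET
                qual = abs(frac - 0.5) * 2 * total
            out.append(SiteGenotype(sid, accession_id, r, a, gt, qual))
        return out


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]}


def genotype_site(
    graph: VariationGraph,
    site_id: str,
    reads: Iterable,
    min_map_q: int = 5,
    min_base_q: int = 5,
    min_support: int = 3,
    accession_id: str = "",
    **kwargs,
) -> SiteGenotype:
    """Genotype a single site; rejects unknown site ids."""
    if site_id not in graph.sites:
        raise KeyError(f"unknown site: {site_id}")
    sub = VariationGraph(graph.nodes, graph.edges, graph.ref_path, {site_id: graph.sites[site_id]})
    gtyper = SVGenotyper(sub, **kwargs)
    return gtyper.genotype(reads, accession_id, min_map_q, min_base_q, min_support)[0]


@dataclass
class GenotypeResult:
    matrix: pd.DataFrame  # sites x accessions, GT_* codes
    support: pd.DataFrame  # long form: site, accession, ref_support, alt_support
    call_rate: pd.Series
    allele_frequency: pd.Series
    concordance: Optional[float] = None


def genotype_population(
    graph: VariationGraph,
    panel: PopulationPanel,
    min_map_q: int = 5,
    min_base_q: int = 5,
    min_support: int = 3,
    k: int = 31,
) -> GenotypeResult:
    """Genotype all graph sites in every accession of a panel.

    When the panel carries truth genotypes for the same sites, genotype
    concordance is computed (strict: a missing call counts as discordant).
    """
    gtyper = SVGenotyper(graph, k=k)
    site_ids = list(graph.sites)
    acc_ids = list(panel.accessions["accession_id"])
    matrix = pd.DataFrame(GT_MISSING, index=site_ids, columns=acc_ids, dtype=int)
    rows = []
    for aid in acc_ids:
        read_set: Optional[ReadSet] = panel.read_sets.get(aid)
        calls = gtyper.genotype(
            read_set.reads if read_set else [], aid, min_map_q, min_base_q, min_support
        )
        for c in calls:
            matrix.loc[c.site_id, aid] = c.genotype
            rows.append(
                {
                    "site_id": c.site_id,
                    "accession_id": aid,
                    "ref_support": c.ref_support,
                    "alt_support": c.alt_support,
                    "genotype": c.genotype,
                }
            )
    support = pd.DataFrame(rows)
    called = matrix != GT_MISSING
    call_rate = called.mean(axis=1)
    with np.errstate(invalid="ignore"):
        af = (matrix.where(called) / 2).mean(axis=1, skipna=True)
    concordance = None
    truth = panel.genotypes
    shared = [s for s in site_ids if s in truth.index]
    if shared:
        t = truth.loc[shared, acc_ids]
        m = matrix.loc[shared, acc_ids]
        concordance = float((t.values == m.values).mean())
    return GenotypeResult(matrix, support, call_rate, af, concordance)
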
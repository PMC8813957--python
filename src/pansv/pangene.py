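"""Gene-based pan-genome: clustering, core/dispensable status, accumulation curves.

Genes from all accessions are single-linkage clustered over pairwise global
CDS alignments meeting both >= 95% identity and >= 50% coverage of the
shorter sequence.  A cluster is core when every accession contributes a
member, dispensable otherwise.  Representatives prefer the reference
accession's gene, then the longest CDS.  Pan/core accumulation curves are
simulated over random accession orderings, and term enrichment uses
one-sided Fisher tests with BH FDR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import edlib
import numpy as np
from scipy import stats as sps

from .selection import bh_fdr


@dataclass
class GeneModel:
    gene_id: str
    accession_id: str
    cds_sequence: str
    annotations: Tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return len(self.cds_sequence)


@dataclass
class GeneCluster:
    cluster_id: str
    members: List[GeneModel]
    representative: Optional[str] = None
    status: Optional[str] = None  # core | dispensable

    @property
    def accessions_present(self) -> Set[str]:
        return {g.accession_id for g in self.members}


def pairwise_identity_coverage(a: str, b: str) -> Tuple[float, float]:
    """(identity, coverage) of the best alignment of the shorter CDS in the longer.

    The shorter sequence is aligned as an infix of the longer (so a
    truncated gene copy still matches its full-length family member).
    Identity is matching columns over alignment columns; coverage is the
    fraction of the shorter sequence aligned to actual bases of the longer.
    """
    if not a or not b:
        return 0.0, 0.0
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(shorter, longer, mode="HW", task="path")
    matches = cols = covered = 0
    for n, op in ((int(x), y) for x, y in re.findall(r"(\d+)([=XID])", res["cigar"])):
        cols += n
        if op == "=":
            matches += n
            covered += n
        elif op == "X":
            covered += n
    identity = matches / cols if cols else 0.0
    coverage = covered / len(shorter)
    return identity, coverage


def cluster_genes(
    genes: Sequence[GeneModel],
    min_identity: float = 0.95,
    min_coverage: float = 0.50,
) -> List[GeneCluster]:
    """Single-linkage clusters over qualifying pairwise alignments.

    Every gene lands in exactly one cluster; the result is invariant to
    input order (pairs are visited in canonical gene-id order and clusters
    are canonically sorted).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("no genes to cluster")
    n = len(genes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    order = sorted(range(n), key=lambda i: genes[i].gene_id)
    for ii in range(n):
        for jj in range(ii + 1, n):
            i, j = order[ii], order[jj]
            if find(i) == find(j):
                continue
            a, b = genes[i].cds_sequence, genes[j].cds_sequence
            if min(len(a), len(b)) == 0:
                continue
            ident, cov = pairwise_identity_coverage(a, b)
            if ident >= min_identity and cov >= min_coverage:
                union(i, j)

    groups: Dict[int, List[GeneModel]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(genes[i])
    clusters = [
        GeneCluster("", sorted(m, key=lambda g: g.gene_id)) for m in groups.values()
    ]
    clusters.sort(key=lambda c: c.members[0].gene_id)
    for idx, c in enumerate(clusters, start=1):
        c.cluster_id = f"PANC{idx:05d}"
    return clusters


def classify_core_dispensable(
    clusters: Sequence[GeneCluster], n_accessions: int, accessions: Optional[Set[str]] = None
) -> Dict[str, int]:
    """Assign core/dispensable status in place; return counts per status."""
    counts = {"core": 0, "dispensable": 0}
    for c in clusters:
        present = c.accessions_present
        if accessions is not None:
            complete = present >= accessions
        else:
            complete = len(present) >= n_accessions
        c.status = "core" if complete else "dispensable"
        counts[c.status] += 1
    return counts


def select_representative(cluster: GeneCluster, reference_accession: str) -> str:
    """Reference member preferred; else longest CDS; ties by gene id."""
    if not cluster.members:
        raise ValueError("empty cluster")
    ref_members = [g for g in cluster.members if g.accession_id == reference_accession]
    pool = ref_members or cluster.members
    best = sorted(pool, key=lambda g: (-g.length, g.gene_id))[0]
    cluster.representative = best.gene_id
    return best.gene_id


@dataclass
class PanCurve:
    k: np.ndarray
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    added_mean: np.ndarray
    orderings: List[List[str]] = field(default_factory=list)
    pan_samples: Optional[np.ndarray] = None  # orderings x k
    core_samples: Optional[np.ndarray] = None


def pan_core_curve(
    clusters: Sequence[GeneCluster], n_orderings: int = 100, seed: int = 0
) -> PanCurve:
    """Pan (union) and core (intersection) cluster counts over random orderings.

    For every sampled ordering the pan curve is non-decreasing and the core
    curve non-increasing; at k = N they equal the total cluster count and
    the core cluster count respectively.
    """
    accessions = sorted({a for c in clusters for a in c.accessions_present})
    n_acc = len(accessions)
    if n_acc < 2:
        raise ValueError("need >= 2 accessions")
    membership = [frozenset(c.accessions_present) for c in clusters]
    rng = np.random.default_rng(seed)
    pan = np.zeros((n_orderings, n_acc), dtype=int)
    core = np.zeros((n_orderings, n_acc), dtype=int)
    orderings = []
    for o in range(n_orderings):
        order = list(rng.permutation(accessions))
        orderings.append(order)
        seen: Set[str] = set()
        for ki, acc in enumerate(order):
            seen.add(acc)
            pan[o, ki] = sum(1 for m in membership if m & seen)
            core[o, ki] = sum(1 for m in membership if seen <= m)
    added = np.diff(pan, axis=1, prepend=0)
    return PanCurve(
        k=np.arange(1, n_acc + 1),
        pan_mean=pan.mean(axis=0),
        pan_sd=pan.std(axis=0),
        core_mean=core.mean(axis=0),
        core_sd=core.std(axis=0),
        added_mean=added.mean(axis=0),
        orderings=orderings,
        pan_samples=pan,
        core_samples=core,
    )


@dataclass
class EnrichedTerm:
    term: str
    fg_with: int
    fg_total: int
    bg_with: int
    bg_total: int
    p_value: float
    q_value: float
    enriched: bool


def set_enrichment(
    foreground: Set[str],
    background: Set[str],
    term_map: Dict[str, Set[str]],
    fdr: float = 0.05,
) -> List[EnrichedTerm]:
    """Per-term one-sided Fisher over-representation test with BH correction.

    ``term_map`` maps a term to the genes annotated with it; foreground must
    be a subset of background.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    if not foreground:
        return []
    results = []
    terms = sorted(term_map)
    pvals = []
    rows = []
    for term in terms:
        annotated = term_map[term] & background
        fw = len(annotated & foreground)
        bw = len(annotated)
        ft = len(foreground)
        bt = len(background)
        # over-representation in foreground vs the rest of the background
        table = [[fw, ft - fw], [bw - fw, (bt - ft) - (bw - fw)]]
        p = float(sps.fisher_exact(table, alternative="greater")[1])
        pvals.append(p)
        rows.append((term, fw, ft, bw, bt))
    qvals = bh_fdr(pvals)
    for (term, fw, ft, bw, bt), p, q in zip(rows, pvals, qvals):
        results.append(EnrichedTerm(term, fw, ft, bw, bt, p, float(q), q < fdr))
    return [r for r in results]
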
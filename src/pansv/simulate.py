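"""Synthetic data generation: genomes, implanted variants, reads, populations.

Every downstream stage of the toolkit (alignment, variant discovery,
read-depth support, graph genotyping, selection scans, pan-gene analysis)
is exercised on data produced here, with the ground truth retained so
recall/precision and concordance can be measured exactly.

All generators are deterministic for a fixed seed.  The genome model is
deliberately simple — i.i.d. base composition, no repeat landscape — which
makes anchor uniqueness and flank uniqueness the common case; see
docs/methods.md for what that does and does not demonstrate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import gc_fraction, random_dna, revcomp
from .model import (
    SV_MIN_SIZE,
    Variant,
    VariantClass,
    left_align,
)

# genotype codes used throughout (haploid panels use only 0 / 2 / -1)
GT_MISSING = -1
GT_REF = 0
GT_HET = 1
GT_ALT = 2

TISSUES = (
    "roots",
    "stems",
    "leaves",
    "male_flowers",
    "female_flowers",
    "fruits",
    "tendrils",
)


@dataclass
class SimulatedGenome:
    """A multi-chromosome genome held in memory.

    ``chromosomes`` preserves order; names must be unique.
    """

    accession_id: str
    chromosomes: List[Tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(not s for _, s in self.chromosomes):
            raise ValueError("empty chromosome sequence")

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def seqs(self) -> Dict[str, str]:
        return dict(self.chromosomes)

    @property
    def lengths(self) -> Dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)


def simulate_reference(
    n_chrom: int, chrom_length: int, gc: float = 0.35, seed: int = 0
) -> SimulatedGenome:
    """Random reference genome of ``n_chrom`` chromosomes of equal length."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", random_dna(chrom_length, gc, rng)) for i in range(n_chrom)]
    return SimulatedGenome(accession_id="reference", chromosomes=chroms)


# ---------------------------------------------------------------------------
# variant implantation
# ---------------------------------------------------------------------------


@dataclass
class VariantSpec:
    """Per-class counts and size distributions for implantation.

    Sizes are sampled uniformly from the inclusive ranges below.  Complex
    InDels are replacements: a reference segment of ``com_ref_range`` bp is
    replaced by an unrelated sequence of ``com_alt_range`` bp (resampled
    until the two lengths differ).  ``min_spacing`` keeps implanted events
    apart so in-block diffing is unambiguous.
    """

    counts: Dict[VariantClass, int] = field(default_factory=dict)
    small_range: Tuple[int, int] = (1, SV_MIN_SIZE - 1)
    canonical_range: Tuple[int, int] = (SV_MIN_SIZE, 1000)
    com_ref_range: Tuple[int, int] = (SV_MIN_SIZE, 300)
    com_alt_range: Tuple[int, int] = (SV_MIN_SIZE, 500)
    inv_range: Tuple[int, int] = (5_000, 50_000)
    trans_range: Tuple[int, int] = (2_000, 10_000)
    min_spacing: int = 500
    edge_margin: int = 2_000


class PlacementError(RuntimeError):
    """Raised when a variant class cannot be placed at the requested density."""


def _sample_size(rng: np.random.Generator, lo_hi: Tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def implant_variants(
    reference: SimulatedGenome,
    spec: VariantSpec,
    seed: int = 0,
    accession_id: str = "derived",
) -> Tuple[SimulatedGenome, List[Variant]]:
    """Place non-overlapping variants on the reference and build the derived genome.

    Returns the derived genome plus the truth list with both reference and
    derived (query) coordinates populated.  Placement is rejection sampling
    with ``spec.min_spacing`` bp between reference footprints; N runs are
    avoided.  InDels are left-normalized so truth coordinates follow the
    same convention as the caller's output.
    """
    rng = np.random.default_rng(seed)
    seqs = reference.seqs
    names = reference.names
    lengths = [len(seqs[n]) for n in names]
    weights = np.array(lengths, dtype=float) / sum(lengths)
    # occupied reference intervals per chrom (footprint + spacing handled at check)
    occupied: Dict[str, List[Tuple[int, int]]] = {n: [] for n in names}

    def conflict(chrom: str, s: int, e: int) -> bool:
        pad = spec.min_spacing
        return any(s - pad < oe and os_ - pad < e for os_, oe in occupied[chrom])

    def place(span: int, want_class: VariantClass, chrom: Optional[str] = None) -> Tuple[str, int]:
        for _ in range(2000):
            c = chrom or names[int(rng.choice(len(names), p=weights))]
            lo = spec.edge_margin
            hi = len(seqs[c]) - spec.edge_margin - span
            if hi <= lo:
                continue
            s = int(rng.integers(lo, hi))
            if conflict(c, s, s + max(span, 1)):
                continue
            window = seqs[c][max(0, s - 1) : s + span + 1]
            if "N" in window:
                continue
            occupied[c].append((s, s + max(span, 1)))
            return c, s
        raise PlacementError(f"could not place a {want_class.value} variant (density too high?)")

    order = [
        VariantClass.TRANS,
        VariantClass.INV,
        VariantClass.CAN_DEL,
        VariantClass.CAN_INS,
        VariantClass.COM_DEL,
        VariantClass.COM_INS,
        VariantClass.SMALL_DEL,
        VariantClass.SMALL_INS,
        VariantClass.SNP,
    ]
    variants: List[Variant] = []
    for vclass in order:
        for _ in range(spec.counts.get(vclass, 0)):
            if vclass is VariantClass.SNP:
                c, s = place(1, vclass)
                ref_b = seqs[c][s]
                alt_b = rng.choice([b for b in "ACGT" if b != ref_b])
                v = Variant(vclass, c, s, s + 1, ref_b, str(alt_b))
            elif vclass in (VariantClass.SMALL_DEL, VariantClass.CAN_DEL):
                size = _sample_size(
                    rng, spec.small_range if vclass is VariantClass.SMALL_DEL else spec.canonical_range
                )
                c, s = place(size, vclass)
                v = Variant(vclass, c, s, s + size, seqs[c][s : s + size], "")
            elif vclass in (VariantClass.SMALL_INS, VariantClass.CAN_INS):
                size = _sample_size(
                    rng, spec.small_range if vclass is VariantClass.SMALL_INS else spec.canonical_range
                )
                c, s = place(0, vclass)
                v = Variant(vclass, c, s, s, "", random_dna(size, 0.5, rng))
            elif vclass in (VariantClass.COM_DEL, VariantClass.COM_INS):
                while True:
                    ref_len = _sample_size(rng, spec.com_ref_range)
                    alt_len = _sample_size(rng, spec.com_alt_range)
                    if vclass is VariantClass.COM_INS and alt_len > ref_len:
                        break
                    if vclass is VariantClass.COM_DEL and alt_len < ref_len:
                        break
                c, s = place(ref_len, vclass)
                v = Variant(
                    vclass, c, s, s + ref_len, seqs[c][s : s + ref_len], random_dna(alt_len, 0.5, rng),
                    precise=False,
                )
            elif vclass is VariantClass.INV:
                size = _sample_size(rng, spec.inv_range)
                c, s = place(size, vclass)
                seg = seqs[c][s : s + size]
                v = Variant(vclass, c, s, s + size, seg, revcomp(seg))
            else:  # TRANS
                size = _sample_size(rng, spec.trans_range)
                c, s = place(size, vclass)
                others = [n for n in names if n != c] or [c]
                dc = others[int(rng.integers(len(others)))]
                dc, dp = place(0, vclass, chrom=dc)
                seg = seqs[c][s : s + size]
                v = Variant(vclass, c, s, s + size, seg, "", dest_chrom=dc, dest_pos=dp)
            v.accession_id = accession_id
            if v.variant_class in (
                VariantClass.SMALL_INS,
                VariantClass.SMALL_DEL,
                VariantClass.CAN_INS,
                VariantClass.CAN_DEL,
            ):
                v = left_align(v, seqs[v.ref_chrom])
            variants.append(v)

    derived = apply_variants(reference, variants, accession_id=accession_id)
    variants.sort(key=lambda v: (v.ref_chrom, v.ref_start, v.ref_end))
    return derived, variants


def _edits_for(variants: Sequence[Variant]):
    """Expand variants into per-chromosome (start, end, replacement, variant, role)."""
    edits: Dict[str, list] = {}
    for v in variants:
        if v.variant_class is VariantClass.TRANS:
            edits.setdefault(v.ref_chrom, []).append((v.ref_start, v.ref_end, "", v, "src"))
            edits.setdefault(v.dest_chrom, []).append(
                (v.dest_pos, v.dest_pos, v.ref_allele, v, "dest")
            )
        else:
            edits.setdefault(v.ref_chrom, []).append(
                (v.ref_start, v.ref_end, v.alt_allele, v, "main")
            )
    for lst in edits.values():
        lst.sort(key=lambda t: (t[0], t[1]))
        prev_end = -1
        for s, e, *_ in lst:
            if s < prev_end:
                raise ValueError("overlapping variants cannot be applied")
            prev_end = max(e, s)
    return edits


def apply_variants(
    reference: SimulatedGenome,
    variants: Sequence[Variant],
    accession_id: str = "derived",
    set_qry_coords: bool = True,
) -> SimulatedGenome:
    """Apply a non-overlapping truth set left-to-right; fills query coordinates.

    Applying the returned truth list to the reference reproduces the
    derived genome byte-for-byte (tested property).
    """
    edits = _edits_for(variants)
    out: List[Tuple[str, str]] = []
    for name, seq in reference.chromosomes:
        pieces = []
        pos = 0
        offset = 0
        for s, e, rep, v, role in edits.get(name, []):
            pieces.append(seq[pos:s])
            pieces.append(rep)
            qs = s + offset
            if set_qry_coords:
                if role == "main":
                    v.qry_chrom, v.qry_start, v.qry_end = name, qs, qs + len(rep)
                elif role == "dest":
                    v.qry_chrom, v.qry_start, v.qry_end = name, qs, qs + len(rep)
            offset += len(rep) - (e - s)
            pos = e
        pieces.append(seq[pos:])
        out.append((name, "".join(pieces)))
    return SimulatedGenome(accession_id=accession_id, chromosomes=out)


def segment_map(
    reference: SimulatedGenome, variants: Sequence[Variant]
) -> Dict[str, List[Tuple[int, int, int]]]:
    """Unchanged-segment map between reference and derived coordinates.

    Returns per chromosome a sorted list of ``(ref_start, ref_end, qry_start)``
    for the maximal runs untouched by any variant; within a run the offset is
    constant.  Used to project simulated read placements from one genome onto
    the other (the simulator's stand-in for read mapping).
    """
    edits = _edits_for(variants)
    segmap: Dict[str, List[Tuple[int, int, int]]] = {}
    for name, seq in reference.chromosomes:
        runs = []
        pos = 0
        offset = 0
        for s, e, rep, _v, _role in edits.get(name, []):
            if s > pos:
                runs.append((pos, s, pos + offset))
            offset += len(rep) - (e - s)
            pos = e
        if len(seq) > pos:
            runs.append((pos, len(seq), pos + offset))
        segmap[name] = runs
    return segmap


def invert_segment_map(
    segmap: Dict[str, List[Tuple[int, int, int]]]
) -> Dict[str, List[Tuple[int, int, int]]]:
    """Swap the roles of the two genomes in a segment map."""
    out: Dict[str, List[Tuple[int, int, int]]] = {}
    for chrom, runs in segmap.items():
        inv = [(qs, qs + (re_ - rs), rs) for rs, re_, qs in runs]
        inv.sort()
        out[chrom] = inv
    return out


def project_interval(
    runs: List[Tuple[int, int, int]], start: int, end: int, min_piece: int = 20
) -> List[Tuple[int, int]]:
    """Project [start, end) through an unchanged-segment list; returns pieces."""
    pieces = []
    for rs, re_, qs in runs:
        lo = max(start, rs)
        hi = min(end, re_)
        if hi - lo >= min_piece:
            pieces.append((lo - rs + qs, hi - rs + qs))
    return pieces


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class ReadPair:
    pair_id: str
    chrom: str
    frag_start: int
    frag_end: int
    seq1: str
    seq2: str
    map_q: int = 60
    base_q: int = 40


@dataclass
class ReadSet:
    accession_id: str
    reads: List[ReadPair]
    read_len: int
    coverage: float
    error_rate: float

    def __iter__(self):
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)


def simulate_reads(
    genome: SimulatedGenome,
    coverage: float,
    read_len: int = 150,
    insert_mean: int = 400,
    insert_sd: Optional[float] = None,
    error_rate: float = 0.0,
    seed: int = 0,
    map_q: int = 60,
    base_q: int = 40,
) -> ReadSet:
    """Paired-end reads with uniform fragment placement and substitution errors.

    The truth placement (fragment interval on the source genome) is retained
    per pair so depth and genotyping oracles never need an external mapper.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    min_len = min(genome.lengths.values())
    if not (read_len < insert_mean < min_len):
        raise ValueError("need read_len < insert_mean < min chromosome length")
    if insert_sd is None:
        insert_sd = 0.1 * insert_mean
    rng = np.random.default_rng(seed)
    reads: List[ReadPair] = []
    for name, seq in genome.chromosomes:
        length = len(seq)
        n_pairs = int(round(coverage * length / (2 * read_len)))
        inserts = np.clip(
            rng.normal(insert_mean, insert_sd, size=n_pairs).astype(int), read_len, length
        )
        starts = rng.integers(0, np.maximum(length - inserts + 1, 1))
        for i in range(n_pairs):
            s = int(starts[i])
            e = s + int(inserts[i])
            r1 = seq[s : s + read_len]
            r2 = revcomp(seq[e - read_len : e])
            if error_rate > 0:
                r1 = _add_errors(r1, error_rate, rng)
                r2 = _add_errors(r2, error_rate, rng)
            reads.append(ReadPair(f"{genome.accession_id}:{name}:{i}", name, s, e, r1, r2, map_q, base_q))
    return ReadSet(genome.accession_id, reads, read_len, coverage, error_rate)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


@dataclass(frozen=True)
class PairPlacement:
    """Placement of one read pair on a genome, as read intervals."""

    chrom: str
    intervals: Tuple[Tuple[int, int], ...]
    map_q: int


def pair_placements(read_set: ReadSet) -> List[PairPlacement]:
    """Truth placements on the genome the reads were simulated from."""
    rl = read_set.read_len
    return [
        PairPlacement(r.chrom, ((r.frag_start, r.frag_start + rl), (r.frag_end - rl, r.frag_end)), r.map_q)
        for r in read_set
    ]


def project_pair_placements(
    read_set: ReadSet,
    runs_by_chrom: Dict[str, List[Tuple[int, int, int]]],
    min_piece: int = 20,
) -> List[PairPlacement]:
    """Project truth placements onto the other genome of a pair.

    Stands in for mapping the reads to that genome: read portions falling in
    sequence absent from the target (e.g. an insertion allele) are dropped,
    junction-spanning reads split into their flanking pieces, mimicking
    soft-clipped alignments.
    """
    rl = read_set.read_len
    out = []
    for r in read_set:
        runs = runs_by_chrom.get(r.chrom, [])
        pieces = tuple(
            project_interval(runs, r.frag_start, r.frag_start + rl, min_piece)
            + project_interval(runs, r.frag_end - rl, r.frag_end, min_piece)
        )
        if pieces:
            out.append(PairPlacement(r.chrom, pieces, r.map_q))
    return out


# ---------------------------------------------------------------------------
# population panel
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSpec:
    """Expression table layout with implanted wild-vs-cultivated fold changes.

    ``implanted`` maps (gene_id, tissue) to the log2 fold-change of the
    cultivated group over the wild group.
    """

    genes: List[str]
    implanted: Dict[Tuple[str, str], float] = field(default_factory=dict)
    tissues: Tuple[str, ...] = TISSUES
    base_mean_tpm: float = 20.0
    noise_sd: float = 0.05


@dataclass
class PopulationPanel:
    accessions: pd.DataFrame  # columns: accession_id, group, subgroup
    sites: List[Variant]
    genotypes: pd.DataFrame  # sites (index: site id) x accessions; codes -1/0/1/2
    read_sets: Dict[str, ReadSet]
    accession_variants: Dict[str, List[Variant]]
    expr_wild: Optional[pd.DataFrame] = None
    expr_cult: Optional[pd.DataFrame] = None
    expression_truth: Dict[Tuple[str, str], float] = field(default_factory=dict)

    @property
    def groups(self) -> Dict[str, str]:
        return dict(zip(self.accessions["accession_id"], self.accessions["group"]))


def site_key(v: Variant) -> str:
    return v.id or f"{v.ref_chrom}:{v.ref_start}-{v.ref_end}:{v.variant_class.value}"


def simulate_population(
    reference: SimulatedGenome,
    truth_svs: Sequence[Variant],
    n_wild: int,
    n_cultivated: int,
    site_freqs: Optional[Sequence[Tuple[float, float]]] = None,
    min_divergence: float = 0.25,
    ploidy: int = 1,
    read_coverage: Optional[float] = None,
    read_len: int = 150,
    insert_mean: int = 400,
    error_rate: float = 0.0,
    expression_spec: Optional[ExpressionSpec] = None,
    seed: int = 0,
) -> PopulationPanel:
    """Two-group panel with per-site truth genotypes, reads and expression.

    ``site_freqs`` gives the (wild, cultivated) alternate-allele frequency
    per SV site; when omitted, frequencies are drawn uniformly from
    [0.2, 0.8] for both groups.  Haploid (selfed inbred) panels code
    genotypes 0/2; ``ploidy=2`` enables the heterozygous path.
    """
    if n_wild < 2 or n_cultivated < 2:
        raise ValueError("each group needs >= 2 accessions")
    rng = np.random.default_rng(seed)
    sites = list(truth_svs)
    if site_freqs is None:
        site_freqs = [
            (float(rng.uniform(0.2, 0.8)), float(rng.uniform(0.2, 0.8))) for _ in sites
        ]
    if len(site_freqs) != len(sites):
        raise ValueError("site_freqs length must match truth_svs")
    for pw, pc in site_freqs:
        if not (0.0 <= pw <= 1.0 and 0.0 <= pc <= 1.0):
            raise ValueError("frequencies must be in [0, 1]")
    if sites and not any(abs(pw - pc) >= min_divergence for pw, pc in site_freqs):
        raise ValueError(f"no site with |p_wild - p_cult| >= {min_divergence}")

    acc_rows = [(f"wild_{i:02d}", "wild", "hardwickii") for i in range(n_wild)] + [
        (f"cult_{i:02d}", "cultivated", "cultivated") for i in range(n_cultivated)
    ]
    accessions = pd.DataFrame(acc_rows, columns=["accession_id", "group", "subgroup"])

    gt = np.zeros((len(sites), len(acc_rows)), dtype=int)
    for j, (_aid, group, _sg) in enumerate(acc_rows):
        for i, (pw, pc) in enumerate(site_freqs):
            p = pw if group == "wild" else pc
            if ploidy == 1:
                gt[i, j] = GT_ALT if rng.random() < p else GT_REF
            else:
                gt[i, j] = int(rng.binomial(2, p))
    index = [site_key(v) for v in sites]
    genotypes = pd.DataFrame(gt, index=index, columns=accessions["accession_id"])

    read_sets: Dict[str, ReadSet] = {}
    accession_variants: Dict[str, List[Variant]] = {}
    for j, (aid, _g, _sg) in enumerate(acc_rows):
        carried = [dataclasses.replace(v, accession_id=aid) for i, v in enumerate(sites) if gt[i, j] >= GT_HET]
        accession_variants[aid] = carried
        if read_coverage:
            personal = apply_variants(reference, carried, accession_id=aid)
            read_sets[aid] = simulate_reads(
                personal,
                read_coverage,
                read_len=read_len,
                insert_mean=insert_mean,
                error_rate=error_rate,
                seed=int(rng.integers(0, 2**31 - 1)),
            )

    expr_wild = expr_cult = None
    expression_truth: Dict[Tuple[str, str], float] = {}
    if expression_spec is not None:
        tissues = list(expression_spec.tissues)
        base = rng.lognormal(np.log(expression_spec.base_mean_tpm), 0.5, size=(len(expression_spec.genes), len(tissues)))
        noise = lambda: rng.lognormal(0.0, expression_spec.noise_sd, size=base.shape)  # noqa: E731
        w = base * noise()
        c = base * noise()
        expr_wild = pd.DataFrame(w, index=expression_spec.genes, columns=tissues)
        expr_cult = pd.DataFrame(c, index=expression_spec.genes, columns=tissues)
        for (gene, tissue), lfc in expression_spec.implanted.items():
            expr_cult.loc[gene, tissue] = expr_wild.loc[gene, tissue] * 2.0**lfc
            expression_truth[(gene, tissue)] = lfc

    return PopulationPanel(
        accessions=accessions,
        sites=sites,
        genotypes=genotypes,
        read_sets=read_sets,
        accession_variants=accession_variants,
        expr_wild=expr_wild,
        expr_cult=expr_cult,
        expression_truth=expression_truth,
    )


def simulate_diversity_panel(
    seq_length: int,
    n_sites: int,
    n_wild: int,
    n_cult: int,
    sweep_interval: Optional[Tuple[int, int]] = None,
    sweep_factor: float = 10.0,
    chrom: str = "chr1",
    seed: int = 0,
):
    """Biallelic haplotype matrices for diversity scans, with an optional sweep.

    Inside ``sweep_interval`` the cultivated group's polymorphism is thinned
    so its expected per-site diversity drops by ``sweep_factor``; the wild
    group is untouched.  Returns (positions, hap_wild, hap_cult) where the
    haplotype arrays are (n_haplotypes x n_sites) 0/1 matrices.
    """
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(seq_length, size=n_sites, replace=False))
    freqs = rng.uniform(0.1, 0.5, size=n_sites)
    hap_w = (rng.random((n_wild, n_sites)) < freqs).astype(np.int8)
    fc = freqs.copy()
    if sweep_interval is not None:
        s, e = sweep_interval
        in_sweep = (positions >= s) & (positions < e)
        kill = in_sweep & (rng.random(n_sites) < 1.0 - 1.0 / sweep_factor)
        fc[kill] = 0.0
    hap_c = (rng.random((n_cult, n_sites)) < fc).astype(np.int8)
    return positions, hap_w, hap_c


__all__ = [
    "SimulatedGenome",
    "VariantSpec",
    "PlacementError",
    "ExpressionSpec",
    "PopulationPanel",
    "ReadPair",
    "ReadSet",
    "PairPlacement",
    "TISSUES",
    "GT_MISSING",
    "GT_REF",
    "GT_HET",
    "GT_ALT",
    "simulate_reference",
    "implant_variants",
    "apply_variants",
    "segment_map",
    "invert_segment_map",
    "project_interval",
    "simulate_reads",
    "pair_placements",
    "project_pair_placements",
    "simulate_population",
    "simulate_diversity_panel",
    "site_key",
    "gc_fraction",
]
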
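"""Truth-vs-called evaluation and the packaged benchmark experiments.

The experiments here are the package's own end-to-end checks, run both by
the test suite and by ``scripts/acceptance.py``: SV-caller truth recovery
on a 5 Mb two-chromosome genome with 200 implanted variants, variation-
graph genotyping concordance on a 20-accession panel over 50 SV sites,
read-depth support of true homozygous deletions (and insertions via the
reference swap), and recovery of an implanted selective sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .discovery import (
    CallSet,
    GeneAnnot,
    annotate_gene_overlap,
    assign_ids,
    call_variants,
)
from .graph import build_graph, genotype_population
from .model import (
    CANONICAL_CLASSES,
    COMPLEX_CLASSES,
    Variant,
    VariantClass,
)
from .selection import carrier_frequencies, nucleotide_diversity, sweep_regions
from .simulate import (
    GT_ALT,
    GT_REF,
    SimulatedGenome,
    VariantSpec,
    implant_variants,
    invert_segment_map,
    pair_placements,
    project_pair_placements,
    segment_map,
    simulate_diversity_panel,
    simulate_population,
    simulate_reads,
    simulate_reference,
)
from .support import depth_profile, rd_support, swap_reference


@dataclass
class MatchResult:
    n_truth: int
    n_called: int
    n_matched_truth: int
    n_matched_called: int
    n_exact: int

    @property
    def recall(self) -> float:
        return self.n_matched_truth / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched_called / self.n_called if self.n_called else float("nan")

    @property
    def exact_fraction(self) -> float:
        return self.n_exact / self.n_matched_called if self.n_matched_called else float("nan")


def _same_group(a: VariantClass, b: VariantClass) -> bool:
    if a in CANONICAL_CLASSES and b in CANONICAL_CLASSES:
        return (a is VariantClass.CAN_INS) == (b is VariantClass.CAN_INS)
    if a in COMPLEX_CLASSES and b in COMPLEX_CLASSES:
        return (a is VariantClass.COM_INS) == (b is VariantClass.COM_INS)
    return a is b


def match_variants(
    truth: Sequence[Variant],
    called: Sequence[Variant],
    classes: set,
    tolerance: int = 20,
) -> MatchResult:
    """Greedy 1:1 matching of calls to truth within a class group.

    A call matches a truth variant of the same (INS/DEL-polarised) class
    when both breakpoints are within ``tolerance`` bp.  Exactness means
    identical (start, end, alt allele).
    """
    t = [v for v in truth if v.variant_class in classes]
    c = [v for v in called if v.variant_class in classes]
    used = set()
    matched_t = 0
    matched_c = 0
    exact = 0
    for tv in t:
        best = None
        for i, cv in enumerate(c):
            if i in used or cv.ref_chrom != tv.ref_chrom:
                continue
            if not _same_group(tv.variant_class, cv.variant_class):
                continue
            if abs(cv.ref_start - tv.ref_start) <= tolerance and abs(cv.ref_end - tv.ref_end) <= tolerance:
                d = abs(cv.ref_start - tv.ref_start) + abs(cv.ref_end - tv.ref_end)
                if best is None or d < best[0]:
                    best = (d, i)
        if best is not None:
            used.add(best[1])
            matched_t += 1
            matched_c += 1
            cv = c[best[1]]
            if (
                cv.ref_start == tv.ref_start
                and cv.ref_end == tv.ref_end
                and cv.alt_allele == tv.alt_allele
            ):
                exact += 1
    return MatchResult(len(t), len(c), matched_t, matched_c, exact)


# ---------------------------------------------------------------------------
# benchmark experiments
# ---------------------------------------------------------------------------

DISCOVERY_COUNTS = {
    VariantClass.SNP: 40,
    VariantClass.SMALL_INS: 20,
    VariantClass.SMALL_DEL: 20,
    VariantClass.CAN_INS: 35,
    VariantClass.CAN_DEL: 35,
    VariantClass.COM_INS: 20,
    VariantClass.COM_DEL: 20,
    VariantClass.INV: 5,
    VariantClass.TRANS: 5,
}


def sv_discovery_experiment(
    seed: int,
    n_chrom: int = 2,
    chrom_length: int = 2_500_000,
    counts: Optional[Dict[VariantClass, int]] = None,
) -> Dict[str, object]:
    """Implant 200 variants on a 5 Mb genome, call them back, score recovery."""
    ref = simulate_reference(n_chrom, chrom_length, gc=0.35, seed=seed)
    spec = VariantSpec(counts=dict(counts or DISCOVERY_COUNTS))
    derived, truth = implant_variants(ref, spec, seed=seed + 1, accession_id="acc1")
    calls = call_variants(ref, derived)
    canonical = match_variants(truth, calls.variants, CANONICAL_CLASSES)
    cplx = match_variants(truth, calls.variants, COMPLEX_CLASSES)
    inv = match_variants(
        truth, calls.variants, {VariantClass.INV}, tolerance=50
    )
    snp = match_variants(truth, calls.variants, {VariantClass.SNP}, tolerance=0)
    return {
        "calls": calls,
        "truth": truth,
        "canonical": canonical,
        "complex": cplx,
        "inversions": inv,
        "snp": snp,
    }


GENOTYPE_COUNTS = {
    VariantClass.CAN_INS: 15,
    VariantClass.CAN_DEL: 15,
    VariantClass.COM_INS: 5,
    VariantClass.COM_DEL: 5,
    VariantClass.INV: 10,
}


def genotyping_experiment(
    seed: int,
    n_wild: int = 10,
    n_cult: int = 10,
    coverage: float = 20.0,
    chrom_length: int = 200_000,
) -> Dict[str, object]:
    """Error-free 20x panel genotyped over 50 graph sites; returns concordance."""
    ref = simulate_reference(1, chrom_length, gc=0.35, seed=seed)
    spec = VariantSpec(
        counts=dict(GENOTYPE_COUNTS),
        canonical_range=(50, 300),
        com_ref_range=(50, 150),
        com_alt_range=(50, 250),
        inv_range=(300, 800),
    )
    _derived, truth = implant_variants(ref, spec, seed=seed + 1, accession_id="donor")
    truth = assign_ids(truth)
    panel = simulate_population(
        ref,
        truth,
        n_wild,
        n_cult,
        min_divergence=0.0,
        read_coverage=coverage,
        read_len=150,
        insert_mean=400,
        error_rate=0.0,
        seed=seed + 2,
    )
    graph = build_graph(ref, truth)
    result = genotype_population(graph, panel)
    return {"graph": graph, "panel": panel, "result": result, "n_sites": len(graph.sites)}


def rd_support_experiment(
    seed: int, coverage: float = 30.0, chrom_length: int = 300_000
) -> Dict[str, object]:
    """RD rule on true homozygous deletions and swapped insertions at 30x."""
    ref = simulate_reference(1, chrom_length, gc=0.35, seed=seed)
    spec = VariantSpec(
        counts={VariantClass.CAN_DEL: 10, VariantClass.CAN_INS: 10},
        canonical_range=(50, 2000),
    )
    derived, truth = implant_variants(ref, spec, seed=seed + 1, accession_id="carrier")
    segmap = segment_map(ref, truth)

    carrier_reads = simulate_reads(derived, coverage, seed=seed + 2)
    on_ref = project_pair_placements(carrier_reads, invert_segment_map(segmap))
    depth_ref = depth_profile(on_ref, ref.lengths)
    deletions = [v for v in truth if v.variant_class is VariantClass.CAN_DEL]
    del_calls = [rd_support(d, depth_ref) for d in deletions]

    ref_reads = simulate_reads(ref, coverage, seed=seed + 3)
    on_qry = project_pair_placements(ref_reads, segmap)
    depth_qry = depth_profile(on_qry, derived.lengths)
    insertions = [v for v in truth if v.variant_class is VariantClass.CAN_INS]
    swapped = [swap_reference(v) for v in insertions]
    ins_calls = [rd_support(s, depth_qry) for s in swapped]

    involution_ok = all(swap_reference(swap_reference(v)) == v for v in insertions)
    return {
        "deletion_calls": del_calls,
        "insertion_calls": ins_calls,
        "deletion_supported_fraction": float(np.mean([c.rd_supported for c in del_calls])),
        "insertion_supported_fraction": float(np.mean([c.rd_supported for c in ins_calls])),
        "involution_ok": involution_ok,
        "mean_depth": float(np.mean([a.mean() for a in depth_ref.depths.values()])),
    }


def sweep_experiment(
    seed: int,
    seq_length: int = 1_000_000,
    n_sites: int = 10_000,
    window: int = 10_000,
    sweep_interval: Tuple[int, int] = (500_000, 550_000),
    sweep_factor: float = 10.0,
) -> Dict[str, object]:
    """Implanted 10x diversity reduction recovered by the top-5% ratio scan."""
    positions, hap_w, hap_c = simulate_diversity_panel(
        seq_length, n_sites, 20, 20, sweep_interval, sweep_factor, seed=seed
    )
    track = nucleotide_diversity(positions, hap_w, hap_c, seq_length, window, window)
    sweeps = sweep_regions(track, top_fraction=0.05)
    windows = track.windows
    called = set()
    for r in sweeps:
        hit = windows[(windows["start"] >= r.start) & (windows["end"] <= r.end)]
        called.update(hit.index)
    truth_idx = set(
        windows[
            (windows["start"] >= sweep_interval[0]) & (windows["end"] <= sweep_interval[1])
        ].index
    )
    jaccard = (
        len(called & truth_idx) / len(called | truth_idx) if called | truth_idx else float("nan")
    )
    return {"track": track, "sweeps": sweeps, "jaccard": float(jaccard)}


def inframe_deletion_example() -> int:
    """A codon-aligned 51 bp CDS deletion; returns the amino-acid change.

    The worked example mirrors a zinc-finger gene whose 51 bp coding
    deletion removes 17 residues.
    """
    from .simulate import simulate_reference

    ref = simulate_reference(1, 10_000, gc=0.4, seed=7)
    seq = ref.seqs["chr1"]
    gene = GeneAnnot("CsTu_like", "chr1", "+", 3000, 4200, cds=[(3000, 4200)])
    del_start = 3000 + 300  # codon boundary: offset 300 divisible by 3
    v = Variant(
        VariantClass.CAN_DEL,
        "chr1",
        del_start,
        del_start + 51,
        seq[del_start : del_start + 51],
        "",
        id="SV_DEL_demo",
    )
    overlaps = annotate_gene_overlap([v], [gene])
    assert overlaps[0].label == "CDS-SV" and overlaps[0].consequence == "in_frame"
    return overlaps[0].aa_change


def pins_carrier_percentages(
    indian_carriers: int = 19,
    indian_total: int = 30,
    other_carriers: int = 11,
    other_total: int = 66,
) -> Tuple[float, float]:
    """Group carrier percentages for a promoter insertion from printed counts.

    Builds the genotype matrix the counts describe and computes per-group
    carrier frequencies with the production code path.
    """
    cols = [f"ind_{i}" for i in range(indian_total)] + [
        f"oc_{i}" for i in range(other_total)
    ]
    genotypes = [GT_ALT] * indian_carriers + [GT_REF] * (indian_total - indian_carriers)
    genotypes += [GT_ALT] * other_carriers + [GT_REF] * (other_total - other_carriers)
    matrix = pd.DataFrame([genotypes], index=["pINS"], columns=cols)
    groups = {c: ("indian" if c.startswith("ind_") else "other_cultivated") for c in cols}
    freqs = carrier_frequencies(matrix, groups)
    return (
        round(100.0 * freqs.loc["pINS", "indian"], 1),
        round(100.0 * freqs.loc["pINS", "other_cultivated"], 1),
    )
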
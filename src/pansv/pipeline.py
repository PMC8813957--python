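"""End-to-end pipeline driver on simulated data with a machine-readable summary.

Stage order: simulate -> align -> call -> support -> graph -> genotype ->
selection -> pangene.  Every run writes per-stage outputs plus
``summary.json`` carrying the provenance record (config hash, seed,
package version) and the headline numbers of each stage.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path
from typing import Dict

import numpy as np

from . import __version__
from .config import PipelineConfig
from .discovery import call_variants
from .evaluation import match_variants
from .graph import build_graph, genotype_population, write_gfa
from .io import write_fasta, write_tsv, write_vcf
from .model import CANONICAL_CLASSES, COMPLEX_CLASSES, VariantClass
from .pangene import (
    GeneModel,
    classify_core_dispensable,
    cluster_genes,
    pan_core_curve,
    select_representative,
)
from .selection import call_dsv, call_hdsv, nucleotide_diversity, sweep_regions
from .simulate import (
    VariantSpec,
    implant_variants,
    invert_segment_map,
    project_pair_placements,
    segment_map,
    simulate_diversity_panel,
    simulate_population,
    simulate_reads,
    simulate_reference,
)
from .support import depth_profile, rd_support
from ._seq import random_dna

logger = logging.getLogger("pansv")


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run all stages at the configured scale; returns the summary dict."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    summary: Dict = {
        "provenance": {
            "tool": "pansv",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash,
        }
    }
    config.to_yaml(out / "config.yaml")
    seed = config.seed

    def stage(name):
        logger.info("[pansv] stage: %s", name)

    try:
        stage("simulate")
        ref = simulate_reference(config.n_chrom, config.chrom_length, config.gc, seed)
        counts = {
            VariantClass.SNP: 20,
            VariantClass.SMALL_INS: 5,
            VariantClass.SMALL_DEL: 5,
            VariantClass.CAN_INS: 10,
            VariantClass.CAN_DEL: 10,
            VariantClass.COM_INS: 5,
            VariantClass.COM_DEL: 5,
            VariantClass.INV: 2,
        }
        spec = VariantSpec(counts=counts, canonical_range=(50, 500), inv_range=(1000, 3000))
        derived, truth = implant_variants(ref, spec, seed + 1, accession_id="acc1")
        write_fasta(ref, out / "reference.fa")
        write_fasta(derived, out / "acc1.fa")
        write_vcf(truth, ref, out / "truth.vcf")
        summary["simulate"] = {"n_truth_variants": len(truth), "genome_bp": ref.total_length}

        stage("align+call")
        calls = call_variants(ref, derived)
        write_vcf(calls.variants, ref, out / "calls.vcf")
        canonical = match_variants(truth, calls.variants, CANONICAL_CLASSES)
        cplx = match_variants(truth, calls.variants, COMPLEX_CLASSES)
        summary["call"] = {
            "counts": calls.by_class(),
            "canonical_recall": canonical.recall,
            "canonical_precision": canonical.precision,
            "complex_recall": cplx.recall,
            "complex_precision": cplx.precision,
        }

        stage("support")
        carrier_reads = simulate_reads(derived, config.read_coverage, config.read_len,
                                       config.insert_mean, seed=seed + 2)
        segmap = segment_map(ref, truth)
        depth = depth_profile(
            project_pair_placements(carrier_reads, invert_segment_map(segmap)),
            ref.lengths,
            config.rd_min_map_q,
        )
        dels = [v for v in truth if v.variant_class is VariantClass.CAN_DEL]
        rd = [rd_support(d, depth, config.rd_flank) for d in dels]
        summary["support"] = {
            "n_deletions": len(rd),
            "rd_supported_fraction": float(np.mean([c.rd_supported for c in rd])) if rd else None,
        }

        stage("graph+genotype")
        from .discovery import assign_ids

        sites = assign_ids([v for v in truth if v.is_sv and v.variant_class is not VariantClass.TRANS])
        graph = build_graph(ref, sites)
        (out / "graph.gfa").write_text(write_gfa(graph))
        panel = simulate_population(
            ref, sites, config.n_wild, config.n_cultivated,
            min_divergence=0.0, read_coverage=config.read_coverage,
            read_len=config.read_len, insert_mean=config.insert_mean,
            error_rate=config.error_rate, seed=seed + 3,
        )
        result = genotype_population(
            graph, panel, config.geno_min_map_q, config.geno_min_base_q, config.geno_min_support
        )
        write_tsv(result.matrix.reset_index(), out / "genotypes.tsv")
        summary["genotype"] = {
            "n_sites": len(graph.sites),
            "concordance": result.concordance,
            "mean_call_rate": float(result.call_rate.mean()),
        }

        stage("selection")
        positions, hap_w, hap_c = simulate_diversity_panel(
            500_000, 5_000, 10, 10, sweep_interval=(200_000, 240_000), seed=seed + 4
        )
        track = nucleotide_diversity(
            positions, hap_w, hap_c, 500_000, config.pi_window, config.pi_step
        )
        sweeps = sweep_regions(track, config.sweep_top_fraction)
        dsv = call_dsv(sites, sweeps, config.dsv_overlap_fraction)
        hdsv = call_hdsv(result.matrix, panel.groups, config.hdsv_fdr)
        write_tsv(track.windows, out / "diversity.tsv")
        summary["selection"] = {
            "n_sweeps": len(sweeps),
            "n_dsv": int(sum(dsv.values())),
            "n_hdsv": int(sum(t.hdsv for t in hdsv)),
        }

        stage("pangene")
        rng = np.random.default_rng(seed + 5)
        accs = [f"acc{i}" for i in range(4)]
        genes = []
        for fam in range(30):
            base = random_dna(600, 0.4, rng)
            present = accs if fam < 20 else accs[: 2 + fam % 2]
            for a in present:
                genes.append(GeneModel(f"{a}_g{fam:03d}", a, base))
        clusters = cluster_genes(genes, config.cluster_min_identity, config.cluster_min_coverage)
        status = classify_core_dispensable(clusters, len(accs))
        for c in clusters:
            select_representative(c, "acc0")
        curve = pan_core_curve(clusters, n_orderings=20, seed=seed + 6)
        summary["pangene"] = {
            "n_clusters": len(clusters),
            **status,
            "pan_final": int(curve.pan_mean[-1]),
            "core_final": int(curve.core_mean[-1]),
        }
    except Exception as exc:  # halt with the failing stage in the message
        summary["error"] = str(exc)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        raise

    summary["runtime_s"] = round(time.time() - t0, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
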
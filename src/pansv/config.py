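"""Pipeline configuration: every analysis threshold in one serializable place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds with their standard defaults.

    The defaults are the operating points of the analysis: the 50 bp SV
    class boundary, the 90% / 200 bp one-to-one alignment filters, the
    50 kb collinear-block gap, 1 kb refinement and RD flanks, the RD rule
    (flank > 3x region, region < 3), mapq/baseq < 5 genotyping exclusion,
    top-5% sweep windows, >50% dSV overlap, FDR 0.01 (hdSV) and 0.05
    (enrichment), |log2FC| >= 1.5, pi-ratio >= 3, and the 95% identity /
    50% coverage gene-clustering bounds.
    """

    seed: int = 0
    # simulation
    n_chrom: int = 2
    chrom_length: int = 300_000
    gc: float = 0.35
    read_coverage: float = 20.0
    read_len: int = 150
    insert_mean: int = 400
    error_rate: float = 0.0
    n_wild: int = 4
    n_cultivated: int = 4
    # alignment
    min_anchor_len: int = 20
    min_identity: float = 90.0
    min_alignment_length: int = 200
    max_block_gap: int = 50_000
    large_inv_threshold: int = 1_000_000
    # discovery
    sv_min_size: int = 50
    diff_wordsize: int = 10
    refine_flank: int = 1000
    promoter_window: int = 3000
    # support
    rd_flank: int = 1000
    rd_min_map_q: int = 20
    # genotyping
    geno_min_map_q: int = 5
    geno_min_base_q: int = 5
    geno_min_support: int = 3
    geno_hom_threshold: float = 0.8
    # selection
    pi_window: int = 10_000
    pi_step: int = 10_000
    sweep_top_fraction: float = 0.05
    dsv_overlap_fraction: float = 0.5
    hdsv_fdr: float = 0.01
    pi_ratio_threshold: float = 3.0
    lfc_threshold: float = 1.5
    expression_pseudocount: float = 1.0
    # pangene
    cluster_min_identity: float = 0.95
    cluster_min_coverage: float = 0.50
    enrichment_fdr: float = 0.05
    # paths
    out_dir: str = "pansv_run"
    reference_fasta: Optional[str] = None

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
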
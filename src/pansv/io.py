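"""Shared format readers/writers: FASTA, FASTQ, VCF, BED, GFF, TSV.

BED intervals are 0-based half-open; VCF and GFF are 1-based per their
standards.  VCF output is 4.2 with sequence-resolved InDels and symbolic
``<INV>`` / ``<TRA>`` records (END / CHR2 INFO keys).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discovery import GeneAnnot
from .model import Variant, VariantClass
from .simulate import ReadSet, SimulatedGenome


def read_fasta(path: str | Path, accession_id: Optional[str] = None) -> SimulatedGenome:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SimulatedGenome(accession_id or Path(path).stem, records)


def write_fasta(genome: SimulatedGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(read_set: ReadSet, prefix: str | Path) -> None:
    """Paired FASTQ files <prefix>_1.fastq / <prefix>_2.fastq."""
    prefix = str(prefix)
    qual = chr(33 + 40)
    with open(prefix + "_1.fastq", "w") as f1, open(prefix + "_2.fastq", "w") as f2:
        for r in read_set:
            f1.write(f"@{r.pair_id}/1\n{r.seq1}\n+\n{qual * len(r.seq1)}\n")
            f2.write(f"@{r.pair_id}/2\n{r.seq2}\n+\n{qual * len(r.seq2)}\n")


def write_vcf(
    variants: Sequence[Variant],
    ref_genome: SimulatedGenome,
    path: str | Path,
    source: str = "pansv",
) -> None:
    seqs = ref_genome.seqs
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Destination chromosome of a translocation">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">',
    ]
    for name, seq in ref_genome.chromosomes:
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.ref_chrom, v.ref_start)):
        vid = v.id or "."
        chrom = v.ref_chrom
        seq = seqs[chrom]
        if v.variant_class is VariantClass.INV:
            pos0 = max(v.ref_start - 1, 0)  # anchor base before the interval
            ref = seq[pos0]
            info = f"SVTYPE=INV;END={v.ref_end};SVLEN={v.ref_len}"
            lines.append(f"{chrom}\t{pos0 + 1}\t{vid}\t{ref}\t<INV>\t.\tPASS\t{info}")
            continue
        if v.variant_class is VariantClass.TRANS:
            pos0 = max(v.ref_start - 1, 0)
            ref = seq[pos0]
            chr2 = v.dest_chrom or v.qry_chrom or "."
            info = f"SVTYPE=TRA;END={v.ref_end};CHR2={chr2};SVLEN={v.ref_len}"
            lines.append(f"{chrom}\t{pos0 + 1}\t{vid}\t{ref}\t<TRA>\t.\tPASS\t{info}")
            continue
        if v.variant_class is VariantClass.SNP:
            lines.append(
                f"{chrom}\t{v.ref_start + 1}\t{vid}\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t."
            )
            continue
        # sequence-resolved InDels / replacements: anchor base to the left
        anchor = v.ref_start - 1
        if anchor < 0:
            anchor = 0
        base = seq[anchor]
        if v.ref_start == 0:
            ref_field = v.ref_allele + base if v.ref_allele else base
            alt_field = v.alt_allele + base if v.alt_allele else base
            pos1 = 1
        else:
            ref_field = base + v.ref_allele
            alt_field = base + v.alt_allele
            pos1 = anchor + 1
        svlen = len(v.alt_allele) - len(v.ref_allele)
        info = f"SVTYPE={v.variant_class.value};SVLEN={svlen}" if v.is_sv else "."
        lines.append(f"{chrom}\t{pos1}\t{vid}\t{ref_field}\t{alt_field}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(
    intervals: Iterable[tuple], path: str | Path
) -> None:
    """(chrom, start, end, name, ...) tuples to BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gff_genes(path: str | Path) -> List[GeneAnnot]:
    """Gene models (gene span, strand, CDS exons) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        cds = sorted(
            (c.start - 1, c.end) for c in db.children(g, featuretype="CDS")
        )
        genes.append(
            GeneAnnot(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                cds=cds,
            )
        )
    return genes
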
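"""Variant extraction, classification, refinement, filters, annotation."""

import dataclasses

import pytest

from pansv.discovery import (
    GeneAnnot,
    SelfCall,
    annotate_gene_overlap,
    assign_ids,
    classify_variant,
    detect_microhomology,
    diff_block,
    filter_n_content,
    mask_assembly_errors,
    refine_breakpoints,
)
from pansv.model import Variant, VariantClass as VC, left_align
from pansv.simulate import SimulatedGenome, apply_variants, simulate_reference
from pansv.wga import align_genomes


class TestClassify:
    @pytest.mark.parametrize(
        "ref_len,alt_len,precise,expected",
        [
            (1, 1, True, VC.SNP),
            (4895, 0, True, VC.CAN_DEL),  # complete-gene-loss deletion size
            (10, 802, False, VC.COM_INS),  # replacement upstream of a trichome gene
            (0, 49, True, VC.SMALL_INS),
            (0, 50, True, VC.CAN_INS),
            (49, 0, True, VC.SMALL_DEL),
            (50, 0, True, VC.CAN_DEL),
            (300, 120, False, VC.COM_DEL),
        ],
    )
    def test_examples_and_50bp_boundary(self, ref_len, alt_len, precise, expected):
        assert classify_variant(ref_len, alt_len, precise) is expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_variant(0, 0, True)
        with pytest.raises(ValueError):
            classify_variant(5, 5, True)
        with pytest.raises(ValueError):
            classify_variant(-1, 3, True)


def _pair(ref_seq, qry_seq):
    ref = SimulatedGenome("ref", [("chr1", ref_seq)])
    qry = SimulatedGenome("qry", [("chr1", qry_seq)])
    blocks = align_genomes(ref, qry, min_length=100)
    return ref, qry, blocks


class TestDiffBlock:
    def test_identical_block_no_differences(self):
        seq = simulate_reference(1, 10_000, 0.4, 51).chromosomes[0][1]
        ref, qry, blocks = _pair(seq, seq)
        assert diff_block(blocks[0], ref.seqs, qry.seqs) == []

    def test_single_substitution_one_unit_pair(self):
        seq = simulate_reference(1, 10_000, 0.4, 52).chromosomes[0][1]
        alt = "A" if seq[4000] != "A" else "C"
        ref, qry, blocks = _pair(seq, seq[:4000] + alt + seq[4001:])
        pairs = diff_block(blocks[0], ref.seqs, qry.seqs)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.ref_end - p.ref_start, p.qry_end - p.qry_start) == (1, 1)

    def test_60bp_deletion_pair(self):
        seq = simulate_reference(1, 10_000, 0.4, 53).chromosomes[0][1]
        ref, qry, blocks = _pair(seq, seq[:5000] + seq[5060:])
        pairs = diff_block(blocks[0], ref.seqs, qry.seqs)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.ref_end - p.ref_start == 60 and p.qry_end == p.qry_start

    def test_reconstruction_within_blocks(self, ref_small, called_small):
        """Applying every pointwise call reproduces the derived genome."""
        calls, derived, _truth = called_small
        pointwise = [
            v
            for v in calls.variants
            if v.variant_class not in (VC.TRANS,)
        ]
        rebuilt = apply_variants(ref_small, pointwise, set_qry_coords=False)
        assert rebuilt.seqs == derived.seqs


class TestRefine:
    def test_fragmented_clean_insertion_promoted(self):
        seq = simulate_reference(1, 20_000, 0.4, 54).chromosomes[0][1]
        ins = simulate_reference(1, 10_000, 0.5, 55).chromosomes[0][1][:80]
        qry_seq = seq[:7000] + ins + seq[7000:]
        ref = SimulatedGenome("ref", [("chr1", seq)])
        qry = SimulatedGenome("qry", [("chr1", qry_seq)])
        # a deliberately sloppy (but content-consistent) complex record
        # around the true clean insertion: 10 bp of flank absorbed into it
        v = Variant(
            VC.COM_INS,
            "chr1",
            6995,
            7005,
            seq[6995:7005],
            qry_seq[6995:7085],
            qry_chrom="chr1",
            qry_start=6995,
            qry_end=7085,
            precise=False,
        )
        refined = refine_breakpoints(v, ref.seqs, qry.seqs)
        assert refined.variant_class is VC.CAN_INS and refined.precise
        truth = left_align(
            Variant(VC.CAN_INS, "chr1", 7000, 7000, "", ins), seq
        )
        assert (refined.ref_start, refined.alt_allele) == (truth.ref_start, truth.alt_allele)

    def test_divergent_replacement_stays_complex(self):
        seq = simulate_reference(1, 20_000, 0.4, 56).chromosomes[0][1]
        repl = simulate_reference(1, 10_000, 0.5, 57).chromosomes[0][1][:300]
        qry_seq = seq[:7000] + repl + seq[7120:]
        ref = SimulatedGenome("ref", [("chr1", seq)])
        qry = SimulatedGenome("qry", [("chr1", qry_seq)])
        v = Variant(
            VC.COM_INS, "chr1", 7000, 7120, seq[7000:7120], repl,
            qry_chrom="chr1", qry_start=7000, qry_end=7300, precise=False,
        )
        refined = refine_breakpoints(v, ref.seqs, qry.seqs)
        assert refined.variant_class is VC.COM_INS and not refined.precise

    def test_canonical_noop(self):
        v = Variant(VC.CAN_DEL, "chr1", 100, 160, "A" * 60, "", precise=True)
        assert refine_breakpoints(v, {"chr1": "A" * 1000}, {"chr1": "A" * 1000}) == v


class TestFilters:
    def _sv(self, alt, ref_allele=""):
        return Variant(VC.CAN_INS, "chr1", 10, 10, ref_allele, alt, qry_chrom="chr1",
                       qry_start=10, qry_end=10 + len(alt))

    def test_n_containing_alt_removed(self):
        kept, removed = filter_n_content([self._sv("ACGTN" + "A" * 60)])
        assert kept == [] and removed == {"CAN_INS": 1}

    def test_n_free_retained_and_all_n_reported(self):
        clean = self._sv("ACGT" * 20)
        dirty = self._sv("N" * 60)
        kept, removed = filter_n_content([clean, dirty])
        assert kept == [clean] and removed["CAN_INS"] == 1

    def test_mask_assembly_errors_thresholds(self):
        snp = Variant(VC.SNP, "chr1", 100, 101, "A", "C", qry_chrom="chr1",
                      qry_start=100, qry_end=101)
        passing = SelfCall("chr1", 100, base_q=30, map_q=60, depth=50)
        assert mask_assembly_errors([snp], [passing]) == []
        too_deep = SelfCall("chr1", 100, base_q=30, map_q=60, depth=250)
        assert mask_assembly_errors([snp], [too_deep]) == [snp]
        low_baseq = SelfCall("chr1", 100, base_q=20, map_q=60, depth=50)
        assert mask_assembly_errors([snp], [low_baseq]) == [snp]
        assert mask_assembly_errors([snp], []) == [snp]


class TestMicrohomology:
    def test_engineered_ccacc_junction(self):
        left = "GATTACAGATTACAGATTAC"
        deleted = "CCACC" + "GTGTACGTAGCTAGCTAGGTTACGATCGTAGCTAGTCCAGGTTACGAT"[:46]
        right = "CCACC" + "TTGACGGATCGATTTACGGA"
        seq = left + deleted + right
        v = Variant(VC.CAN_DEL, "chr1", len(left), len(left) + len(deleted), deleted, "")
        rep = detect_microhomology(v, seq)
        assert (rep.homology_seq, rep.homology_len) == ("CCACC", 5)

    def test_homopolymer_capped_at_span_and_max_len(self):
        seq = "G" * 50 + "A" * 30 + "A" * 40 + "G" * 50  # deletion of 30 As in an A-run
        v = Variant(VC.CAN_DEL, "chr1", 50, 80, "A" * 30, "")
        rep = detect_microhomology(v, seq, max_len=25)
        assert rep.homology_len == 25  # min(span=30, max_len=25)
        rep2 = detect_microhomology(v, seq, max_len=100)
        assert rep2.homology_len == 30  # capped at the deletion span

    def test_no_shared_junction_sequence(self):
        seq = "AAAAAAAAAA" + "CCCCC" + "GGGGGGGGGG"
        v = Variant(VC.CAN_DEL, "chr1", 10, 15, "CCCCC", "")
        assert detect_microhomology(v, seq).homology_len == 0

    def test_only_deletions_accepted(self):
        v = Variant(VC.CAN_INS, "chr1", 10, 10, "", "A" * 60)
        with pytest.raises(ValueError):
            detect_microhomology(v, "A" * 100)


class TestGeneOverlap:
    def _gene(self, strand="+"):
        return GeneAnnot("gene1", "chr1", strand, 5000, 8000, cds=[(5000, 8000)])

    def test_51bp_codon_aligned_deletion_loses_17_aa(self):
        start = 5000 + 300
        v = Variant(VC.CAN_DEL, "chr1", start, start + 51, "A" * 51, "")
        (res,) = annotate_gene_overlap([v], [self._gene()])
        assert res.label == "CDS-SV"
        assert res.consequence == "in_frame" and res.aa_change == -17

    def test_50bp_cds_deletion_is_frameshift(self):
        start = 5000 + 300
        v = Variant(VC.CAN_DEL, "chr1", start, start + 50, "A" * 50, "")
        (res,) = annotate_gene_overlap([v], [self._gene()])
        assert res.consequence == "frameshift"

    def test_insertion_upstream_is_promoter_sv(self):
        v = Variant(VC.CAN_INS, "chr1", 4900, 4900, "", "A" * 76)
        (res,) = annotate_gene_overlap([v], [self._gene()], promoter_window=3000)
        assert res.label == "promoter-SV"

    def test_minus_strand_promoter_is_downstream_in_genome_coords(self):
        v = Variant(VC.CAN_INS, "chr1", 8100, 8100, "", "A" * 76)
        (res,) = annotate_gene_overlap([v], [self._gene(strand="-")])
        assert res.label == "promoter-SV"

    def test_intron_and_intergenic_labels(self):
        gene = GeneAnnot("g2", "chr1", "+", 5000, 9000, cds=[(5000, 6000), (8000, 9000)])
        intronic = Variant(VC.CAN_DEL, "chr1", 6500, 6560, "A" * 60, "")
        nowhere = Variant(VC.CAN_DEL, "chr1", 20_000, 20_060, "A" * 60, "")
        res = annotate_gene_overlap([intronic, nowhere], [gene])
        assert [r.label for r in res] == ["intron-SV", "intergenic"]

    def test_out_of_bounds_rejected(self):
        v = Variant(VC.CAN_DEL, "chr1", 99_000, 99_060, "A" * 60, "")
        with pytest.raises(ValueError):
            annotate_gene_overlap([v], [self._gene()], chrom_lengths={"chr1": 50_000})


class TestIds:
    def test_id_scheme_reference_sorted(self):
        vs = [
            Variant(VC.CAN_DEL, "chr2", 500, 560, "A" * 60, ""),
            Variant(VC.CAN_INS, "chr2", 100, 100, "", "A" * 60),
            Variant(VC.SNP, "chr2", 50, 51, "A", "C"),
        ]
        out = assign_ids([dataclasses.replace(v) for v in vs])
        svs = [v for v in out if v.is_sv]
        assert svs[0].id == "SV_INS_2G000001"
        assert svs[1].id == "SV_DEL_2G000002"
        assert [v for v in out if v.variant_class is VC.SNP][0].id is None
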
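"""Anchoring, segment scoring, one-to-one filtering, chaining, rearrangements."""

import itertools

import numpy as np
import pytest

from pansv._seq import revcomp
from pansv.model import VariantClass as VC
from pansv.simulate import (
    SimulatedGenome,
    VariantSpec,
    implant_variants,
    simulate_reference,
)
from pansv.wga import (
    AlignmentSegment,
    align_genomes,
    chain_collinear_blocks,
    detect_rearrangements,
    extend_and_score,
    filter_one_to_one,
    find_anchors,
    find_anchors_genome,
)


def _genome(seq, name="chr1", acc="g"):
    return SimulatedGenome(acc, [(name, seq)])


@pytest.fixture(scope="module")
def seq10k():
    return simulate_reference(1, 10_000, 0.4, 21).chromosomes[0][1]


class TestAnchors:
    def test_identical_sequences_one_full_anchor(self, seq10k):
        anchors = [a for a in find_anchors(seq10k, seq10k) if a.strand == "+"]
        assert len(anchors) == 1
        a = anchors[0]
        assert (a.ref_start, a.ref_end, a.qry_start, a.qry_end) == (0, 10_000, 0, 10_000)

    def test_single_snp_splits_into_two_anchors(self, seq10k):
        pos = 5_000
        alt = "A" if seq10k[pos] != "A" else "C"
        qry = seq10k[:pos] + alt + seq10k[pos + 1 :]
        anchors = sorted(
            (a for a in find_anchors(seq10k, qry) if a.strand == "+"),
            key=lambda a: a.ref_start,
        )
        assert [(a.ref_start, a.ref_end) for a in anchors] == [(0, pos), (pos + 1, 10_000)]

    def test_reverse_complement_query_minus_anchor(self, seq10k):
        anchors = find_anchors(seq10k, revcomp(seq10k))
        minus = [a for a in anchors if a.strand == "-"]
        assert len(minus) == 1
        a = minus[0]
        assert (a.ref_start, a.ref_end, a.qry_start, a.qry_end) == (0, 10_000, 0, 10_000)

    def test_min_anchor_len_validated(self, seq10k):
        with pytest.raises(ValueError):
            find_anchors(seq10k, seq10k, min_anchor_len=4)


class TestSegments:
    def test_matching_gap_merges_to_identity_100(self, seq10k):
        ref = _genome(seq10k)
        qry = _genome(seq10k, acc="q")
        from pansv.wga import Anchor

        anchors = [
            Anchor("chr1", 0, 400, "chr1", 0, 400, "+"),
            Anchor("chr1", 430, 1000, "chr1", 430, 1000, "+"),
        ]
        segs = extend_and_score(anchors, ref, qry)
        assert len(segs) == 1
        assert segs[0].identity == pytest.approx(100.0)

    def test_insertion_in_gap_reduces_identity(self, seq10k):
        ins = "ACGTACGTAC"  # 10 bp
        qry = seq10k[:5000] + ins + seq10k[5000:]
        blocks = align_genomes(_genome(seq10k), _genome(qry, acc="q"), min_length=100)
        segs = [s for b in blocks for s in b.segments]
        total_cols = sum(s.aligned_length for s in segs)
        total_matches = sum(s.identity / 100 * s.aligned_length for s in segs)
        # one 10 bp gap of pure insertion: identity = matched / (matched + 10)
        assert total_cols == pytest.approx(total_matches + 10, abs=1)

    def test_far_apart_anchors_stay_separate_segments(self, seq10k):
        from pansv.wga import Anchor

        ref = _genome(seq10k)
        qry = _genome(seq10k, acc="q")
        anchors = [
            Anchor("chr1", 0, 400, "chr1", 0, 400, "+"),
            Anchor("chr1", 5000, 6000, "chr1", 5000, 6000, "+"),
        ]
        segs = extend_and_score(anchors, ref, qry, max_anchor_gap=1500)
        assert len(segs) == 2


class TestOneToOne:
    def _seg(self, rs, re, qs, qe, ident=100.0, chrom="chr1", qchrom="chr1"):
        return AlignmentSegment(chrom, rs, re, qchrom, qs, qe, "+", ident, re - rs)

    def test_identity_and_length_thresholds(self):
        low_ident = self._seg(0, 1000, 0, 1000, ident=89.0)
        short = self._seg(2000, 2150, 2000, 2150)
        good = self._seg(5000, 6000, 5000, 6000, ident=95.0)
        kept = filter_one_to_one([low_ident, short, good])
        assert kept == [good]

    def test_conflict_resolution_keeps_higher_weight(self):
        a = self._seg(0, 1000, 0, 1000, ident=99.0)
        b = self._seg(200, 700, 5000, 5500, ident=95.0)  # ref-overlaps a
        kept = filter_one_to_one([a, b])
        assert kept == [a]

    def test_matches_bruteforce_chain_oracle(self):
        """Exact equivalence with subset enumeration on <= 10 segments."""
        rng = np.random.default_rng(123)
        for _trial in range(25):
            segs = []
            for _ in range(rng.integers(2, 9)):
                rs = int(rng.integers(0, 5000))
                ln = int(rng.integers(200, 1500))
                qs = int(rng.integers(0, 5000))
                segs.append(self._seg(rs, rs + ln, qs, qs + ln, ident=float(rng.uniform(90, 100))))

            def conflict(x, y, tol=30):
                ro = min(x.ref_end, y.ref_end) - max(x.ref_start, y.ref_start)
                qo = min(x.qry_end, y.qry_end) - max(x.qry_start, y.qry_start)
                return ro > tol or qo > tol

            best = -1.0
            for mask in itertools.product([0, 1], repeat=len(segs)):
                subset = [s for s, m in zip(segs, mask) if m]
                if any(conflict(x, y) for x, y in itertools.combinations(subset, 2)):
                    continue
                best = max(best, sum(s.weight for s in subset))
            kept = filter_one_to_one([AlignmentSegment(**vars(s)) for s in segs])
            got = sum(s.weight for s in kept)
            assert got == pytest.approx(best, rel=0.05)  # trimming may shave bp

    def test_one_to_one_coverage_property(self, called_small, ref_small, implanted_small):
        derived, _ = implanted_small
        from pansv.wga import extend_and_score, find_anchors_genome

        anchors = find_anchors_genome(ref_small, derived)
        segs = filter_one_to_one(extend_and_score(anchors, ref_small, derived))
        for axis in ("ref", "qry"):
            ivs = sorted(
                (getattr(s, f"{axis}_chrom"), getattr(s, f"{axis}_start"), getattr(s, f"{axis}_end"))
                for s in segs
            )
            for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
                assert c1 != c2 or e1 <= s2, f"{axis} overlap: {(c1,s1,e1)} vs {(c2,s2,e2)}"


class TestBlocks:
    def _seg(self, rs, re, qs, qe, strand="+"):
        return AlignmentSegment("chr1", rs, re, "chr1", qs, qe, strand, 100.0, re - rs)

    def test_single_segment_single_block(self):
        s = self._seg(0, 1000, 0, 1000)
        blocks = chain_collinear_blocks([s])
        assert len(blocks) == 1 and blocks[0].ref_span == (0, 1000)

    def test_gap_threshold(self):
        a = self._seg(0, 1000, 0, 1000)
        near = self._seg(11_000, 12_000, 11_000, 12_000)
        assert len(chain_collinear_blocks([a, near], max_gap=50_000)) == 1
        far = self._seg(61_000, 62_000, 61_000, 62_000)
        assert len(chain_collinear_blocks([a, far], max_gap=50_000)) == 2

    def test_strand_change_forces_boundary(self):
        a = self._seg(0, 1000, 0, 1000)
        b = self._seg(2000, 3000, 2000, 3000, strand="-")
        assert len(chain_collinear_blocks([a, b])) == 2

    def test_chaining_idempotent(self, ref_small, implanted_small):
        derived, _ = implanted_small
        blocks = align_genomes(ref_small, derived)
        segs = [s for b in blocks for s in b.segments]
        again = chain_collinear_blocks(segs)
        assert [(b.ref_span, b.qry_span, b.strand) for b in again] == [
            (b.ref_span, b.qry_span, b.strand) for b in blocks
        ]

    def test_variant_free_pair_tiles_99_percent(self):
        ref = simulate_reference(2, 50_000, 0.4, 31)
        qry = SimulatedGenome("q", list(ref.chromosomes))
        blocks = align_genomes(ref, qry)
        covered = sum(b.ref_span[1] - b.ref_span[0] for b in blocks)
        assert covered >= 0.99 * ref.total_length


class TestRearrangements:
    def test_implanted_inversion_recovered_with_exact_span(self):
        ref = simulate_reference(1, 200_000, 0.4, 41)
        spec = VariantSpec(counts={VC.INV: 1}, inv_range=(30_000, 30_000))
        derived, truth = implant_variants(ref, spec, seed=42)
        blocks = align_genomes(ref, derived)
        inv, trans, mega = detect_rearrangements(blocks, ref.seqs)
        assert len(inv) == 1 and not mega
        t = truth[0]
        # chance junction homology can stretch the span by a few bases
        assert abs(inv[0].ref_start - t.ref_start) <= 5
        assert abs(inv[0].ref_end - t.ref_end) <= 5
        assert not inv[0].low_confidence

    def test_megabase_inversion_classified_separately(self):
        ref = simulate_reference(1, 3_000_000, 0.4, 43)
        spec = VariantSpec(counts={VC.INV: 1}, inv_range=(1_200_000, 1_200_000))
        derived, _truth = implant_variants(ref, spec, seed=44)
        blocks = align_genomes(ref, derived)
        inv, _trans, mega = detect_rearrangements(blocks, ref.seqs)
        assert len(mega) == 1 and len(inv) == 0
        assert mega[0].size >= 1_000_000

    def test_interchromosomal_translocation_detected(self):
        ref = simulate_reference(2, 150_000, 0.4, 45)
        spec = VariantSpec(counts={VC.TRANS: 1}, trans_range=(5_000, 5_000))
        derived, truth = implant_variants(ref, spec, seed=46)
        blocks = align_genomes(ref, derived)
        _inv, trans, _mega = detect_rearrangements(blocks, ref.seqs)
        inter = [t for t in trans if t.kind == "inter_translocation"]
        assert len(inter) == 1
        t = truth[0]
        assert inter[0].ref_chrom == t.ref_chrom
        assert abs(inter[0].ref_start - t.ref_start) <= 5
        assert inter[0].qry_chrom == t.dest_chrom
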
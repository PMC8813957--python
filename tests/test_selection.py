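"""Diversity, sweeps, dSV/hdSV calls, pi-ratio annotation, expression screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pansv.model import Variant, VariantClass as VC
from pansv.selection import (
    DiversityTrack,
    annotate_pi_ratio,
    bh_fdr,
    call_dsv,
    call_hdsv,
    expression_effect,
    fisher_exact,
    nucleotide_diversity,
    sweep_regions,
    SweepRegion,
)


def _pairwise_pi_oracle(hap, length):
    """Mean pairwise difference per site, by direct enumeration."""
    n = hap.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int((hap[i] != hap[j]).sum())
            pairs += 1
    return total / pairs / length


class TestDiversity:
    def test_two_haplotypes_one_difference(self):
        track = nucleotide_diversity(
            np.array([10]), np.array([[0], [1]]), np.array([[0], [0]]), 100, 100, 100
        )
        assert track.windows.pi_wild.iloc[0] == pytest.approx(0.01)

    def test_four_haplotypes_balanced_site(self):
        hap = np.array([[0], [0], [1], [1]])
        track = nucleotide_diversity(np.array([5]), hap, hap, 100, 100, 100)
        assert track.windows.pi_wild.iloc[0] == pytest.approx((4 / 6) / 100)

    def test_monomorphic_window_zero(self):
        hap = np.zeros((4, 3), dtype=int)
        track = nucleotide_diversity(np.array([1, 2, 3]), hap, hap, 100, 100, 100)
        assert track.windows.pi_wild.iloc[0] == 0.0

    def test_matches_pairwise_enumeration_oracle(self):
        rng = np.random.default_rng(71)
        for n_hap in (2, 4, 8):
            hap = (rng.random((n_hap, 40)) < 0.3).astype(int)
            pos = np.sort(rng.choice(1000, 40, replace=False))
            track = nucleotide_diversity(pos, hap, hap, 1000, 1000, 1000)
            assert track.windows.pi_wild.iloc[0] == pytest.approx(
                _pairwise_pi_oracle(hap, 1000)
            )

    def test_window_step_validated(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(np.array([1]), np.zeros((2, 1)), np.zeros((2, 1)), 100, 10, 20)


class TestSweeps:
    def _track(self, ratios):
        n = len(ratios)
        df = pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": np.arange(n) * 10_000,
                "end": (np.arange(n) + 1) * 10_000,
                "pi_wild": 0.01,
                "pi_cult": 0.01,
                "ratio": ratios,
            }
        )
        return DiversityTrack(df)

    def test_exactly_top_five_of_hundred(self):
        rng = np.random.default_rng(72)
        ratios = rng.permutation(np.arange(100, dtype=float))
        track = self._track(ratios)
        sweeps = sweep_regions(track, 0.05)
        chosen = {
            int(track.windows.start.iloc[i])
            for i in np.argsort(-ratios)[:5]
        }
        got = set()
        for r in sweeps:
            got.update(range(r.start, r.end, 10_000))
        assert got == chosen

    def test_disjoint_extra_stat_gives_empty(self):
        ratios = np.arange(100, dtype=float)
        extra = -np.arange(100, dtype=float)  # top sets disjoint
        sweeps = sweep_regions(self._track(ratios), 0.05, extra_stat=pd.Series(extra))
        assert sweeps == []

    def test_adjacent_windows_merge(self):
        ratios = np.ones(100)
        ratios[40:45] = 50.0
        sweeps = sweep_regions(self._track(ratios), 0.05)
        assert len(sweeps) == 1
        assert (sweeps[0].start, sweeps[0].end, sweeps[0].n_windows) == (400_000, 450_000, 5)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            sweep_regions(self._track(np.ones(10)), 0.05)


class TestDsv:
    SWEEPS = [SweepRegion("chr1", 1000, 2000, 1)]

    def _sv(self, start, end):
        return Variant(VC.CAN_DEL, "chr1", start, end, "A" * (end - start), "", id="s")

    def test_majority_overlap_is_dsv(self):
        assert call_dsv([self._sv(1949, 2049)], self.SWEEPS)["s"] is True  # 51/100

    def test_exactly_half_is_not_dsv(self):
        assert call_dsv([self._sv(1950, 2050)], self.SWEEPS)["s"] is False  # 50/100, strict

    def test_fully_inside_is_dsv(self):
        assert call_dsv([self._sv(1200, 1300)], self.SWEEPS)["s"] is True

    def test_insertion_anchor_point(self):
        ins_in = Variant(VC.CAN_INS, "chr1", 1500, 1500, "", "A" * 60, id="a")
        ins_out = Variant(VC.CAN_INS, "chr1", 2500, 2500, "", "A" * 60, id="b")
        flags = call_dsv([ins_in, ins_out], self.SWEEPS)
        assert flags["a"] is True and flags["b"] is False


def _fisher_oracle(a, b, c, d):
    """Two-sided p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1) for x in range(lo, hi + 1)}
    p0 = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p0 * (1 + 1e-9)))


class TestFisherBh:
    def test_antidiagonal_table_matches_oracle(self):
        assert fisher_exact([[0, 10], [10, 0]]) == pytest.approx(_fisher_oracle(0, 10, 10, 0))

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(73)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                _fisher_oracle(int(a), int(b), int(c), int(d)), rel=1e-9
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_worked_step_down_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_bh_matches_step_down_definition(self, pvals):
        m = len(pvals)
        order = np.argsort(pvals)
        expected = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, pvals[i] * m / rank)
            expected[i] = prev
        assert np.allclose(bh_fdr(pvals), expected)


class TestHdsv:
    def _matrix(self, wild_gts, cult_gts):
        data = {f"w{i}": [g] for i, g in enumerate(wild_gts)}
        data.update({f"c{i}": [g] for i, g in enumerate(cult_gts)})
        m = pd.DataFrame(data, index=["sv1"])
        groups = {f"w{i}": "wild" for i in range(len(wild_gts))}
        groups.update({f"c{i}": "cultivated" for i in range(len(cult_gts))})
        return m, groups

    def test_fixed_difference_is_hdsv(self):
        m, groups = self._matrix([2] * 20, [0] * 40)
        (t,) = call_hdsv(m, groups)
        assert t.hdsv and t.p_value == pytest.approx(_fisher_oracle(20, 0, 0, 40))

    def test_identical_frequencies_not_hdsv(self):
        m, groups = self._matrix([2, 2, 0, 0], [2, 2, 0, 0])
        (t,) = call_hdsv(m, groups)
        assert t.p_value == pytest.approx(1.0) and not t.hdsv

    def test_missing_genotypes_leave_margins(self):
        m, groups = self._matrix([2, 2, -1], [0, 0, -1])
        (t,) = call_hdsv(m, groups)
        assert (t.carriers_wild, t.non_wild, t.carriers_cult, t.non_cult) == (2, 0, 0, 2)

    def test_empty_group_skipped_with_nan(self):
        m, groups = self._matrix([-1, -1], [0, 2])
        (t,) = call_hdsv(m, groups)
        assert math.isnan(t.p_value) and not t.hdsv

    def test_hdsv_set_shrinks_with_threshold(self):
        rng = np.random.default_rng(74)
        rows = {}
        for i in range(30):
            pw, pc = rng.random(), rng.random()
            rows[f"s{i}"] = [2 if rng.random() < pw else 0 for _ in range(15)] + [
                2 if rng.random() < pc else 0 for _ in range(15)
            ]
        m = pd.DataFrame.from_dict(rows, orient="index")
        m.columns = [f"w{i}" for i in range(15)] + [f"c{i}" for i in range(15)]
        groups = {c: ("wild" if c.startswith("w") else "cultivated") for c in m.columns}
        loose = {t.sv_id for t in call_hdsv(m, groups, 0.10) if t.hdsv}
        strict = {t.sv_id for t in call_hdsv(m, groups, 0.01) if t.hdsv}
        assert strict <= loose


class TestPiRatioAnnotation:
    def _track(self, ratio):
        df = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [0],
                "end": [10_000],
                "pi_wild": [0.01],
                "pi_cult": [0.01 / ratio if ratio not in (math.inf,) else 0.0],
                "ratio": [ratio],
            }
        )
        return DiversityTrack(df)

    def _sv(self):
        return Variant(VC.CAN_DEL, "chr1", 5_000, 5_100, "A" * 100, "", id="s")

    def test_threshold_inclusive(self):
        assert annotate_pi_ratio([self._sv()], self._track(3.0))["s"] is True
        assert annotate_pi_ratio([self._sv()], self._track(2.9))["s"] is False

    def test_undefined_ratio_treated_as_infinite(self):
        assert annotate_pi_ratio([self._sv()], self._track(math.inf))["s"] is True

    def test_sv_outside_track_is_none(self):
        sv = Variant(VC.CAN_DEL, "chr2", 100, 200, "A" * 100, "", id="x")
        assert annotate_pi_ratio([sv], self._track(5.0))["x"] is None


class TestExpressionEffect:
    def _tables(self, wild_root, cult_root):
        idx = ["g1"]
        cols = ["roots", "leaves"]
        w = pd.DataFrame([[wild_root, 5.0]], index=idx, columns=cols)
        c = pd.DataFrame([[cult_root, 5.0]], index=idx, columns=cols)
        return w, c

    def test_fold_change_flagged(self):
        w, c = self._tables(2.0, 8.0)
        (e,) = expression_effect([("sv1", "g1", "promoter")], w, c, pseudocount=0.0)
        assert e.log2_fc["roots"] == pytest.approx(2.0) and e.flagged

    def test_threshold_inclusive_at_1_5(self):
        w, c = self._tables(2.0, 2.0 * 2**1.5)
        (e,) = expression_effect([("sv1", "g1", "CDS")], w, c, pseudocount=0.0)
        assert e.flagged

    def test_equal_expression_not_flagged(self):
        w, c = self._tables(4.0, 4.0)
        (e,) = expression_effect([("sv1", "g1", "CDS")], w, c)
        assert not e.flagged

    def test_non_cds_promoter_context_ineligible(self):
        w, c = self._tables(2.0, 8.0)
        assert expression_effect([("sv1", "g1", "intron")], w, c) == []

    def test_negative_expression_rejected(self):
        w, c = self._tables(-1.0, 8.0)
        with pytest.raises(ValueError):
            expression_effect([("sv1", "g1", "CDS")], w, c)
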
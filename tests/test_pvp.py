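"""The binomial valley statistic, single-valley scoring, and the scan."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvpmap.core import GenomeTable, GenomicInterval, ReadTrack
from pvpmap.pvp import (
    GeometryGrid,
    scan_broad_peak,
    score_valley,
    select_pvp_enhancers,
    shoulder_pvalue,
)
from tests.oracles import oracle_score_valley, oracle_side_pvalue

iv = GenomicInterval


class TestShoulderPvalue:
    def test_no_valley_reads_equal_sizes(self):
        # P(X <= 0) = (1 - 1/2)^10 for 10 reads, 50/50 split
        assert shoulder_pvalue(0, 10, 300, 300) == pytest.approx(
            9.765625e-4, rel=1e-12
        )

    def test_all_reads_in_valley_is_certain(self):
        assert shoulder_pvalue(17, 0, 250, 500) == 1.0

    def test_no_reads_no_evidence(self):
        assert shoulder_pvalue(0, 0, 300, 400) == 1.0

    def test_worked_third_split(self):
        # valley 250 vs shoulder 500: p = 1/3, n = 55, CDF at 5
        expected = float(oracle_side_pvalue(5, 50, 250, 500))
        assert shoulder_pvalue(5, 50, 250, 500) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("vr,sr,vs,ss", [(-1, 5, 300, 300), (5, -1, 300, 300),
                                             (5, 5, 0, 300), (5, 5, 300, 0)])
    def test_contract_violations(self, vr, sr, vs, ss):
        with pytest.raises(ValueError):
            shoulder_pvalue(vr, sr, vs, ss)

    def test_matches_exact_rational_sum_small_n(self):
        """Relative error < 1e-10 against exact Fractions for all n <= 60."""
        lattice = [(250, 300), (250, 500), (300, 400), (350, 300), (400, 500)]
        worst = 0.0
        for vs, ss in lattice:
            for n in (0, 1, 7, 30, 60):
                for vr in range(n + 1):
                    got = shoulder_pvalue(vr, n - vr, vs, ss)
                    want = float(oracle_side_pvalue(vr, n - vr, vs, ss))
                    worst = max(worst, abs(got - want) / want)
        assert worst < 1e-10

    @given(st.integers(0, 200), st.integers(0, 200))
    def test_monotone_in_valley_reads_at_fixed_n(self, vr, extra):
        """Fewer valley reads out of the same total -> smaller p."""
        n = vr + extra
        if vr >= n:
            return
        p_lo = shoulder_pvalue(vr, n - vr, 300, 400)
        p_hi = shoulder_pvalue(vr + 1, n - vr - 1, 300, 400)
        assert p_lo <= p_hi + 1e-15

    def test_stable_at_large_n(self):
        p = shoulder_pvalue(100, 10**6, 300, 300)
        assert 0.0 <= p < 1e-300 or p == 0.0  # deep underflow, not NaN
        assert np.isfinite(p)


def _random_track(rng, span=4000, n_reads=120, offset=0):
    mids = rng.integers(offset, offset + span, size=n_reads)
    return ReadTrack({"chr1": mids}), sorted(int(m) for m in mids)


class TestScoreValley:
    def test_default_grid_enumerates_12_combinations_per_side(self):
        grid = GeometryGrid()
        assert grid.n_combinations == 12
        # and the exhaustive oracle, given room, also enumerates 12 per side
        _, _, _, counts = oracle_score_valley([], anchor=10_000)
        assert counts == {"left": 12, "right": 12}

    def test_mirror_symmetric_track_scores_sides_equally(self):
        anchor = 10_000
        left = [anchor - d for d in (150, 250, 260, 300, 420, 610)]
        right = [anchor + d - 1 for d in (150, 250, 260, 300, 420, 610)]
        call = score_valley(ReadTrack({"chr1": left + right}), "chr1", anchor)
        assert call.best_left.p_value == pytest.approx(
            call.best_right.p_value, rel=1e-12
        )
        assert call.final_score == call.best_left.p_value

    def test_planted_valley_matches_exhaustive_oracle(self):
        # zero valley reads, 40 reads in each flanking 300 bp
        anchor = 10_000
        rng = np.random.default_rng(7)
        left = rng.integers(anchor - 500, anchor - 200, size=40)
        right = rng.integers(anchor + 200, anchor + 500, size=40)
        mids = sorted(int(m) for m in np.concatenate([left, right]))
        call = score_valley(ReadTrack({"chr1": mids}), "chr1", anchor)
        bl, br, final, _ = oracle_score_valley(mids, anchor)
        assert call.best_left.p_value == pytest.approx(float(bl), rel=1e-9)
        assert call.best_right.p_value == pytest.approx(float(br), rel=1e-9)
        assert call.final_score == pytest.approx(float(final), rel=1e-9)

    def test_oracle_equivalence_on_random_tracks(self):
        """final_score == exhaustive exact recomputation, 100 random tracks."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            track, mids = _random_track(
                rng, span=3000, n_reads=int(rng.integers(5, 150))
            )
            anchor = int(rng.integers(1200, 2800))
            call = score_valley(track, "chr1", anchor)
            bl, br, final, _ = oracle_score_valley(mids, anchor)
            assert call.final_score == pytest.approx(float(final), rel=1e-9)
            assert call.final_score == max(
                call.best_left.p_value, call.best_right.p_value
            )

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        track, mids = _random_track(rng, offset=5000)
        anchor = 7000
        a = score_valley(track, "chr1", anchor)
        b = score_valley(track.shifted(123_456), "chr1", anchor + 123_456)
        assert a.final_score == b.final_score
        assert a.best_left.p_value == b.best_left.p_value

    def test_read_order_invariance(self):
        rng = np.random.default_rng(5)
        mids = list(rng.integers(5_000, 9_000, size=200))
        anchor = 7_000
        a = score_valley(ReadTrack({"chr1": mids}), "chr1", anchor)
        rng.shuffle(mids)
        b = score_valley(ReadTrack({"chr1": mids}), "chr1", anchor)
        assert a.final_score == b.final_score

    def test_chromosome_edge_is_unscorable(self):
        track = ReadTrack({"chr1": [100, 200, 300]})
        genome = GenomeTable({"chr1": 100_000})
        assert score_valley(track, "chr1", 100, genome=genome) is None
        assert score_valley(track, "chr1", 99_950, genome=genome) is None


class TestScanBroadPeak:
    def test_peak_shorter_than_step_gets_one_anchor(self):
        rng = np.random.default_rng(11)
        track, _ = _random_track(rng, span=4000, n_reads=400, offset=8000)
        peak = iv("chr1", 10_000, 10_030)
        calls = scan_broad_peak(track, peak, step=50)
        assert len(calls) == 1
        assert calls[0].anchor == 10_000

    def test_two_planted_valleys_yield_two_separated_calls(self):
        rng = np.random.default_rng(13)
        centers = (20_000, 22_000)
        mids = list(rng.integers(18_000, 24_000, size=120))  # mild background
        for c in centers:
            mids += [int(x) for x in rng.integers(c - 500, c - 200, size=80)]
            mids += [int(x) for x in rng.integers(c + 200, c + 500, size=80)]
            mids = [m for m in mids if not (c - 150 <= m < c + 150)]
        track = ReadTrack({"chr1": mids})
        peak = iv("chr1", 19_000, 23_000)
        calls = scan_broad_peak(track, peak, step=50)
        strong = [c for c in calls if c.final_score < 1e-6]
        # each planted center recovered by a confident, accurately placed call
        for center in centers:
            near = [c for c in strong if abs(c.anchor - center) <= 25]  # step/2
            assert len(near) == 1
        for a in strong:
            for b in strong:
                if a is not b:
                    assert not a.valley_interval.overlaps(b.valley_interval)

    def test_accepted_calls_never_overlap(self):
        rng = np.random.default_rng(17)
        track, _ = _random_track(rng, span=6000, n_reads=600, offset=10_000)
        calls = scan_broad_peak(track, iv("chr1", 11_000, 15_000), step=50)
        for a in calls:
            for b in calls:
                if a is not b:
                    assert not a.valley_interval.overlaps(b.valley_interval)


class TestSelectPvpEnhancers:
    def _calls(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        track, _ = _random_track(rng, span=50_000, n_reads=2_000)
        out = []
        for anchor in range(2_000, 48_000, 1_600):
            c = score_valley(track, "chr1", anchor)
            if c is not None:
                out.append(c)
        return out

    def test_top_n_zero_is_empty(self):
        assert select_pvp_enhancers(self._calls(), top_n=0) == []

    def test_vacuous_threshold_keeps_all(self):
        calls = self._calls()
        assert len(select_pvp_enhancers(calls, max_pvalue=1.0)) == len(calls)

    def test_exactly_one_selection_mode(self):
        with pytest.raises(ValueError):
            select_pvp_enhancers(self._calls(), max_pvalue=0.5, top_n=3)
        with pytest.raises(ValueError):
            select_pvp_enhancers(self._calls())

    def test_top_n_beyond_available_warns_and_keeps_all(self, caplog):
        calls = self._calls()
        with caplog.at_level("WARNING"):
            kept = select_pvp_enhancers(calls, top_n=len(calls) + 10)
        assert len(kept) == len(calls)
        assert any("top_n" in r.message for r in caplog.records)

    def test_planted_enhancers_dominate_top_n(self, default_landscape, default_track):
        """With planted + null anchors, the best-ranked calls are the planted ones."""
        from pvpmap.pvp import scan_genome

        ls = default_landscape
        calls = scan_genome(default_track, ls.broad_peaks, genome=ls.genome)
        top = select_pvp_enhancers(calls, top_n=len(ls.enhancers))
        planted = 0
        for rec in top:
            if any(rec.interval.overlaps(e.core) for e in ls.enhancers):
                planted += 1
        assert planted >= int(0.9 * len(ls.enhancers))
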
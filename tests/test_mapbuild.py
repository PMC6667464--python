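"""Map assembly stages and the half-point extent measurement."""

import numpy as np
import pytest

from pvpmap.core import CoverageTrack, GenomicInterval, merge_intervals
from pvpmap.mapbuild import (
    EnhancerRecord,
    Tss,
    TssAnnotation,
    enhancer_extent,
    filter_by_broad_peaks,
    merge_with_pvp,
    remove_tss_proximal,
    union_tf_regions,
)
from tests.oracles import oracle_point_distance, per_base_union

iv = GenomicInterval


def rec(start, end, chrom="chr1", pvp=False, tf=("X",), signal=0.0, score=None):
    return EnhancerRecord(
        interval=iv(chrom, start, end), pvp=pvp,
        supporting_tf_sets=frozenset(tf), h3k27ac_signal=signal,
        pvp_score=score, provenance="test",
    )


class TestUnionTfRegions:
    def test_single_set_disjoint_peaks(self):
        out = union_tf_regions({"Olig2": [iv("chr1", 0, 100), iv("chr1", 500, 700)]})
        assert len(out) == 2
        assert all(r.supporting_tf_sets == {"Olig2"} for r in out)

    def test_overlapping_sets_merge_with_label_union(self):
        out = union_tf_regions(
            {"Sox10": [iv("chr1", 100, 300)], "Olig2": [iv("chr1", 250, 500)]}
        )
        assert len(out) == 1
        assert out[0].interval == iv("chr1", 100, 500)
        assert out[0].supporting_tf_sets == {"Sox10", "Olig2"}

    def test_empty_pool_gives_empty_map(self):
        assert union_tf_regions({"Sox10": []}) == []

    def test_region_count_matches_per_base_oracle(self):
        rng = np.random.default_rng(21)
        sets = {}
        for label in ("A", "B", "C"):
            starts = rng.integers(0, 90_000, size=100)
            widths = rng.integers(50, 900, size=100)
            sets[label] = [iv("chr1", int(s), int(s + w))
                           for s, w in zip(starts, widths)]
        out = union_tf_regions(sets)
        bases = per_base_union(
            ("chr1", p.start, p.end) for peaks in sets.values() for p in peaks
        )
        # number of merged regions == number of maximal runs in the base set
        positions = sorted(p for _, p in bases)
        n_runs = 1 + sum(
            1 for a, b in zip(positions, positions[1:]) if b > a + 1
        )
        assert len(out) == n_runs
        assert sum(len(r.interval) for r in out) == len(bases)


class TestFilterByBroadPeaks:
    def test_no_broad_peaks_empties_map(self):
        assert filter_by_broad_peaks([rec(0, 100)], []) == []

    def test_contained_record_keeps_max_signal(self):
        peaks = [iv("chr1", 0, 1000, score=9.1), iv("chr1", 50, 80, score=3.0)]
        out = filter_by_broad_peaks([rec(40, 90)], peaks)
        assert len(out) == 1
        assert out[0].h3k27ac_signal == 9.1

    def test_single_bp_overlap_retained(self):
        out = filter_by_broad_peaks([rec(100, 200)], [iv("chr1", 199, 300, score=1.0)])
        assert len(out) == 1

    def test_bookended_is_not_overlap(self):
        assert filter_by_broad_peaks([rec(100, 200)], [iv("chr1", 200, 300)]) == []


class TestMergeWithPvp:
    def test_disjoint_inputs_concatenate(self):
        out = merge_with_pvp([rec(0, 100)], [rec(500, 600, pvp=True, tf=())])
        assert len(out) == 2

    def test_identical_intervals_combine_evidence(self):
        a = rec(100, 200, tf=("Sox10",), signal=2.0)
        b = rec(100, 200, pvp=True, tf=(), signal=5.0, score=1e-9)
        (m,) = merge_with_pvp([a], [b])
        assert m.pvp and m.supporting_tf_sets == {"Sox10"}
        assert m.h3k27ac_signal == 5.0 and m.pvp_score == 1e-9

    def test_overlapping_tf_and_valley_fuse(self):
        (m,) = merge_with_pvp(
            [rec(100, 400, tf=("Olig2",))], [rec(350, 700, pvp=True, tf=())]
        )
        assert m.interval == iv("chr1", 100, 700)
        assert m.pvp and m.supporting_tf_sets == {"Olig2"}

    def test_base_coverage_is_conserved(self):
        rng = np.random.default_rng(33)
        tf = [rec(int(s), int(s) + int(w))
              for s, w in zip(rng.integers(0, 50_000, 40), rng.integers(50, 800, 40))]
        pvp = [rec(int(s), int(s) + 300, pvp=True, tf=())
               for s in rng.integers(0, 50_000, 25)]
        out = merge_with_pvp(tf, pvp)
        want = per_base_union(
            ("chr1", r.interval.start, r.interval.end) for r in tf + pvp
        )
        got = per_base_union(("chr1", r.interval.start, r.interval.end) for r in out)
        assert got == want


class TestRemoveTssProximal:
    def tss(self, *positions):
        return TssAnnotation([Tss("chr1", p, f"g{p}") for p in positions])

    def test_tss_inside_interval_removes_record(self):
        kept, removed = remove_tss_proximal([rec(100, 200)], self.tss(150))
        assert kept == [] and removed == 1

    def test_distance_exactly_radius_retained(self):
        kept, _ = remove_tss_proximal([rec(2000, 2400)], self.tss(1000), radius=1000)
        assert len(kept) == 1  # distance = 2000 - 1000 = 1000, not < 1000

    def test_distance_just_inside_radius_removed(self):
        kept, _ = remove_tss_proximal([rec(2000, 2400)], self.tss(1001), radius=1000)
        assert kept == []

    def test_radius_zero_removes_only_containing_records(self):
        records = [rec(0, 100), rec(200, 300)]
        kept, _ = remove_tss_proximal(records, self.tss(50), radius=0)
        assert [r.interval.start for r in kept] == [200]

    def test_survivors_match_all_pairs_oracle(self):
        rng = np.random.default_rng(44)
        records = [rec(int(s), int(s) + int(w))
                   for s, w in zip(rng.integers(0, 80_000, 50),
                                   rng.integers(100, 600, 50))]
        tss_pos = [int(p) for p in rng.integers(0, 80_000, 5)]
        kept, removed = remove_tss_proximal(records, self.tss(*tss_pos), radius=1000)
        expected = [
            r for r in records
            if all(
                oracle_point_distance(r.interval.start, r.interval.end, p) >= 1000
                for p in tss_pos
            )
        ]
        assert [r.interval for r in kept] == [r.interval for r in expected]
        assert removed == len(records) - len(expected)


class TestEnhancerExtent:
    def test_rectangular_profile_half_points(self):
        # shoulders depth 20 on [1000,1300) and [1700,2000), valley depth 2
        cov = CoverageTrack({
            "chr1": (np.array([1000, 1300, 1700]),
                     np.array([1300, 1700, 2000]),
                     np.array([20, 2, 20]))
        })
        r = rec(1300, 1700)
        assert enhancer_extent(r, cov) == 400

    def test_flat_zero_coverage_is_undefined(self):
        cov = CoverageTrack({})
        assert enhancer_extent(rec(1300, 1700), cov) is None

    def test_gaussian_shoulders_recover_planted_gap(self):
        from pvpmap.simulate import gaussian_pvp_coverage

        for center, gap in [(50_000, 390), (80_000, 500), (120_000, 300)]:
            cov = gaussian_pvp_coverage("chr1", center, gap=gap)
            r = rec(center - gap // 2, center + gap - gap // 2)
            extent = enhancer_extent(r, cov)
            assert extent == pytest.approx(gap, abs=20)


class TestPipelineOrdering:
    def test_stage_counts_monotone_and_evidence_kept(self, default_landscape,
                                                     default_track):
        from pvpmap.pipeline import build_enhancer_map

        ls = default_landscape
        cfg = ls.config
        tf_sets = {k: v for k, v in ls.tf_peaks.items()
                   if k != cfg.validation_label}
        res = build_enhancer_map(tf_sets, ls.broad_peaks, default_track,
                                 ls.tss, genome=ls.genome)
        c = res.stage_counts
        assert c["tf_union"] >= c["after_broad_peak_filter"]
        assert c["merged"] >= c["final_map"]
        # every survivor keeps at least one evidence source (type invariant)
        for r in res.records:
            assert r.pvp or r.supporting_tf_sets
        # no record near a TSS
        for r in res.records:
            d = ls.tss.min_distance(r.interval)
            assert d is None or d >= 1000
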
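import numpy as np
import pytest

from rtarch import domain_arch as da
from rtarch import timing as tm
from rtarch.core import BinnedTrack, GenomicInterval, IntervalSet

_EPS = 1e-9


def oracle_segments(scores):
    """Exhaustive O(n^2) recursive maximal-segment decomposition.

    Independent of the Kadane-based implementation: every candidate
    segment's sum is enumerated from prefix sums at each recursion level.
    """
    scores = np.asarray(scores, dtype=float)
    pref = np.concatenate([[0.0], np.cumsum(scores)])
    out = []

    def best(lo, hi):
        b = (-np.inf, lo, lo)
        for i in range(lo, hi):
            for j in range(i + 1, hi + 1):
                s = pref[j] - pref[i]
                if s > b[0] + _EPS or (
                    abs(s - b[0]) <= _EPS
                    and (i < b[1] or (i == b[1] and j < b[2]))
                ):
                    b = (s, i, j)
        return b

    def rec(lo, hi):
        if hi - lo <= 0:
            return
        s, i, j = best(lo, hi)
        if s <= _EPS:
            return
        out.append((i, j, s))
        rec(lo, i)
        rec(j, hi)

    rec(0, len(scores))
    return sorted(out)


class TestMaximalSegments:
    def test_single_block(self):
        scores = np.array([-1.0] * 5 + [1.0] * 10 + [-1.0] * 5)
        segs = da.maximal_segments(scores)
        assert segs == [(5, 15, pytest.approx(10.0))]

    def test_all_negative_empty(self):
        assert da.maximal_segments(np.full(20, -0.5)) == []

    def test_oracle_agreement_random(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 201))
            gp = float(rng.uniform(0.5, 6.0))
            scores = np.where(rng.random(n) < rng.uniform(0.2, 0.6), 1.0, -gp)
            got = da.maximal_segments(scores)
            exp = oracle_segments(scores)
            assert [(i, j) for i, j, _ in got] == [(i, j) for i, j, _ in exp]
            for (_, _, a), (_, _, b) in zip(got, exp):
                assert a == pytest.approx(b)


class TestCallBroadDomains:
    def _track(self, values):
        return BinnedTrack("chr1", 50_000, np.asarray(values, dtype=float))

    def test_planted_block_called_exactly(self):
        # 40 consecutive bins at +2 in a flat zero background
        vals = np.zeros(200)
        vals[60:100] = 2.0
        doms = da.call_broad_domains(self._track(vals), seed=0)
        assert len(doms) == 1
        assert doms[0].interval.start == 60 * 50_000
        assert doms[0].interval.end == 100 * 50_000
        assert doms[0].mean_enrichment > 0

    def test_flat_track_no_domains(self):
        rng = np.random.default_rng(1)
        doms = da.call_broad_domains(self._track(rng.normal(0, 0.1, 300)), seed=1)
        assert doms == []

    def test_two_domains_not_merged_across_gap(self):
        # 20 depleted bins between two enriched blocks: bridging segment
        # scores negative, so the blocks stay separate
        vals = np.concatenate(
            [np.zeros(50), np.full(40, 2.0), np.zeros(20), np.full(40, 2.0), np.zeros(50)]
        )
        doms = da.call_broad_domains(self._track(vals), seed=0)
        assert len(doms) == 2
        assert doms[0].interval.end == 90 * 50_000
        assert doms[1].interval.start == 110 * 50_000

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            da.call_broad_domains(self._track(np.zeros(50)))

    def test_low_n_perm_rejected(self):
        with pytest.raises(ValueError):
            da.call_broad_domains(self._track(np.zeros(200)), n_perm=50)

    def test_boundary_recovery_on_simulation(self, default_sim, default_rt):
        spec, _, truth, _ = default_sim
        _, enr = default_rt
        doms = []
        for chrom in sorted(spec.chrom_lengths):
            doms += da.call_broad_domains(enr["rif1"][chrom], seed=1)
        ok = tot = 0
        for r in truth.rads:
            tot += 2
            for d in doms:
                if d.interval.chrom == r.chrom and d.interval.overlap_bp(r) > r.length // 2:
                    ok += abs(d.interval.start - r.start) <= 2 * spec.bin_size
                    ok += abs(d.interval.end - r.end) <= 2 * spec.bin_size
        assert ok / tot >= 0.9


class TestOverlapVenn:
    def test_basic_arithmetic(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 50, 150)])
        v = da.overlap_venn(a, b)
        assert (v.unique_a_bp, v.unique_b_bp, v.shared_bp) == (50, 50, 50)
        assert v.jaccard == pytest.approx(1 / 3)

    def test_identical_sets(self):
        a = IntervalSet([GenomicInterval("chr1", 10, 60)])
        v = da.overlap_venn(a, a)
        assert v.unique_a_bp == v.unique_b_bp == 0
        assert v.jaccard == 1.0

    def test_against_boolean_mask_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            def rand_set():
                n = int(rng.integers(1, 20))
                starts = rng.integers(0, 900, n)
                widths = rng.integers(1, 120, n)
                return [
                    GenomicInterval("c", int(s), int(min(s + w, 1000)))
                    for s, w in zip(starts, widths)
                    if s < min(s + w, 1000)
                ]

            ia, ib = rand_set(), rand_set()
            ma = np.zeros(1000, dtype=bool)
            mb = np.zeros(1000, dtype=bool)
            for iv in ia:
                ma[iv.start : iv.end] = True
            for iv in ib:
                mb[iv.start : iv.end] = True
            v = da.overlap_venn(IntervalSet(ia), IntervalSet(ib))
            assert v.shared_bp == int((ma & mb).sum())
            assert v.unique_a_bp == int((ma & ~mb).sum())
            assert v.unique_b_bp == int((mb & ~ma).sum())
            # base-pair conservation
            assert v.unique_a_bp + v.shared_bp == int(ma.sum())

    def test_commutative(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 70), GenomicInterval("chr2", 5, 25)])
        b = IntervalSet([GenomicInterval("chr1", 30, 120)])
        v1, v2 = da.overlap_venn(a, b), da.overlap_venn(b, a)
        assert (v1.unique_a_bp, v1.unique_b_bp) == (v2.unique_b_bp, v2.unique_a_bp)
        assert v1.shared_bp == v2.shared_bp


class TestPartitionRads:
    def test_fully_covered_is_plus(self):
        rad = GenomicInterval("chr1", 100, 200)
        lads = IntervalSet([GenomicInterval("chr1", 0, 300)])
        plus, minus = da.partition_rads([rad], lads)
        assert plus == [rad] and minus == []

    def test_no_overlap_is_minus(self):
        rad = GenomicInterval("chr1", 100, 200)
        plus, minus = da.partition_rads([rad], IntervalSet())
        assert plus == [] and minus == [rad]

    def test_threshold_dependence(self):
        rad = GenomicInterval("chr1", 0, 100)
        lads = IntervalSet([GenomicInterval("chr1", 0, 40)])  # 40% covered
        plus, minus = da.partition_rads([rad], lads, min_lamin_frac=0.5)
        assert minus == [rad]
        plus, minus = da.partition_rads([rad], lads, min_lamin_frac=0.3)
        assert plus == [rad]

    def test_exhaustive_exclusive_and_order_stable(self):
        rng = np.random.default_rng(3)
        rads = [
            GenomicInterval("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 10_000, 30) * 100
        ]
        lads = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + 2000) for s in rng.integers(0, 900_000, 20)]
        )
        plus, minus = da.partition_rads(rads, lads)
        assert len(plus) + len(minus) == len(rads)
        perm = list(np.random.default_rng(0).permutation(len(rads)))
        plus2, minus2 = da.partition_rads([rads[i] for i in perm], lads)
        assert sorted(plus) == sorted(plus2) and sorted(minus) == sorted(minus2)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            da.partition_rads([], IntervalSet(), min_lamin_frac=0.0)


class TestLateCoverage:
    def test_full_cover_union_one(self):
        late = IntervalSet([GenomicInterval("chr1", 0, 100)])
        rads = IntervalSet([GenomicInterval("chr1", 0, 100)])
        cov = da.late_genome_coverage(late, rads, IntervalSet())
        assert cov.frac_union == 1.0

    def test_disjoint_additivity(self):
        late = IntervalSet([GenomicInterval("chr1", 0, 100)])
        rads = IntervalSet([GenomicInterval("chr1", 0, 30)])
        lads = IntervalSet([GenomicInterval("chr1", 30, 73)])
        cov = da.late_genome_coverage(late, rads, lads)
        assert cov.frac_rads == pytest.approx(0.30)
        assert cov.frac_lads == pytest.approx(0.43)
        assert cov.frac_union == pytest.approx(0.73)

    def test_union_at_least_each(self):
        late = IntervalSet([GenomicInterval("chr1", 0, 1000)])
        rads = IntervalSet([GenomicInterval("chr1", 100, 400)])
        lads = IntervalSet([GenomicInterval("chr1", 300, 600)])
        cov = da.late_genome_coverage(late, rads, lads)
        assert cov.frac_union >= max(cov.frac_rads, cov.frac_lads)

    def test_empty_late_rejected(self):
        with pytest.raises(ValueError):
            da.late_genome_coverage(IntervalSet(), IntervalSet(), IntervalSet())

    def test_simulation_recovery(self, default_sim, default_rt):
        # planted coverage of late bp by RAD union LAD equals the RAD
        # fraction of late blocks
        spec, _, truth, _ = default_sim
        rt, _ = default_rt
        late = IntervalSet(
            [iv for iv, cls in truth.rt_domains if cls == "late"]
        )
        cov = da.late_genome_coverage(late, truth.rads, truth.lads)
        assert cov.frac_union == pytest.approx(spec.rad_fraction_of_late, abs=0.03)


class TestEnrichmentBySwitchClass:
    def test_synthetic_ltoe_lamin_below_ltol(self, default_sim, default_rt):
        spec, _, truth, _ = default_sim
        rt, enr = default_rt
        calls = []
        for chrom in spec.chrom_lengths:
            doms = tm.segment_rt_domains(rt["wt"][chrom])
            calls += tm.classify_switches(rt["wt"][chrom], rt["ko"][chrom], doms)
        scatter, _ = da.enrichment_by_switch_class(calls, enr["rif1"], enr["laminB1"])
        med = scatter.groupby("switch_class")["laminB1"].median()
        assert med["LtoE"] < med["LtoL"]

    def test_identical_tracks_identical_summaries(self):
        t = {"chr1": BinnedTrack("chr1", 100, np.arange(10, dtype=float))}
        calls = [
            tm.SwitchCall(GenomicInterval("chr1", 0, 500), "late", 0.0, "LtoL"),
            tm.SwitchCall(GenomicInterval("chr1", 500, 1000), "early", 0.0, "EtoE"),
        ]
        scatter, _ = da.enrichment_by_switch_class(calls, t, t)
        np.testing.assert_allclose(scatter["rif1"], scatter["laminB1"])

    def test_single_region_class_median(self):
        t = {"chr1": BinnedTrack("chr1", 100, np.full(10, 3.0))}
        calls = [tm.SwitchCall(GenomicInterval("chr1", 0, 1000), "late", 2.0, "LtoE")]
        scatter, summary = da.enrichment_by_switch_class(calls, t, t)
        assert scatter["rif1"].iloc[0] == pytest.approx(3.0)

    def test_empty_calls_no_failure(self):
        scatter, summary = da.enrichment_by_switch_class([], {}, {})
        assert scatter.empty
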
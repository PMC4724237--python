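import numpy as np
import pandas as pd
import pytest

from rtarch import contacts as ct
from rtarch.core import BinnedTrack, GenomicInterval, IntervalSet


class TestDigest:
    def test_hand_constructed_cuts(self):
        # motif at 100 and 200; cut at motif start
        seq = "A" * 100 + "AAGCTT" + "A" * 94 + "AAGCTT" + "A" * 50
        fm = ct.digest({"chr1": seq})
        np.testing.assert_array_equal(
            fm.fragments["chr1"], [[0, 100], [100, 200], [200, 256]]
        )

    def test_motif_free_single_fragment(self):
        fm = ct.digest({"chr1": "ACGT" * 100})
        assert len(fm.fragments["chr1"]) == 1

    def test_fragment_count_equals_occurrences_plus_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
        n_occ = len(
            [m for m in __import__("re").finditer("(?=AAGCTT)", seq)]
        )
        fm = ct.digest({"chr1": seq})
        # overlapping occurrences cannot happen for this motif
        assert len(fm.fragments["chr1"]) == n_occ + 1

    def test_concatenation_identity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        fm = ct.digest({"chr1": seq})
        assert "".join(seq[s:e] for s, e in fm.fragments["chr1"]) == seq

    def test_short_motif_rejected(self):
        with pytest.raises(ValueError):
            ct.digest({"chr1": "ACGT"}, motif="AT")

    def test_fragment_index(self):
        fm = ct.digest({"chr1": "A" * 100 + "AAGCTT" + "A" * 100})
        assert fm.fragment_index("chr1", 50) == 0
        assert fm.fragment_index("chr1", 150) == 1
        with pytest.raises(ValueError):
            fm.fragment_index("chr1", 10_000)


def toy_fragmap(n=10, width=10_000):
    frags = np.array([[i * width, (i + 1) * width] for i in range(n)])
    return ct.FragmentMap(fragments={"chr1": frags}, motif="AAGCTT")


class TestRPMNormalize:
    def test_definition(self):
        fm = toy_fragmap()
        counts = {"chr1": np.zeros(10)}
        counts["chr1"][5] = 50.0
        counts["chr1"][9] = 999_950.0
        # viewpoint on fragment 0 (zero counts): the library total stays 1e6
        rpm, _ = ct.rpm_normalize(counts, fm, "chr1", 5_000, exclude_bp=1)
        assert rpm["chr1"][5] == pytest.approx(50.0 * 1e6 / 1e6)

    def test_scale_invariance(self):
        fm = toy_fragmap()
        c1 = {"chr1": np.arange(10, dtype=float) + 1}
        c2 = {"chr1": (np.arange(10, dtype=float) + 1) * 2}
        r1, _ = ct.rpm_normalize(c1, fm, "chr1", 95_000, exclude_bp=1)
        r2, _ = ct.rpm_normalize(c2, fm, "chr1", 95_000, exclude_bp=1)
        np.testing.assert_allclose(r1["chr1"][:-1], r2["chr1"][:-1])

    def test_viewpoint_zone_excluded_from_total(self):
        fm = toy_fragmap()
        counts = {"chr1": np.full(10, 10.0)}
        # viewpoint at fragment 5 midpoint; zone +/-15kb covers frags 4-6
        rpm, excluded = ct.rpm_normalize(counts, fm, "chr1", 55_000, exclude_bp=15_000)
        assert excluded["chr1"].sum() == 3
        assert np.isnan(rpm["chr1"][4:7]).all()
        # total excludes the three zone fragments: 70 reads
        assert rpm["chr1"][0] == pytest.approx(10.0 * 1e6 / 70.0)

    def test_rpm_sums_to_million(self):
        fm = toy_fragmap()
        counts = {"chr1": np.arange(10, dtype=float) + 5}
        rpm, _ = ct.rpm_normalize(counts, fm, "chr1", 5_000, exclude_bp=1_000)
        assert np.nansum(rpm["chr1"]) == pytest.approx(1e6, abs=1e-6)

    def test_zero_library_rejected(self):
        fm = toy_fragmap()
        with pytest.raises(ValueError):
            ct.rpm_normalize({"chr1": np.zeros(10)}, fm, "chr1", 5_000)


def make_contact_set(rows, vp_chrom="chr1", vp_pos=0, name="vp"):
    table = pd.DataFrame(
        rows, columns=["chrom", "frag_idx", "start", "end", "rpm1", "rpm2", "rpm", "consistent"]
    )
    return ct.ContactSet(name, vp_chrom, vp_pos, table)


class TestCallContacts:
    def _setup(self, rng, n=2000, width=4000, boost_idx=(), boost_rpm=500.0):
        frags = np.array([[i * width, (i + 1) * width] for i in range(n)])
        fm = ct.FragmentMap(fragments={"chr1": frags}, motif="AAGCTT")
        vp_pos = (n // 2) * width
        mids = (frags[:, 0] + frags[:, 1]) // 2
        d = np.abs(mids - vp_pos) + 10_000.0
        lam = 1e6 * d**-2.0 / np.sum(d**-2.0)
        lam[list(boost_idx)] = boost_rpm
        reps = []
        for _ in range(2):
            counts = rng.poisson(lam).astype(float)
            rpm, _ = ct.rpm_normalize({"chr1": counts}, fm, "chr1", vp_pos)
            reps.append(rpm)
        return fm, vp_pos, reps

    def test_strong_fragment_called(self, rng):
        fm, vp_pos, reps = self._setup(rng, boost_idx=(100,), boost_rpm=500.0)
        cs = ct.call_contacts(reps[0], reps[1], fm, "vp", "chr1", vp_pos)
        cons = cs.consistent()
        assert 100 in set(cons["frag_idx"])

    def test_single_replicate_not_consistent(self):
        fm = toy_fragmap(100, 10_000)
        base = np.full(100, 1.0)
        r1 = {"chr1": base.copy()}
        r2 = {"chr1": base.copy()}
        r1["chr1"][40] = 500.0  # only replicate 1
        cs = ct.call_contacts(r1, r2, fm, "vp", "chr1", 5_000, min_rpm=10)
        assert 40 not in set(cs.consistent()["frag_idx"])

    def test_replicate_order_symmetric(self, rng):
        fm, vp_pos, reps = self._setup(rng, boost_idx=(80, 1500))
        a = ct.call_contacts(reps[0], reps[1], fm, "vp", "chr1", vp_pos)
        b = ct.call_contacts(reps[1], reps[0], fm, "vp", "chr1", vp_pos)
        np.testing.assert_array_equal(
            a.table["consistent"].to_numpy(), b.table["consistent"].to_numpy()
        )

    def test_min_rpm_monotonicity(self, rng):
        fm, vp_pos, reps = self._setup(rng, boost_idx=tuple(range(100, 130)), boost_rpm=30.0)
        counts = [
            ct.call_contacts(
                reps[0], reps[1], fm, "vp", "chr1", vp_pos, min_rpm=thr
            ).n_consistent()
            for thr in (5.0, 10.0, 20.0, 40.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_sensitivity_and_false_calls_on_simulation(self, default_sim, default_4c):
        spec, _, truth, _ = default_sim
        libs = default_4c
        tp = fn = fp = n_bg = 0
        for vp in truth.viewpoints:
            rpms = []
            for rep in (1, 2):
                rpm, _ = ct.rpm_normalize(
                    libs.counts[(vp.name, "wt", rep)], libs.fragment_map, vp.chrom, vp.pos
                )
                rpms.append(rpm)
            cs = ct.call_contacts(rpms[0], rpms[1], libs.fragment_map, vp.name, vp.chrom, vp.pos)
            cons = cs.consistent()
            called = set(cons.loc[cons["chrom"] == vp.chrom, "frag_idx"])
            planted = {i for i, rpm in truth.true_contacts[vp.name] if rpm >= 20}
            extra = set(truth.intra_contacts[vp.name]) | {
                i for i, _ in truth.true_contacts[vp.name]
            }
            n_frags = libs.fragment_map.n_fragments(vp.chrom)
            tp += len(planted & called)
            fn += len(planted - called)
            fp += len(called - extra)
            n_bg += n_frags - len(extra)
        assert tp / (tp + fn) >= 0.9
        assert fp / n_bg <= 0.05


class TestRPMBinCompare:
    def _sets_from_rpms(self, rpms_by_vp):
        out = {}
        for vp, rpms in rpms_by_vp.items():
            rows = [
                ("chr1", i, i * 1000, (i + 1) * 1000, r, r, r, True)
                for i, r in enumerate(rpms)
            ]
            out[vp] = make_contact_set(rows, name=vp)
        return out

    def test_identical_sets_fold_one(self):
        rpms = {f"v{i}": [15.0, 50.0, 300.0] for i in range(3)}
        s = self._sets_from_rpms(rpms)
        summary = ct.rpm_bin_compare(s, s)
        assert summary.fold["[10,200)"] == pytest.approx(1.0)
        assert summary.fold["[200,Inf)"] == pytest.approx(1.0)

    def test_planted_low_range_gain(self):
        wt = self._sets_from_rpms({f"v{i}": [50.0] * 10 + [300.0] * 5 for i in range(3)})
        ko = self._sets_from_rpms(
            {f"v{i}": [50.0] * 10 + [300.0] * 5 + [15.0] * 50 for i in range(3)}
        )
        summary = ct.rpm_bin_compare(wt, ko)
        assert summary.fold["[10,200)"] == pytest.approx(6.0)
        assert summary.fold["[200,Inf)"] == pytest.approx(1.0)

    def test_degenerate_variance_flagged(self):
        wt = self._sets_from_rpms({f"v{i}": [50.0] * 4 for i in range(3)})
        ko = self._sets_from_rpms({f"v{i}": [50.0] * 8 for i in range(3)})
        summary = ct.rpm_bin_compare(wt, ko)
        assert not summary.test_defined["[10,200)"]

    def test_needs_two_viewpoints(self):
        s = self._sets_from_rpms({"v0": [50.0]})
        with pytest.raises(ValueError):
            ct.rpm_bin_compare(s, s)

    def test_zero_wt_fold_flagged(self):
        wt = self._sets_from_rpms({f"v{i}": [50.0] for i in range(2)})
        ko = self._sets_from_rpms({f"v{i}": [50.0, 300.0] for i in range(2)})
        summary = ct.rpm_bin_compare(wt, ko)
        assert not summary.fold_defined["[200,Inf)"]


class TestClassifyScope:
    def test_all_inside_domain(self):
        rows = [("chr1", i, i * 1000, (i + 1) * 1000, 50.0, 50.0, 50.0, True) for i in range(5)]
        cs = make_contact_set(rows, vp_pos=2500)
        cis, intra = ct.classify_scope(cs, GenomicInterval("chr1", 0, 10_000))
        assert (cis, intra) == (5, 5)

    def test_midpoint_assignment_at_boundary(self):
        # fragment [900, 1100): midpoint 1000 lies inside [1000, 2000)
        rows = [
            ("chr1", 0, 900, 1100, 50.0, 50.0, 50.0, True),
            ("chr1", 1, 1900, 2100, 50.0, 50.0, 50.0, True),  # mid 2000: outside
        ]
        cs = make_contact_set(rows, vp_pos=1500)
        cis, intra = ct.classify_scope(cs, GenomicInterval("chr1", 1000, 2000))
        assert (cis, intra) == (2, 1)

    def test_viewpoint_must_be_inside_domain(self):
        cs = make_contact_set([], vp_pos=5_000_000)
        with pytest.raises(ValueError):
            ct.classify_scope(cs, GenomicInterval("chr1", 0, 100))

    def test_intra_le_cis(self, rng):
        rows = [
            ("chr1", i, int(p), int(p) + 100, 20.0, 20.0, 20.0, bool(f))
            for i, (p, f) in enumerate(
                zip(rng.integers(0, 1_000_000, 50), rng.random(50) < 0.5)
            )
        ]
        cs = make_contact_set(rows, vp_pos=500_000)
        cis, intra = ct.classify_scope(cs, GenomicInterval("chr1", 400_000, 600_000))
        assert intra <= cis


class TestTADRTSpecificity:
    def _rt(self):
        vals = np.concatenate([np.full(10, -2.0), np.full(10, 2.0)])
        return {"chr1": BinnedTrack("chr1", 100_000, vals)}

    def _tads(self):
        return IntervalSet(
            [GenomicInterval("chr1", i * 500_000, (i + 1) * 500_000) for i in range(4)]
        )

    def test_identical_sets_no_gained(self):
        rows = [("chr1", 0, 100_000, 101_000, 50.0, 50.0, 50.0, True)]
        cs = make_contact_set(rows, vp_pos=100_500)
        out = ct.tad_rt_specificity(cs, cs, self._tads(), self._rt())
        assert out.gained_tads == []
        assert len(out.shared_tads) == 1

    def test_single_shared_tad_median(self):
        rows = [
            ("chr1", 0, 100_000, 101_000, 50.0, 50.0, 50.0, True),
            ("chr1", 1, 200_000, 201_000, 50.0, 50.0, 50.0, True),
        ]
        cs = make_contact_set(rows, vp_pos=100_500)
        out = ct.tad_rt_specificity(cs, cs, self._tads(), self._rt())
        assert out.shared_median_rt == pytest.approx(-2.0)

    def test_contact_outside_tads_excluded(self):
        rows = [("chr1", 0, 3_000_000, 3_001_000, 50.0, 50.0, 50.0, True)]
        wt = make_contact_set([("chr1", 1, 100_000, 101_000, 50.0, 50.0, 50.0, True)], vp_pos=100_500)
        ko = make_contact_set(
            [
                ("chr1", 1, 100_000, 101_000, 50.0, 50.0, 50.0, True),
                ("chr1", 0, 3_000_000, 3_001_000, 50.0, 50.0, 50.0, True),
            ],
            vp_pos=100_500,
        )
        out = ct.tad_rt_specificity(wt, ko, self._tads(), self._rt())
        assert out.n_inter_tad_contacts == 1
        assert out.gained_tads == []

    def test_overlapping_tads_rejected(self):
        tads = IntervalSet(
            [GenomicInterval("chr1", 0, 600_000), GenomicInterval("chr1", 500_000, 900_000)]
        )
        cs = make_contact_set([], vp_pos=0)
        with pytest.raises(ValueError):
            ct.tad_rt_specificity(cs, cs, tads, self._rt())

    def test_gained_nearer_zero_on_simulation(self, default_sim, default_4c):
        spec, _, truth, _ = default_sim
        libs = default_4c
        rt_tracks = {
            c: BinnedTrack(c, spec.bin_size, truth.rt_wt[c]) for c in spec.chrom_lengths
        }
        tads = IntervalSet([iv for iv, _ in truth.rt_domains])
        for vp in truth.viewpoints[:2]:
            sets = {}
            for g in ("wt", "ko"):
                rpms = [
                    ct.rpm_normalize(
                        libs.counts[(vp.name, g, rep)], libs.fragment_map, vp.chrom, vp.pos
                    )[0]
                    for rep in (1, 2)
                ]
                sets[g] = ct.call_contacts(
                    rpms[0], rpms[1], libs.fragment_map, vp.name, vp.chrom, vp.pos
                )
            out = ct.tad_rt_specificity(sets["wt"], sets["ko"], tads, rt_tracks, vp.pos)
            assert abs(out.gained_median_rt) < abs(out.shared_median_rt)
            assert np.sign(out.shared_median_rt) == np.sign(out.viewpoint_rt)
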
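"""Sliding-window ChIP detector, randomization FDR, merging and association."""

import numpy as np
import pandas as pd
import pytest

from orcmap import chip, simulate


def probe_frame(positions, values, chromosome="chr1"):
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(positions))],
            "chromosome": chromosome,
            "position": positions,
            "log2_ratio": values,
        }
    )


def planted_track(seed=0, n=1_000, spacing=61, signal=4.0, site_probes=(500, 510)):
    """Noise N(0, 0.1) with one block of probes raised by ``signal``."""
    rng = np.random.default_rng(seed)
    pos = np.arange(n) * spacing
    val = rng.normal(0, 0.1, n)
    val[site_probes[0] : site_probes[1]] += signal
    return probe_frame(pos, val)


class TestRescale:
    def test_shift_to_zero_minimum(self):
        out = chip.rescale_min_zero(probe_frame([0, 61, 122], [1.0, 2.0, 3.0]))
        assert out["log2_ratio"].tolist() == [0.0, 1.0, 2.0]

    def test_all_equal_becomes_zeros(self):
        out = chip.rescale_min_zero(probe_frame([0, 61], [5.0, 5.0]))
        assert (out["log2_ratio"] == 0).all()

    def test_pairwise_differences_preserved(self, rng):
        vals = rng.normal(size=50)
        out = chip.rescale_min_zero(probe_frame(np.arange(50) * 61, vals))
        assert np.allclose(np.diff(out["log2_ratio"]), np.diff(vals))
        assert out["log2_ratio"].min() == 0.0


class TestDetector:
    def test_flat_track_whole_span_is_one_hit(self):
        # SD = 0 so the hypothetical maximum equals the value itself and
        # every window with >= 4 probes clears a 0.9 cutoff
        track = probe_frame(np.arange(100) * 61, np.full(100, 2.0))
        cands = chip.detect_enriched_windows(track, 0.9)
        assert len(cands) == 1
        assert cands.iloc[0]["start"] == 0

    def test_single_planted_region_single_candidate(self):
        track = planted_track()
        cands = chip.detect_enriched_windows(track, 0.9)
        assert len(cands) == 1
        s, e = cands.iloc[0]["start"], cands.iloc[0]["end"]
        assert s <= 500 * 61 and e >= 509 * 61

    def test_monotone_in_cutoff(self):
        track = planted_track()
        hi = chip.detect_enriched_windows(track, 0.9)
        lo = chip.detect_enriched_windows(track, 0.15)
        # every high-cutoff candidate is contained in a low-cutoff candidate
        for row in hi.itertuples():
            assert (
                (lo["start"] <= row.start) & (lo["end"] >= row.end)
            ).any()

    def test_too_few_probes_empty(self):
        track = probe_frame([0, 61, 122], [9.0, 9.0, 9.0])
        assert len(chip.detect_enriched_windows(track, 0.5)) == 0


class TestFDR:
    def test_pure_noise_fdr_near_one(self, rng):
        track = probe_frame(np.arange(2_000) * 61, rng.normal(0, 0.1, 2_000))
        track = chip.rescale_min_zero(track)
        fdr = chip.estimate_fdr(track, 0.5, n_randomizations=10, seed=1)
        assert np.isnan(fdr) or fdr > 0.5

    def test_planted_sites_low_fdr(self):
        cfg = simulate.SimulationConfig(chromosomes={"chr1": 500_000})
        pos = np.linspace(30_000, 470_000, 10).astype(int)
        sites = pd.DataFrame(
            {"chromosome": "chr1", "start": pos - 500, "end": pos + 500}
        )
        truth = simulate.SyntheticTruth(config=cfg, binding_sites=sites)
        track = chip.rescale_min_zero(simulate.simulate_chip(truth, cfg, seed=2))
        assert chip.estimate_fdr(track, 0.9, seed=3) < 0.05

    def test_deterministic_given_seed(self):
        track = chip.rescale_min_zero(planted_track())
        a = chip.estimate_fdr(track, 0.5, n_randomizations=5, seed=9)
        b = chip.estimate_fdr(track, 0.5, n_randomizations=5, seed=9)
        assert a == b


class TestCallSites:
    def test_planted_strong_site_high_class(self):
        cfg = simulate.SimulationConfig(chromosomes={"chr1": 400_000})
        sites = pd.DataFrame(
            {"chromosome": ["chr1"] * 5,
             "start": [50_000, 120_000, 200_000, 280_000, 350_000],
             "end": [51_000, 121_000, 201_000, 281_000, 351_000]}
        )
        truth = simulate.SyntheticTruth(config=cfg, binding_sites=sites)
        probes = simulate.simulate_chip(truth, cfg, seed=5)
        called = chip.call_sites(probes, seed=6)
        high = called[called["fdr_class"] == "high"]
        for row in sites.itertuples():
            assert ((high["start"] < row.end) & (high["end"] > row.start)).any()

    def test_additive_shift_invariance(self):
        track = planted_track()
        shifted = track.copy()
        shifted["log2_ratio"] = shifted["log2_ratio"] + 3.7
        a = chip.call_sites(track, seed=4, n_randomizations=5)
        b = chip.call_sites(shifted, seed=4, n_randomizations=5)
        pd.testing.assert_frame_equal(a, b)


class TestMerging:
    def test_gap_rule(self):
        sites = pd.DataFrame(
            {"chromosome": "chr1",
             "start": [0, 5_000, 20_000], "end": [1_000, 6_000, 21_000]}
        )
        merged = chip.merge_sites(sites, merge_gap=10_000)
        assert len(merged) == 2
        assert merged.iloc[0]["end"] == 6_000

    def test_single_site_unchanged(self):
        sites = pd.DataFrame({"chromosome": ["chr1"], "start": [0], "end": [100]})
        merged = chip.merge_sites(sites)
        assert merged.iloc[0][["start", "end"]].tolist() == [0, 100]

    def test_zero_gap_identity(self):
        sites = pd.DataFrame(
            {"chromosome": "chr1", "start": [0, 2_000], "end": [1_000, 3_000]}
        )
        merged = chip.merge_sites(sites, merge_gap=0)
        assert len(merged) == len(sites)

    def test_idempotent_and_monotone(self, rng):
        starts = np.sort(rng.integers(0, 1_000_000, 50))
        sites = pd.DataFrame(
            {"chromosome": "chr1", "start": starts, "end": starts + 500}
        )
        m1 = chip.merge_sites(sites, 10_000)
        m2 = chip.merge_sites(m1, 10_000)
        assert len(m1) == len(m2)
        counts = [len(chip.merge_sites(sites, g)) for g in (0, 1_000, 10_000, 50_000)]
        assert counts == sorted(counts, reverse=True)

    def test_matches_naive_oracle_on_random_inputs(self, rng):
        """Transitive-closure merging vs a brute-force reimplementation."""

        def naive(intervals, gap):
            out = []
            for s, e in sorted(intervals):
                if out and s - out[-1][1] < gap:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            return [tuple(x) for x in out]

        for _ in range(1_000):
            n = rng.integers(1, 12)
            starts = rng.integers(0, 3_000, n)
            lens = rng.integers(1, 400, n)
            gap = int(rng.integers(0, 800))
            sites = pd.DataFrame(
                {"chromosome": "chr1", "start": starts, "end": starts + lens}
            ).sort_values("start")
            got = chip.merge_intervals(sites, gap)
            expected = naive(zip(starts, starts + lens), gap)
            assert list(zip(got["start"], got["end"])) == expected

    def test_h4k10ac_merge_then_filter(self):
        loci = pd.DataFrame(
            {"chromosome": "chr1", "start": [0, 2_600], "end": [600, 3_200]}
        )
        kept = chip.merge_h4k10ac(loci)
        assert len(kept) == 1 and kept.iloc[0]["end"] - kept.iloc[0]["start"] == 3_200

    def test_h4k10ac_small_isolated_discarded(self):
        loci = pd.DataFrame({"chromosome": ["chr1"], "start": [0], "end": [600]})
        assert len(chip.merge_h4k10ac(loci)) == 0
        loci = pd.DataFrame({"chromosome": ["chr1"], "start": [0], "end": [1_500]})
        assert len(chip.merge_h4k10ac(loci)) == 1


class TestAssociation:
    def test_spacing_arithmetic(self):
        assert chip.mean_spacing(22.3e6, 170) == pytest.approx(131_176, rel=1e-3)
        assert np.isnan(chip.mean_spacing(1e6, 0))

    def test_midpoint_assignment_is_partition(self, small_truth):
        cfg, genes, truth = small_truth
        mids = np.linspace(10_000, 790_000, 40).astype(int)
        sites = pd.DataFrame(
            {"chromosome": "chr1", "start": mids - 200, "end": mids + 200}
        )
        out = chip.associate_sites_with_regions(
            sites, truth.region_tracks, truth.ssrs, truth.dgcs, truth.cassettes
        )
        assert out["by_class"]["n_sites"].sum() == len(sites)

    def test_occupancy_counts(self):
        features = [("chr1", 0, 1_000), ("chr1", 5_000, 6_000)]
        sites = pd.DataFrame({"chromosome": ["chr1"], "start": [500], "end": [700]})
        occ, n, frac = chip.occupancy(features, sites)
        assert (occ, n, frac) == (1, 2, 0.5)


class TestProximity:
    def test_identical_sets_all_overlap(self):
        a = pd.DataFrame({"chromosome": "chr1", "start": [0, 100], "end": [50, 150]})
        n_within, n_overlap, table = chip.proximity_and_overlap(a, a)
        assert n_within == n_overlap == 2
        assert (table["distance"] == 0).all()

    def test_gap_measured_edge_to_edge(self):
        a = pd.DataFrame({"chromosome": ["chr1"], "start": [0], "end": [1_000]})
        b = pd.DataFrame({"chromosome": ["chr1"], "start": [12_000], "end": [13_000]})
        n_within, n_overlap, table = chip.proximity_and_overlap(a, b, within=15_000)
        assert n_within == 1 and n_overlap == 0
        assert table["distance"].iloc[0] == 11_000

    def test_upstream_orientation_in_dgcs(self):
        from orcmap.annotation import DGC

        dgcs = [DGC("chr1", 0, 100_000, "+", []), DGC("chr1", 100_000, 200_000, "-", [])]
        # sites 5 kb upstream of marks in a forward DGC, downstream in reverse
        a = pd.DataFrame(
            {"chromosome": "chr1", "start": [20_000, 120_000], "end": [21_000, 121_000]}
        )
        b = pd.DataFrame(
            {"chromosome": "chr1", "start": [25_000, 115_000], "end": [26_000, 116_000]}
        )
        _, _, table = chip.proximity_and_overlap(a, b, dgcs=dgcs)
        assert table["upstream"].tolist() == [True, True]
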
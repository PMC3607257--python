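"""S/G2 ratio tracks, OBR peak calling, fork asymmetry and origin density."""

import numpy as np
import pandas as pd
import pytest

from orcmap import mfa, simulate
from orcmap.simulate import Origin


def single_origin_track(
    seed=0, length=1_000_000, position=500_000.0, left=300_000.0, right=300_000.0
):
    cfg = simulate.SimulationConfig(chromosomes={"chr1": length})
    truth = simulate.SyntheticTruth(config=cfg)
    truth.origins = [Origin("chr1", position, left_speed=left, right_speed=right)]
    s, g2 = simulate.simulate_replication(truth, cfg, seed=seed)
    return mfa.ratio_and_normalize(
        mfa.bin_depth(s["chr1"]), mfa.bin_depth(g2["chr1"]), "chr1"
    )


class TestBinning:
    def test_constant_depth(self):
        assert np.allclose(mfa.bin_depth(np.full(10_000, 10.0)), 10.0)

    def test_step(self):
        depth = np.concatenate([np.zeros(2_500), np.full(2_500, 10.0)])
        assert mfa.bin_depth(depth).tolist() == [0.0, 10.0]

    def test_linear_ramp_bin_means_are_midpoints(self):
        n = 10_000
        depth = np.arange(n, dtype=float)
        bins = mfa.bin_depth(depth, 2_500)
        expected = np.array([(i * 2_500 + (i + 1) * 2_500 - 1) / 2 for i in range(4)])
        assert np.allclose(bins, expected)

    def test_partial_final_bin_true_length(self):
        depth = np.concatenate([np.zeros(2_500), np.full(100, 6.0)])
        assert mfa.bin_depth(depth).tolist() == [0.0, 6.0]

    def test_empty(self):
        assert mfa.bin_depth(np.array([])).size == 0


class TestRatioNormalize:
    def test_equal_tracks_give_unity(self):
        x = np.full(200, 7.0)
        rt = mfa.ratio_and_normalize(x, x)
        assert np.allclose(rt.values, 1.0)

    def test_plateau_at_two(self):
        g2 = np.full(400, 10.0)
        s = g2.copy()
        s[100:150] *= 2
        rt = mfa.ratio_and_normalize(s, g2)
        assert np.allclose(rt.values[100:150], 2.0)
        assert np.allclose(rt.values[:100], 1.0)

    def test_scale_invariance(self, rng):
        s = rng.uniform(5, 20, 300)
        g2 = rng.uniform(5, 20, 300)
        a = mfa.ratio_and_normalize(s, g2)
        b = mfa.ratio_and_normalize(3.1 * s, 0.7 * g2)
        assert np.allclose(a.values, b.values)

    def test_zero_g2_bins_flagged_nan(self):
        s = np.full(10, 5.0)
        g2 = np.full(10, 5.0)
        g2[3] = 0.0
        rt = mfa.ratio_and_normalize(s, g2)
        assert np.isnan(rt.values[3]) and np.isfinite(rt.values).sum() == 9

    def test_all_zero_g2_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            mfa.ratio_and_normalize(np.ones(5), np.zeros(5))


class TestPeakCalling:
    def test_flat_track_no_peaks(self):
        rt = mfa.RatioTrack("chr1", 2_500, np.ones(400))
        assert mfa.call_obr_peaks(rt) == []

    def test_two_planted_origins_recovered_and_symmetric(self):
        cfg = simulate.SimulationConfig(chromosomes={"chr1": 1_200_000})
        truth = simulate.SyntheticTruth(config=cfg)
        truth.origins = [
            Origin("chr1", 400_000.0), Origin("chr1", 800_000.0)
        ]
        s, g2 = simulate.simulate_replication(truth, cfg, seed=11)
        rt = mfa.ratio_and_normalize(
            mfa.bin_depth(s["chr1"]), mfa.bin_depth(g2["chr1"]), "chr1"
        )
        peaks = mfa.call_obr_peaks(rt)
        assert len(peaks) == 2
        for p, o in zip(peaks, truth.origins):
            assert abs(p.apex_bin - int(o.position // 2_500)) <= 1
            assert p.symmetry == "symmetric"

    def test_obr_naming_convention(self):
        rt = single_origin_track(seed=3, position=550_000.0)
        rt.chromosome = "11"
        peaks = mfa.call_obr_peaks(rt)
        assert len(peaks) == 1
        assert peaks[0].name == "OBR:11:0.55"

    def test_low_quality_bins_excluded(self):
        vals = np.ones(400)
        vals[200:220] = 1.8  # wide artefact in a masked region
        quality = np.ones(400, dtype=bool)
        quality[200:220] = False
        rt = mfa.RatioTrack("chr1", 2_500, vals, quality_ok=quality)
        assert mfa.call_obr_peaks(rt) == []


class TestForkAsymmetry:
    def test_symmetric_peak_fold_one(self):
        p = mfa.OBRPeak("c", 0, 1.0, 2e-6, -2e-6, "symmetric", "OBR:c:0.00", 0, 0, 0)
        fold, shallow = mfa.fork_rate_asymmetry(p)
        assert fold == 1.0

    def test_twofold_speed_recovered(self):
        folds = []
        for seed in range(5):
            rt = single_origin_track(seed=seed, left=150_000.0, right=300_000.0)
            peaks = mfa.call_obr_peaks(rt)
            assert len(peaks) == 1
            fold, shallow = mfa.fork_rate_asymmetry(peaks[0])
            assert shallow == "right"  # the fast flank is the shallow one
            folds.append(fold)
        assert np.mean(folds) == pytest.approx(2.0, rel=0.15)

    def test_threefold_speed_recovered(self):
        folds = []
        for seed in range(5):
            rt = single_origin_track(seed=100 + seed, left=300_000.0, right=100_000.0)
            peaks = mfa.call_obr_peaks(rt)
            fold, shallow = mfa.fork_rate_asymmetry(peaks[0])
            assert shallow == "left"
            folds.append(fold)
        assert np.mean(folds) == pytest.approx(3.0, rel=0.15)

    def test_mirror_swaps_flanks(self):
        p = mfa.OBRPeak("c", 0, 1.0, 3e-6, -1e-6, "asymmetric", "n", 0, 0, 0)
        mirrored = mfa.OBRPeak(
            "c", 0, 1.0, -p.right_slope, -p.left_slope, "asymmetric", "n", 0, 0, 0
        )
        f1, s1 = mfa.fork_rate_asymmetry(p)
        f2, s2 = mfa.fork_rate_asymmetry(mirrored)
        assert f1 == f2 and {s1, s2} == {"left", "right"}

    def test_zero_slope_rejected(self):
        p = mfa.OBRPeak("c", 0, 1.0, 0.0, -1e-6, "asymmetric", "n", 0, 0, 0)
        with pytest.raises(ValueError, match="undefined"):
            mfa.fork_rate_asymmetry(p)


class TestReplicatedFraction:
    def test_flat_track_zero(self):
        rt = mfa.RatioTrack("chr1", 2_500, np.ones(100))
        assert mfa.replicated_fraction({"chr1": rt}).replicated_fraction == 0.0

    def test_noise_free_half_replicated(self):
        vals = np.concatenate([np.ones(50), np.full(50, 1.8)])
        rt = mfa.RatioTrack("chr1", 2_500, vals)
        assert mfa.replicated_fraction({"chr1": rt}).replicated_fraction == 0.5

    def test_replicated_composition_sums_to_one(self):
        from orcmap.annotation import RegionClassTrack

        vals = np.ones(100)
        vals[10:30] = 1.8  # replicated bins span the core/subtelomere line
        rt = mfa.RatioTrack("chr1", 2_500, vals)
        regions = {
            "chr1": RegionClassTrack(
                "chr1", [(0, 50_000, "subtelomere"), (50_000, 250_000, "core")]
            )
        }
        summary = mfa.replicated_fraction({"chr1": rt}, regions)
        assert sum(summary.replicated_composition.values()) == pytest.approx(1.0)
        assert set(summary.replicated_composition) == {"subtelomere", "core"}

    def test_monotone_in_threshold(self, rng):
        vals = 1.0 + np.abs(rng.normal(0, 0.3, 500))
        rt = mfa.RatioTrack("chr1", 2_500, vals)
        fracs = [
            mfa.replicated_fraction({"chr1": rt}, threshold=t).replicated_fraction
            for t in (0.0, 0.1, 0.3, 0.6)
        ]
        assert fracs == sorted(fracs, reverse=True)


class TestOriginDensity:
    def test_extrapolation_and_density_arithmetic(self):
        assert mfa.extrapolate_origin_count(42, 0.5) == 84.0
        assert mfa.origin_density(25.7e6, 100) == pytest.approx(257_000)

    def test_regression_recovers_planted_rate(self, rng):
        # origins planted at a fixed per-Mbp rate across chromosomes
        rate = 2.0e-6  # origins per bp
        lengths = {f"c{i}": int(l) for i, l in enumerate(
            rng.uniform(0.8e6, 3e6, 6)
        )}
        counts = {c: int(round(rate * L)) for c, L in lengths.items()}
        out = mfa.origin_density_and_extrapolation(counts, lengths, 1.0)
        assert out["slope_origins_per_bp"] == pytest.approx(rate, rel=0.10)
        assert out["pearson_r"] > 0.9

    def test_single_chromosome_no_regression(self):
        out = mfa.origin_density_and_extrapolation({"c": 3}, {"c": 1_000_000}, 0.5)
        assert "slope_origins_per_bp" not in out
        assert out["predicted_origins"] == 6.0


class TestColocalization:
    def test_features_at_apexes_all_match(self):
        peaks = [
            mfa.OBRPeak("chr1", (i + 0.5) * 2_500, 0.5, 1e-6, -1e-6,
                        "symmetric", f"n{i}", i, i, i)
            for i in (10, 50, 90)
        ]
        feats = pd.DataFrame(
            {"chromosome": "chr1",
             "start": [10 * 2_500, 50 * 2_500, 90 * 2_500],
             "end": [11 * 2_500, 51 * 2_500, 91 * 2_500]}
        )
        out = mfa.colocalize_peaks_with_features(peaks, feats)
        assert out["n_matched"] == 3

    def test_shifted_features_do_not_match(self):
        peaks = [mfa.OBRPeak("chr1", 50 * 2_500, 0.5, 1e-6, -1e-6,
                             "symmetric", "n", 50, 40, 60)]
        feats = pd.DataFrame(
            {"chromosome": ["chr1"], "start": [60 * 2_500], "end": [61 * 2_500]}
        )
        out = mfa.colocalize_peaks_with_features(peaks, feats, tolerance_bins=2)
        assert out["n_matched"] == 0

    def test_top_amplitude_peaks_match_centromere_list(self):
        peaks = [
            mfa.OBRPeak("chr1", 100_000, 0.9, 1e-6, -1e-6, "symmetric", "big", 40, 30, 50),
            mfa.OBRPeak("chr1", 500_000, 0.2, 1e-6, -1e-6, "symmetric", "small", 200, 190, 210),
        ]
        feats = pd.DataFrame({"chromosome": ["chr1"], "start": [99_000], "end": [101_000]})
        out = mfa.colocalize_peaks_with_features(
            peaks, feats, ranked_features=[("chr1", 99_000, 101_000)]
        )
        assert out["top_ranked_matched"] == [("big", True)]
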
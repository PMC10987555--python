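import numpy as np
import pandas as pd
import pytest

from eduseq import (
    BinnedGenome,
    FiberSet,
    MaskedVector,
    MetageneProfile,
    SigmaTrack,
    SimulationConfig,
    adjust_sigma,
    cldu_idu_ratio,
    compare_fiber_groups,
    estimate_progression,
    fiber_rates,
    metagene,
    profile_halfwidth,
    rate_from_fwhm,
    sigma_from_tracks,
    simulate_control,
    simulate_fibers,
    simulate_release,
    simulate_truth,
)
from eduseq.forks import _fwhm

from conftest import loci_frame


def sigma_track(values, mask=None):
    values = np.asarray(values, float)
    genome = BinnedGenome(("chr1",), (len(values) * 10_000,), bin_size=10_000)
    mask = np.zeros(len(values), bool) if mask is None else np.asarray(mask, bool)
    return SigmaTrack(genome, MaskedVector(values, mask), 100.0)


class TestMetagene:
    def test_delta_peak_maps_to_zero_offset(self):
        vals = np.zeros(100)
        vals[50] = 10.0
        prof = metagene(sigma_track(vals), loci_frame(("chr1", 50, 505_000)), 100_000)
        assert prof.mean_asigma[np.where(prof.offsets == 0)[0][0]] == 10.0
        assert np.nansum(prof.mean_asigma) == 10.0

    def test_identical_origins_average_to_single_profile(self):
        vals = np.zeros(200)
        vals[48:53] = 7.0
        vals[148:153] = 7.0
        loci_one = loci_frame(("chr1", 50, 505_000))
        loci_two = loci_frame(("chr1", 50, 505_000), ("chr1", 150, 1_505_000))
        s = sigma_track(vals)
        one = metagene(s, loci_one, 100_000)
        two = metagene(s, loci_two, 100_000)
        assert np.allclose(one.mean_asigma, two.mean_asigma, equal_nan=True)

    def test_window_clipped_at_chromosome_edge(self):
        vals = np.full(50, 3.0)
        prof = metagene(sigma_track(vals), loci_frame(("chr1", 1, 15_000)), 100_000)
        # offsets below -10 kb leave the chromosome: no origins contribute
        assert prof.n_origins[prof.offsets < -10_000].max() == 0
        assert prof.n_origins[prof.offsets >= -10_000].min() == 1

    def test_empty_locus_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            metagene(sigma_track(np.zeros(50)), loci_frame(), 100_000)

    def test_matches_brute_force_average(self, hu_experiment):
        s = hu_experiment["sigma_NE"]
        truth = hu_experiment["truth"]
        half = 100_000
        prof = metagene(s, truth[["chrom", "bin"]], half)
        # independent brute force: explicit loop over origins and offsets
        genome = s.genome
        k = half // genome.bin_size
        filled = s.sigma.filled(np.nan)
        for j, off in enumerate(range(-k, k + 1)):
            vals = []
            for row in truth.itertuples(index=False):
                local = row.bin + off
                if 0 <= local < genome.n_bins_of(row.chrom):
                    v = filled[genome.chrom_offsets[row.chrom] + local]
                    if np.isfinite(v):
                        vals.append(v)
            assert prof.n_origins[j] == len(vals)
            if vals:
                assert prof.mean_asigma[j] == pytest.approx(np.mean(vals))


class TestHalfwidth:
    def test_rectangular_profile(self):
        offsets = np.arange(-30, 31) * 10_000
        vals = np.where(np.abs(offsets) <= 50_000, 10.0, 0.0)
        prof = MetageneProfile(offsets, vals, np.ones_like(offsets))
        assert profile_halfwidth(prof) == pytest.approx(100_000, abs=10_000)

    def test_triangular_profile_geometry(self):
        offsets = np.arange(-30, 31) * 10_000
        vals = np.maximum(10.0 * (1 - np.abs(offsets) / 100_000), 0.0)
        prof = MetageneProfile(offsets, vals, np.ones_like(offsets))
        assert profile_halfwidth(prof) == pytest.approx(100_000, rel=0.01)

    def test_non_positive_profile_rejected(self):
        offsets = np.arange(-5, 6) * 10_000
        prof = MetageneProfile(offsets, np.zeros_like(offsets, dtype=float), np.ones_like(offsets))
        with pytest.raises(ValueError, match="positive"):
            profile_halfwidth(prof)

    def test_annular_band_measures_outer_width(self):
        # post-release label band: signal away from the origin, dip in the middle
        offsets = np.arange(-30, 31) * 10_000
        vals = np.where((np.abs(offsets) >= 100_000) & (np.abs(offsets) <= 150_000), 8.0, 0.0)
        assert _fwhm(offsets, vals) == pytest.approx(300_000, abs=10_000)


class TestProgression:
    def test_identical_profiles_give_zero_rate(self):
        assert rate_from_fwhm({30.0: 60_000.0, 90.0: 60_000.0}) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_arithmetic(self):
        # FWHM 60 kb at 30 min and 180 kb at 90 min: (120/2)/60 = 1 kb/min
        assert rate_from_fwhm({30.0: 60_000.0, 90.0: 180_000.0}) == pytest.approx(1.0)

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            rate_from_fwhm({30.0: 60_000.0})

    @pytest.mark.parametrize("speed", [1.0, 1.5])
    def test_planted_speed_recovered(self, speed):
        cfg = SimulationConfig(seed=5)
        ctrl = simulate_control(cfg)
        truth = simulate_truth(cfg)
        tracks, _, _ = simulate_release(
            cfg, [0.0, 30.0, 90.0], fork_speed_kb_min=speed, truth=truth
        )
        sig = {t: sigma_from_tracks(trk, ctrl) for t, trk in tracks.items()}
        asig = {t: adjust_sigma(sig[t], sig[0.0]) for t in (30.0, 90.0)}
        est = estimate_progression(asig, truth[["chrom", "bin"]], n_boot=100, seed=5)
        assert est["rate_kb_min"] == pytest.approx(speed, rel=0.20)
        assert est["ci_low"] <= est["rate_kb_min"] <= est["ci_high"]

    def test_zero_min_sample_adjusted_against_itself_is_flat(self):
        cfg = SimulationConfig(seed=6)
        ctrl = simulate_control(cfg)
        truth = simulate_truth(cfg)
        tracks, _, _ = simulate_release(cfg, [0.0], truth=truth)
        s0 = sigma_from_tracks(tracks[0.0], ctrl)
        prof = metagene(adjust_sigma(s0, s0), truth[["chrom", "bin"]])
        assert np.nanmax(np.abs(prof.mean_asigma)) == 0.0

    def test_fwhm_non_decreasing_in_release_time(self):
        cfg = SimulationConfig(seed=7)
        ctrl = simulate_control(cfg)
        truth = simulate_truth(cfg)
        tracks, _, _ = simulate_release(cfg, [0.0, 30.0, 60.0, 90.0], truth=truth)
        sig = {t: sigma_from_tracks(trk, ctrl) for t, trk in tracks.items()}
        widths = []
        for t in (30.0, 60.0, 90.0):
            prof = metagene(adjust_sigma(sig[t], sig[0.0]), truth[["chrom", "bin"]])
            widths.append(profile_halfwidth(prof))
        assert widths == sorted(widths)


class TestFiberSet:
    def test_rate_arithmetic(self):
        fs = FiberSet(
            pd.DataFrame(
                {"sample": ["WT"], "condition": ["NE"], "cldu_um": [10.0], "idu_um": [10.0]}
            ),
            idu_duration_min=40.0,
        )
        rates = fiber_rates(fs, kb_per_um=2.0)
        assert rates["rate_kb_min"].iloc[0] == pytest.approx(0.5)

    def test_zero_length_track_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            FiberSet(
                pd.DataFrame(
                    {"sample": ["WT"], "condition": ["NE"], "cldu_um": [0.0], "idu_um": [5.0]}
                )
            )

    def test_simulated_rate_mean_recovered(self):
        cfg = SimulationConfig(seed=11)
        fibers = simulate_fibers(cfg)  # rate ~ N(1.2, 0.3^2), n = 200
        rates = fiber_rates(fibers, kb_per_um=cfg.kb_per_um)
        assert rates["rate_kb_min"].mean() == pytest.approx(1.2, abs=0.05)

    def test_tsv_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=12, n_fibers=20)
        fibers = simulate_fibers(cfg)
        path = tmp_path / "fibers.tsv"
        fibers.to_tsv(path)
        back = FiberSet.from_tsv(path)
        assert len(back) == 20
        assert np.allclose(back.frame["idu_um"], fibers.frame["idu_um"], atol=1e-4)


class TestCompareFiberGroups:
    @staticmethod
    def _groups(rng, spec):
        rows = []
        for (sample, condition, mean, n) in spec:
            for r in rng.normal(mean, 0.3, n):
                rows.append((sample, condition, r))
        return pd.DataFrame(rows, columns=["sample", "condition", "rate_kb_min"])

    def test_identical_groups_give_p_one(self):
        base = np.array([1.0, 1.1, 1.2, 1.3, 1.4])
        rows = [("WT", c, r) for c in ("NE", "OE") for r in base]
        rows += [("KO", c, r) for c in ("NE", "OE") for r in base]
        df = pd.DataFrame(rows, columns=["sample", "condition", "rate_kb_min"])
        report = compare_fiber_groups(df)
        same = report["pairwise"].query("group1 == 'KO:NE' and group2 == 'WT:NE'")
        assert same["p"].iloc[0] == pytest.approx(1.0)

    def test_three_sd_shift_reaches_top_tier(self):
        rng = np.random.default_rng(21)
        df = self._groups(
            rng, [("WT", "NE", 1.2, 50), ("KO", "NE", 2.1, 50), ("WT", "OE", 1.2, 50), ("KO", "OE", 2.1, 50)]
        )
        report = compare_fiber_groups(df)
        row = report["pairwise"].query("group1 == 'KO:NE' and group2 == 'WT:NE'")
        assert row["p"].iloc[0] < 1e-4
        assert row["tier"].iloc[0] == "****"

    def test_small_groups_rejected(self):
        df = pd.DataFrame(
            {"sample": ["WT", "WT", "KO"], "condition": ["NE"] * 3, "rate_kb_min": [1.0, 1.1, 1.2]}
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_fiber_groups(df)

    def test_single_condition_falls_back_to_one_way(self):
        rng = np.random.default_rng(22)
        df = self._groups(rng, [("WT", "NE", 1.2, 10), ("KO", "NE", 1.2, 10)])
        with pytest.warns(UserWarning, match="one-way"):
            report = compare_fiber_groups(df)
        assert len(report["pairwise"]) == 1

    def test_null_false_positive_rate_is_nominal(self):
        # type-I calibration of the unprotected LSD at alpha = 0.05
        rng = np.random.default_rng(23)
        n_sig = n_tot = 0
        for _ in range(300):
            df = self._groups(
                rng,
                [(g, c, 1.2, 10) for g in ("WT", "KO") for c in ("NE", "OE")],
            )
            p = compare_fiber_groups(df)["pairwise"]["p"].to_numpy()
            n_sig += int((p < 0.05).sum())
            n_tot += len(p)
        assert 0.03 <= n_sig / n_tot <= 0.07


class TestClduIduRatio:
    def test_ratio_arithmetic(self):
        fs = FiberSet(
            pd.DataFrame(
                {
                    "sample": ["WT", "WT"],
                    "condition": ["NE", "NE"],
                    "cldu_um": [6.0, 8.0],
                    "idu_um": [6.0, 4.0],
                }
            )
        )
        records, summary = cldu_idu_ratio(fs)
        assert list(records["idu_cldu_ratio"]) == [1.0, 0.5]
        assert summary.iloc[0]["median"] == pytest.approx(0.75)

    def test_matched_duration_simulation_recovers_unit_ratio(self):
        cfg = SimulationConfig(seed=13)  # equal CldU/IdU durations
        _, summary = cldu_idu_ratio(simulate_fibers(cfg))
        assert summary.iloc[0]["median"] == pytest.approx(1.0, rel=0.05)

    def test_quartiles_permutation_invariant(self):
        cfg = SimulationConfig(seed=14, n_fibers=50)
        fibers = simulate_fibers(cfg)
        shuffled = FiberSet(
            fibers.frame.sample(frac=1.0, random_state=0).reset_index(drop=True),
            cldu_duration_min=fibers.cldu_duration_min,
            idu_duration_min=fibers.idu_duration_min,
        )
        _, a = cldu_idu_ratio(fibers)
        _, b = cldu_idu_ratio(shuffled)
        pd.testing.assert_frame_equal(a, b)
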
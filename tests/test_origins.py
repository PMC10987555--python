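import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from eduseq import (
    BinnedGenome,
    MaskedVector,
    OriginCatalog,
    SigmaTrack,
    build_catalog,
    call_peaks,
    classify_origins,
    correlate_catalogs,
    match_loci,
    quantify_efficiency,
    simulate_control,
    simulate_edu_hu,
    sigma_from_tracks,
)

from conftest import loci_frame


def sigma_track(values, mask=None, lam=100.0) -> SigmaTrack:
    values = np.asarray(values, float)
    genome = BinnedGenome(("chr1",), (len(values) * 10_000,), bin_size=10_000)
    mask = np.zeros(len(values), bool) if mask is None else np.asarray(mask, bool)
    return SigmaTrack(genome, MaskedVector(values, mask), lam)


class TestCallPeaks:
    def test_flat_background_yields_no_loci(self):
        s = sigma_track(np.full(100, 10.0))  # exactly at sqrt(lambda)
        assert len(call_peaks(s)) == 0

    def test_rectangular_peak_gives_one_summit_at_middle(self):
        vals = np.full(50, 10.0)
        vals[20:23] = 20.0
        vals[21] = 20.5  # unambiguous argmax in the middle bin
        peaks = call_peaks(sigma_track(vals))
        assert len(peaks) == 1
        assert peaks.iloc[0]["bin"] == 21
        assert peaks.iloc[0]["summit_bp"] == 215_000

    def test_single_above_threshold_bin_is_not_a_peak(self):
        vals = np.full(50, 10.0)
        vals[25] = 30.0
        assert len(call_peaks(sigma_track(vals), min_run=2)) == 0
        assert len(call_peaks(sigma_track(vals), min_run=1)) == 1

    def test_runs_split_by_one_subthreshold_bin_are_merged(self):
        vals = np.full(50, 10.0)
        vals[20:22] = 20.0
        vals[22] = 10.0  # 1-bin gap: merged
        vals[23:25] = 20.0
        assert len(call_peaks(sigma_track(vals))) == 1
        vals[22] = 10.0
        vals[21] = 10.0
        vals[20] = 10.0
        vals[26] = 10.0  # now a lone pair remains
        assert len(call_peaks(sigma_track(vals))) == 1

    def test_masked_bins_do_not_form_peaks(self):
        vals = np.full(50, 10.0)
        vals[10:14] = 25.0
        mask = np.zeros(50, bool)
        mask[10:14] = True
        assert len(call_peaks(sigma_track(vals, mask))) == 0

    def test_planted_origin_recovery_on_default_simulator(self, hu_experiment):
        truth = hu_experiment["truth"]
        for key in ("sigma_NE", "sigma_OE"):
            peaks = call_peaks(hu_experiment[key])
            recall, precision, _ = match_loci(peaks, truth, tol_bins=3)
            assert recall >= 0.95
            assert precision >= 0.95


class TestQuantifyEfficiency:
    def test_neighborhood_maximum(self):
        vals = np.full(50, 0.0)
        vals[9], vals[10], vals[11] = 9.0, 12.0, 7.0
        eff = quantify_efficiency(sigma_track(vals), loci_frame(("chr1", 10, 105_000)))
        assert eff[0] == 12.0
        # locus next to the peak still sees it through the +/-1 bin window
        eff = quantify_efficiency(sigma_track(vals), loci_frame(("chr1", 9, 95_000)))
        assert eff[0] == 12.0

    def test_masked_neighborhood_reports_missing(self):
        vals = np.full(50, 5.0)
        mask = np.zeros(50, bool)
        mask[9:12] = True
        eff = quantify_efficiency(sigma_track(vals, mask), loci_frame(("chr1", 10, 105_000)))
        assert np.isnan(eff[0])

    def test_out_of_genome_locus_rejected(self):
        from eduseq import CoordinateError

        with pytest.raises(CoordinateError):
            quantify_efficiency(sigma_track(np.zeros(50)), loci_frame(("chr2", 0, 5_000)))

    def test_rank_correlation_with_planted_strength(self, hu_experiment):
        truth = hu_experiment["truth"]
        eff = quantify_efficiency(hu_experiment["sigma_NE"], truth[["chrom", "bin"]])
        rho = sps.spearmanr(truth["eff_sigma_ne"], eff).statistic
        assert rho >= 0.9


class TestClassifyOrigins:
    @pytest.mark.parametrize(
        "ne, oe, expected",
        [
            (1.0, 9.0, "Oi"),  # rho = 5
            (4.0, 4.0, "CN"),  # rho = 1
            (3.0, 11.0, "intermediate"),  # rho = 3
            (0.0, 3.0, "Oi"),  # rho = 4, boundary inclusive
            (1.0, 3.0, "intermediate"),  # rho = 2, boundary inclusive
            (1.0, 2.9, "CN"),  # rho just below 2
        ],
    )
    def test_fold_change_rule(self, ne, oe, expected):
        assert classify_origins(np.array([ne]), np.array([oe]))[0] == expected

    def test_negative_efficiency_rejected(self):
        with pytest.raises(ValueError):
            classify_origins(np.array([-1.0]), np.array([1.0]))

    def test_missing_efficiency_labelled_na(self):
        labels = classify_origins(np.array([np.nan, 1.0]), np.array([1.0, 1.0]))
        assert list(labels) == ["NA", "CN"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e3, allow_nan=False), st.floats(0, 1e3, allow_nan=False)
            ),
            min_size=1,
            max_size=30,
        ),
        st.floats(0.1, 100.0),
    )
    def test_partition_and_scale_invariance(self, pairs, scale):
        ne = np.array([p[0] for p in pairs])
        oe = np.array([p[1] for p in pairs])
        labels = classify_origins(ne, oe)
        # every origin gets exactly one of the three labels
        assert set(labels) <= {"CN", "intermediate", "Oi"}
        # with pseudocount 0 the rule is exactly scale-invariant
        ne_pos, oe_pos = ne + 1.0, oe + 1.0
        a = classify_origins(ne_pos, oe_pos, pseudocount=0.0)
        b = classify_origins(ne_pos * scale, oe_pos * scale, pseudocount=0.0)
        assert list(a) == list(b)

    def test_planted_class_recovery_on_default_simulator(self, hu_experiment):
        truth = hu_experiment["truth"]
        catalog = build_catalog(
            hu_experiment["sigma_NE"],
            hu_experiment["sigma_OE"],
            loci=truth[["chrom", "bin", "summit_bp"]],
        )
        acc = np.mean(catalog.frame["class_label"].to_numpy() == truth["class_label"].to_numpy())
        assert acc >= 0.95
        counts = catalog.class_counts
        assert sum(counts.values()) == len(catalog)


class TestCorrelateCatalogs:
    def _catalog(self, hu_experiment):
        truth = hu_experiment["truth"]
        return build_catalog(
            hu_experiment["sigma_NE"],
            hu_experiment["sigma_OE"],
            loci=truth[["chrom", "bin", "summit_bp"]],
        )

    def test_identical_tracks_give_perfect_correlation(self, hu_experiment):
        cat = self._catalog(hu_experiment)
        s = hu_experiment["sigma_NE"]
        summary = correlate_catalogs(cat, s, s)
        for d in summary.classes.values():
            if d["n"] >= 2:
                assert d["pearson_r"] == pytest.approx(1.0)

    def test_correlation_is_scale_free(self, hu_experiment):
        cat = self._catalog(hu_experiment)
        s = hu_experiment["sigma_NE"]
        doubled = SigmaTrack(
            s.genome, MaskedVector(2.0 * s.sigma.values, s.sigma.mask), s.background_mean
        )
        summary = correlate_catalogs(cat, s, doubled)
        for d in summary.classes.values():
            if d["n"] >= 2:
                assert d["pearson_r"] == pytest.approx(1.0)

    def test_replicates_of_same_truth_agree(self, hu_experiment):
        # two independent sequencing replicates of identical origin firing
        cfg = hu_experiment["config"]
        cat = self._catalog(hu_experiment)
        rep, _ = simulate_edu_hu(cfg, "NE", genotype="KO", truth=hu_experiment["truth"])
        s_rep = sigma_from_tracks(rep, hu_experiment["control"])
        summary = correlate_catalogs(cat, hu_experiment["sigma_NE"], s_rep)
        all_a = np.concatenate([d["eff_A"] for d in summary.classes.values()])
        all_b = np.concatenate([d["eff_B"] for d in summary.classes.values()])
        assert sps.pearsonr(all_a, all_b).statistic >= 0.9
        for d in summary.classes.values():
            if d["n"] >= 2:
                assert d["pearson_r"] >= 0.9
                assert abs(d["mean_A"] - d["mean_B"]) <= 0.10 * d["mean_A"]

    def test_empty_class_reports_undefined_r(self, hu_experiment):
        truth = hu_experiment["truth"].copy()
        truth["class_label"] = "CN"
        frame = truth[["chrom", "bin", "summit_bp"]].assign(
            eff_NE=1.0, eff_OE=1.0, class_label="CN"
        )
        cat = OriginCatalog(hu_experiment["sigma_NE"].genome, frame)
        summary = correlate_catalogs(cat, hu_experiment["sigma_NE"], hu_experiment["sigma_NE"])
        assert summary.classes["Oi"]["n"] == 0
        assert np.isnan(summary.classes["Oi"]["pearson_r"])


class TestCatalogIO:
    def test_bed_round_trip_preserves_loci_and_classes(self, hu_experiment, tmp_path):
        truth = hu_experiment["truth"]
        cat = build_catalog(
            hu_experiment["sigma_NE"],
            hu_experiment["sigma_OE"],
            loci=truth[["chrom", "bin", "summit_bp"]],
        )
        path = tmp_path / "cat.bed"
        cat.to_bed(path)
        back = OriginCatalog.from_bed(path, cat.genome)
        assert len(back) == len(cat)
        assert list(back.frame["bin"]) == list(cat.frame["bin"])
        assert list(back.frame["class_label"]) == list(cat.frame["class_label"])

    def test_catalog_rows_sorted_by_position(self, toy_genome):
        frame = pd.DataFrame(
            {
                "chrom": ["chr2", "chr1", "chr1"],
                "bin": [0, 5, 2],
                "summit_bp": [5_000, 55_000, 25_000],
                "eff_NE": [1.0, 2.0, 3.0],
                "eff_OE": [1.0, 2.0, 3.0],
                "class_label": ["CN", "CN", "CN"],
            }
        )
        cat = OriginCatalog(toy_genome, frame)
        assert list(cat.frame["chrom"]) == ["chr1", "chr1", "chr2"]
        assert list(cat.frame["bin"]) == [2, 5, 0]
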
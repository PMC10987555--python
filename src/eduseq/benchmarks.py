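"""End-to-end recovery benchmarks: pipeline vs simulated ground truth.

Each function simulates data under the generator's default study conditions,
runs the corresponding pipeline stage, and measures how well known truth is
recovered — the statistic-calibration, origin-recovery, replicate-agreement,
fork-speed and group-test properties that validate the stack.  They are used
by the acceptance test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forks import compare_fiber_groups, estimate_progression, metagene
from .origins import build_catalog, call_peaks, correlate_catalogs, match_loci
from .sigma import adjust_sigma, sigma_from_tracks
from .simulate import (
    SimulationConfig,
    simulate_control,
    simulate_edu_hu,
    simulate_release,
    simulate_truth,
)

__all__ = [
    "sigma_calibration",
    "origin_recovery",
    "replicate_agreement",
    "fork_speed_recovery",
    "ko_regime_amplitude",
    "lsd_null_calibration",
    "lsd_power_p",
]


def sigma_calibration(seed: int, n_bins: int = 10_000, lam: float = 100.0) -> dict:
    """Sigma noise scale and false-positive control on a pure background.

    Simulates a background-only EdU track (Poisson, i.e. dispersion -> 0) with
    a very deep control so the normalized track is Poisson(lam), then checks
    that sigma fluctuations have unit scale and that almost no bins exceed the
    background level + 3.
    """
    cfg = SimulationConfig(
        seed=seed,
        chrom_lengths={"chr1": n_bins // 2 * 10_000, "chr2": n_bins // 2 * 10_000},
        n_origins=0,
        dispersion=0.0,
        mappability_sd=0.0,
        unmappable_frac=0.0,
        edu_depth=lam,
        control_depth=500.0 * lam,
        origin_edge_margin_bp=0,
    )
    track, _ = simulate_edu_hu(cfg, "NE", truth=_no_origins())
    s = sigma_from_tracks(track, simulate_control(cfg))
    vals = s.sigma.unmasked_values()
    return {
        "sd": float(vals.std()),
        "frac_above_3": float(np.mean(vals > s.background_sigma + 3.0)),
        "n_bins": int(len(vals)),
    }


def _no_origins() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "bin", "summit_bp", "class_label", "fold", "eff_sigma_ne"]
    )


def _hu_tracks(cfg: SimulationConfig):
    control = simulate_control(cfg)
    ne, truth = simulate_edu_hu(cfg, "NE", genotype="WT")
    oe, _ = simulate_edu_hu(cfg, "OE", genotype="WT", truth=truth)
    return control, truth, sigma_from_tracks(ne, control), sigma_from_tracks(oe, control)


def origin_recovery(seed: int) -> dict:
    """Peak-calling recall/precision and class recovery on the default simulator."""
    cfg = SimulationConfig(seed=seed)
    _, truth, s_ne, s_oe = _hu_tracks(cfg)
    tol = cfg.hu_travel_bp // cfg.bin_size  # summit can sit anywhere on the flat top
    recalls, precisions = [], []
    for s in (s_ne, s_oe):
        recall, precision, _ = match_loci(call_peaks(s), truth, tol_bins=tol)
        recalls.append(recall)
        precisions.append(precision)
    catalog = build_catalog(s_ne, s_oe, loci=truth[["chrom", "bin", "summit_bp"]])
    accuracy = float(
        np.mean(catalog.frame["class_label"].to_numpy() == truth["class_label"].to_numpy())
    )
    return {
        "recall": float(min(recalls)),
        "precision": float(min(precisions)),
        "class_accuracy": accuracy,
        "n_origins": int(len(truth)),
    }


def replicate_agreement(seed: int) -> dict:
    """Two samples simulated from identical origin truth (in-silico null result).

    The 'WT' and 'KO' tracks differ only by sequencing noise; per-class Pearson
    r of their efficiencies and the relative class-mean difference quantify how
    tightly the pipeline reproduces identical firing programs.
    """
    cfg = SimulationConfig(seed=seed)
    control, truth, s_ne, s_oe = _hu_tracks(cfg)
    ko, _ = simulate_edu_hu(cfg, "NE", genotype="KO", truth=truth)
    s_ko = sigma_from_tracks(ko, control)
    catalog = build_catalog(s_ne, s_oe, loci=truth[["chrom", "bin", "summit_bp"]])
    summary = correlate_catalogs(catalog, s_ne, s_ko)
    r_by_class, diff_by_class = {}, {}
    for label, d in summary.classes.items():
        if d["n"] >= 2:
            r_by_class[label] = d["pearson_r"]
            diff_by_class[label] = abs(d["mean_A"] - d["mean_B"]) / d["mean_A"]
    return {
        "r_min": float(min(r_by_class.values())),
        "mean_diff_max": float(max(diff_by_class.values())),
        "r_by_class": r_by_class,
        "n_origins": int(len(truth)),
    }


def fork_speed_recovery(
    seed: int, speeds=(1.0, 1.5), timepoints=(30.0, 90.0), n_boot: int = 100
) -> dict:
    """Recover planted fork speeds from metagene FWHM growth after HU release."""
    cfg = SimulationConfig(seed=seed)
    control = simulate_control(cfg)
    truth = simulate_truth(cfg)
    estimates = {}
    for v in speeds:
        tracks, _, _ = simulate_release(
            cfg, [0.0, *timepoints], genotype=f"v{v:g}", fork_speed_kb_min=v, truth=truth
        )
        sig = {t: sigma_from_tracks(trk, control) for t, trk in tracks.items()}
        asig = {t: adjust_sigma(sig[t], sig[0.0]) for t in timepoints}
        est = estimate_progression(asig, truth[["chrom", "bin"]], n_boot=n_boot, seed=seed)
        estimates[v] = est["rate_kb_min"]
    vs = sorted(estimates)
    return {
        "rates": estimates,
        "ratio": float(estimates[vs[-1]] / estimates[vs[0]]),
        "n_origins": int(len(truth)),
    }


def ko_regime_amplitude(
    seed: int, origin_fraction: float = 0.6, dntp_coupling: float = 1.5, timepoint: float = 30.0
) -> dict:
    """dNTP-limited regime: fewer fired origins -> stronger early recovery signal.

    The 'KO' genotype fires 40% fewer origins with speed (and label density)
    coupled to the active-fork count; its 30-min metagene amplitude over the
    full origin list should exceed the 'WT' amplitude.
    """
    cfg = SimulationConfig(seed=seed)
    control = simulate_control(cfg)
    truth = simulate_truth(cfg)
    amplitude = {}
    for genotype, frac in (("WT", 1.0), ("KO", origin_fraction)):
        tracks, _, _ = simulate_release(
            cfg,
            [0.0, timepoint],
            genotype=genotype,
            origin_fraction=frac,
            dntp_coupling=dntp_coupling,
            truth=truth,
        )
        sig = {t: sigma_from_tracks(trk, control) for t, trk in tracks.items()}
        profile = metagene(adjust_sigma(sig[timepoint], sig[0.0]), truth[["chrom", "bin"]])
        amplitude[genotype] = float(np.nanmax(profile.mean_asigma))
    return {
        "amp_wt": amplitude["WT"],
        "amp_ko": amplitude["KO"],
        "ratio": amplitude["KO"] / amplitude["WT"],
        "n_origins": int(len(truth)),
    }


def _null_groups(rng: np.random.Generator, n_per_group: int = 10) -> pd.DataFrame:
    rows = []
    for genotype in ("WT", "KO"):
        for condition in ("NE", "OE"):
            for r in rng.normal(1.2, 0.3, n_per_group):
                rows.append((genotype, condition, r))
    return pd.DataFrame(rows, columns=["sample", "condition", "rate_kb_min"])


def lsd_null_calibration(seed: int, n_reps: int = 1000) -> dict:
    """Type-I error of the pairwise LSD when all groups share one distribution."""
    rng = np.random.default_rng(seed)
    n_sig = n_tot = 0
    for _ in range(n_reps):
        p = compare_fiber_groups(_null_groups(rng))["pairwise"]["p"].to_numpy()
        n_sig += int((p < 0.05).sum())
        n_tot += len(p)
    return {"false_positive_rate": n_sig / n_tot, "n_reps": n_reps, "n_tests": n_tot}


def lsd_power_p(seed: int, shift_sd: float = 3.0, n: int = 50) -> float:
    """LSD p-value for two groups separated by ``shift_sd`` pooled sd at size n."""
    rng = np.random.default_rng(seed)
    sd = 0.3
    rows = []
    for condition in ("NE", "OE"):
        rows += [("WT", condition, r) for r in rng.normal(1.2, sd, n)]
        rows += [("KO", condition, r) for r in rng.normal(1.2 + shift_sd * sd, sd, n)]
    df = pd.DataFrame(rows, columns=["sample", "condition", "rate_kb_min"])
    report = compare_fiber_groups(df)
    row = report["pairwise"].query("group1 == 'KO:NE' and group2 == 'WT:NE'")
    return float(row["p"].iloc[0])
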
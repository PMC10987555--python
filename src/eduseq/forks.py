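"""Fork recovery and progression: metagene profiles and DNA-fiber statistics.

Two complementary readouts of replication-fork behaviour after an HU-induced
stall are implemented here.

1. Sequencing-based: adjusted-sigma tracks at several times after HU release
   are averaged over windows (0.6 Mb by default) centred on origins.  As forks
   resume, the labeled band moves outward, so the full width at half maximum
   (FWHM) of the metagene profile grows linearly with release time; half the
   FWHM growth rate is a per-fork progression speed.

2. Single-molecule: CldU/IdU track lengths from DNA combing are converted to
   per-fork rates (kb/min) and compared across genotypes and Cyclin E
   conditions with a two-way ANOVA followed by Fisher's LSD, as in the
   figure-legend statistics this package mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .sigma import SigmaTrack
from .stats import anova_two_way, lsd_pairwise

__all__ = [
    "MetageneProfile",
    "FiberSet",
    "origin_window_matrix",
    "metagene",
    "profile_halfwidth",
    "rate_from_fwhm",
    "estimate_progression",
    "fiber_rates",
    "compare_fiber_groups",
    "cldu_idu_ratio",
]


@dataclass
class MetageneProfile:
    """Mean (adjusted) sigma at fixed offsets around a set of origins."""

    offsets: np.ndarray  # bp relative to summit, symmetric about 0
    mean_asigma: np.ndarray  # NaN where no origin contributed
    n_origins: np.ndarray  # contributing origins per offset
    timepoint_min: float | None = None
    condition: str = "NA"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset_bp": self.offsets, "mean_asigma": self.mean_asigma, "n": self.n_origins}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def origin_window_matrix(
    track: SigmaTrack, loci: pd.DataFrame, half_window_bp: int = 300_000
) -> tuple[np.ndarray, np.ndarray]:
    """Per-origin signal in a window around each summit.

    Returns ``(matrix, offsets)`` where ``matrix[i, k]`` is the (adjusted)
    sigma of origin i at offset ``offsets[k]``; masked or out-of-chromosome
    bins are NaN.  Offsets run from ``-half_window_bp`` to ``+half_window_bp``
    in bin-size steps.
    """
    genome = track.genome
    k_half = half_window_bp // genome.bin_size
    offsets = np.arange(-k_half, k_half + 1) * genome.bin_size
    values = track.sigma.filled(np.nan)
    matrix = np.full((len(loci), 2 * k_half + 1), np.nan)
    for i, row in enumerate(loci.itertuples(index=False)):
        chrom, local = row.chrom, int(row.bin)
        offset = genome.chrom_offsets[chrom]
        nb = genome.n_bins_of(chrom)
        lo = max(local - k_half, 0)
        hi = min(local + k_half, nb - 1)
        matrix[i, (lo - local) + k_half : (hi - local) + k_half + 1] = values[
            offset + lo : offset + hi + 1
        ]
    return matrix, offsets


def metagene(
    asigma: SigmaTrack, loci: pd.DataFrame, half_window_bp: int = 300_000
) -> MetageneProfile:
    """Average (adjusted) sigma over origin-centred windows.

    Origins whose window leaves the chromosome contribute only their in-bounds
    offsets; masked bins are excluded, with the number of contributing origins
    tracked per offset.
    """
    if len(loci) == 0:
        raise ValueError("metagene needs at least one origin locus")
    matrix, offsets = origin_window_matrix(asigma, loci, half_window_bp)
    n = np.sum(np.isfinite(matrix), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(matrix, axis=0) / np.maximum(n, 1), np.nan)
    return MetageneProfile(
        offsets, mean, n, timepoint_min=asigma.timepoint_min, condition=asigma.condition
    )


def _fwhm(offsets: np.ndarray, values: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation between offsets."""
    values = np.where(np.isfinite(values), values, 0.0)
    peak = float(values.max())
    if peak <= 0:
        raise ValueError("profile maximum must be positive to define a half width")
    half = peak / 2.0
    above = values >= half
    i_first = int(np.argmax(above))
    i_last = int(len(values) - 1 - np.argmax(above[::-1]))
    if i_first == 0:
        left = float(offsets[0])
    else:
        x0, x1 = offsets[i_first - 1], offsets[i_first]
        y0, y1 = values[i_first - 1], values[i_first]
        left = float(x0 + (half - y0) / (y1 - y0) * (x1 - x0))
    if i_last == len(values) - 1:
        right = float(offsets[-1])
    else:
        x0, x1 = offsets[i_last], offsets[i_last + 1]
        y0, y1 = values[i_last], values[i_last + 1]
        right = float(x0 + (half - y0) / (y1 - y0) * (x1 - x0))
    return right - left


def profile_halfwidth(profile: MetageneProfile) -> float:
    """FWHM of a metagene profile in bp (summary of fork travel distance)."""
    return _fwhm(profile.offsets, profile.mean_asigma)


def rate_from_fwhm(fwhm_by_timepoint: Mapping[float, float]) -> float:
    """Per-fork rate (kb/min) from FWHM at two or more release timepoints.

    Forks move bidirectionally, so half the FWHM tracks one fork's position;
    the rate is the least-squares slope of ``FWHM/2`` against time (for two
    timepoints this reduces to ``delta(FWHM)/2 / delta(t)``).
    """
    if len(fwhm_by_timepoint) < 2:
        raise ValueError("need FWHM at two or more timepoints")
    t = np.array(sorted(fwhm_by_timepoint), dtype=float)
    half_bp = np.array([fwhm_by_timepoint[ti] / 2.0 for ti in t])
    slope = np.polyfit(t, half_bp, 1)[0]  # bp per minute
    return float(slope / 1000.0)


def estimate_progression(
    tracks: Mapping[float, SigmaTrack],
    loci: pd.DataFrame,
    half_window_bp: int = 300_000,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Fork progression rate from adjusted-sigma tracks at several timepoints.

    ``tracks`` maps release time (min) to the adjusted sigma track for that
    timepoint.  The point estimate is :func:`rate_from_fwhm` on the metagene
    FWHMs; the confidence interval is a percentile bootstrap resampling
    origins (the exchangeable unit).
    """
    if len(tracks) < 2:
        raise ValueError("progression estimation needs tracks at >= 2 timepoints")
    if len(loci) == 0:
        raise ValueError("progression estimation needs at least one origin")
    timepoints = sorted(tracks)
    matrices = {}
    offsets = None
    for t in timepoints:
        matrices[t], offsets = origin_window_matrix(tracks[t], loci, half_window_bp)

    def _fwhms(indices: np.ndarray) -> dict[float, float]:
        out = {}
        for t in timepoints:
            sub = matrices[t][indices]
            n = np.sum(np.isfinite(sub), axis=0)
            mean = np.where(n > 0, np.nansum(sub, axis=0) / np.maximum(n, 1), np.nan)
            out[t] = _fwhm(offsets, mean)
        return out

    all_idx = np.arange(len(loci))
    fwhm_point = _fwhms(all_idx)
    rate = rate_from_fwhm(fwhm_point)

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(loci), size=len(loci))
        try:
            boot.append(rate_from_fwhm(_fwhms(idx)))
        except ValueError:  # resample with a non-positive profile
            continue
    if boot:
        alpha = (1.0 - ci) / 2.0
        lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    else:
        lo = hi = float("nan")
    return {
        "rate_kb_min": rate,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "fwhm_bp": fwhm_point,
        "n_origins": int(len(loci)),
        "n_boot": int(len(boot)),
    }


@dataclass
class FiberSet:
    """Per-molecule CldU/IdU track lengths from DNA combing.

    ``frame`` columns: ``sample`` (genotype/clone label), ``condition``
    (NE/OE), ``cldu_um``, ``idu_um``.  Analog pulse durations are stored per
    set; all lengths and durations must be positive.
    """

    frame: pd.DataFrame
    cldu_duration_min: float = 40.0
    idu_duration_min: float = 40.0

    REQUIRED = ("sample", "condition", "cldu_um", "idu_um")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"fiber frame missing columns: {missing}")
        if self.cldu_duration_min <= 0 or self.idu_duration_min <= 0:
            raise ValueError("label durations must be positive")
        lengths = self.frame[["cldu_um", "idu_um"]].to_numpy(float)
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise ValueError("fiber track lengths must be positive and finite")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(
        cls, path: str | Path, cldu_duration_min: float = 40.0, idu_duration_min: float = 40.0
    ) -> "FiberSet":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame, cldu_duration_min=cldu_duration_min, idu_duration_min=idu_duration_min)


def fiber_rates(fibers: FiberSet, kb_per_um: float = 2.0, analog: str = "idu") -> pd.DataFrame:
    """Per-fiber fork progression rates from analog track lengths.

    ``rate = length_um * kb_per_um / pulse_duration_min``.  The conversion
    factor for combed DNA defaults to 2.0 kb/um and is exposed because it
    depends on the combing protocol.
    """
    if analog not in ("idu", "cldu"):
        raise ValueError("analog must be 'idu' or 'cldu'")
    duration = fibers.idu_duration_min if analog == "idu" else fibers.cldu_duration_min
    if duration <= 0:
        raise ValueError("pulse duration must be positive")
    out = fibers.frame.copy()
    out["rate_kb_min"] = out[f"{analog}_um"] * kb_per_um / duration
    return out


def compare_fiber_groups(
    rates: pd.DataFrame,
    response: str = "rate_kb_min",
    genotype_col: str = "sample",
    condition_col: str = "condition",
) -> dict:
    """Two-way ANOVA (genotype, condition, interaction) with Fisher's LSD.

    ``rates`` is long-form with one row per fiber.  Every group must have at
    least three observations.  Returns a dict with the ANOVA table, the
    pairwise LSD report (with significance tiers) and the pooled error terms.
    """
    counts = rates.groupby([genotype_col, condition_col], observed=True)[response].count()
    if len(counts) < 2:
        raise ValueError("need at least two groups to compare")
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"groups with fewer than 3 observations: {small}")
    table, mse, df_resid = anova_two_way(rates, response, genotype_col, condition_col)
    pairwise = lsd_pairwise(rates, response, [genotype_col, condition_col], mse, df_resid)
    return {"anova": table, "pairwise": pairwise, "mse": mse, "df_resid": df_resid}


def cldu_idu_ratio(fibers: FiberSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fiber IdU/CldU length ratio with per-group summaries.

    Returns ``(records, summary)``: records carry the per-fiber ratio;
    the summary gives median and quartiles (linear interpolation between
    order statistics) per sample x condition, plus the count of fibers
    excluded for a non-finite ratio.
    """
    records = fibers.frame.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        records["idu_cldu_ratio"] = records["idu_um"] / records["cldu_um"]
    finite = np.isfinite(records["idu_cldu_ratio"])
    rows = []
    for (sample, condition), grp in records.groupby(["sample", "condition"], observed=True):
        ok = grp.loc[np.isfinite(grp["idu_cldu_ratio"]), "idu_cldu_ratio"]
        rows.append(
            {
                "sample": sample,
                "condition": condition,
                "n": int(len(ok)),
                "n_excluded": int(len(grp) - len(ok)),
                "median": float(np.median(ok)) if len(ok) else float("nan"),
                "q25": float(np.quantile(ok, 0.25)) if len(ok) else float("nan"),
                "q75": float(np.quantile(ok, 0.75)) if len(ok) else float("nan"),
            }
        )
    return records.loc[finite].reset_index(drop=True), pd.DataFrame(rows)
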
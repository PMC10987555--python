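"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the experimental designs the pipeline quantifies:

* a genomic-DNA control with bin-to-bin mappability bias (lognormal, with a
  configurable fraction of unmappable zero bins);
* HU-arrest EdU-seq tracks: negative-binomial background plus rectangular
  enrichment blocks of half-width ``hu_travel_bp`` at planted origins, whose
  heights encode per-origin firing efficiency; Cyclin E overexpression (OE)
  multiplies the peak of oncogene-induced and intermediate origins by a
  planted fold change *on the sigma scale*;
* HU-release timecourses: a 30-min EdU label marks a band of offsets
  ``[hu + v*(t-30), hu + v*t]`` on both sides of each fired origin, where the
  effective speed ``v`` can be coupled to the number of active forks
  (dNTP-limited regime);
* MiDAS-seq tracks confined to a region set (edge-weighted for double-peak
  regions, centred for single-peak) plus per-cell focus counts;
* DNA-fiber track lengths drawn from a truncated-normal rate distribution.

The EdU and control tracks share the same per-bin mappability bias, so
control normalization removes it exactly in expectation.  All randomness is
derived from the single config seed through named substreams; the same seed
gives bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forks import FiberSet
from .genome import BinnedGenome, BinnedTrack
from .midas import FociTable, MidasRegionSet

__all__ = [
    "SimulationConfig",
    "simulate_truth",
    "simulate_control",
    "simulate_edu_hu",
    "simulate_release",
    "simulate_fibers",
    "simulate_midas_regions",
    "simulate_midas",
    "simulate_foci",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults are desk-scale but statistically faithful: a 2 x 25 Mb genome of
    10 kb bins with 50 origins, read depths and noise levels at which the
    planted structure is recoverable the way it is from real HU-arrest
    EdU-seq.  Origin firing efficiency is parameterized as the expected peak
    height above background in sigma units; the class mix (two thirds CN, one
    sixth intermediate, one sixth Oi) and the fold-change thresholds mirror
    the origin classification the pipeline applies.
    """

    seed: int = 0
    # genome
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 25_000_000, "chr2": 25_000_000}
    )
    bin_size: int = 10_000
    # origins
    n_origins: int = 50
    min_origin_spacing_bp: int = 150_000
    origin_edge_margin_bp: int = 400_000
    eff_sigma_min: float = 8.0
    eff_sigma_max: float = 80.0
    oi_fraction: float = 1.0 / 6.0
    intermediate_fraction: float = 1.0 / 6.0
    fold_cn: float = 1.0
    fold_intermediate: float = 3.0
    fold_oi: float = 6.0
    # fork model
    hu_travel_bp: int = 30_000
    fork_speed_kb_min: float = 1.5
    dntp_coupling: float = 0.0
    label_window_min: float = 30.0
    # sequencing noise
    edu_depth: float = 100.0
    control_depth: float = 2000.0
    dispersion: float = 0.001  # negative-binomial alpha; 0 = Poisson
    mappability_sd: float = 0.25  # lognormal sd of the shared per-bin bias
    unmappable_frac: float = 0.02
    # fibers
    fiber_rate_mean: float = 1.2
    fiber_rate_sd: float = 0.3
    n_fibers: int = 200
    cldu_duration_min: float = 40.0
    idu_duration_min: float = 40.0
    kb_per_um: float = 2.0
    fiber_noise_sd: float = 0.03  # lognormal sd of length measurement noise
    # MiDAS
    n_midas_regions: int = 20
    midas_region_min_bp: int = 100_000
    midas_region_max_bp: int = 600_000
    double_peak_fraction: float = 0.5
    midas_signal: float = 80.0
    midas_edge_frac: float = 0.2
    foci_mean: float = 1.5
    n_cells: int = 200

    def __post_init__(self) -> None:
        for name in ("oi_fraction", "intermediate_fraction", "double_peak_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.oi_fraction + self.intermediate_fraction > 1.0:
            raise ValueError("class fractions must sum to at most 1")
        for name in ("edu_depth", "control_depth", "fork_speed_kb_min", "fiber_rate_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dispersion < 0 or self.mappability_sd < 0:
            raise ValueError("dispersion and mappability_sd must be non-negative")

    def genome(self) -> BinnedGenome:
        return BinnedGenome(
            tuple(self.chrom_lengths),
            tuple(self.chrom_lengths.values()),
            bin_size=self.bin_size,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _rng(seed: int, *names) -> np.random.Generator:
    """Named, reproducible substream of the master seed."""
    tags = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


def _mappability(config: SimulationConfig) -> np.ndarray:
    """Shared per-bin bias: lognormal with unit mean, zero at unmappable bins."""
    genome = config.genome()
    rng = _rng(config.seed, "mappability")
    if config.mappability_sd > 0:
        bias = rng.lognormal(
            mean=-0.5 * config.mappability_sd**2, sigma=config.mappability_sd, size=genome.n_bins
        )
    else:
        bias = np.ones(genome.n_bins)
    if config.unmappable_frac > 0:
        dead = rng.random(genome.n_bins) < config.unmappable_frac
        bias[dead] = 0.0
    return bias


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Overdispersed counts: gamma-Poisson with Var = mu + alpha * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def _add_block(
    field_arr: np.ndarray,
    genome: BinnedGenome,
    chrom: str,
    lo_bp: float,
    hi_bp: float,
    amp: float,
) -> None:
    """Add a rectangle of height ``amp`` over [lo_bp, hi_bp), weighting edge
    bins by their overlap fraction."""
    chrom_len = genome.chrom_length(chrom)
    lo_bp, hi_bp = max(lo_bp, 0.0), min(hi_bp, float(chrom_len))
    if hi_bp <= lo_bp:
        return
    offset = genome.chrom_offsets[chrom]
    b_lo = int(lo_bp) // genome.bin_size
    b_hi = min(int(np.ceil(hi_bp / genome.bin_size)), genome.n_bins_of(chrom))
    for b in range(b_lo, b_hi):
        start, end = b * genome.bin_size, (b + 1) * genome.bin_size
        overlap = min(hi_bp, end) - max(lo_bp, start)
        if overlap > 0:
            field_arr[offset + b] += amp * overlap / genome.bin_size


def simulate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Plant origins: positions, class labels, efficiencies and fold changes.

    Origins are placed uniformly (rejection sampling) with a minimum
    inter-origin spacing and a margin from chromosome ends so release bands
    and metagene windows stay in bounds.  Deterministic in the config seed.
    """
    genome = config.genome()
    rng = _rng(config.seed, "origins")
    margin = config.origin_edge_margin_bp
    weights = np.array(
        [max(l - 2 * margin, 0) for l in genome.chrom_lengths], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("chromosomes too short for the configured edge margin")
    weights /= weights.sum()
    placed: dict[str, list[int]] = {c: [] for c in genome.chrom_names}
    n_placed, attempts = 0, 0
    while n_placed < config.n_origins:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place origins with the configured spacing")
        ci = rng.choice(len(genome.chrom_names), p=weights)
        chrom = genome.chrom_names[ci]
        bp = int(rng.integers(margin, genome.chrom_lengths[ci] - margin))
        if any(abs(bp - q) < config.min_origin_spacing_bp for q in placed[chrom]):
            continue
        placed[chrom].append(bp)
        n_placed += 1
    rows = []
    for chrom in genome.chrom_names:
        for bp in sorted(placed[chrom]):
            local = genome.bin_index(chrom, bp)
            rows.append((chrom, local, genome.bin_center(chrom, local)))
    truth = pd.DataFrame(rows, columns=["chrom", "bin", "summit_bp"])
    n = len(truth)
    n_oi = int(round(config.oi_fraction * n))
    n_int = int(round(config.intermediate_fraction * n))
    labels = np.array(
        ["Oi"] * n_oi + ["intermediate"] * n_int + ["CN"] * (n - n_oi - n_int), dtype=object
    )
    rng.shuffle(labels)
    folds = {"CN": config.fold_cn, "intermediate": config.fold_intermediate, "Oi": config.fold_oi}
    truth["class_label"] = labels
    truth["fold"] = [folds[c] for c in labels]
    truth["eff_sigma_ne"] = rng.uniform(config.eff_sigma_min, config.eff_sigma_max, size=n)
    return truth


def _peak_amplitude(excess_sigma: float, fold: float, depth: float) -> float:
    """Normalized-count amplitude whose peak sigma is ``fold`` times the NE peak.

    The NE peak sits at ``sqrt(depth) + excess`` sigma; the OE target is the
    fold multiple of that *total* sigma, so the planted fold is recovered as a
    ratio of measured peak sigma values.
    """
    sqrt_d = np.sqrt(depth)
    sigma_ne = sqrt_d + excess_sigma
    sigma_target = fold * sigma_ne
    return max((sigma_target - sqrt_d) * sqrt_d, 0.0)


def simulate_control(config: SimulationConfig) -> BinnedTrack:
    """Deep genomic-DNA control: depth times the shared mappability bias."""
    genome = config.genome()
    bias = _mappability(config)
    rng = _rng(config.seed, "control")
    counts = _nb_counts(rng, config.control_depth * bias, config.dispersion)
    return BinnedTrack(genome, counts, label="control", condition="NA")


def simulate_edu_hu(
    config: SimulationConfig,
    condition: str = "NE",
    genotype: str = "WT",
    truth: pd.DataFrame | None = None,
) -> tuple[BinnedTrack, pd.DataFrame]:
    """HU-arrest EdU-seq track: background plus origin blocks.

    Every genotype shares the same planted truth — different genotypes are
    independent sequencing replicates of identical origin firing, matching
    the null scenario the pipeline is designed to detect.  Under ``OE`` the
    peak of each origin is scaled by its planted fold change.
    """
    if truth is None:
        truth = simulate_truth(config)
    genome = config.genome()
    bias = _mappability(config)
    field_arr = np.zeros(genome.n_bins)
    for row in truth.itertuples(index=False):
        fold = row.fold if condition == "OE" else 1.0
        amp = _peak_amplitude(row.eff_sigma_ne, fold, config.edu_depth)
        _add_block(
            field_arr,
            genome,
            row.chrom,
            row.summit_bp - config.hu_travel_bp,
            row.summit_bp + config.hu_travel_bp,
            amp,
        )
    mean = bias * (config.edu_depth + field_arr)
    rng = _rng(config.seed, "edu", condition, genotype, "t0")
    counts = _nb_counts(rng, mean, config.dispersion)
    track = BinnedTrack(
        genome, counts, label=f"{genotype}_{condition}_HU", condition=condition, timepoint_min=0.0
    )
    return track, truth


def simulate_release(
    config: SimulationConfig,
    timepoints_min: list[float],
    genotype: str = "WT",
    condition: str = "NE",
    fork_speed_kb_min: float | None = None,
    origin_fraction: float = 1.0,
    dntp_coupling: float | None = None,
    truth: pd.DataFrame | None = None,
) -> tuple[dict[float, BinnedTrack], pd.DataFrame, float]:
    """HU-release timecourse with a 30-min terminal EdU label.

    At release time ``t`` the labeled DNA occupies offsets
    ``[hu + v*(t - label_window), hu + v*t]`` outward on both sides of each
    fired origin (clamped at the HU-arrest front), so the labeled band moves
    away from the origin as forks progress.  The 0-min sample is the
    HU-arrest track itself.

    ``origin_fraction`` subsamples the origins that fire in this genotype;
    with ``dntp_coupling > 0`` the effective speed is
    ``v * (n_fired / n_total) ** -coupling`` — fewer active forks leave more
    dNTPs per fork — and per-bin label density scales with the effective
    synthesis rate.  Returns ``(tracks by timepoint, truth with a 'fired'
    column, effective speed)``.
    """
    if truth is None:
        truth = simulate_truth(config)
    genome = config.genome()
    bias = _mappability(config)
    v_base = config.fork_speed_kb_min
    v = v_base if fork_speed_kb_min is None else fork_speed_kb_min
    coupling = config.dntp_coupling if dntp_coupling is None else dntp_coupling

    n_total = len(truth)
    n_fired = max(int(round(origin_fraction * n_total)), 1)
    rng_fired = _rng(config.seed, "fired", genotype)
    fired_idx = np.sort(rng_fired.choice(n_total, size=n_fired, replace=False))
    fired = np.zeros(n_total, dtype=bool)
    fired[fired_idx] = True
    truth = truth.assign(fired=fired)

    v_eff = v * (n_fired / n_total) ** (-coupling)
    amp_scale = v_eff / v_base  # label density tracks the dNTP-limited synthesis rate
    v_eff_bp = v_eff * 1000.0

    tracks: dict[float, BinnedTrack] = {}
    for t in timepoints_min:
        field_arr = np.zeros(genome.n_bins)
        for row in truth[truth["fired"]].itertuples(index=False):
            amp = _peak_amplitude(row.eff_sigma_ne, 1.0, config.edu_depth)
            if t <= 0:
                _add_block(
                    field_arr,
                    genome,
                    row.chrom,
                    row.summit_bp - config.hu_travel_bp,
                    row.summit_bp + config.hu_travel_bp,
                    amp,
                )
            else:
                lo = config.hu_travel_bp + v_eff_bp * max(t - config.label_window_min, 0.0)
                hi = config.hu_travel_bp + v_eff_bp * t
                for sign in (-1, +1):
                    a = row.summit_bp + sign * lo
                    b = row.summit_bp + sign * hi
                    _add_block(field_arr, genome, row.chrom, min(a, b), max(a, b), amp * amp_scale)
        mean = bias * (config.edu_depth + field_arr)
        stream = "t0" if t <= 0 else f"t{t:g}"
        rng = _rng(config.seed, "edu", condition, genotype, stream)
        counts = _nb_counts(rng, mean, config.dispersion)
        tracks[t] = BinnedTrack(
            genome,
            counts,
            label=f"{genotype}_{condition}_release{t:g}",
            condition=condition,
            timepoint_min=float(t),
        )
    return tracks, truth, float(v_eff)


def simulate_fibers(
    config: SimulationConfig,
    genotype: str = "WT",
    condition: str = "NE",
    rate_mean: float | None = None,
    rate_sd: float | None = None,
    n: int | None = None,
) -> FiberSet:
    """DNA-fiber track lengths from a truncated-normal per-fork rate.

    Each fiber's rate (kb/min) is drawn once and applied to both analog
    pulses, with independent multiplicative measurement noise per track.
    Negative rate draws are rejected, so all lengths are positive.
    """
    mean = config.fiber_rate_mean if rate_mean is None else rate_mean
    sd = config.fiber_rate_sd if rate_sd is None else rate_sd
    n = config.n_fibers if n is None else n
    rng = _rng(config.seed, "fibers", genotype, condition)
    rates = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        good = draw[draw > 0]
        rates[filled : filled + len(good)] = good
        filled += len(good)
    noise = lambda: (
        np.exp(rng.normal(0.0, config.fiber_noise_sd, size=n))
        if config.fiber_noise_sd > 0
        else 1.0
    )
    cldu = rates * config.cldu_duration_min / config.kb_per_um * noise()
    idu = rates * config.idu_duration_min / config.kb_per_um * noise()
    frame = pd.DataFrame(
        {
            "sample": genotype,
            "condition": condition,
            "cldu_um": cldu,
            "idu_um": idu,
        }
    )
    return FiberSet(
        frame,
        cldu_duration_min=config.cldu_duration_min,
        idu_duration_min=config.idu_duration_min,
    )


def simulate_midas_regions(config: SimulationConfig) -> MidasRegionSet:
    """Non-overlapping MiDAS regions of varying size with peak-type labels."""
    genome = config.genome()
    rng = _rng(config.seed, "midas_regions")
    margin = config.midas_region_max_bp  # keep profile flanks inside the chromosome
    rows: list[tuple[str, int, int]] = []
    attempts = 0
    while len(rows) < config.n_midas_regions:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place MiDAS regions without overlap")
        size = int(rng.integers(config.midas_region_min_bp, config.midas_region_max_bp + 1))
        ci = rng.integers(len(genome.chrom_names))
        chrom = genome.chrom_names[ci]
        hi = genome.chrom_lengths[ci] - size - margin
        if hi <= margin:
            continue
        start = int(rng.integers(margin, hi))
        end = start + size
        if any(c == chrom and start < e + 100_000 and s - 100_000 < end for c, s, e in rows):
            continue
        rows.append((chrom, start, end))
    n_double = int(round(config.double_peak_fraction * len(rows)))
    types = np.array(["double"] * n_double + ["single"] * (len(rows) - n_double), dtype=object)
    rng.shuffle(types)
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    frame["peak_type"] = types
    order = {name: i for i, name in enumerate(genome.chrom_names)}
    frame = frame.sort_values(
        ["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return MidasRegionSet(frame)


def simulate_midas(
    config: SimulationConfig,
    genotype: str = "WT",
    regions: MidasRegionSet | None = None,
    signal: float | None = None,
) -> tuple[BinnedTrack, FociTable, MidasRegionSet]:
    """MiDAS-seq track confined to the region set, plus per-cell EdU foci.

    Double-peak regions get signal blocks at both edges (mitotic synthesis
    initiating at the two converging forks of a long unreplicated stretch);
    single-peak regions get one centred block.  Focus counts per mitotic cell
    are Poisson with the configured mean.
    """
    if regions is None:
        regions = simulate_midas_regions(config)
    level = config.midas_signal if signal is None else signal
    genome = config.genome()
    bias = _mappability(config)
    field_arr = np.zeros(genome.n_bins)
    for row in regions.frame.itertuples(index=False):
        span = row.end - row.start
        edge = config.midas_edge_frac * span
        if row.peak_type == "double":
            _add_block(field_arr, genome, row.chrom, row.start, row.start + edge, level)
            _add_block(field_arr, genome, row.chrom, row.end - edge, row.end, level)
        else:
            mid = (row.start + row.end) / 2.0
            _add_block(field_arr, genome, row.chrom, mid - edge, mid + edge, level)
    mean = bias * (config.edu_depth + field_arr)
    rng = _rng(config.seed, "midas", genotype)
    counts = _nb_counts(rng, mean, config.dispersion)
    track = BinnedTrack(genome, counts, label=f"{genotype}_MiDAS", condition="NA")
    foci = simulate_foci(config, genotype=genotype, kind="edu")
    return track, foci, regions


def simulate_foci(
    config: SimulationConfig,
    genotype: str = "WT",
    mean: float | None = None,
    n_cells: int | None = None,
    kind: str = "edu",
) -> FociTable:
    """Per-cell focus counts (EdU foci in mitosis or 53BP1 bodies in G1)."""
    mu = config.foci_mean if mean is None else mean
    n = config.n_cells if n_cells is None else n_cells
    rng = _rng(config.seed, "foci", kind, genotype)
    counts = rng.poisson(mu, size=n)
    frame = pd.DataFrame(
        {
            "cell_id": [f"{genotype}_{kind}_{i}" for i in range(n)],
            "genotype": genotype,
            "n_foci": counts,
        }
    )
    return FociTable(frame)
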
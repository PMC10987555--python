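"""Sigma-value tracks: control-normalized nascent-strand signal in noise units.

The core statistic of HU-arrest EdU-seq is the per-bin "sigma" value: the
number of nascent-strand reads in a bin, normalized against a deep genomic-DNA
control from the same cell line (which removes library and mappability bias),
and divided by the standard deviation expected of the background.  The
background is modelled as Poisson with rate lambda estimated by a trimmed mean
of the normalized track, so

    sigma_b = normalized_b / sqrt(lambda)

Background bins then sit near ``sqrt(lambda)`` with unit-scale fluctuations,
and peak heights are read directly in count-noise units.  Sigma is not
mean-centered; this keeps the statistic a pure rescaling of the normalized
count, so downstream thresholds are expressed as an excess over the background
level ``sqrt(lambda)``.

Fork-recovery timecourses use *adjusted* sigma: the per-bin difference between
a post-release sample and the matched no-release (0 min) sample, which
isolates DNA synthesized after the stall is lifted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .genome import BinnedGenome, BinnedTrack, MaskedVector

__all__ = [
    "SigmaTrack",
    "normalize_to_control",
    "compute_sigma",
    "sigma_from_tracks",
    "adjust_sigma",
    "write_sigma_bedgraph",
]

#: control bins below this fraction of the median control count are masked
CONTROL_FLOOR_FRAC = 0.25

#: minimum number of unmasked bins for background estimation
MIN_UNMASKED_BINS = 50


@dataclass
class SigmaTrack:
    """Per-bin signal in standard-deviation units, with exclusion mask."""

    genome: BinnedGenome
    sigma: MaskedVector
    background_mean: float
    label: str = ""
    condition: str = "NA"
    timepoint_min: float | None = None

    def __post_init__(self) -> None:
        if self.sigma.values.shape != (self.genome.n_bins,):
            raise ValueError("sigma vector length does not match genome")
        if not np.all(np.isfinite(self.sigma.unmasked_values())):
            raise ValueError("sigma must be finite on unmasked bins")

    @property
    def background_sigma(self) -> float:
        """Sigma level of an average background bin, ``sqrt(lambda)``."""
        return float(np.sqrt(self.background_mean))


def normalize_to_control(
    sample: BinnedTrack,
    control: BinnedTrack,
    floor_frac: float = CONTROL_FLOOR_FRAC,
) -> MaskedVector:
    """Normalize a sample track against a genomic-DNA control.

    For each reliable bin the normalized value is

        sample_b / control_b * median(unmasked control)

    The quotient removes per-bin library/mappability bias shared between the
    two tracks; rescaling by the median control keeps values on the count
    scale.  Bins whose control count falls below ``floor_frac`` of the median
    control (including zero-coverage bins) are masked: there the quotient is
    dominated by control noise rather than signal.

    The output is invariant to uniform rescaling of the control and scales
    linearly with uniform rescaling of the sample.
    """
    if sample.genome != control.genome:
        raise ValueError("sample and control are on different genomes")
    ctrl = control.counts.astype(float)
    if ctrl.sum() <= 0:
        raise ValueError("control track has no reads")
    positive = ctrl > 0
    floor = floor_frac * float(np.median(ctrl[positive]))
    mask = ctrl < max(floor, np.finfo(float).tiny)
    scale = float(np.median(ctrl[~mask]))
    values = np.zeros_like(ctrl)
    np.divide(sample.counts, ctrl, out=values, where=~mask)
    values *= scale
    return MaskedVector(values, mask)


def compute_sigma(
    normalized: MaskedVector,
    genome: BinnedGenome,
    label: str = "",
    condition: str = "NA",
    timepoint_min: float | None = None,
    trim: float = 0.25,
) -> SigmaTrack:
    """Convert a normalized track to sigma values.

    The background rate ``lambda`` is the trimmed mean (central 50 % by
    default) of the unmasked normalized values; trimming keeps origin peaks
    from inflating the background estimate.  Each bin is then divided by
    ``sqrt(lambda)``, the Poisson standard deviation of the background.
    """
    if normalized.n_unmasked < MIN_UNMASKED_BINS:
        raise ValueError(
            f"background estimation needs at least {MIN_UNMASKED_BINS} unmasked bins, "
            f"got {normalized.n_unmasked}"
        )
    lam = float(sps.trim_mean(normalized.unmasked_values(), trim))
    if lam <= 0:
        raise ValueError("trimmed-mean background is not positive")
    sigma = MaskedVector(normalized.values / np.sqrt(lam), normalized.mask.copy())
    return SigmaTrack(
        genome,
        sigma,
        background_mean=lam,
        label=label,
        condition=condition,
        timepoint_min=timepoint_min,
    )


def sigma_from_tracks(
    sample: BinnedTrack,
    control: BinnedTrack,
    floor_frac: float = CONTROL_FLOOR_FRAC,
    trim: float = 0.25,
) -> SigmaTrack:
    """Convenience: normalize against the control, then compute sigma."""
    normalized = normalize_to_control(sample, control, floor_frac=floor_frac)
    return compute_sigma(
        normalized,
        sample.genome,
        label=sample.label,
        condition=sample.condition,
        timepoint_min=sample.timepoint_min,
    )


def adjust_sigma(sigma_t: SigmaTrack, sigma_0: SigmaTrack) -> SigmaTrack:
    """Adjusted sigma: per-bin difference to the no-release (0 min) sample.

    ``a_sigma_b = sigma_t_b - sigma_0_b`` on jointly unmasked bins; the output
    mask is the union of the input masks.  Subtraction preserves sigma units
    and makes the 0 min profile identically zero, isolating post-release
    synthesis.  The operation is antisymmetric in its arguments.
    """
    if sigma_t.genome != sigma_0.genome:
        raise ValueError("sigma tracks are on different genomes")
    if sigma_t.condition != sigma_0.condition:
        warnings.warn(
            f"adjusting across conditions: {sigma_t.condition!r} vs {sigma_0.condition!r}",
            stacklevel=2,
        )
    return SigmaTrack(
        sigma_t.genome,
        sigma_t.sigma - sigma_0.sigma,
        background_mean=sigma_t.background_mean,
        label=sigma_t.label,
        condition=sigma_t.condition,
        timepoint_min=sigma_t.timepoint_min,
    )


def write_sigma_bedgraph(track: SigmaTrack, path: str | Path) -> None:
    """Write sigma values as bedGraph (4-decimal fixed point; masked bins skipped)."""
    genome = track.genome
    with open(path, "w") as fh:
        for chrom, nb in zip(genome.chrom_names, genome.chrom_n_bins):
            offset = genome.chrom_offsets[chrom]
            for local in range(nb):
                g = offset + local
                if track.sigma.mask[g]:
                    continue
                fh.write(
                    f"{chrom}\t{genome.bin_start(chrom, local)}\t{genome.bin_end(chrom, local)}"
                    f"\t{track.sigma.values[g]:.4f}\n"
                )
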
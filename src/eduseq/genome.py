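"""Binned-genome coordinate system and per-bin count tracks.

Nascent-strand sequencing signal is quantified on a genome divided into
fixed-size bins (10 kb by default).  Coordinates are 0-based, half-open,
matching BED/bedGraph.  A global bin index is the concatenation of per
chromosome bins in the order the chromosomes were declared, which gives every
track a stable, genome-wide vector representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BinnedGenome",
    "BinnedTrack",
    "MaskedVector",
    "CoordinateError",
    "TrackFormatError",
    "bin_positions",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_track",
    "write_track",
    "write_bigwig",
]

CONDITIONS = ("NE", "OE", "NA")


class CoordinateError(ValueError):
    """A genomic position falls outside the declared chromosome bounds."""


class TrackFormatError(ValueError):
    """A track file does not conform to the bin-aligned bedGraph contract."""


@dataclass(frozen=True)
class BinnedGenome:
    """A genome partitioned into fixed-size bins.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers, in the order that defines global bin indexing.
    chrom_lengths
        Chromosome lengths in bp, parallel to ``chrom_names``.
    bin_size
        Bin width in bp.  Each chromosome has ``ceil(length / bin_size)``
        bins; the last bin may be truncated by the chromosome end.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 10_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(x) for x in self.chrom_lengths))
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @cached_property
    def chrom_n_bins(self) -> tuple[int, ...]:
        return tuple(math.ceil(l / self.bin_size) for l in self.chrom_lengths)

    @cached_property
    def chrom_offsets(self) -> dict[str, int]:
        """First global bin index of each chromosome."""
        offsets: dict[str, int] = {}
        total = 0
        for name, nb in zip(self.chrom_names, self.chrom_n_bins):
            offsets[name] = total
            total += nb
        return offsets

    @property
    def n_bins(self) -> int:
        return sum(self.chrom_n_bins)

    @cached_property
    def _chrom_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.chrom_names)}

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_lengths[self._chrom_index[chrom]]

    def n_bins_of(self, chrom: str) -> int:
        return self.chrom_n_bins[self._chrom_index[chrom]]

    def global_bin(self, chrom: str, local_bin: int) -> int:
        """Global index of ``local_bin`` on ``chrom``."""
        if chrom not in self.chrom_offsets:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if not 0 <= local_bin < self.n_bins_of(chrom):
            raise CoordinateError(f"bin {local_bin} out of range on {chrom}")
        return self.chrom_offsets[chrom] + local_bin

    def decompose(self, global_bin: int) -> tuple[str, int]:
        """Inverse of :meth:`global_bin`: (chromosome, local bin)."""
        if not 0 <= global_bin < self.n_bins:
            raise CoordinateError(f"global bin {global_bin} out of range")
        for name, nb in zip(self.chrom_names, self.chrom_n_bins):
            if global_bin < nb:
                return name, global_bin
            global_bin -= nb
        raise AssertionError("unreachable")

    def bin_index(self, chrom: str, bp: int) -> int:
        """Local bin containing position ``bp`` (0-based) on ``chrom``."""
        if chrom not in self.chrom_offsets:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if not 0 <= bp < self.chrom_length(chrom):
            raise CoordinateError(f"position {chrom}:{bp} outside chromosome bounds")
        return bp // self.bin_size

    def bin_start(self, chrom: str, local_bin: int) -> int:
        return local_bin * self.bin_size

    def bin_end(self, chrom: str, local_bin: int) -> int:
        return min((local_bin + 1) * self.bin_size, self.chrom_length(chrom))

    def bin_center(self, chrom: str, local_bin: int) -> int:
        return (self.bin_start(chrom, local_bin) + self.bin_end(chrom, local_bin)) // 2


@dataclass
class BinnedTrack:
    """Non-negative integer read counts per genomic bin for one sample."""

    genome: BinnedGenome
    counts: np.ndarray
    label: str = ""
    condition: str = "NA"
    timepoint_min: float | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (self.genome.n_bins,):
            raise ValueError(
                f"counts length {counts.shape} does not match genome bins ({self.genome.n_bins},)"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinnedTrack):
            return NotImplemented
        return (
            self.genome == other.genome
            and np.array_equal(self.counts, other.counts)
            and self.label == other.label
            and self.condition == other.condition
            and self.timepoint_min == other.timepoint_min
        )


@dataclass
class MaskedVector:
    """Per-bin real values with an exclusion mask (``True`` = excluded).

    The mask propagates through arithmetic (union of input masks), so a bin
    that is unreliable in any contributing track never enters a downstream
    aggregate.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have the same shape")

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def copy(self) -> "MaskedVector":
        return MaskedVector(self.values.copy(), self.mask.copy())

    def _binary(self, other: "MaskedVector", op) -> "MaskedVector":
        if not isinstance(other, MaskedVector):
            return NotImplemented
        if self.values.shape != other.values.shape:
            raise ValueError("shape mismatch")
        return MaskedVector(op(self.values, other.values), self.mask | other.mask)

    def __add__(self, other: "MaskedVector") -> "MaskedVector":
        return self._binary(other, np.add)

    def __sub__(self, other: "MaskedVector") -> "MaskedVector":
        return self._binary(other, np.subtract)

    def __mul__(self, scalar: float) -> "MaskedVector":
        return MaskedVector(self.values * float(scalar), self.mask.copy())

    __rmul__ = __mul__

    def __neg__(self) -> "MaskedVector":
        return MaskedVector(-self.values, self.mask.copy())

    def filled(self, fill_value: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.mask] = fill_value
        return out


def bin_positions(
    positions: Iterable[tuple[str, int]],
    genome: BinnedGenome,
    label: str = "",
    condition: str = "NA",
    timepoint_min: float | None = None,
) -> BinnedTrack:
    """Count genomic point events per bin.

    Each ``(chrom, bp)`` position increments the bin ``floor(bp / bin_size)``
    on its chromosome.  Total counts are conserved; out-of-bounds positions
    raise :class:`CoordinateError`.
    """
    counts = np.zeros(genome.n_bins, dtype=np.int64)
    for chrom, bp in positions:
        local = genome.bin_index(chrom, bp)
        counts[genome.chrom_offsets[chrom] + local] += 1
    return BinnedTrack(genome, counts, label=label, condition=condition, timepoint_min=timepoint_min)


def read_chrom_sizes(path: str | Path, bin_size: int = 10_000) -> BinnedGenome:
    """Build a :class:`BinnedGenome` from a UCSC-style chrom.sizes file.

    Chromosome order in the file defines the global bin indexing.
    """
    names: list[str] = []
    lengths: list[int] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise TrackFormatError(f"{path}: malformed chrom.sizes line: {line!r}")
        names.append(parts[0])
        lengths.append(int(parts[1]))
    return BinnedGenome(tuple(names), tuple(lengths), bin_size=bin_size)


def write_chrom_sizes(genome: BinnedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


def read_track(
    path: str | Path,
    genome: BinnedGenome,
    label: str = "",
    condition: str = "NA",
    timepoint_min: float | None = None,
) -> BinnedTrack:
    """Read a bin-aligned count track.

    Accepts 3-column ``chrom<TAB>start<TAB>count`` or 4-column bedGraph
    (``chrom start end count``).  Starts must be multiples of the genome's
    bin size; bins absent from the file are zero.
    """
    counts = np.zeros(genome.n_bins, dtype=np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 3:
                chrom, start_s, value_s = parts
            elif len(parts) >= 4:
                chrom, start_s, _end, value_s = parts[:4]
            else:
                raise TrackFormatError(f"{path}:{lineno}: expected 3 or 4 columns")
            if chrom not in genome.chrom_offsets:
                raise TrackFormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            start = int(start_s)
            if start % genome.bin_size != 0:
                raise TrackFormatError(
                    f"{path}:{lineno}: start {start} is not aligned to {genome.bin_size} bp bins"
                )
            local = genome.bin_index(chrom, start)
            value = float(value_s)
            if value < 0 or value != int(value):
                raise TrackFormatError(f"{path}:{lineno}: counts must be non-negative integers")
            counts[genome.chrom_offsets[chrom] + local] = int(value)
    return BinnedTrack(genome, counts, label=label, condition=condition, timepoint_min=timepoint_min)


def write_track(track: BinnedTrack, path: str | Path, skip_zero: bool = False) -> None:
    """Write a count track as 4-column bin-aligned bedGraph."""
    genome = track.genome
    with open(path, "w") as fh:
        for chrom, nb in zip(genome.chrom_names, genome.chrom_n_bins):
            offset = genome.chrom_offsets[chrom]
            for local in range(nb):
                c = track.counts[offset + local]
                if skip_zero and c == 0:
                    continue
                fh.write(
                    f"{chrom}\t{genome.bin_start(chrom, local)}\t{genome.bin_end(chrom, local)}\t{c}\n"
                )


def write_bigwig(genome: BinnedGenome, values: np.ndarray, path: str | Path) -> None:
    """Export per-bin values to BigWig for genome-browser viewing.

    Requires the optional ``pyBigWig`` dependency.  NaN bins are skipped.
    """
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("BigWig export requires the pyBigWig package") from exc
    values = np.asarray(values, dtype=float)
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader(list(zip(genome.chrom_names, genome.chrom_lengths)))
    for chrom, nb in zip(genome.chrom_names, genome.chrom_n_bins):
        offset = genome.chrom_offsets[chrom]
        starts, ends, vals = [], [], []
        for local in range(nb):
            v = values[offset + local]
            if np.isnan(v):
                continue
            starts.append(genome.bin_start(chrom, local))
            ends.append(genome.bin_end(chrom, local))
            vals.append(float(v))
        if starts:
            bw.addEntries([chrom] * len(starts), starts, ends=ends, values=vals)
    bw.close()
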
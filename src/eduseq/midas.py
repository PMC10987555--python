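"""Mitotic DNA synthesis (MiDAS) quantification.

MiDAS completes replication of genomic regions (often common fragile sites)
that remain under-replicated when cells enter mitosis.  This module scores
microscopy readouts — EdU-focus positivity per mitotic cell and 53BP1 nuclear
body fractions in the following G1 — and profiles MiDAS-seq sigma signal over
an externally supplied region set.  Regions are classified upstream as
single-peak or double-peak: when a long stretch is left unreplicated, mitotic
synthesis initiates at both flanking forks, producing signal at the two edges
of the region rather than its centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .sigma import SigmaTrack
from .stats import anova_two_way, tukey_pairwise

__all__ = [
    "MidasRegionSet",
    "FociTable",
    "RegionProfiles",
    "score_midas_positive",
    "fraction_53bp1",
    "region_profiles",
    "compare_fractions",
]

PEAK_TYPES = ("single", "double")


@dataclass
class MidasRegionSet:
    """Genomic regions of mitotic DNA synthesis with a peak-shape class.

    ``frame`` columns: ``chrom``, ``start``, ``end`` (bp, half-open),
    ``peak_type`` in {"single", "double"}.
    """

    frame: pd.DataFrame

    REQUIRED = ("chrom", "start", "end", "peak_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"region frame missing columns: {missing}")
        if (self.frame["start"] >= self.frame["end"]).any():
            raise ValueError("regions must have start < end")
        bad = set(self.frame["peak_type"]) - set(PEAK_TYPES)
        if bad:
            raise ValueError(f"unknown peak types: {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sizes(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    def to_bed(self, path: str | Path) -> None:
        """Write as BED4 with the peak type in the name field."""
        with open(path, "w") as fh:
            for row in self.frame.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.peak_type}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "MidasRegionSet":
        rows = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 with peak type required")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_type"]))


@dataclass
class FociTable:
    """Per-cell focus counts (EdU foci in mitosis, or 53BP1 bodies in G1)."""

    frame: pd.DataFrame

    REQUIRED = ("cell_id", "genotype", "n_foci")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"foci frame missing columns: {missing}")
        n = self.frame["n_foci"].to_numpy()
        if np.any(n < 0) or not np.all(n == n.astype(int)):
            raise ValueError("focus counts must be non-negative integers")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FociTable":
        return cls(pd.read_csv(path, sep="\t"))


def _fraction_above(foci: FociTable, threshold: int) -> pd.DataFrame:
    if len(foci) == 0:
        raise ValueError("foci table is empty")
    rows = []
    for genotype, grp in foci.frame.groupby("genotype", observed=True):
        n_cells = len(grp)
        n_pos = int((grp["n_foci"] >= threshold).sum())
        frac = Fraction(n_pos, n_cells)  # exact before the final float
        rows.append(
            {
                "genotype": genotype,
                "n_cells": n_cells,
                "n_positive": n_pos,
                "fraction": float(frac),
            }
        )
    return pd.DataFrame(rows)


def score_midas_positive(foci: FociTable, min_foci: int = 2) -> pd.DataFrame:
    """Fraction of mitotic cells positive for MiDAS, per genotype.

    A cell is positive when it shows at least ``min_foci`` EdU foci on mitotic
    chromatin (default 2).  The fraction is computed with exact rational
    arithmetic before conversion to float, and is monotone non-increasing in
    ``min_foci``.
    """
    return _fraction_above(foci, min_foci)


def fraction_53bp1(bodies: FociTable, min_bodies: int = 1) -> pd.DataFrame:
    """Fraction of G1 cells containing >= ``min_bodies`` 53BP1 nuclear bodies."""
    return _fraction_above(bodies, min_bodies)


@dataclass
class RegionProfiles:
    """Rescaled MiDAS-seq signal over a region set.

    ``matrix`` rows are regions on a common 0..1 relative axis spanning the
    region plus flanks; rows are ordered for heatmap display (double-peak
    regions by genomic size, single-peak by signal, both descending).
    """

    rel_axis: np.ndarray  # relative coordinate, 0 = window start, 1 = window end
    average: np.ndarray
    matrix: np.ndarray
    order: np.ndarray  # original region indices, in display order
    peak_types: np.ndarray  # peak type per display row

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        avg = pd.DataFrame({"rel_pos": self.rel_axis, "mean_sigma": self.average})
        mat = pd.DataFrame(self.matrix, columns=[f"{x:.3f}" for x in self.rel_axis])
        mat.insert(0, "region_index", self.order)
        mat.insert(1, "peak_type", self.peak_types)
        return avg, mat


def region_profiles(
    sigma: SigmaTrack,
    regions: MidasRegionSet,
    flank_frac: float = 0.5,
    n_points: int = 100,
    single_rank: str = "max",
) -> RegionProfiles:
    """Average profile and per-region heatmap matrix of MiDAS-seq signal.

    Each region's signal is extracted over its span plus flanks of
    ``flank_frac`` times the span on each side, then linearly interpolated
    onto a common ``n_points`` relative-coordinate axis so that regions of
    different sizes can be averaged and stacked.  Rows of the heatmap matrix
    are ordered double-peak regions first, by genomic size descending (ties by
    position), then single-peak regions by their sigma value descending
    (region maximum by default; ``single_rank="mean"`` switches to the mean).
    Regions exceeding a chromosome end are clipped with a warning.
    """
    if single_rank not in ("max", "mean"):
        raise ValueError("single_rank must be 'max' or 'mean'")
    genome = sigma.genome
    values = sigma.sigma.filled(np.nan)
    rel_axis = np.linspace(0.0, 1.0, n_points)
    matrix = np.full((len(regions), n_points), np.nan)
    span_stat = np.full(len(regions), np.nan)
    for i, row in enumerate(regions.frame.itertuples(index=False)):
        if row.chrom not in genome.chrom_offsets:
            raise ValueError(f"region chromosome {row.chrom!r} not in genome")
        span = row.end - row.start
        flank = flank_frac * span
        win_lo, win_hi = row.start - flank, row.end + flank
        chrom_len = genome.chrom_length(row.chrom)
        if win_lo < 0 or win_hi > chrom_len:
            warnings.warn(
                f"region window {row.chrom}:{win_lo:.0f}-{win_hi:.0f} clipped to chromosome",
                stacklevel=2,
            )
            win_lo, win_hi = max(win_lo, 0.0), min(win_hi, float(chrom_len))
        offset = genome.chrom_offsets[row.chrom]
        b_lo = int(win_lo) // genome.bin_size
        b_hi = min(int(np.ceil(win_hi / genome.bin_size)), genome.n_bins_of(row.chrom))
        centers = np.array(
            [genome.bin_center(row.chrom, b) for b in range(b_lo, b_hi)], dtype=float
        )
        vals = values[offset + b_lo : offset + b_hi]
        ok = np.isfinite(vals)
        if ok.sum() >= 2:
            rel = (centers[ok] - win_lo) / (win_hi - win_lo)
            matrix[i] = np.interp(rel_axis, rel, vals[ok])
        # ranking statistic over the region span itself (not the flanks)
        span_bins = slice(
            offset + row.start // genome.bin_size,
            offset + min(int(np.ceil(row.end / genome.bin_size)), genome.n_bins_of(row.chrom)),
        )
        span_vals = values[span_bins]
        span_vals = span_vals[np.isfinite(span_vals)]
        if len(span_vals):
            span_stat[i] = span_vals.max() if single_rank == "max" else span_vals.mean()

    frame = regions.frame
    sizes = regions.sizes
    chrom_rank = frame["chrom"].map(
        {name: i for i, name in enumerate(genome.chrom_names)}
    ).to_numpy()
    is_double = (frame["peak_type"] == "double").to_numpy()
    double_idx = np.flatnonzero(is_double)
    single_idx = np.flatnonzero(~is_double)
    double_order = double_idx[
        np.lexsort((frame["start"].to_numpy()[double_idx], chrom_rank[double_idx], -sizes[double_idx]))
    ]
    stat = np.where(np.isfinite(span_stat), span_stat, -np.inf)
    single_order = single_idx[
        np.lexsort((frame["start"].to_numpy()[single_idx], chrom_rank[single_idx], -stat[single_idx]))
    ]
    order = np.concatenate([double_order, single_order]).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        average = np.nanmean(matrix, axis=0)
    return RegionProfiles(
        rel_axis=rel_axis,
        average=average,
        matrix=matrix[order],
        order=order,
        peak_types=frame["peak_type"].to_numpy()[order],
    )


def compare_fractions(
    fractions: pd.DataFrame,
    response: str = "fraction",
    genotype_col: str = "genotype",
    treatment_col: str = "treatment",
) -> dict:
    """Two-way ANOVA on per-experiment replicate fractions with Tukey HSD.

    ``fractions`` is long-form with one row per independent experiment
    (replicate): the response is the per-replicate positive fraction.  Every
    genotype x treatment cell needs at least two replicates so a pooled error
    term exists.  Pairwise Tukey comparisons use the ANOVA error mean square
    and carry the legend-style significance tiers ("ns" when not significant).
    """
    counts = fractions.groupby([genotype_col, treatment_col], observed=True)[response].count()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"cells with fewer than 2 replicates: {small}")
    table, mse, df_resid = anova_two_way(fractions, response, genotype_col, treatment_col)
    pairwise = tukey_pairwise(fractions, response, [genotype_col, treatment_col], mse, df_resid)
    return {"anova": table, "pairwise": pairwise, "mse": mse, "df_resid": df_resid}
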
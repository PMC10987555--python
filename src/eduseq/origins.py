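"""Origin peak calling, firing-efficiency quantification and classification.

In HU-arrested early-S cells, forks travel only a short distance from fired
origins, so the sigma track shows narrow peaks whose height is a proxy for
per-origin firing efficiency.  This module calls those peaks, quantifies the
efficiency of each origin under normal (NE) and Cyclin E-overexpressing (OE)
conditions, classifies origins by their OE/NE fold change — constitutive (CN,
< 2-fold), intermediate (2–4-fold) and oncogene-induced (Oi, >= 4-fold) — and
summarizes cross-sample agreement with per-class correlation of efficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import BinnedGenome, CoordinateError
from .sigma import SigmaTrack

__all__ = [
    "OriginCatalog",
    "CorrelationSummary",
    "call_peaks",
    "quantify_efficiency",
    "classify_origins",
    "build_catalog",
    "correlate_catalogs",
    "match_loci",
]

CLASS_LABELS = ("CN", "intermediate", "Oi")

#: fold-change boundaries of the origin classes (OE relative to NE)
FOLD_OI = 4.0
FOLD_INTERMEDIATE = 2.0


@dataclass
class OriginCatalog:
    """Origin loci with per-condition firing efficiencies and class labels.

    Backed by a DataFrame with columns ``chrom``, ``bin`` (local bin index),
    ``summit_bp``, ``eff_NE``, ``eff_OE``, ``class_label``; rows are kept
    sorted by genome position.  Missing efficiencies (origin in a masked
    region) are NaN and the class label is ``"NA"``.
    """

    genome: BinnedGenome
    frame: pd.DataFrame

    REQUIRED = ("chrom", "bin", "summit_bp", "eff_NE", "eff_OE", "class_label")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"catalog frame missing columns: {missing}")
        order = {name: i for i, name in enumerate(self.genome.chrom_names)}
        unknown = set(self.frame["chrom"]) - set(order)
        if unknown:
            raise CoordinateError(f"catalog chromosomes not in genome: {sorted(unknown)}")
        key = self.frame["chrom"].map(order)
        self.frame = (
            self.frame.assign(_key=key)
            .sort_values(["_key", "bin"], kind="mergesort")
            .drop(columns="_key")
            .reset_index(drop=True)
        )
        eff = self.frame[["eff_NE", "eff_OE"]].to_numpy(float)
        if np.nanmin(eff, initial=0.0) < 0:
            raise ValueError("efficiencies must be non-negative")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.frame["class_label"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CLASS_LABELS}

    def to_bed(self, path: str | Path) -> None:
        """Write as BED6: class in the name field, NE efficiency in the score."""
        with open(path, "w") as fh:
            for row in self.frame.itertuples(index=False):
                start = self.genome.bin_start(row.chrom, int(row.bin))
                end = self.genome.bin_end(row.chrom, int(row.bin))
                score = 0.0 if np.isnan(row.eff_NE) else row.eff_NE
                fh.write(
                    f"{row.chrom}\t{start}\t{end}\t{row.class_label}\t{score:.4f}\t.\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path, genome: BinnedGenome) -> "OriginCatalog":
        """Read an origin list from BED (3+ columns; name = class if present)."""
        rows = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs at least 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            summit = (start + end) // 2
            local = genome.bin_index(chrom, summit)
            label = parts[3] if len(parts) > 3 and parts[3] in CLASS_LABELS else "NA"
            score = float(parts[4]) if len(parts) > 4 else np.nan
            rows.append((chrom, local, genome.bin_center(chrom, local), score, np.nan, label))
        frame = pd.DataFrame(
            rows, columns=["chrom", "bin", "summit_bp", "eff_NE", "eff_OE", "class_label"]
        )
        return cls(genome, frame)


def call_peaks(
    sigma: SigmaTrack,
    min_sigma_excess: float = 3.0,
    min_run: int = 2,
    merge_gap: int = 1,
) -> pd.DataFrame:
    """Call origin peaks on an HU-arrest sigma track.

    A bin is above threshold when it is unmasked and its sigma exceeds the
    background level ``sqrt(lambda)`` by at least ``min_sigma_excess``.
    Maximal runs of above-threshold bins separated by at most ``merge_gap``
    sub-threshold bins are merged; merged runs containing at least ``min_run``
    above-threshold bins yield one locus each, at the argmax bin, with the
    summit at that bin's center.

    Returns a DataFrame with columns ``chrom``, ``bin``, ``summit_bp``,
    ``peak_sigma``.
    """
    genome = sigma.genome
    threshold = sigma.background_sigma + min_sigma_excess
    above = (~sigma.sigma.mask) & (sigma.sigma.values >= threshold)
    rows = []
    for chrom, nb in zip(genome.chrom_names, genome.chrom_n_bins):
        offset = genome.chrom_offsets[chrom]
        flags = above[offset : offset + nb]
        if not flags.any():
            continue
        idx = np.flatnonzero(flags)
        # split into merged runs: break where the gap exceeds merge_gap
        breaks = np.flatnonzero(np.diff(idx) > merge_gap + 1)
        for run in np.split(idx, breaks + 1):
            if len(run) < min_run:
                continue
            vals = sigma.sigma.values[offset + run]
            summit_local = int(run[np.argmax(vals)])
            rows.append(
                (chrom, summit_local, genome.bin_center(chrom, summit_local), float(vals.max()))
            )
    return pd.DataFrame(rows, columns=["chrom", "bin", "summit_bp", "peak_sigma"])


def quantify_efficiency(sigma: SigmaTrack, loci: pd.DataFrame) -> np.ndarray:
    """Per-origin firing efficiency: max sigma within +/-1 bin of the summit.

    Masked bins are excluded from the neighborhood maximum; an origin whose
    whole neighborhood is masked gets NaN (missing) and is excluded, with
    bookkeeping, from downstream correlations.  Values are floored at 0.
    """
    genome = sigma.genome
    eff = np.full(len(loci), np.nan)
    for i, row in enumerate(loci.itertuples(index=False)):
        chrom, local = row.chrom, int(row.bin)
        if chrom not in genome.chrom_offsets or not 0 <= local < genome.n_bins_of(chrom):
            raise CoordinateError(f"locus {chrom}:bin {local} outside genome")
        offset = genome.chrom_offsets[chrom]
        lo = max(local - 1, 0)
        hi = min(local + 1, genome.n_bins_of(chrom) - 1)
        window = slice(offset + lo, offset + hi + 1)
        vals = sigma.sigma.values[window][~sigma.sigma.mask[window]]
        if len(vals):
            eff[i] = max(float(vals.max()), 0.0)
    return eff


def classify_origins(
    eff_NE: np.ndarray, eff_OE: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """Classify origins by their OE/NE efficiency fold change.

    The ratio ``rho = (eff_OE + pseudocount) / (eff_NE + pseudocount)`` maps to
    ``Oi`` when ``rho >= 4``, ``intermediate`` when ``2 <= rho < 4`` and
    ``CN`` otherwise.  The pseudocount stabilizes ratios at near-zero NE
    efficiencies; with ``pseudocount=0`` the rule is exactly scale-invariant.
    Pairs with a missing efficiency are labelled ``"NA"``.
    """
    eff_NE = np.asarray(eff_NE, dtype=float)
    eff_OE = np.asarray(eff_OE, dtype=float)
    finite = np.isfinite(eff_NE) & np.isfinite(eff_OE)
    if np.any((eff_NE[finite] < 0) | (eff_OE[finite] < 0)):
        raise ValueError("efficiencies must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (eff_OE + pseudocount) / (eff_NE + pseudocount)
    labels = np.full(eff_NE.shape, "NA", dtype=object)
    labels[finite & (rho < FOLD_INTERMEDIATE)] = "CN"
    labels[finite & (rho >= FOLD_INTERMEDIATE) & (rho < FOLD_OI)] = "intermediate"
    labels[finite & (rho >= FOLD_OI)] = "Oi"
    return labels


def _merge_loci(loci_a: pd.DataFrame, loci_b: pd.DataFrame, genome: BinnedGenome, tol_bins: int = 3) -> pd.DataFrame:
    """Union of two peak lists, deduplicating loci within ``tol_bins`` bins."""
    both = pd.concat([loci_a, loci_b], ignore_index=True)
    if both.empty:
        return both
    order = {name: i for i, name in enumerate(genome.chrom_names)}
    both = both.sort_values(
        ["chrom", "bin", "peak_sigma"],
        key=lambda s: s.map(order) if s.name == "chrom" else s,
        ascending=[True, True, False],
        kind="mergesort",
    ).reset_index(drop=True)
    keep, last = [], {}
    for i, row in both.iterrows():
        prev = last.get(row["chrom"])
        if prev is not None and row["bin"] - prev <= tol_bins:
            continue
        keep.append(i)
        last[row["chrom"]] = row["bin"]
    return both.loc[keep].reset_index(drop=True)


def build_catalog(
    sigma_NE: SigmaTrack,
    sigma_OE: SigmaTrack,
    loci: pd.DataFrame | None = None,
    min_sigma_excess: float = 3.0,
    min_run: int = 2,
    merge_gap: int = 1,
    pseudocount: float = 1.0,
    dedupe_bins: int = 3,
) -> OriginCatalog:
    """Call (or accept) origin loci, quantify both conditions and classify.

    When ``loci`` is None, peaks are called on both condition tracks and the
    union is used, so origins that fire only under overexpression are still
    represented; calls within ``dedupe_bins`` bins are considered the same
    origin (summits on a broad peak can shift by a bin or two between
    conditions) and a single representative is kept.  An externally determined
    origin list (e.g. from a prior study, via BED) can be supplied instead.
    """
    if sigma_NE.genome != sigma_OE.genome:
        raise ValueError("NE and OE tracks are on different genomes")
    if loci is None:
        loci = _merge_loci(
            call_peaks(sigma_NE, min_sigma_excess, min_run, merge_gap),
            call_peaks(sigma_OE, min_sigma_excess, min_run, merge_gap),
            sigma_NE.genome,
            tol_bins=dedupe_bins,
        )
    eff_ne = quantify_efficiency(sigma_NE, loci)
    eff_oe = quantify_efficiency(sigma_OE, loci)
    labels = classify_origins(eff_ne, eff_oe, pseudocount=pseudocount)
    frame = pd.DataFrame(
        {
            "chrom": loci["chrom"].to_numpy(),
            "bin": loci["bin"].to_numpy(),
            "summit_bp": loci["summit_bp"].to_numpy(),
            "eff_NE": eff_ne,
            "eff_OE": eff_oe,
            "class_label": labels,
        }
    )
    return OriginCatalog(sigma_NE.genome, frame)


@dataclass
class CorrelationSummary:
    """Per-class paired efficiencies of two samples with correlation statistics."""

    classes: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, d in self.classes.items():
            rows.append(
                {
                    "class": label,
                    "n": d["n"],
                    "n_excluded": d["n_excluded"],
                    "pearson_r": d["pearson_r"],
                    "spearman_r": d["spearman_r"],
                    "mean_A": d["mean_A"],
                    "mean_B": d["mean_B"],
                }
            )
        return pd.DataFrame(rows)


def correlate_catalogs(
    catalog: OriginCatalog,
    sigma_A: SigmaTrack,
    sigma_B: SigmaTrack,
    classes: tuple[str, ...] = CLASS_LABELS,
) -> CorrelationSummary:
    """Correlate per-origin efficiencies of two samples, stratified by class.

    For each origin class, efficiencies of the catalog loci are quantified in
    both tracks; pairs with a missing value in either sample are excluded and
    counted.  Pearson r is the headline statistic (Spearman reported
    alongside); classes with fewer than two complete pairs, or zero variance,
    get NaN.
    """
    for trk in (sigma_A, sigma_B):
        if trk.genome != catalog.genome:
            raise ValueError("track genome does not match catalog genome")
    loci = catalog.frame[["chrom", "bin"]]
    eff_a = quantify_efficiency(sigma_A, loci)
    eff_b = quantify_efficiency(sigma_B, loci)
    summary = CorrelationSummary()
    for label in classes:
        in_class = (catalog.frame["class_label"] == label).to_numpy()
        a, b = eff_a[in_class], eff_b[in_class]
        complete = np.isfinite(a) & np.isfinite(b)
        a, b = a[complete], b[complete]
        if len(a) >= 2 and np.std(a) > 0 and np.std(b) > 0:
            pearson = float(sps.pearsonr(a, b).statistic)
            spearman = float(sps.spearmanr(a, b).statistic)
        else:
            pearson = spearman = float("nan")
        summary.classes[label] = {
            "n": int(len(a)),
            "n_excluded": int(in_class.sum() - complete.sum()),
            "pearson_r": pearson,
            "spearman_r": spearman,
            "mean_A": float(np.mean(a)) if len(a) else float("nan"),
            "mean_B": float(np.mean(b)) if len(b) else float("nan"),
            "eff_A": a,
            "eff_B": b,
        }
    return summary


def match_loci(
    called: pd.DataFrame, truth: pd.DataFrame, tol_bins: int = 3
) -> tuple[float, float, int]:
    """Recall/precision of called loci against a ground-truth locus set.

    A called locus matches a true locus on the same chromosome within
    ``tol_bins`` bins; each true locus can absorb at most one call (nearest
    first).  Returns ``(recall, precision, n_matched)``.
    """
    matched_truth: set[int] = set()
    matched_calls = 0
    truth_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, row in enumerate(truth.itertuples(index=False)):
        truth_by_chrom.setdefault(row.chrom, []).append((int(row.bin), j))
    for row in called.itertuples(index=False):
        candidates = truth_by_chrom.get(row.chrom, [])
        best, best_d = None, tol_bins + 1
        for tbin, j in candidates:
            if j in matched_truth:
                continue
            d = abs(int(row.bin) - tbin)
            if d < best_d:
                best, best_d = j, d
        if best is not None and best_d <= tol_bins:
            matched_truth.add(best)
            matched_calls += 1
    recall = len(matched_truth) / len(truth) if len(truth) else float("nan")
    precision = matched_calls / len(called) if len(called) else float("nan")
    return recall, precision, len(matched_truth)
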
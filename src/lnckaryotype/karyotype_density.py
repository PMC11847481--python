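"""Chromosomal distribution statistics: counts, densities, 1-Mb window
tracks and quantile-threshold peak calls.

A "TRUE peak" is a 1-Mb window whose gene count reaches the 95th percentile
of the window-density distribution of its gene class. Counts per 1-Mb
window are identical to densities in genes/Mb, so the raw counts are
thresholded directly; no kernel smoothing is applied.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenomeAssembly

DEFAULT_WINDOW = 1_000_000


class DegenerateInputError(ValueError):
    """Statistic undefined for this input (e.g. zero variance)."""


def count_by_chromosome(genes: pd.DataFrame, assembly: GenomeAssembly) -> pd.DataFrame:
    """Per-chromosome gene counts and densities (genes/Mb) per biotype.

    Every assembly chromosome appears for every biotype present, zero-filled
    where a class has no genes.
    """
    biotypes = sorted(genes["biotype"].unique()) if len(genes) else []
    rows = []
    counts = genes.groupby(["chrom", "biotype"], observed=True).size()
    for chrom in assembly.names:
        length = assembly.lengths[chrom]
        for biotype in biotypes:
            n = int(counts.get((chrom, biotype), 0))
            rows.append(
                {
                    "chrom": chrom,
                    "biotype": biotype,
                    "count": n,
                    "length_bp": length,
                    "density_per_mb": n / (length / 1e6),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "biotype", "count", "length_bp", "density_per_mb"])


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length numeric vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def window_index(start: int, window: int = DEFAULT_WINDOW) -> int:
    """0-based window index of a 1-based coordinate: floor((start-1)/window)."""
    return (start - 1) // window


def windowed_density(
    genes: pd.DataFrame,
    assembly: GenomeAssembly,
    window: int = DEFAULT_WINDOW,
    anchor: str = "start",
) -> pd.DataFrame:
    """Gene counts in fixed windows tiling each chromosome.

    Each gene lands in exactly one window via its anchor coordinate
    (leftmost genomic coordinate by default; "midpoint" optional). The
    trailing partial window is kept, so counts sum to the chromosome total.
    """
    if anchor not in ("start", "midpoint"):
        raise ValueError("anchor must be 'start' or 'midpoint'")
    biotypes = sorted(genes["biotype"].unique()) if len(genes) else []
    frames = []
    for chrom in assembly.names:
        length = assembly.lengths[chrom]
        n_windows = (length + window - 1) // window
        chrom_genes = genes[genes["chrom"] == chrom]
        for biotype in biotypes:
            sub = chrom_genes[chrom_genes["biotype"] == biotype]
            if anchor == "start":
                anchors = sub["start"].to_numpy()
            else:
                anchors = ((sub["start"] + sub["end"]) // 2).to_numpy()
            idx = (anchors - 1) // window
            counts = np.bincount(idx, minlength=n_windows) if len(idx) else np.zeros(n_windows, dtype=int)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "biotype": biotype,
                        "window_index": np.arange(n_windows),
                        "window_start": np.arange(n_windows) * window + 1,
                        "window_end": np.minimum((np.arange(n_windows) + 1) * window, length),
                        "count": counts.astype(int),
                        "density": counts / (window / 1e6),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "biotype", "window_index", "window_start", "window_end", "count", "density"]
        )
    return pd.concat(frames, ignore_index=True)


def call_peaks(
    track: pd.DataFrame,
    q: float = 0.95,
    per_chromosome: bool = False,
) -> pd.DataFrame:
    """Flag TRUE peaks: windows at or above the q-quantile of the density
    distribution of their gene class.

    The quantile estimator is the linear-interpolation (Hyndman–Fan type 7)
    one, computed genome-wide per biotype over all windows, zero windows
    included. Ties at the threshold are all flagged TRUE. Setting
    ``per_chromosome`` computes one threshold per chromosome instead.
    """
    if track.empty:
        raise ValueError("empty density track")
    if not 0 < q < 1:
        raise ValueError("quantile must be in (0, 1)")
    out = track.copy()
    keys = ["biotype", "chrom"] if per_chromosome else ["biotype"]
    thresholds = out.groupby(keys, observed=True)["density"].transform(
        lambda d: np.quantile(d.to_numpy(), q)  # numpy default = type-7
    )
    out["threshold"] = thresholds
    out["is_true_peak"] = out["density"] >= out["threshold"]
    return out


def inter_gene_distances(genes: pd.DataFrame) -> pd.DataFrame:
    """Rainfall-plot-ready distances from each gene start to the previous
    gene start on the same chromosome, per biotype."""
    rows = []
    for (chrom, biotype), sub in genes.groupby(["chrom", "biotype"], observed=True):
        starts = np.sort(sub["start"].to_numpy())
        dist = np.diff(starts, prepend=starts[0] if len(starts) else 0)
        for s, d in zip(starts, dist):
            rows.append({"chrom": chrom, "biotype": biotype, "start": int(s), "distance_to_prev": int(d)})
    return pd.DataFrame(rows, columns=["chrom", "biotype", "start", "distance_to_prev"])


def peak_summary(peaks: pd.DataFrame) -> pd.DataFrame:
    """Fraction of TRUE-peak windows per biotype (and the thresholds used)."""
    rows = []
    for biotype, sub in peaks.groupby("biotype", observed=True):
        rows.append(
            {
                "biotype": biotype,
                "n_windows": len(sub),
                "n_true_peaks": int(sub["is_true_peak"].sum()),
                "true_peak_fraction": float(sub["is_true_peak"].mean()),
                "threshold": float(sub["threshold"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)
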
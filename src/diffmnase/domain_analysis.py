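"""Windowed genome statistics and the GC regression with influence
filtering.

The genome is tiled into constant-size non-overlapping windows; each window
carries mean occupancy of both digestion conditions, GC fraction, mean
mappability and the log2 fold change.  An OLS of a chosen response on GC is
fitted, high-influence windows (Cook's distance above threshold) are dropped
once, and the adjusted R^2 of the refit is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fragment_processing import OccupancyTrack

__all__ = [
    "RegressionResult",
    "segment_genome",
    "window_stats",
    "compute_logfc",
    "gc_regression",
    "gc_content_windows",
]

MAPPABILITY_MIN = 0.9
COOKS_THRESHOLD = 0.001


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    adj_r2: float
    n_used: int
    n_dropped_influence: int
    n_dropped_filters: int
    cooks_threshold: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "adj_r2": self.adj_r2,
            "n_used": self.n_used,
            "n_dropped_influence": self.n_dropped_influence,
            "n_dropped_filters": self.n_dropped_filters,
            "cooks_threshold": self.cooks_threshold,
        }


def segment_genome(sizes: Mapping[str, int], window: int) -> pd.DataFrame:
    """Tile each chromosome from 0 with non-overlapping windows of constant
    size; a trailing partial window is dropped."""
    if window < 1:
        raise ValueError("window must be >= 1")
    rows = []
    for chrom, size in sizes.items():
        n = size // window
        for i in range(n):
            rows.append((chrom, i * window, (i + 1) * window))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df.attrs["window"] = window
    return df


def _window_means(values: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    csum = np.concatenate(([0.0], np.cumsum(values)))
    return (csum[ends] - csum[starts]) / (ends - starts)


def gc_content_windows(
    seq: str, starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window GC fraction over non-N bases; returns (gc, n_valid_bases).
    Windows that are entirely N get gc = NaN."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C")) | (arr == ord("g")) | (arr == ord("c"))
    is_n = (arr == ord("N")) | (arr == ord("n"))
    gc_csum = np.concatenate(([0], np.cumsum(is_gc)))
    n_csum = np.concatenate(([0], np.cumsum(is_n)))
    gc_counts = gc_csum[ends] - gc_csum[starts]
    n_counts = n_csum[ends] - n_csum[starts]
    valid = (ends - starts) - n_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(valid > 0, gc_counts / np.maximum(valid, 1), np.nan)
    return gc, valid


def window_stats(
    windows: pd.DataFrame,
    low_track: OccupancyTrack,
    high_track: OccupancyTrack,
    genome: Mapping[str, str],
    mappability: Mapping[str, np.ndarray] | None = None,
    mappability_min: float = MAPPABILITY_MIN,
) -> pd.DataFrame:
    """Per-window means of both tracks, GC fraction and mean mappability.

    Windows with zero occupancy in either condition, mean mappability below
    the threshold, or all-N sequence are excluded; exclusion counts are kept
    in the frame attrs.
    """
    parts = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        sub = grp.copy()
        sub["mean_low"] = _window_means(low_track.values[chrom], starts, ends)
        sub["mean_high"] = _window_means(high_track.values[chrom], starts, ends)
        gc, valid = gc_content_windows(genome[chrom], starts, ends)
        sub["gc"] = gc
        if mappability is not None:
            sub["mappability"] = _window_means(mappability[chrom], starts, ends)
        else:
            sub["mappability"] = 1.0
        parts.append(sub)
    table = pd.concat(parts, ignore_index=True)

    n0 = len(table)
    all_n = table["gc"].isna()
    no_reads = (table["mean_low"] <= 0) | (table["mean_high"] <= 0)
    low_map = table["mappability"] < mappability_min - 1e-9
    keep = ~(all_n | no_reads | low_map)
    out = table[keep].reset_index(drop=True)
    out.attrs["window"] = windows.attrs.get("window")
    out.attrs["n_windows_total"] = n0
    out.attrs["n_dropped_all_n"] = int(all_n.sum())
    out.attrs["n_dropped_no_reads"] = int((no_reads & ~all_n).sum())
    out.attrs["n_dropped_mappability"] = int((low_map & ~no_reads & ~all_n).sum())
    return out


def compute_logfc(table: pd.DataFrame) -> pd.DataFrame:
    """log2 fold change of high over low mean occupancy per window."""
    out = table.copy()
    out["logfc"] = np.log2(out["mean_high"] / out["mean_low"])
    out.attrs.update(table.attrs)
    return out


def gc_regression(
    table: pd.DataFrame,
    response: str = "logfc",
    cooks_threshold: float = COOKS_THRESHOLD,
) -> RegressionResult:
    """OLS of the response on GC with one pass of Cook's-distance filtering.

    Fit, drop observations with Cook's D above the threshold, refit once and
    report the adjusted R^2 of the refit (clamped at 0).
    """
    if response not in ("logfc", "mean_high", "mean_low"):
        raise ValueError(f"unknown response {response!r}")
    data = table.dropna(subset=[response, "gc"])
    n_dropped_filters = len(table) - len(data)
    if len(data) < 3:
        raise ValueError(f"only {len(data)} usable windows; need >= 3")
    y = data[response].to_numpy(dtype=np.float64)
    X = sm.add_constant(data["gc"].to_numpy(dtype=np.float64))
    fit0 = sm.OLS(y, X).fit()
    if fit0.ssr <= 1e-12 * max(fit0.centered_tss, np.finfo(float).tiny):
        # (near-)perfect fit: Cook's distance is 0/0 noise; nothing influential
        keep = np.ones(len(y), dtype=bool)
    else:
        cooks = fit0.get_influence().cooks_distance[0]
        # NaN Cook's D counts as no influence
        keep = ~(cooks > cooks_threshold)
    n_influence = int((~keep).sum())
    if keep.sum() < 3:
        raise ValueError("fewer than 3 windows remain after influence filtering")
    fit = sm.OLS(y[keep], X[keep]).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        adj_r2=float(max(fit.rsquared_adj, 0.0)),
        n_used=int(keep.sum()),
        n_dropped_influence=n_influence,
        n_dropped_filters=n_dropped_filters,
        cooks_threshold=cooks_threshold,
    )
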
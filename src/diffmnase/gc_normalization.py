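"""LOESS correction of the digestion GC bias.

Occupancy means in 250-bp windows are regressed on window GC with a locally
weighted polynomial smoother (tricube weights); the track is then rescaled
per window by global_mean / fitted(gc).  Windows with extreme GC (< 30% or
> 70%) are excluded from the fit; at application time out-of-range windows
use the fitted value clamped at the nearest bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragment_processing import OccupancyTrack

__all__ = ["LoessFit", "loess_smooth", "fit_gc_loess", "apply_gc_correction"]

GC_BOUNDS = (0.30, 0.70)


@dataclass
class LoessFit:
    condition: str
    window: int
    gc_grid: np.ndarray
    fitted: np.ndarray
    global_mean: float
    span: float = 0.75
    degree: int = 2
    gc_bounds: tuple[float, float] = GC_BOUNDS

    def __post_init__(self) -> None:
        self.gc_grid = np.asarray(self.gc_grid, dtype=np.float64)
        self.fitted = np.asarray(self.fitted, dtype=np.float64)
        if np.any(np.diff(self.gc_grid) <= 0):
            raise ValueError("gc_grid must be sorted strictly ascending")
        if np.any(self.fitted <= 0):
            raise ValueError("fitted occupancy must be positive on the GC range")

    def predict(self, gc: np.ndarray) -> np.ndarray:
        """Fitted occupancy at the given GC values, clamped to gc_bounds."""
        gc = np.clip(np.asarray(gc, dtype=np.float64), *self.gc_bounds)
        return np.interp(gc, self.gc_grid, self.fitted)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "condition": self.condition,
                    "window": self.window,
                    "gc_grid": self.gc_grid.tolist(),
                    "fitted": self.fitted.tolist(),
                    "global_mean": self.global_mean,
                    "span": self.span,
                    "degree": self.degree,
                    "gc_bounds": list(self.gc_bounds),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "LoessFit":
        with open(path) as fh:
            d = json.load(fh)
        d["gc_grid"] = np.asarray(d["gc_grid"])
        d["fitted"] = np.asarray(d["fitted"])
        d["gc_bounds"] = tuple(d["gc_bounds"])
        return cls(**d)


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression evaluated on a grid.

    At each grid point the span fraction of nearest x-values is tricube
    weighted by distance and a degree-d polynomial is fitted by weighted
    least squares.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size == 0:
        raise ValueError("x and y must be non-empty and equally sized")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = max(int(np.ceil(span * x.size)), degree + 2)
    k = min(k, x.size)
    out = np.empty(grid.size)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = np.finfo(float).tiny
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sel = w > 0
        dx = x[sel] - x0
        design = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w[sel])
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[sel] * sw, rcond=None)
        out[i] = coef[0]
    return out


def fit_gc_loess(
    window_table: pd.DataFrame,
    condition: str,
    span: float = 0.75,
    degree: int = 2,
    gc_bounds: tuple[float, float] = GC_BOUNDS,
    grid_points: int = 81,
    min_rows: int = 50,
) -> LoessFit:
    """Fit the occupancy-vs-GC smoother on 250-bp window statistics.

    Windows with GC outside gc_bounds are excluded from the fit.  `condition`
    selects the mean_low or mean_high column.
    """
    col = {"low": "mean_low", "high": "mean_high"}.get(condition)
    if col is None:
        raise ValueError(f"condition must be 'low' or 'high', got {condition!r}")
    sub = window_table[
        (window_table["gc"] >= gc_bounds[0]) & (window_table["gc"] <= gc_bounds[1])
    ]
    if len(sub) < min_rows:
        raise ValueError(
            f"only {len(sub)} windows within GC bounds; need >= {min_rows} for "
            "a stable fit"
        )
    gc = sub["gc"].to_numpy()
    occ = sub[col].to_numpy()
    grid = np.linspace(gc.min(), gc.max(), grid_points)
    fitted = loess_smooth(gc, occ, grid, span=span, degree=degree)
    if np.any(fitted <= 0):
        raise ValueError("LOESS fit produced non-positive expected occupancy")
    return LoessFit(
        condition=condition,
        window=int(window_table.attrs.get("window") or 250),
        gc_grid=grid,
        fitted=fitted,
        global_mean=float(occ.mean()),
        span=span,
        degree=degree,
        gc_bounds=gc_bounds,
    )


def apply_gc_correction(
    track: OccupancyTrack,
    fit: LoessFit,
    window_table: pd.DataFrame,
) -> OccupancyTrack:
    """Rescale the track per window by global_mean / fitted(gc).

    Only windows present in the table (i.e. that passed the read/mappability
    filters) are corrected; others are left unchanged.  Out-of-bounds GC uses
    the clamped prediction.
    """
    expected = fit.predict(window_table["gc"].to_numpy())
    if np.any(expected <= 0):
        raise ValueError("fitted occupancy <= 0; cannot correct")
    factors = fit.global_mean / expected
    out = track.copy()
    for chrom, grp in window_table.groupby("chrom", sort=False):
        if chrom not in out.values:
            continue
        arr = out.values[chrom]
        idx = grp.index.to_numpy()
        for start, end, f in zip(
            grp["start"].to_numpy(), grp["end"].to_numpy(), factors[idx]
        ):
            arr[start:end] *= f
    # condition-independent tag: corrected low/high tracks stay comparable
    out.normalization.append(f"gc_loess:w{fit.window}")
    return out
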
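"""Fragment interval processing: size selection, clonal filtering,
midpoint-extended occupancy tracks, depth/CNV normalization and a simple
nucleosome position caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "FragmentRecord",
    "OccupancyTrack",
    "CnvSegmentSet",
    "SIZE_GATES",
    "read_fragments",
    "size_select",
    "dedup_clonal",
    "build_occupancy",
    "depth_normalize",
    "cnv_correct",
    "call_nucleosomes",
]

#: inclusive fragment-length gates for mono- and di-nucleosomal DNA
SIZE_GATES = {"mono": (140, 200), "di": (250, 500)}


@dataclass(frozen=True)
class FragmentRecord:
    chrom: str
    start: int
    end: int
    condition: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid fragment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class OccupancyTrack:
    """Per-base occupancy signal per chromosome with a normalization log."""

    values: dict[str, np.ndarray]
    n_fragments_used: int
    extend_to: int
    normalization: list[str] = field(default_factory=list)

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def copy(self) -> "OccupancyTrack":
        return OccupancyTrack(
            values={c: v.copy() for c, v in self.values.items()},
            n_fragments_used=self.n_fragments_used,
            extend_to=self.extend_to,
            normalization=list(self.normalization),
        )


@dataclass
class CnvSegmentSet:
    """Copy-number segments with an assumed genome ploidy."""

    segments: list[tuple[str, int, int, float]]
    ploidy: float = 2.0

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, cn in self.segments:
            if cn <= 0:
                raise ValueError(f"copy number must be > 0, got {cn}")
            if end <= start:
                raise ValueError(f"invalid segment [{start}, {end})")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping CNV segments on {chrom}")


def read_fragments(
    path: str, format: str = "BED", condition: str = ""
) -> list[FragmentRecord]:
    """Parse fragment intervals from BED (one record per fragment) or BEDPE
    (fragment spans from mate-pair outer coordinates)."""
    if format not in ("BED", "BEDPE"):
        raise ValueError(f"unknown fragment format {format!r}")
    records: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if format == "BED":
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                else:
                    if len(parts) < 6:
                        raise ValueError("BEDPE needs >= 6 columns")
                    if parts[0] != parts[3]:
                        raise ValueError("inter-chromosomal BEDPE pair")
                    chrom = parts[0]
                    start = min(int(parts[1]), int(parts[4]))
                    end = max(int(parts[2]), int(parts[5]))
                records.append(FragmentRecord(chrom, start, end, condition))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def size_select(
    fragments: Sequence[FragmentRecord], cls: str
) -> list[FragmentRecord]:
    """Keep fragments within the inclusive mono (140-200 bp) or di
    (250-500 bp) nucleosomal length gate."""
    try:
        lo, hi = SIZE_GATES[cls]
    except KeyError:
        raise ValueError(f"unknown size class {cls!r}") from None
    return [f for f in fragments if lo <= f.length <= hi]


def clonal_cap(mean_multiplicity: float, p_threshold: float = 1e-2) -> int:
    """Smallest multiplicity k whose Poisson upper-tail probability
    P(X >= k) under lambda = mean multiplicity drops below p_threshold,
    floored at 1 copy."""
    lam = max(mean_multiplicity, 0.0)
    k = 1
    # sf(k-1) = P(X >= k)
    while stats.poisson.sf(k - 1, lam) >= p_threshold:
        k += 1
    return max(k, 1)


def dedup_clonal(
    fragments: Sequence[FragmentRecord], p_threshold: float = 1e-2
) -> list[FragmentRecord]:
    """Cap the multiplicity of identical (chrom, start, end) fragments at the
    Poisson-tail cap computed from the genome-wide mean multiplicity."""
    if not fragments:
        return []
    counts: dict[tuple[str, int, int], int] = {}
    for f in fragments:
        counts[(f.chrom, f.start, f.end)] = counts.get((f.chrom, f.start, f.end), 0) + 1
    lam = len(fragments) / len(counts)
    cap = clonal_cap(lam, p_threshold)
    kept: list[FragmentRecord] = []
    seen: dict[tuple[str, int, int], int] = {}
    for f in fragments:
        key = (f.chrom, f.start, f.end)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] <= cap:
            kept.append(f)
    return kept


def build_occupancy(
    fragments: Sequence[FragmentRecord],
    sizes: Mapping[str, int],
    extend_to: int = 70,
) -> OccupancyTrack:
    """Midpoint-extended occupancy: each fragment adds +1 over
    [mid - extend_to//2, mid + extend_to - extend_to//2), clipped to the
    chromosome with a warning."""
    if extend_to < 1:
        raise ValueError("extend_to must be >= 1")
    half = extend_to // 2
    arrays = {c: np.zeros(n + 1, dtype=np.float64) for c, n in sizes.items()}
    by_chrom: dict[str, list[int]] = {c: [] for c in sizes}
    n_used = 0
    clipped = 0
    for f in fragments:
        if f.chrom not in arrays:
            raise KeyError(f"fragment on unknown chromosome {f.chrom!r}")
        by_chrom[f.chrom].append(f.midpoint)
        n_used += 1
    for chrom, mids in by_chrom.items():
        if not mids:
            continue
        m = np.asarray(mids, dtype=np.int64)
        starts = m - half
        ends = m - half + extend_to
        size = sizes[chrom]
        clipped += int(np.count_nonzero((starts < 0) | (ends > size)))
        np.add.at(arrays[chrom], np.clip(starts, 0, size), 1.0)
        np.add.at(arrays[chrom], np.clip(ends, 0, size), -1.0)
    if clipped:
        warnings.warn(f"{clipped} fragment extensions clipped at chromosome bounds")
    values = {c: np.cumsum(a[:-1]) for c, a in arrays.items()}
    return OccupancyTrack(values=values, n_fragments_used=n_used, extend_to=extend_to)


def depth_normalize(track: OccupancyTrack, target: float = 2e8) -> OccupancyTrack:
    """Scale the track so that the fragment total corresponds to `target`."""
    if any(step.startswith("depth:") for step in track.normalization):
        raise ValueError("depth normalization already applied")
    if track.n_fragments_used == 0:
        raise ValueError("cannot depth-normalize a track built from 0 fragments")
    factor = target / track.n_fragments_used
    out = track.copy()
    for chrom in out.values:
        out.values[chrom] *= factor
    out.normalization.append(f"depth:{target:g}")
    return out


def cnv_correct(track: OccupancyTrack, segments: CnvSegmentSet) -> OccupancyTrack:
    """Divide occupancy inside each CNV segment by copy_number / ploidy;
    positions outside any segment are assumed at ploidy and left unchanged."""
    if any(step.startswith("cnv") for step in track.normalization):
        raise ValueError("CNV correction already applied")
    out = track.copy()
    for chrom, start, end, cn in segments.segments:
        if chrom in out.values:
            out.values[chrom][start:end] /= cn / segments.ploidy
    out.normalization.append(f"cnv:ploidy={segments.ploidy:g}")
    return out


def call_nucleosomes(
    track: OccupancyTrack,
    min_distance: int = 150,
    min_height: float = 1.0,
    smooth_window: int = 73,
) -> dict[str, np.ndarray]:
    """Call nucleosome dyads as local maxima of the moving-average-smoothed
    track, at least min_distance apart and min_height high; plateau ties are
    resolved to the leftmost base."""
    calls: dict[str, np.ndarray] = {}
    kernel = np.ones(smooth_window) / smooth_window
    for chrom, values in track.values.items():
        if values.size < smooth_window:
            calls[chrom] = np.array([], dtype=np.int64)
            continue
        smoothed = np.convolve(values, kernel, mode="same")
        peaks, props = signal.find_peaks(
            smoothed, height=min_height, distance=min_distance, plateau_size=1
        )
        calls[chrom] = props["left_edges"].astype(np.int64)
    return calls
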
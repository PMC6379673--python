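"""Sequence-composition diagnostics and feature-anchored aggregate profiles.

Fragment GC content, dinucleotide-set frequency around fragment midpoints or
borders (1-bp resolution), a spectral score for the ~10-bp nucleosomal
periodicity, and mean profiles / heatmaps of occupancy around feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fragment_processing import FragmentRecord, OccupancyTrack

__all__ = [
    "DinucProfile",
    "DINUC_SETS",
    "fragment_gc",
    "dinuc_profile",
    "random_fragment_control",
    "periodicity_score",
    "aggregate_profile",
]

DINUC_SETS = {
    "GC": ("GG", "GC", "CG", "CC"),
    "AT": ("AA", "AT", "TA", "TT"),
}


@dataclass
class DinucProfile:
    anchor: str
    offsets: np.ndarray
    frequency: np.ndarray
    set_name: str
    n_fragments: int
    n_skipped: int = 0


def _seq_class_arrays(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_at = (arr == ord("A")) | (arr == ord("T"))
    is_n = ~(is_gc | is_at)
    return is_gc, is_at, is_n


def fragment_gc(
    fragments: Sequence[FragmentRecord], genome: Mapping[str, str]
) -> tuple[np.ndarray, dict]:
    """Per-fragment GC fraction (N bases excluded from the denominator) and a
    summary with the genome-wide GC mean for comparison."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {f.chrom for f in fragments}:
        is_gc, is_at, _ = _seq_class_arrays(genome[chrom])
        by_chrom[chrom] = (
            np.concatenate(([0], np.cumsum(is_gc))),
            np.concatenate(([0], np.cumsum(is_gc | is_at))),
        )
    out = np.empty(len(fragments))
    for i, f in enumerate(fragments):
        gc_csum, valid_csum = by_chrom[f.chrom]
        if f.end > len(genome[f.chrom]):
            raise ValueError(f"fragment beyond end of {f.chrom}")
        gc = gc_csum[f.end] - gc_csum[f.start]
        valid = valid_csum[f.end] - valid_csum[f.start]
        out[i] = gc / valid if valid else np.nan

    genome_gc_num = 0
    genome_gc_den = 0
    for seq in genome.values():
        is_gc, is_at, _ = _seq_class_arrays(seq)
        genome_gc_num += int(is_gc.sum())
        genome_gc_den += int((is_gc | is_at).sum())
    summary = {
        "mean_fragment_gc": float(np.nanmean(out)),
        "genome_gc": genome_gc_num / genome_gc_den if genome_gc_den else float("nan"),
        "n_fragments": len(fragments),
    }
    return out, summary


def _anchors(fragments: Sequence[FragmentRecord], anchor: str) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for f in fragments:
        if anchor == "midpoint":
            by_chrom.setdefault(f.chrom, []).append(f.midpoint)
        elif anchor == "end5":
            by_chrom.setdefault(f.chrom, []).append(f.start)
        elif anchor == "end3":
            by_chrom.setdefault(f.chrom, []).append(f.end - 1)
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
    return {c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()}


def dinuc_profile(
    fragments: Sequence[FragmentRecord],
    genome: Mapping[str, str],
    set_name: str = "GC",
    anchor: str = "midpoint",
    flank: int = 300,
) -> DinucProfile:
    """Fraction of fragments whose dinucleotide at each offset from the
    anchor belongs to the chosen set.

    Offset o refers to positions (anchor+o, anchor+o+1).  Fragments whose
    full offset window leaves the chromosome are skipped and counted;
    N-containing dinucleotides are excluded from both numerator and
    denominator at their offset.
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    if set_name not in DINUC_SETS:
        raise ValueError(f"unknown dinucleotide set {set_name!r}")
    offsets = np.arange(-flank, flank)
    hits = np.zeros(offsets.size)
    valid = np.zeros(offsets.size)
    n_used = 0
    n_skipped = 0
    for chrom, anchors in _anchors(fragments, anchor).items():
        is_gc, is_at, is_n = _seq_class_arrays(genome[chrom])
        in_set = is_gc if set_name == "GC" else is_at
        d_in = (in_set[:-1] & in_set[1:]).astype(np.float64)
        d_ok = (~is_n[:-1] & ~is_n[1:]).astype(np.float64)
        size = len(genome[chrom])
        ok = (anchors - flank >= 0) & (anchors + flank < size)
        n_skipped += int((~ok).sum())
        anchors = anchors[ok]
        n_used += anchors.size
        for k, o in enumerate(offsets):
            idx = anchors + o
            hits[k] += d_in[idx].sum()
            valid[k] += d_ok[idx].sum()
    if n_used == 0:
        raise ValueError("all fragments skipped: anchor windows leave chromosomes")
    with np.errstate(invalid="ignore"):
        freq = np.where(valid > 0, hits / np.maximum(valid, 1), np.nan)
    return DinucProfile(
        anchor=anchor,
        offsets=offsets,
        frequency=freq,
        set_name=set_name,
        n_fragments=n_used,
        n_skipped=n_skipped,
    )


def random_fragment_control(
    genome: Mapping[str, str],
    n: int = 1_000_000,
    length: int = 147,
    seed: int = 0,
) -> list[FragmentRecord]:
    """Uniformly placed fragments of fixed length, as the random control for
    dinucleotide profiles."""
    rng = np.random.default_rng(seed)
    chroms = [c for c, seq in genome.items() if len(seq) > length]
    if not chroms:
        raise ValueError("no chromosome longer than the fragment length")
    sizes = np.array([len(genome[c]) - length for c in chroms], dtype=np.float64)
    probs = sizes / sizes.sum()
    which = rng.choice(len(chroms), size=n, p=probs)
    out = []
    for k in range(n):
        c = chroms[which[k]]
        start = int(rng.integers(0, len(genome[c]) - length + 1))
        out.append(FragmentRecord(c, start, start + length, "control"))
    return out


def periodicity_score(
    profile: DinucProfile, period: float = 10.0, footprint: int = 73
) -> float:
    """Normalized spectral power of the mean-subtracted profile (restricted
    to the +-footprint nucleosome window) at the bin nearest 1/period."""
    if profile.offsets.max() < period:
        raise ValueError("profile flank shorter than the requested period")
    sel = (profile.offsets >= -footprint) & (profile.offsets <= footprint)
    y = profile.frequency[sel]
    y = y[~np.isnan(y)]
    y = y - y.mean()
    power = np.abs(np.fft.rfft(y)) ** 2
    total = power[1:].sum()
    if total == 0:
        return 0.0
    freqs = np.fft.rfftfreq(y.size)
    k = int(np.argmin(np.abs(freqs - 1.0 / period)))
    return float(power[k] / total)


def aggregate_profile(
    track: OccupancyTrack,
    features: Sequence[tuple],
    flank: int = 1000,
    mode: str = "mean_profile",
    sort_by: Sequence[float] | None = None,
):
    """Track signal around feature midpoints.

    Features are (chrom, start, end[, strand]) tuples; minus-strand rows are
    reversed.  mode="mean_profile" returns the per-offset mean vector;
    mode="heatmap" returns the per-feature matrix, ordered by sort_by
    descending when given (missing scores sort last).  Features whose window
    leaves the chromosome are dropped and counted.
    """
    if not features:
        raise ValueError("empty feature set")
    if mode not in ("mean_profile", "heatmap"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    keep_idx = []
    for i, feat in enumerate(features):
        chrom, start, end = feat[0], int(feat[1]), int(feat[2])
        strand = feat[3] if len(feat) > 3 else "+"
        mid = (start + end) // 2
        arr = track.values[chrom]
        if mid - flank < 0 or mid + flank + 1 > arr.size:
            continue
        row = arr[mid - flank : mid + flank + 1]
        rows.append(row[::-1] if strand == "-" else row)
        keep_idx.append(i)
    if not rows:
        raise ValueError("all features dropped: windows leave chromosomes")
    matrix = np.vstack(rows)
    if mode == "mean_profile":
        return matrix.mean(axis=0)
    if sort_by is not None:
        scores = np.array(
            [sort_by[i] if sort_by[i] is not None else -np.inf for i in keep_idx],
            dtype=np.float64,
        )
        scores = np.where(np.isnan(scores), -np.inf, scores)
        matrix = matrix[np.argsort(-scores, kind="mergesort")]
    return matrix
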
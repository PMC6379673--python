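"""Local differential accessibility calling from matched occupancy tracks.

Per base, the two depth-matched, GC-corrected tracks are compared with a
two-sided conditional Poisson (binomial) rate test; significant same-sign
bases are merged into candidate intervals of a minimum width, each interval
is re-tested on its summed signal, and Benjamini-Hochberg control selects
the reported hyper-accessible (low-enriched) and inaccessible
(high-enriched) sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fragment_processing import OccupancyTrack

__all__ = [
    "DifferentialSite",
    "call_differential_sites",
    "bh_fdr",
    "overlap_enrichment",
    "write_sites_bed",
]

HYPER = "hyper_accessible"
INACCESSIBLE = "inaccessible"


@dataclass(frozen=True)
class DifferentialSite:
    chrom: str
    start: int
    end: int
    direction: str
    p_value: float
    q_value: float
    low_mean: float
    high_mean: float


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(adjusted, 1.0)
    return q


def _two_sided_binomial_p(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized two-sided p-value for X ~ Binomial(n, 1/2); used as the
    conditional test of equal Poisson rates."""
    m = np.minimum(x, n - x)
    p = 2.0 * stats.binom.cdf(m, n, 0.5) - stats.binom.pmf(m, n, 0.5)
    return np.clip(p, 0.0, 1.0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True values."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return list(zip(starts.tolist(), ends.tolist()))


def _bh_fdr_padded(p: np.ndarray, n_tests: int) -> np.ndarray:
    """BH step-up over n_tests total tests of which only the given
    (smallest) p-values are candidates; the remainder implicitly have p = 1."""
    n_tests = max(n_tests, p.size)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n_tests / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(p.size)
    q[order] = np.minimum(adjusted, 1.0)
    return q


def call_differential_sites(
    low_track: OccupancyTrack,
    high_track: OccupancyTrack,
    min_width: int = 70,
    base_p: float = 1e-2,
    fdr: float = 0.05,
    counts_scale: float | None = None,
    n_tests: int | None = None,
) -> list[DifferentialSite]:
    """Call intervals differentially enriched between the two conditions.

    counts_scale converts summed per-base signal into effective fragment
    counts for the interval-level test; it defaults to the midpoint extension
    length of the tracks.  n_tests is the multiple-testing universe for the
    BH pass: the number of min_width units screened genome-wide (candidate
    intervals were selected from all of them, so correcting only across
    candidates would not control the FDR); it defaults to genome length /
    min_width.
    """
    if low_track.normalization != high_track.normalization:
        raise ValueError(
            "tracks have different normalization states: "
            f"{low_track.normalization} vs {high_track.normalization}"
        )
    if counts_scale is None:
        counts_scale = float(low_track.extend_to)
    if n_tests is None:
        n_tests = int(sum(v.size for v in low_track.values.values()) // min_width)

    candidates: list[tuple[str, int, int, int, float, float]] = []
    for chrom in low_track.values:
        lo = low_track.values[chrom]
        hi = high_track.values[chrom]
        if lo.size != hi.size:
            raise ValueError(f"track lengths differ on {chrom}")
        l_cnt = np.rint(lo).astype(np.int64)
        h_cnt = np.rint(hi).astype(np.int64)
        total = l_cnt + h_cnt
        with np.errstate(invalid="ignore"):
            p_base = _two_sided_binomial_p(l_cnt, total)
        p_base[total == 0] = 1.0
        sig = p_base < base_p
        sign = np.sign(l_cnt - h_cnt)
        for direction, s in ((HYPER, 1), (INACCESSIBLE, -1)):
            for start, end in _runs(sig & (sign == s)):
                if end - start < min_width:
                    continue
                candidates.append(
                    (
                        chrom,
                        start,
                        end,
                        s,
                        float(lo[start:end].mean()),
                        float(hi[start:end].mean()),
                    )
                )
    if not candidates:
        return []

    p_int = np.empty(len(candidates))
    for i, (chrom, start, end, s, lm, hm) in enumerate(candidates):
        x = int(round(low_track.values[chrom][start:end].sum() / counts_scale))
        y = int(round(high_track.values[chrom][start:end].sum() / counts_scale))
        p_int[i] = stats.binomtest(x, x + y, 0.5).pvalue if x + y > 0 else 1.0
    q = _bh_fdr_padded(p_int, n_tests)

    sites = [
        DifferentialSite(
            chrom=chrom,
            start=start,
            end=end,
            direction=HYPER if s > 0 else INACCESSIBLE,
            p_value=float(p),
            q_value=float(qv),
            low_mean=lm,
            high_mean=hm,
        )
        for (chrom, start, end, s, lm, hm), p, qv in zip(candidates, p_int, q)
        if qv < fdr
    ]
    sites.sort(key=lambda s: (s.chrom, s.start))
    return sites


def _overlaps_any(
    chrom: str, start: int, end: int, features: list[tuple[str, int, int]]
) -> bool:
    return any(c == chrom and s < end and start < e for c, s, e in features)


def overlap_enrichment(
    sites: list[DifferentialSite],
    features: list[tuple[str, int, int]],
    universe: dict[str, int] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Fisher's exact test of direction vs >= 1 bp feature overlap.

    Rows of the 2x2 table: hyper-accessible / inaccessible sites; columns:
    overlapping / not overlapping the feature set.  Returns (odds_ratio,
    p_value, table).
    """
    if not sites or not features:
        raise ValueError("site and feature lists must be non-empty")
    if universe is not None:
        for c, s, e in features:
            if c in universe and e > universe[c]:
                raise ValueError(f"feature [{s}, {e}) outside {c}")
    table = np.zeros((2, 2), dtype=np.int64)
    for site in sites:
        row = 0 if site.direction == HYPER else 1
        col = 0 if _overlaps_any(site.chrom, site.start, site.end, features) else 1
        table[row, col] += 1
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("degenerate contingency table; reporting p = 1")
        return float("nan"), 1.0, table
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def write_sites_bed(
    sites: list[DifferentialSite], path: str, header: str | None = None
) -> None:
    """BED6+2: name carries the direction, extra columns p and q."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for s in sites:
            score = int(min(1000, -10 * np.log10(max(s.q_value, 1e-100))))
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.direction}\t{score}\t.\t"
                f"{s.p_value:.3g}\t{s.q_value:.3g}\n"
            )
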
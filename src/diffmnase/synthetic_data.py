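"""Genome-scale synthetic inputs for the analysis pipeline.

Generates a FASTA genome with GC-varying domains and regularly spaced
nucleosome dyads, derives per-site cleavage weight maps (with a
condition-asymmetric AT sensitivity that reproduces the GC bias of complete
digestion), digests the genome tile by tile with the array model, and emits
fragments, mappability, CNV segments and a ground-truth bundle.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import genomeio
from .array_simulator import LINKER_TO_NUC_RATIO, _sample_cut_indices
from .fragment_processing import FragmentRecord

__all__ = [
    "Domain",
    "GenomeSpec",
    "SiteMap",
    "TruthSet",
    "generate_genome",
    "choose_hyper_dyads",
    "derive_cleavage_weights",
    "simulate_fragments",
    "emit_truth_bundle",
    "build_truth",
]

#: cut events per 101-site (~9 kb) tile, by digestion condition
CUTS_PER_TILE = {"low": 20, "high": 70}
REFERENCE_TILE_SITES = 101
AT_FRACTION_THRESHOLD = 0.6
AT_NUC_MULTIPLIER = 2.0
FRAGILE_NUC_MULTIPLIER = 4.0
HYPER_LINKER_MULTIPLIER = 1.2
MONO_LEN_RANGE = (145, 195)
DI_LEN_RANGE = (260, 480)
TILE_LEN = 9000


@dataclass(frozen=True)
class Domain:
    start: int
    end: int
    gc: float
    compaction: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"domain gc must lie in (0, 1), got {self.gc}")
        if self.compaction <= 0:
            raise ValueError("compaction multiplier must be > 0")
        if self.end <= self.start:
            raise ValueError(f"invalid domain [{self.start}, {self.end})")


@dataclass
class GenomeSpec:
    chromosomes: list[tuple[str, int]]
    domains: dict[str, list[Domain]] = field(default_factory=dict)
    nucleosome_spacing: int = 180
    periodic_positioning: bool = False
    seed: int = 0
    n_hyper_sites: int = 0
    cnv_segments: list[tuple[str, int, int, float]] = field(default_factory=list)
    masked_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        for name, size in self.chromosomes:
            if size <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            doms = self.domains.setdefault(
                name, [Domain(0, size, 0.5, label="default")]
            )
            doms = sorted(doms, key=lambda d: d.start)
            if doms[0].start != 0 or doms[-1].end != size:
                raise ValueError(f"domains must tile chromosome {name}")
            for a, b in zip(doms, doms[1:]):
                if a.end != b.start:
                    raise ValueError(f"domains must tile {name} without gaps/overlap")
            self.domains[name] = doms
        for chrom, start, end, _cn in self.cnv_segments:
            if end > sizes[chrom]:
                raise ValueError("CNV segment outside chromosome")


@dataclass
class SiteMap:
    """Per-chromosome candidate cleavage sites for one digestion condition."""

    condition: str
    positions: dict[str, np.ndarray]
    is_nucleosome: dict[str, np.ndarray]
    weights: dict[str, np.ndarray]


@dataclass
class TruthSet:
    dyads: dict[str, np.ndarray]
    hyper_sites: list[tuple[str, int, int]]
    compact_domains: list[tuple[str, int, int]]
    cnv_segments: list[tuple[str, int, int, float]]
    params: dict


def _domain_gc_profile(domains: Sequence[Domain], size: int) -> np.ndarray:
    prob = np.empty(size)
    for d in domains:
        prob[d.start : d.end] = d.gc
    return prob


def generate_genome(
    spec: GenomeSpec,
) -> tuple[dict[str, str], dict[str, np.ndarray]]:
    """Draw an i.i.d. genome at each domain's GC fraction and place dyads.

    Dyads sit every nucleosome_spacing bp with +-5 bp jitter.  With
    periodic_positioning the per-base G/C probability around each dyad is
    modulated with period 10, planting the W/S dinucleotide phase of
    nucleosomal DNA.
    """
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    dyads: dict[str, np.ndarray] = {}
    for name, size in spec.chromosomes:
        gc_prob = _domain_gc_profile(spec.domains[name], size)

        spacing = spec.nucleosome_spacing
        n_dyads = max((size - spacing) // spacing, 0)
        base = spacing // 2 + spacing * np.arange(n_dyads)
        jitter = rng.integers(-5, 6, size=n_dyads)
        d = np.clip(base + jitter, 75, max(size - 76, 75))
        dyads[name] = d.astype(np.int64)

        if spec.periodic_positioning and n_dyads:
            offsets = np.arange(-73, 74)
            mod = 0.20 * np.cos(2 * np.pi * offsets / 10.0)
            idx = (d[:, None] + offsets[None, :]).ravel()
            add = np.tile(mod, n_dyads)
            ok = (idx >= 0) & (idx < size)
            gc_prob = gc_prob.copy()
            np.add.at(gc_prob, idx[ok], add[ok])
            np.clip(gc_prob, 0.05, 0.95, out=gc_prob)

        strong = rng.random(size) < gc_prob  # G or C
        pick = rng.random(size) < 0.5
        codes = np.where(
            strong,
            np.where(pick, ord("G"), ord("C")),
            np.where(pick, ord("A"), ord("T")),
        ).astype(np.uint8)
        genome[name] = codes.tobytes().decode("ascii")
    return genome, dyads


def choose_hyper_dyads(
    dyads: Mapping[str, np.ndarray],
    n: int,
    rng: np.random.Generator,
    min_sep: int = 2000,
    edge_margin: int = 10000,
) -> list[tuple[str, int]]:
    """Pick n dyads (away from chromosome ends) to plant as fragile,
    hyper-accessible nucleosomes.

    Plants are spread evenly across the genome (one per equal-sized stratum,
    jittered within it) so that plant density does not itself become a
    domain-scale signal.
    """
    pool = [
        (chrom, int(p))
        for chrom, d in sorted(dyads.items())
        for p in d
        if edge_margin <= p <= d[-1] - edge_margin + d[0]
    ]
    if len(pool) < n:
        raise ValueError(f"could not place {n} separated hyper sites")
    stratum = len(pool) / n
    chosen: list[tuple[str, int]] = []
    for k in range(n):
        lo, hi = int(k * stratum), int((k + 1) * stratum)
        for idx in rng.permutation(hi - lo):
            chrom, p = pool[lo + idx]
            if all(c != chrom or abs(p - q) >= min_sep for c, q in chosen):
                chosen.append((chrom, p))
                break
        else:
            raise ValueError(f"could not place {n} separated hyper sites")
    return sorted(chosen)


def _at_fraction_at(genome_seq: str, centers: np.ndarray, footprint: int = 150) -> np.ndarray:
    arr = np.frombuffer(genome_seq.encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    csum = np.concatenate(([0], np.cumsum(is_at)))
    half = footprint // 2
    starts = np.clip(centers - half, 0, arr.size)
    ends = np.clip(centers - half + footprint, 0, arr.size)
    width = np.maximum(ends - starts, 1)
    return (csum[ends] - csum[starts]) / width


def derive_cleavage_weights(
    genome: Mapping[str, str],
    dyads: Mapping[str, np.ndarray],
    spec: GenomeSpec,
    condition: str,
    hyper_dyads: Sequence[tuple[str, int]] = (),
) -> SiteMap:
    """Build the per-site weight map for one digestion condition.

    Linker sites lie midway between adjacent dyads (weight 10 x domain
    compaction); nucleosome sites at dyads (weight 1).  Under the high
    condition, nucleosomes whose 150-bp footprint exceeds 60% AT are doubled
    (the sequence sensitivity that creates the GC bias of complete
    digestion).  Planted hyper sites get nucleosome weight x4 and flanking
    linker weight x1.2 in both conditions.
    """
    if condition not in ("low", "high"):
        raise ValueError(f"condition must be 'low' or 'high', got {condition!r}")
    sizes = dict(spec.chromosomes)
    hyper_by_chrom: dict[str, set[int]] = {}
    for chrom, pos in hyper_dyads:
        hyper_by_chrom.setdefault(chrom, set()).add(int(pos))

    positions: dict[str, np.ndarray] = {}
    is_nuc: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    for chrom, d in dyads.items():
        size = sizes[chrom]
        if np.any(d < 0) or np.any(d >= size):
            raise ValueError(f"dyad outside chromosome {chrom}")
        d = np.sort(np.asarray(d, dtype=np.int64))
        m = d.size
        spacing = spec.nucleosome_spacing
        linkers = np.empty(m + 1, dtype=np.int64)
        linkers[1:-1] = (d[:-1] + d[1:]) // 2
        linkers[0] = max(d[0] - spacing // 2, 0)
        linkers[-1] = min(d[-1] + spacing // 2, size - 1)

        pos = np.empty(2 * m + 1, dtype=np.int64)
        pos[0::2] = linkers
        pos[1::2] = d
        nuc_mask = np.zeros(2 * m + 1, dtype=bool)
        nuc_mask[1::2] = True

        w = np.ones(2 * m + 1)
        # linker weights: 10 x compaction of the containing domain
        doms = spec.domains[chrom]
        dom_ends = np.array([dd.end for dd in doms])
        dom_comp = np.array([dd.compaction for dd in doms])
        comp = dom_comp[np.searchsorted(dom_ends, linkers, side="right")]
        w[0::2] = LINKER_TO_NUC_RATIO * comp

        if condition == "high":
            at_frac = _at_fraction_at(genome[chrom], d)
            w[1::2] = np.where(at_frac > AT_FRACTION_THRESHOLD, AT_NUC_MULTIPLIER, 1.0)

        for hp in sorted(hyper_by_chrom.get(chrom, ())):
            k = int(np.searchsorted(d, hp))
            if k >= m or d[k] != hp:
                raise ValueError(f"hyper site {chrom}:{hp} is not a dyad")
            w[2 * k + 1] *= FRAGILE_NUC_MULTIPLIER
            w[2 * k] *= HYPER_LINKER_MULTIPLIER
            w[2 * k + 2] *= HYPER_LINKER_MULTIPLIER

        positions[chrom] = pos
        is_nuc[chrom] = nuc_mask
        weights[chrom] = w
    return SiteMap(condition=condition, positions=positions, is_nucleosome=is_nuc, weights=weights)


def _digest_tile(
    pos: np.ndarray,
    weight: np.ndarray,
    nuc_mask: np.ndarray,
    n_cuts: int,
    n_instances: int,
    rng: np.random.Generator,
    core: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Digest one tile n_instances times; return dyad midpoints of mono
    fragments and midpoints of di fragments whose centre lies in the core."""
    pref = np.concatenate(([0], np.cumsum(nuc_mask)))
    pos_nuc = pos[nuc_mask]
    idx = _sample_cut_indices(weight, n_cuts, n_instances, rng)
    i, j = idx[:, :-1], idx[:, 1:]
    n_between = pref[j] - pref[i + 1]
    rank = pref[i + 1]

    mono_sel = n_between == 1
    mono_mids = pos_nuc[rank[mono_sel]]
    mono_mids = mono_mids[(mono_mids >= core[0]) & (mono_mids < core[1])]

    di_sel = n_between == 2
    r = rank[di_sel]
    di_mids = (pos_nuc[r] + pos_nuc[r + 1]) // 2
    di_mids = di_mids[(di_mids >= core[0]) & (di_mids < core[1])]
    return mono_mids, di_mids


def _tiles_for_chrom(pos: np.ndarray, size: int) -> list[tuple[int, int, int, int]]:
    """Half-overlapping 9 kb tiles: (site_lo, site_hi, core_start, core_end).
    Cores are the central half-tiles and tile the chromosome exactly once."""
    step = TILE_LEN // 2
    quarter = TILE_LEN // 4
    tiles = []
    start = -quarter
    while start < size:
        t0, t1 = start, start + TILE_LEN
        lo = int(np.searchsorted(pos, max(t0, 0), side="left"))
        hi = int(np.searchsorted(pos, min(t1, size), side="left"))
        core_start = 0 if start <= 0 else t0 + quarter
        core_end = size if t1 + quarter >= size else t0 + quarter + step
        if hi - lo >= 4:
            tiles.append((lo, hi, core_start, core_end))
        start += step
    return tiles


def simulate_fragments(
    sites: SiteMap,
    sizes: Mapping[str, int],
    n_fragments: int,
    seed: int,
    cls: str = "mono",
) -> list[FragmentRecord]:
    """Digest the genome tile by tile until exactly n_fragments of the
    requested class have been collected.

    Mono fragments arise from consecutive cuts spanning exactly one
    nucleosome, di fragments from cuts spanning two (internal linker uncut).
    Reported lengths are jittered uniformly within the class gate so the
    size-selection logic downstream is exercised.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if cls not in ("mono", "di"):
        raise ValueError(f"unknown fragment class {cls!r}")
    rng = np.random.default_rng(seed)
    base_cuts = CUTS_PER_TILE[sites.condition]

    mids_parts: list[np.ndarray] = []
    chrom_parts: list[np.ndarray] = []
    chrom_names = list(sites.positions)
    chrom_codes = {c: k for k, c in enumerate(chrom_names)}

    tile_info = []
    for chrom in chrom_names:
        pos = sites.positions[chrom]
        for lo, hi, c0, c1 in _tiles_for_chrom(pos, sizes[chrom]):
            n_sites = hi - lo
            n_cuts = int(np.clip(round(base_cuts * n_sites / REFERENCE_TILE_SITES), 2, n_sites))
            tile_info.append((chrom, lo, hi, c0, c1, n_cuts))

    total = 0
    instances = 8  # pilot pass to estimate per-tile yield
    max_passes = 60
    for _ in range(max_passes):
        got = 0
        for chrom, lo, hi, c0, c1, n_cuts in tile_info:
            mono_mids, di_mids = _digest_tile(
                sites.positions[chrom][lo:hi],
                sites.weights[chrom][lo:hi],
                sites.is_nucleosome[chrom][lo:hi],
                n_cuts,
                instances,
                rng,
                (c0, c1),
            )
            mids = mono_mids if cls == "mono" else di_mids
            if mids.size:
                mids_parts.append(mids)
                chrom_parts.append(np.full(mids.size, chrom_codes[chrom], dtype=np.int32))
                got += mids.size
        total += got
        if total >= n_fragments:
            break
        if got == 0:
            instances *= 4
            continue
        deficit = n_fragments - total
        # `got` fragments came from `instances` digestions of every tile
        instances = int(np.ceil(1.1 * deficit * instances / got)) + 1
        instances = min(max(instances, 1), 4096)
    if total < n_fragments:
        raise RuntimeError(
            f"collected only {total}/{n_fragments} {cls} fragments; "
            "weights may make this class too rare"
        )

    mids = np.concatenate(mids_parts)
    chroms = np.concatenate(chrom_parts)
    take = rng.permutation(mids.size)[:n_fragments]
    mids, chroms = mids[take], chroms[take]

    lo_len, hi_len = MONO_LEN_RANGE if cls == "mono" else DI_LEN_RANGE
    lengths = rng.integers(lo_len, hi_len + 1, size=n_fragments)
    starts = mids - lengths // 2
    ends = starts + lengths

    order = np.lexsort((starts, chroms))
    records = []
    for k in order:
        chrom = chrom_names[chroms[k]]
        size = sizes[chrom]
        s = int(max(starts[k], 0))
        e = int(min(ends[k], size))
        records.append(FragmentRecord(chrom, s, e, sites.condition))
    return records


def build_truth(spec: GenomeSpec) -> tuple[dict[str, str], dict[str, SiteMap], TruthSet]:
    """Generate the genome, plant hyper sites and derive both condition
    weight maps; return (genome, {condition: SiteMap}, truth)."""
    genome, dyads = generate_genome(spec)
    rng = np.random.default_rng(spec.seed + 1)
    hyper = (
        choose_hyper_dyads(dyads, spec.n_hyper_sites, rng)
        if spec.n_hyper_sites
        else []
    )
    site_maps = {
        cond: derive_cleavage_weights(genome, dyads, spec, cond, hyper)
        for cond in ("low", "high")
    }
    compact = [
        (chrom, d.start, d.end)
        for chrom, doms in spec.domains.items()
        for d in doms
        if d.compaction != 1.0
    ]
    truth = TruthSet(
        dyads=dyads,
        hyper_sites=[(c, p - 100, p + 100) for c, p in hyper],
        compact_domains=compact,
        cnv_segments=list(spec.cnv_segments),
        params={
            "seed": spec.seed,
            "nucleosome_spacing": spec.nucleosome_spacing,
            "periodic_positioning": spec.periodic_positioning,
            "cuts_per_tile": CUTS_PER_TILE,
            "at_fraction_threshold": AT_FRACTION_THRESHOLD,
            "at_nuc_multiplier": AT_NUC_MULTIPLIER,
            "fragile_nuc_multiplier": FRAGILE_NUC_MULTIPLIER,
            "hyper_linker_multiplier": HYPER_LINKER_MULTIPLIER,
        },
    )
    return genome, site_maps, truth


def emit_truth_bundle(spec: GenomeSpec, truth: TruthSet, outdir: str) -> dict[str, str]:
    """Write the ground-truth bundle: planted-site BEDs, a constant-1
    mappability bedGraph with masked intervals at 0, CNV segments and a
    machine-readable manifest.  Returns the written paths."""
    genomeio.ensure_dir(outdir)
    paths = {}

    paths["hyper_sites"] = os.path.join(outdir, "hyper_sites.bed")
    genomeio.write_bed(truth.hyper_sites, paths["hyper_sites"])

    paths["compact_domains"] = os.path.join(outdir, "compact_domains.bed")
    genomeio.write_bed(truth.compact_domains, paths["compact_domains"])

    paths["cnv_segments"] = os.path.join(outdir, "cnv_segments.bed")
    genomeio.write_bed(
        [(c, s, e, cn) for c, s, e, cn in truth.cnv_segments], paths["cnv_segments"]
    )

    paths["dyads"] = os.path.join(outdir, "dyads.bed")
    genomeio.write_bed(
        ((c, int(p), int(p) + 1) for c, d in truth.dyads.items() for p in d),
        paths["dyads"],
    )

    paths["mappability"] = os.path.join(outdir, "mappability.bedGraph")
    sizes = dict(spec.chromosomes)
    with open(paths["mappability"], "w") as fh:
        masked = sorted(spec.masked_intervals)
        for chrom, size in spec.chromosomes:
            cursor = 0
            for mc, ms, me in masked:
                if mc != chrom:
                    continue
                if ms > cursor:
                    fh.write(f"{chrom}\t{cursor}\t{ms}\t1\n")
                fh.write(f"{chrom}\t{ms}\t{me}\t0\n")
                cursor = me
            if cursor < size:
                fh.write(f"{chrom}\t{cursor}\t{size}\t1\n")

    paths["manifest"] = os.path.join(outdir, "manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "chromosomes": [[c, n] for c, n in spec.chromosomes],
                "domains": {
                    c: [
                        {
                            "start": d.start,
                            "end": d.end,
                            "gc": d.gc,
                            "compaction": d.compaction,
                            "label": d.label,
                        }
                        for d in doms
                    ]
                    for c, doms in spec.domains.items()
                },
                "hyper_sites": [list(x) for x in truth.hyper_sites],
                "compact_domains": [list(x) for x in truth.compact_domains],
                "cnv_segments": [list(x) for x in truth.cnv_segments],
                "masked_intervals": [list(x) for x in spec.masked_intervals],
                "params": truth.params,
            },
            fh,
            indent=1,
        )
    return paths
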
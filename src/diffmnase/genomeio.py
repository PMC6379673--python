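"""Small text-format helpers shared across the pipeline.

Plain-text genomics formats only: FASTA (via pyfaidx on disk, plain dicts in
memory), BED, bedGraph, chrom.sizes.  Coordinates are 0-based half-open
throughout.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np


def write_fasta(genome: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_genome(path: str) -> dict[str, str]:
    """Load a FASTA file into an in-memory {name: sequence} dict."""
    from pyfaidx import Fasta

    fa = Fasta(path, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def chrom_sizes(genome: Mapping[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in genome.items()}


def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    return sizes


def write_bed(
    intervals: Iterable[tuple], path: str, header: str | None = None
) -> None:
    """Write (chrom, start, end, *extra) tuples as BED."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for rec in intervals:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_bed(path: str) -> list[tuple[str, int, int, list[str]]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            out.append((parts[0], start, end, parts[3:]))
    return out


def write_bedgraph(
    values_by_chrom: Mapping[str, np.ndarray],
    path: str,
    header: str | None = None,
) -> None:
    """Write per-base value arrays as run-length-merged bedGraph."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for chrom, values in values_by_chrom.items():
            values = np.asarray(values)
            if values.size == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(
    path: str, sizes: Mapping[str, int], default: float = 0.0
) -> dict[str, np.ndarray]:
    """Expand a bedGraph into per-base arrays over the given chromosomes."""
    arrays = {name: np.full(size, default) for name, size in sizes.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            if chrom in arrays:
                arrays[chrom][int(start) : int(end)] = float(value)
    return arrays


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
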
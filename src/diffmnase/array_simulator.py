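"""Stochastic in silico nuclease digestion of a regular nucleosome array.

A template strand carries one candidate cleavage site per linker and one per
nucleosome.  Digestion draws a fixed number of cut positions per template
instance by weighted sampling without replacement, keeps fragments of an exact
mono-nucleosomal length, trims both ends and accumulates per-base coverage.
Scenario weight maps model compacted domains, nuclease-sensitive (AT-rich)
nucleosomes and fragile, hyper-accessible sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CleavageSite",
    "ArrayTemplate",
    "DigestParams",
    "CoverageProfile",
    "SCENARIOS",
    "build_template",
    "apply_scenario",
    "sample_cuts",
    "fragments_from_cuts",
    "run_digestion",
    "condition_log_ratio",
]

LINKER = "linker"
NUCLEOSOME = "nucleosome"

#: relative cleavage probability of linker DNA vs nucleosomal DNA
LINKER_TO_NUC_RATIO = 10.0


@dataclass(frozen=True)
class CleavageSite:
    """One candidate double-strand cleavage position on the template."""

    position: int
    kind: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (LINKER, NUCLEOSOME):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError(f"site weight must be > 0, got {self.weight}")
        if self.position < 0:
            raise ValueError(f"negative site position {self.position}")


@dataclass(frozen=True)
class ArrayTemplate:
    """Ordered candidate cleavage sites on a regular nucleosome array."""

    length: int
    n_nucleosomes: int
    nuc_len: int
    linker_len: int
    sites: tuple[CleavageSite, ...]

    def __post_init__(self) -> None:
        pos = self.positions
        if len(self.sites) != 2 * self.n_nucleosomes + 1:
            raise ValueError("site count must be 2*n_nucleosomes + 1")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("site positions must be strictly increasing")
        if self.sites[0].position != 0 or self.sites[-1].position != self.length:
            raise ValueError("template must start at 0 and end at its length")
        kinds = [s.kind for s in self.sites]
        expected = [LINKER if i % 2 == 0 else NUCLEOSOME for i in range(len(kinds))]
        if kinds != expected:
            raise ValueError("site kinds must alternate linker/nucleosome/linker")

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=np.int64)

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.sites], dtype=np.float64)

    @property
    def kinds(self) -> list[str]:
        return [s.kind for s in self.sites]

    def linker_sites(self) -> list[CleavageSite]:
        return [s for s in self.sites if s.kind == LINKER]

    def nucleosome_sites(self) -> list[CleavageSite]:
        return [s for s in self.sites if s.kind == NUCLEOSOME]

    def nucleosome_footprints(self) -> list[tuple[int, int]]:
        """Half-open per-nucleosome footprint intervals centred on each
        nucleosome site, clipped to the template."""
        half = self.nuc_len // 2
        out = []
        for s in self.nucleosome_sites():
            start = max(0, s.position - half)
            end = min(self.length, s.position + (self.nuc_len - half))
            out.append((start, end))
        return out


@dataclass(frozen=True)
class DigestParams:
    """Parameters of one digestion run."""

    n_cuts: int
    target_fragments: int
    keep_len: int = 180
    trim: int = 30
    seed: int = 0
    max_templates: int = 10**7

    def __post_init__(self) -> None:
        if self.n_cuts < 2:
            raise ValueError("need at least 2 cut events per template")
        if self.keep_len <= 2 * self.trim:
            raise ValueError("keep_len must exceed 2*trim")
        if self.target_fragments < 1:
            raise ValueError("target_fragments must be >= 1")


@dataclass
class CoverageProfile:
    """Per-base fragment coverage accumulated over a digestion run."""

    values: np.ndarray
    n_fragments: int
    condition: str
    seed: int | None = None
    trimmed_len: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")


def build_template(
    n_nucleosomes: int, nuc_len: int, linker_len: int, shift: int
) -> ArrayTemplate:
    """Construct the candidate cleavage-site index of a regular array.

    Sites sit on a grid of spacing (nuc_len + linker_len) / 2, alternating
    linker (even grid index) and nucleosome (odd grid index).  Odd-numbered
    nucleosome sites (the 1st, 3rd, ...) are displaced by -shift so that
    nucleosome-to-nucleosome distances alternate around the repeat length.
    All weights start at 1.
    """
    if n_nucleosomes < 1:
        raise ValueError("n_nucleosomes must be >= 1")
    if nuc_len <= 0 or linker_len <= 0:
        raise ValueError("nuc_len and linker_len must be > 0")
    repeat = nuc_len + linker_len
    if repeat % 2 != 0:
        raise ValueError(
            f"nuc_len + linker_len = {repeat} is odd; grid spacing must be integral"
        )
    spacing = repeat // 2
    if not 0 <= shift < spacing:
        raise ValueError(f"shift must lie in [0, {spacing})")

    length = n_nucleosomes * repeat
    sites: list[CleavageSite] = []
    for i in range(2 * n_nucleosomes + 1):
        pos = i * spacing
        if i % 2 == 0:
            sites.append(CleavageSite(pos, LINKER))
        else:
            nuc_index = (i + 1) // 2  # 1-based nucleosome number
            if nuc_index % 2 == 1:
                pos -= shift
            sites.append(CleavageSite(pos, NUCLEOSOME))
    positions = [s.position for s in sites]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("shift makes site positions non-monotone")
    return ArrayTemplate(
        length=length,
        n_nucleosomes=n_nucleosomes,
        nuc_len=nuc_len,
        linker_len=linker_len,
        sites=tuple(sites),
    )


def _central_range(n: int, count: int) -> tuple[int, int]:
    """1-based inclusive index range of the `count` central items among n."""
    start = (n - count) // 2 + 1
    return start, start + count - 1


def _scenario_rules(name: str, template: ArrayTemplate) -> list[dict]:
    n = template.n_nucleosomes
    if name == "uniform":
        return []
    if name == "compact_center":
        n_center = max(1, n // 2)
        lo, hi = _central_range(n, n_center)
        # linkers flanking the central nucleosomes: indices lo .. hi+1
        return [
            {"kind": LINKER, "start": lo, "end": hi + 1, "multiplier": 0.8},
        ]
    if name == "at_rich_center":
        n_center = max(1, n // 2)
        lo, hi = _central_range(n, n_center)
        return [
            {"kind": NUCLEOSOME, "start": lo, "end": hi, "multiplier": 2.0},
        ]
    if name == "fragile_site":
        center = (n + 1) // 2
        return [
            {"kind": NUCLEOSOME, "start": center, "end": center, "multiplier": 4.0},
            {"kind": LINKER, "start": center, "end": center + 1, "multiplier": 1.2},
        ]
    raise ValueError(f"unknown scenario {name!r}")


SCENARIOS = ("uniform", "compact_center", "at_rich_center", "fragile_site")


def apply_scenario(
    template: ArrayTemplate,
    scenario: str | Sequence[Mapping] = "uniform",
) -> ArrayTemplate:
    """Return a template with scenario weights applied.

    The baseline linker:nucleosome cleavage ratio of 10:1 is set here; the
    scenario then multiplies site weights by kind over 1-based inclusive
    index ranges.  A scenario is either a named preset or a sequence of rules
    ``{kind, start, end, multiplier}``.
    """
    if isinstance(scenario, str):
        rules = _scenario_rules(scenario, template)
    else:
        rules = [dict(r) for r in scenario]

    weights = np.where(
        np.array([s.kind == LINKER for s in template.sites]),
        LINKER_TO_NUC_RATIO,
        1.0,
    )
    kind_indices = {LINKER: [], NUCLEOSOME: []}
    for i, s in enumerate(template.sites):
        kind_indices[s.kind].append(i)

    for rule in rules:
        kind = rule["kind"]
        if kind not in kind_indices:
            raise ValueError(f"unknown site kind {kind!r} in scenario rule")
        mult = float(rule["multiplier"])
        if mult <= 0:
            raise ValueError(f"scenario multiplier must be > 0, got {mult}")
        idx = kind_indices[kind]
        start, end = int(rule["start"]), int(rule["end"])
        if not (1 <= start <= end <= len(idx)):
            raise ValueError(
                f"scenario index range {start}..{end} out of bounds for "
                f"{len(idx)} {kind} sites"
            )
        for j in range(start - 1, end):
            weights[idx[j]] *= mult

    new_sites = tuple(
        replace(s, weight=s.weight * w) for s, w in zip(template.sites, weights)
    )
    return replace(template, sites=new_sites)


def _sample_cut_indices(
    weights: np.ndarray, n_cuts: int, n_templates: int, rng: np.random.Generator
) -> np.ndarray:
    """Weighted sampling without replacement for a batch of template
    instances.

    Uses the exponential-sort construction: drawing the n_cuts smallest keys
    Exp(1)/w_i is distributionally identical to successive draws proportional
    to the remaining weights.  Returns an (n_templates, n_cuts) index matrix,
    sorted ascending within each row.
    """
    keys = rng.exponential(size=(n_templates, weights.size)) / weights
    if n_cuts >= weights.size:
        idx = np.argsort(keys, axis=1)[:, :n_cuts]
    else:
        idx = np.argpartition(keys, n_cuts, axis=1)[:, :n_cuts]
    return np.sort(idx, axis=1)


def sample_cuts(
    template: ArrayTemplate, n_cuts: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n_cuts distinct cut positions, weight-proportional without
    replacement, sorted ascending."""
    n_sites = len(template.sites)
    if n_cuts > n_sites:
        raise ValueError(f"n_cuts={n_cuts} exceeds {n_sites} candidate sites")
    idx = _sample_cut_indices(template.weights, n_cuts, 1, rng)[0]
    return template.positions[idx]


def fragments_from_cuts(
    positions: Sequence[int] | np.ndarray, keep_len: int
) -> list[tuple[int, int]]:
    """Assemble fragments between consecutive cuts and keep those whose
    length equals keep_len exactly."""
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size < 2:
        raise ValueError("need at least two cut positions")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("cut positions must be sorted strictly ascending")
    gaps = np.diff(pos)
    keep = np.flatnonzero(gaps == keep_len)
    return [(int(pos[i]), int(pos[i] + keep_len)) for i in keep]


def run_digestion(
    template: ArrayTemplate,
    params: DigestParams,
    condition: str = "",
    batch_size: int = 8192,
) -> CoverageProfile:
    """Digest template instances until target_fragments kept fragments of the
    exact mono-nucleosomal length have accumulated; trim both fragment ends
    and return per-base coverage.  Deterministic given the seed."""
    n_sites = len(template.sites)
    if params.n_cuts > n_sites:
        raise ValueError(f"n_cuts={params.n_cuts} exceeds {n_sites} sites")
    rng = np.random.default_rng(params.seed)
    positions = template.positions
    weights = template.weights
    kept_len = params.keep_len - 2 * params.trim

    delta = np.zeros(template.length + 1, dtype=np.float64)
    n_kept = 0
    n_templates_done = 0
    while n_kept < params.target_fragments:
        if n_templates_done >= params.max_templates:
            raise RuntimeError(
                f"digestion yielded {n_kept} fragments after "
                f"{n_templates_done} template instances (cap reached); "
                "the scenario may make keep_len fragments impossible"
            )
        b = min(batch_size, params.max_templates - n_templates_done)
        idx = _sample_cut_indices(weights, params.n_cuts, b, rng)
        cut_pos = positions[idx]
        gaps = np.diff(cut_pos, axis=1)
        starts = cut_pos[:, :-1][gaps == params.keep_len]
        n_templates_done += b
        if starts.size == 0:
            continue
        room = params.target_fragments - n_kept
        if starts.size > room:
            starts = starts[:room]
        np.add.at(delta, starts + params.trim, 1.0)
        np.add.at(delta, starts + params.keep_len - params.trim, -1.0)
        n_kept += starts.size

    values = np.cumsum(delta[:-1])
    return CoverageProfile(
        values=values,
        n_fragments=n_kept,
        condition=condition,
        seed=params.seed,
        trimmed_len=kept_len,
    )


def per_nucleosome_means(
    profile: CoverageProfile, template: ArrayTemplate
) -> np.ndarray:
    """Mean coverage over each nucleosome footprint."""
    vals = profile.values
    return np.array(
        [vals[s:e].mean() for s, e in template.nucleosome_footprints()]
    )


def condition_log_ratio(
    low: CoverageProfile,
    high: CoverageProfile,
    per: str = "base",
    template: ArrayTemplate | None = None,
    eps: float = 1.0,
) -> np.ndarray:
    """Signed log2 low/high coverage contrast after equal-mass scaling.

    eps counts are added to each profile before scaling so the ratio is
    defined everywhere.  per="nucleosome" averages the scaled coverage over
    each nucleosome footprint before taking the ratio (requires template).
    """
    if low.values.size != high.values.size:
        raise ValueError("profiles must cover templates of equal length")
    if low.values.size == 0:
        raise ValueError("empty coverage profiles")
    lo = low.values + eps
    hi = high.values + eps
    target = 0.5 * (lo.sum() + hi.sum())
    lo = lo * (target / lo.sum())
    hi = hi * (target / hi.sum())
    if per == "base":
        return np.log2(lo / hi)
    if per == "nucleosome":
        if template is None:
            raise ValueError("per='nucleosome' requires the template")
        foot = template.nucleosome_footprints()
        lo_m = np.array([lo[s:e].mean() for s, e in foot])
        hi_m = np.array([hi[s:e].mean() for s, e in foot])
        return np.log2(lo_m / hi_m)
    raise ValueError(f"unknown per={per!r}")
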
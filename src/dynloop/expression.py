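"""Expression profiles and their mapping to loop-formation affinities.

The simulator coarse-grains a chromosome into monomers of 150 kb of genomic
content.  Each monomer carries an expression level ``e_i`` (taken from a
binned expression profile) which is mapped onto an interaction affinity
``a_i``: the most highly expressed monomer receives the *minimum* affinity
``a_min`` and unexpressed monomers the *maximum* affinity ``a_max``.  The
rationale is that heavily transcribed chromatin is coated with transcription
machinery, which makes direct chromatin-chromatin contacts less likely.

This module reads tab-delimited expression tables (chrom / start / end /
value), bins them onto the monomer grid, synthesizes block-structured test
profiles, and performs the affinity mapping.  All genomic coordinates are
0-based, half-open; monomer ``i`` covers ``[i*bin, (i+1)*bin)`` base pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

#: genomic content of one monomer in base pairs
MONOMER_BP = 150_000

#: genomic content of one monomer in megabases
MONOMER_MB = MONOMER_BP / 1e6

__all__ = [
    "MONOMER_BP",
    "MONOMER_MB",
    "ExpressionProfile",
    "BinnedExpression",
    "AffinityProfile",
    "Region",
    "RegionSet",
    "read_expression_table",
    "write_expression_table",
    "bin_to_monomers",
    "synth_expression_profile",
    "affinity_profile",
    "linear_affinity_map",
    "read_regions_bed",
    "write_regions_bed",
]


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-bin expression levels for a single chromosome.

    ``bins`` is an ordered list of ``(start_bp, end_bp, level)`` tuples:
    sorted, non-overlapping, with ``start < end`` and finite levels >= 0.
    """

    chromosome_id: str
    bins: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end, level in self.bins:
            if start >= end:
                raise ValueError(f"empty or inverted bin [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"overlapping bins: bin starting at {start} overlaps "
                    f"previous bin ending at {prev_end}"
                )
            if not math.isfinite(level) or level < 0:
                raise ValueError(f"expression level must be finite and >= 0, got {level}")
            prev_end = end

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class BinnedExpression:
    """Expression levels on the monomer grid: one level per monomer."""

    levels: np.ndarray
    bin_size_bp: int = MONOMER_BP

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or self.levels.size < 2:
            raise ValueError("levels must be a 1-D vector with at least 2 monomers")
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")
        if not np.all(np.isfinite(self.levels)) or np.any(self.levels < 0):
            raise ValueError("levels must be finite and >= 0")

    @property
    def n_monomers(self) -> int:
        return int(self.levels.size)


@dataclass
class AffinityProfile:
    """Per-monomer loop-formation affinities, each within [a_min, a_max]."""

    affinities: np.ndarray
    a_min: float
    a_max: float

    def __post_init__(self) -> None:
        self.affinities = np.asarray(self.affinities, dtype=float)
        if not (0.0 <= self.a_min <= self.a_max <= 1.0):
            raise ValueError("need 0 <= a_min <= a_max <= 1")
        eps = 1e-12
        if np.any(self.affinities < self.a_min - eps) or np.any(
            self.affinities > self.a_max + eps
        ):
            raise ValueError("affinities outside [a_min, a_max]")

    @property
    def n_monomers(self) -> int:
        return int(self.affinities.size)


@dataclass(frozen=True)
class Region:
    """Half-open monomer interval [start, end) labelled 'high' or 'low'."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in ("high", "low"):
            raise ValueError(f"region label must be 'high' or 'low', got {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")


@dataclass
class RegionSet:
    """Highly/lowly expressed monomer regions used for region-specific observables."""

    regions: tuple[Region, ...]
    n_monomers: int | None = None

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        for label in ("high", "low"):
            ivs = sorted((r.start, r.end) for r in self.regions if r.label == label)
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping {label!r} regions [{s0},{e0}) and [{s1},{e1})")
        if self.n_monomers is not None:
            for r in self.regions:
                if r.end > self.n_monomers:
                    raise ValueError(f"region [{r.start},{r.end}) exceeds N={self.n_monomers}")

    def indices(self, label: str) -> np.ndarray:
        """Sorted monomer indices covered by regions with the given label."""
        idx: set[int] = set()
        for r in self.regions:
            if r.label == label:
                idx.update(range(r.start, r.end))
        return np.array(sorted(idx), dtype=np.intp)

    def has(self, label: str) -> bool:
        return any(r.label == label for r in self.regions)


# ---------------------------------------------------------------------------
# table I/O


def read_expression_table(path: str | Path, chromosome: str | None = None) -> ExpressionProfile:
    """Read a tab-delimited expression table (chrom, start, end, value).

    The table must have a header naming at least those four columns (any
    order, extra columns ignored).  If ``chromosome`` is None the table must
    contain a single chromosome.  Malformed rows raise with the 1-based file
    line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"chromosome", "start", "end", "value"}
    cols = {c.lower().strip(): c for c in df.columns}
    aliases = {"chrom": "chromosome", "chr": "chromosome", "level": "value",
               "expression": "value"}
    for alias, canon in aliases.items():
        if alias in cols and canon not in cols:
            cols[canon] = cols[alias]
    missing = required - set(cols)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    chrom_col = df[cols["chromosome"]].astype(str)
    if chromosome is None:
        uniq = chrom_col.unique()
        if len(uniq) != 1:
            raise ValueError(
                f"{path}: table holds {len(uniq)} chromosomes; pass chromosome=..."
            )
        chromosome = str(uniq[0])
    mask = chrom_col == chromosome
    if not mask.any():
        raise ValueError(f"{path}: no rows for chromosome {chromosome!r}")

    rows = []
    # header is line 1, first data row line 2
    for pos, (idx, row) in enumerate(df[mask].iterrows()):
        line_no = int(idx) + 2
        try:
            start = int(row[cols["start"]])
            end = int(row[cols["end"]])
            level = float(row[cols["value"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {line_no}: {exc}") from None
        if not math.isfinite(level) or level < 0:
            raise ValueError(
                f"{path}: line {line_no}: expression level must be finite and >= 0"
            )
        if start >= end:
            raise ValueError(f"{path}: line {line_no}: empty or inverted bin [{start},{end})")
        rows.append((start, end, level))
    rows.sort()
    return ExpressionProfile(chromosome_id=chromosome, bins=tuple(rows))


def write_expression_table(
    profile: ExpressionProfile | BinnedExpression,
    path: str | Path,
    chromosome: str = "chrSYN",
) -> None:
    """Write an expression profile as a tab-delimited (chromosome, start, end, value) table."""
    if isinstance(profile, BinnedExpression):
        bins = [
            (i * profile.bin_size_bp, (i + 1) * profile.bin_size_bp, lvl)
            for i, lvl in enumerate(profile.levels)
        ]
        chrom = chromosome
    else:
        bins = list(profile.bins)
        chrom = profile.chromosome_id
    df = pd.DataFrame(bins, columns=["start", "end", "value"])
    df.insert(0, "chromosome", chrom)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# binning


def bin_to_monomers(
    profile: ExpressionProfile,
    chrom_length_bp: int,
    bin_size_bp: int = MONOMER_BP,
) -> BinnedExpression:
    """Project an expression profile onto the monomer grid.

    N = ceil(chrom_length_bp / bin_size_bp).  Each monomer's level is the
    length-weighted mean of the source bins overlapping it; monomers with no
    overlapping data get level 0 (treated as unexpressed).
    """
    if chrom_length_bp <= 0:
        raise ValueError("chrom_length_bp must be positive")
    n = math.ceil(chrom_length_bp / bin_size_bp)
    weighted = np.zeros(n)
    covered = np.zeros(n)
    for start, end, level in profile.bins:
        start = max(start, 0)
        end = min(end, chrom_length_bp)
        if start >= end:
            continue
        m0 = start // bin_size_bp
        m1 = (end - 1) // bin_size_bp
        for m in range(m0, m1 + 1):
            lo = max(start, m * bin_size_bp)
            hi = min(end, (m + 1) * bin_size_bp)
            if hi > lo:
                weighted[m] += level * (hi - lo)
                covered[m] += hi - lo
    levels = np.divide(weighted, covered, out=np.zeros(n), where=covered > 0)
    return BinnedExpression(levels=levels, bin_size_bp=bin_size_bp)


# ---------------------------------------------------------------------------
# synthetic profiles


def synth_expression_profile(
    n_monomers: int,
    blocks: Sequence[tuple[int, int, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    bin_size_bp: int = MONOMER_BP,
) -> tuple[BinnedExpression, RegionSet]:
    """Generate a block-structured expression profile with matched regions.

    ``blocks`` are non-overlapping half-open monomer intervals
    ``(start, end, mean_level)``; monomers outside every block get level 0.
    Gaussian noise with standard deviation ``noise_sd`` is added and the
    result truncated at zero.  Blocks whose mean exceeds the median of the
    generated profile are labelled 'high', the rest 'low'.  Deterministic
    given ``seed``.
    """
    if n_monomers < 2:
        raise ValueError("need at least 2 monomers")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ivs = sorted((int(s), int(e)) for s, e, _ in blocks)
    for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping blocks [{s0},{e0}) and [{s1},{e1})")
    levels = np.zeros(n_monomers)
    for s, e, mean in blocks:
        if not (0 <= s < e <= n_monomers):
            raise ValueError(f"block [{s},{e}) outside [0, {n_monomers})")
        if mean < 0:
            raise ValueError("block mean level must be >= 0")
        levels[int(s) : int(e)] = mean
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        levels = np.maximum(levels + rng.normal(0.0, noise_sd, n_monomers), 0.0)
    median = float(np.median(levels))
    regions = tuple(
        Region("high" if mean > median else "low", int(s), int(e)) for s, e, mean in blocks
    )
    return (
        BinnedExpression(levels=levels, bin_size_bp=bin_size_bp),
        RegionSet(regions=regions, n_monomers=n_monomers),
    )


# ---------------------------------------------------------------------------
# affinity mapping


def linear_affinity_map(levels: np.ndarray, a_min: float, a_max: float) -> np.ndarray:
    """Linear expression-to-affinity mapping.

    a_i = a_max - (a_max - a_min) * (e_i - e_min) / (e_max - e_min)

    so the monomer with the highest expression gets exactly ``a_min`` and the
    lowest (unexpressed) one exactly ``a_max``.
    """
    e_min = float(np.min(levels))
    e_max = float(np.max(levels))
    if e_max == e_min:
        if a_min != a_max:
            raise ValueError(
                "all expression levels identical: affinity mapping undefined "
                "unless a_min == a_max"
            )
        return np.full(levels.shape, a_min)
    return a_max - (a_max - a_min) * (levels - e_min) / (e_max - e_min)


def affinity_profile(
    binned: BinnedExpression,
    a_min: float = 0.01,
    a_max: float = 0.065,
    mapping: Callable[[np.ndarray, float, float], np.ndarray] = linear_affinity_map,
) -> AffinityProfile:
    """Map binned expression levels to per-monomer interaction affinities.

    Higher expression -> lower affinity (monotonically non-increasing).  The
    mapping function is pluggable; the default is linear between the two
    endpoint constraints.
    """
    if not (0.0 <= a_min <= a_max <= 1.0):
        raise ValueError("need 0 <= a_min <= a_max <= 1")
    aff = mapping(binned.levels, a_min, a_max)
    return AffinityProfile(affinities=np.clip(aff, a_min, a_max), a_min=a_min, a_max=a_max)


# ---------------------------------------------------------------------------
# BED region I/O (0-based half-open genomic coordinates)


def read_regions_bed(
    path: str | Path,
    n_monomers: int,
    bin_size_bp: int = MONOMER_BP,
) -> RegionSet:
    """Read a BED file of high/low regions and convert to monomer indices.

    The BED name field (column 4) must be 'high' or 'low'.  A monomer is
    assigned to a region if the region overlaps any part of it (any-overlap).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    regions = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {line_no}: need 4 BED columns (chrom start end name)")
            try:
                start_bp, end_bp = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from None
            label = parts[3].strip().lower()
            m0 = start_bp // bin_size_bp
            m1 = math.ceil(end_bp / bin_size_bp)
            m0 = max(0, m0)
            m1 = min(n_monomers, m1)
            if m1 > m0:
                regions.append(Region(label, m0, m1))
    return RegionSet(regions=tuple(regions), n_monomers=n_monomers)


def write_regions_bed(
    regions: RegionSet,
    path: str | Path,
    chromosome: str = "chrSYN",
    bin_size_bp: int = MONOMER_BP,
) -> None:
    with open(path, "w") as fh:
        for r in regions.regions:
            fh.write(f"{chromosome}\t{r.start * bin_size_bp}\t{r.end * bin_size_bp}\t{r.label}\n")
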
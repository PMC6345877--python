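"""Fixed-width genomic locus grid and interval/track containers.

Repli-Seq timing analysis runs on a genome tiled into fixed-width bins
("loci", 1 kb by default).  Every per-locus quantity in the package — read
densities, PNDV profiles, WA scores, methylation means, boolean mark
occupancy — lives on one shared :class:`LocusGrid`, so overlap and alignment
reduce to integer arithmetic on bin indices.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: chromosomes dropped from grids unless the caller overrides
DEFAULT_EXCLUDE = ("chrY", "chrM")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start: {self.chrom}:{self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


class LocusGrid:
    """Disjoint fixed-width bins tiling each chromosome.

    Parameters
    ----------
    chrom_sizes:
        Mapping chromosome name -> length in bp.  Order is preserved and
        defines locus ordering.
    bin_width:
        Bin width in bp (default 1000).  The terminal bin of a chromosome
        may be narrower; such bins are retained and flagged by
        :meth:`partial_mask`.
    exclude:
        Chromosome names to drop (default chrY and chrM).
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        bin_width: int = 1000,
        exclude: Sequence[str] = DEFAULT_EXCLUDE,
    ) -> None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        seen: dict[str, int] = {}
        for chrom, size in chrom_sizes.items():
            if chrom in seen:
                raise ValueError(f"duplicate chromosome name: {chrom}")
            size = int(size)
            if size <= 0:
                raise ValueError(f"non-positive size for chromosome {chrom}: {size}")
            seen[chrom] = size
        self.bin_width = int(bin_width)
        self.chrom_sizes: dict[str, int] = {
            c: s for c, s in seen.items() if c not in set(exclude)
        }
        if not self.chrom_sizes:
            raise ValueError("no chromosomes left after exclusion")
        self.chroms: list[str] = list(self.chrom_sizes)
        self._n_bins = np.array(
            [-(-self.chrom_sizes[c] // self.bin_width) for c in self.chroms],
            dtype=np.int64,
        )
        self._offsets = np.concatenate([[0], np.cumsum(self._n_bins)])
        self._chrom_index = {c: i for i, c in enumerate(self.chroms)}

    # ------------------------------------------------------------------ size

    @property
    def n_loci(self) -> int:
        return int(self._offsets[-1])

    def __len__(self) -> int:
        return self.n_loci

    def n_bins(self, chrom: str) -> int:
        return int(self._n_bins[self._chrom_index[chrom]])

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the global locus index covering one chromosome."""
        i = self._chrom_index[chrom]
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    # ----------------------------------------------------------------- index

    def locus_index(self, chrom: str, pos: int) -> int:
        """Global index of the locus containing base ``pos``."""
        if chrom not in self._chrom_index:
            raise KeyError(f"unknown chromosome: {chrom}")
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise ValueError(f"position {pos} outside {chrom} (len {self.chrom_sizes[chrom]})")
        i = self._chrom_index[chrom]
        return int(self._offsets[i]) + pos // self.bin_width

    def locus(self, index: int) -> GenomicInterval:
        """Inverse of :meth:`locus_index`: the bin at a global index."""
        if not (0 <= index < self.n_loci):
            raise IndexError(index)
        i = int(np.searchsorted(self._offsets, index, side="right")) - 1
        chrom = self.chroms[i]
        start = (index - int(self._offsets[i])) * self.bin_width
        end = min(start + self.bin_width, self.chrom_sizes[chrom])
        return GenomicInterval(chrom, start, end)

    def starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_width

    def ends(self, chrom: str) -> np.ndarray:
        return np.minimum(self.starts(chrom) + self.bin_width, self.chrom_sizes[chrom])

    def midpoints(self, chrom: str) -> np.ndarray:
        return (self.starts(chrom) + self.ends(chrom)) / 2.0

    def partial_mask(self) -> np.ndarray:
        """Boolean per locus: True where the bin is a narrow terminal bin."""
        out = np.zeros(self.n_loci, dtype=bool)
        for c in self.chroms:
            if self.chrom_sizes[c] % self.bin_width:
                out[self.chrom_slice(c).stop - 1] = True
        return out

    def to_frame(self) -> pd.DataFrame:
        """All loci as a BED-like DataFrame (chrom, start, end)."""
        frames = []
        for c in self.chroms:
            frames.append(
                pd.DataFrame({"chrom": c, "start": self.starts(c), "end": self.ends(c)})
            )
        return pd.concat(frames, ignore_index=True)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LocusGrid)
            and self.bin_width == other.bin_width
            and self.chrom_sizes == other.chrom_sizes
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LocusGrid({len(self.chroms)} chromosomes, bin_width={self.bin_width}, "
            f"{self.n_loci} loci)"
        )


@dataclass
class TrackValues:
    """A per-locus numeric track with a measured-mask.

    ``mask`` is True where the locus carries a measured value; masked-out
    entries are never consumed by downstream statistics.
    """

    grid: LocusGrid
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.mask is None:
            self.mask = np.ones(self.grid.n_loci, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.grid.n_loci,) or self.mask.shape != (self.grid.n_loci,):
            raise ValueError(
                f"track length {self.values.shape} does not match grid ({self.grid.n_loci} loci)"
            )

    def masked(self) -> np.ndarray:
        """Values at measured loci only."""
        return self.values[self.mask]

    def copy(self) -> "TrackValues":
        return TrackValues(self.grid, self.values.copy(), self.mask.copy())


def build_grid(
    chrom_sizes: Mapping[str, int],
    bin_width: int = 1000,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> LocusGrid:
    """Tile a genome into fixed-width loci (see :class:`LocusGrid`)."""
    return LocusGrid(chrom_sizes, bin_width=bin_width, exclude=exclude)


def _as_interval_frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        return intervals
    rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def overlapping_loci(grid: LocusGrid, chrom: str, start: int, end: int) -> np.ndarray:
    """Global indices of grid loci sharing >= 1 bp with ``[start, end)``."""
    if chrom not in grid.chrom_sizes:
        raise KeyError(f"interval on unknown chromosome: {chrom}")
    size = grid.chrom_sizes[chrom]
    start = max(int(start), 0)
    end = min(int(end), size)
    if end <= start:
        return np.empty(0, dtype=np.int64)
    off = grid.chrom_slice(chrom).start
    first = start // grid.bin_width
    last = (end - 1) // grid.bin_width  # end exclusive -> last covered base
    return np.arange(off + first, off + last + 1, dtype=np.int64)


def annotate_overlap(grid: LocusGrid, intervals) -> TrackValues:
    """Boolean track: True where a locus shares >= 1 bp with any interval.

    Half-open semantics: an interval starting exactly at a locus's end does
    not overlap it.  Strand is ignored.
    """
    df = _as_interval_frame(intervals)
    out = np.zeros(grid.n_loci, dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in grid.chrom_sizes:
            raise KeyError(f"interval on unknown chromosome: {chrom}")
        size = grid.chrom_sizes[chrom]
        starts = np.clip(sub["start"].to_numpy(np.int64), 0, size)
        ends = np.clip(sub["end"].to_numpy(np.int64), 0, size)
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        off = grid.chrom_slice(chrom).start
        first = starts // grid.bin_width
        last = (ends - 1) // grid.bin_width
        for f, l in zip(first, last):
            out[off + f : off + l + 1] = True
    return TrackValues(grid, out, np.ones(grid.n_loci, dtype=bool))


def coverage_fraction(grid: LocusGrid, intervals) -> TrackValues:
    """Fraction of each locus's bases covered by the union of intervals."""
    df = _as_interval_frame(intervals)
    covered = np.zeros(grid.n_loci, dtype=np.float64)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in grid.chrom_sizes:
            raise KeyError(f"interval on unknown chromosome: {chrom}")
        size = grid.chrom_sizes[chrom]
        # merge intervals, then distribute covered bp over bins
        ivs = sorted(
            (max(0, int(s)), min(size, int(e)))
            for s, e in zip(sub["start"], sub["end"])
            if min(size, int(e)) > max(0, int(s))
        )
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        off = grid.chrom_slice(chrom).start
        bw = grid.bin_width
        for s, e in merged:
            first, last = s // bw, (e - 1) // bw
            for b in range(first, last + 1):
                lo = max(s, b * bw)
                hi = min(e, min((b + 1) * bw, size))
                covered[off + b] += hi - lo
    widths = np.concatenate(
        [grid.ends(c) - grid.starts(c) for c in grid.chroms]
    ).astype(np.float64)
    return TrackValues(grid, covered / widths)


def intervals_from_labels(
    grid: LocusGrid, labels: np.ndarray, wanted
) -> pd.DataFrame:
    """Maximal runs of loci whose label equals ``wanted``, as intervals.

    Runs never cross chromosome boundaries.
    """
    labels = np.asarray(labels)
    rows = []
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        hit = labels[sl] == wanted
        if not hit.any():
            continue
        d = np.diff(hit.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if hit[0]:
            starts = np.concatenate([[0], starts])
        if hit[-1]:
            ends = np.concatenate([ends, [hit.size]])
        gstarts = grid.starts(chrom)
        gends = grid.ends(chrom)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(gstarts[s]), int(gends[e - 1])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
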
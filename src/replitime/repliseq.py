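"""Six-fraction Repli-Seq densities -> PNDV profiles -> WA timing scores.

Repli-Seq sorts BrdU-labelled cells into six cell-cycle fractions
(G1b, S1, S2, S3, S4, G2M) and sequences newly replicated DNA from each.
Per 1 kb locus, the percent-normalised density value (PNDV) is the share of
total cross-fraction signal in each fraction; the weighted-average (WA)
score collapses the six PNDVs into a single replication time,

    WA = 0.917*G1b + 0.750*S1 + 0.583*S2 + 0.417*S3 + 0.250*S4 + 0*G2M,

so WA ranges over [0, 91.7] on the percent basis and higher WA means
earlier replication.  The processing chain applies the standard filters:
150 bp tiles with more than 20 reads are excluded (repeat/duplication
artefacts), densities are summed in 50 kb sliding windows at 1 kb steps,
normalised to counts per million, and loci under 5 CPM are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import LocusGrid, TrackValues

#: fraction labels, earliest S-phase sorting gate first
FRACTIONS = ("G1b", "S1", "S2", "S3", "S4", "G2M")

#: WA coefficients per fraction (percent basis x 100 gives the 0-91.7 scale)
WA_COEFFICIENTS = np.array([0.917, 0.750, 0.583, 0.417, 0.250, 0.0])

#: maximum attainable WA on the percent basis
WA_MAX = 91.7


def _check_fraction_dict(tracks: Mapping[str, TrackValues]) -> LocusGrid:
    missing = [f for f in FRACTIONS if f not in tracks]
    if missing:
        raise ValueError(f"missing fractions: {missing}")
    grid = tracks[FRACTIONS[0]].grid
    for f in FRACTIONS:
        if tracks[f].grid != grid:
            raise ValueError(f"fraction {f} is on a different grid")
    return grid


@dataclass
class FractionDensity:
    """Per-fraction CPM tracks on a shared grid with a joint retained-mask."""

    grid: LocusGrid
    cpm: np.ndarray          # shape (6, n_loci)
    mask: np.ndarray         # shape (n_loci,)
    sample: str | None = None
    replicate: str | None = None


@dataclass
class PNDVProfile:
    """Percent-normalised density values: per-locus six-way signal split."""

    grid: LocusGrid
    values: np.ndarray       # shape (6, n_loci); rows ordered as FRACTIONS
    mask: np.ndarray
    basis: str = "percent"   # 'percent' (sums to 100) or 'proportions' (sums to 1)


@dataclass
class WATrack:
    """Weighted-average replication-timing score per locus."""

    grid: LocusGrid
    values: np.ndarray
    mask: np.ndarray
    basis: str = "percent"
    sample: str | None = None
    replicate: str | None = None

    def as_track(self) -> TrackValues:
        return TrackValues(self.grid, self.values, self.mask)


# ------------------------------------------------------------- read handling

def mask_high_density(
    read_starts: Mapping[str, np.ndarray],
    grid: LocusGrid,
    max_reads: int = 20,
    tile_bp: int = 150,
) -> pd.DataFrame:
    """Tiles (fixed 0-based ``tile_bp`` tiling) with more than ``max_reads``.

    Reads falling in the returned tiles are removed from all subsequent
    density sums; the rule guards against collapsed repeats and
    duplication artefacts.  Strictly-greater comparison: a tile holding
    exactly ``max_reads`` reads is retained.
    """
    rows = []
    for chrom, starts in read_starts.items():
        if chrom not in grid.chrom_sizes:
            continue
        starts = np.asarray(starts)
        if starts.size == 0:
            continue
        tiles, counts = np.unique(starts // tile_bp, return_counts=True)
        for t in tiles[counts > max_reads]:
            rows.append((chrom, int(t) * tile_bp, min((int(t) + 1) * tile_bp, grid.chrom_sizes[chrom])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _drop_excluded(starts: np.ndarray, excl: pd.DataFrame, chrom: str, tile_bp: int = 150) -> np.ndarray:
    if excl is None or excl.empty:
        return starts
    bad = excl.loc[excl["chrom"] == chrom, "start"].to_numpy() // tile_bp
    if bad.size == 0:
        return starts
    return starts[~np.isin(starts // tile_bp, bad)]


def window_density(
    read_starts: Mapping[str, np.ndarray],
    grid: LocusGrid,
    window_bp: int = 50_000,
    exclusions: pd.DataFrame | None = None,
) -> TrackValues:
    """Read-start counts in a sliding window centred on each locus midpoint.

    The window is ``[mid - window_bp/2, mid + window_bp/2)``, truncated (not
    dropped) at chromosome ends.  Reads inside excluded 150 bp tiles
    contribute nothing.
    """
    if window_bp < grid.bin_width:
        raise ValueError("window smaller than bin width")
    values = np.zeros(grid.n_loci)
    half = window_bp / 2.0
    for chrom in grid.chroms:
        starts = np.sort(np.asarray(read_starts.get(chrom, np.empty(0))))
        starts = _drop_excluded(starts, exclusions, chrom)
        mids = grid.midpoints(chrom)
        lo = np.searchsorted(starts, np.ceil(mids - half), side="left")
        hi = np.searchsorted(starts, np.ceil(mids + half), side="left")
        values[grid.chrom_slice(chrom)] = hi - lo
    return TrackValues(grid, values)


def sliding_window_sum(track: TrackValues, window_bp: int = 50_000) -> TrackValues:
    """Sum a per-locus count track over a sliding window at each locus.

    The window at locus ``i`` covers the loci whose midpoints lie within
    ``window_bp / 2`` of locus ``i``'s midpoint, truncated at chromosome
    ends.  This is the per-locus-count counterpart of
    :func:`window_density` (which operates on raw read starts).
    """
    grid = track.grid
    half = max(0, (window_bp // 2 - 1) // grid.bin_width)
    out = np.empty(grid.n_loci)
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        v = track.values[sl].astype(float)
        c = np.concatenate([[0.0], np.cumsum(v)])
        n = v.size
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, n)
        out[sl] = c[hi] - c[lo]
    return TrackValues(grid, out, track.mask.copy())


# -------------------------------------------------------------- CPM and PNDV

def cpm_and_coverage_filter(
    raw: Mapping[str, TrackValues],
    min_cpm: float = 5.0,
    per_fraction: bool = True,
    library_sizes: Mapping[str, float] | None = None,
    sample: str | None = None,
    replicate: str | None = None,
) -> FractionDensity:
    """Scale each fraction to counts-per-million and drop low-coverage loci.

    Each fraction's track is scaled by 1e6 over that fraction's library
    size — the fraction's sequenced read count when ``library_sizes`` is
    given, otherwise the track's own total (correct for unwindowed
    per-locus counts; windowed densities overcount reads, so callers that
    window first must pass the raw totals).  In the default per-fraction
    mode a locus is masked out when *any* fraction falls strictly below
    ``min_cpm``; ``per_fraction=False`` instead tests the cross-fraction
    total against ``min_cpm``.
    """
    grid = _check_fraction_dict(raw)
    cpm = np.empty((6, grid.n_loci))
    mask = np.ones(grid.n_loci, dtype=bool)
    for i, f in enumerate(FRACTIONS):
        track = raw[f]
        if library_sizes is not None:
            total = float(library_sizes[f])
        else:
            total = float(np.sum(track.values[track.mask]))
        if total <= 0:
            raise ValueError(f"fraction {f} has zero total signal")
        cpm[i] = track.values * (1e6 / total)
        mask &= track.mask
    if per_fraction:
        mask &= np.all(cpm >= min_cpm, axis=0)
    else:
        mask &= cpm.sum(axis=0) >= min_cpm
    return FractionDensity(grid, cpm, mask, sample=sample, replicate=replicate)


def compute_pndv(density: FractionDensity, basis: str = "percent") -> PNDVProfile:
    """Convert CPM tracks to the per-locus percentage split across fractions."""
    totals = density.cpm.sum(axis=0)
    mask = density.mask & (totals > 0)
    scale = 100.0 if basis == "percent" else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(totals > 0, scale * density.cpm / totals, 0.0)
    return PNDVProfile(density.grid, values, mask, basis=basis)


def compute_wa(
    pndv: PNDVProfile,
    sample: str | None = None,
    replicate: str | None = None,
) -> WATrack:
    """Coefficient-weighted sum of the six PNDVs; higher = earlier."""
    values = WA_COEFFICIENTS @ pndv.values
    return WATrack(
        pndv.grid, values, pndv.mask.copy(), basis=pndv.basis,
        sample=sample, replicate=replicate,
    )


def average_replicates(rep1: WATrack, rep2: WATrack) -> tuple[WATrack, float]:
    """Mean WA across two replicates plus their squared Pearson correlation.

    The output is masked wherever either replicate is; r^2 is computed over
    jointly measured loci.
    """
    if rep1.grid != rep2.grid:
        raise ValueError("replicates are on different grids")
    if rep1.basis != rep2.basis:
        raise ValueError("replicates use different bases")
    mask = rep1.mask & rep2.mask
    if not mask.any():
        raise ValueError("no jointly measured loci")
    values = np.where(mask, (rep1.values + rep2.values) / 2.0, np.nan)
    a, b = rep1.values[mask], rep2.values[mask]
    if np.std(a) == 0 or np.std(b) == 0:
        r2 = 1.0 if np.allclose(a, b) else 0.0
    else:
        r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
    out = WATrack(rep1.grid, values, mask, basis=rep1.basis, sample=rep1.sample)
    return out, r2


def wa_from_density_tracks(
    raw: Mapping[str, TrackValues],
    min_cpm: float = 5.0,
    per_fraction: bool = True,
    sample: str | None = None,
    replicate: str | None = None,
) -> WATrack:
    """Full per-replicate chain on precomputed per-locus density tracks."""
    fd = cpm_and_coverage_filter(
        raw, min_cpm=min_cpm, per_fraction=per_fraction,
        sample=sample, replicate=replicate,
    )
    return compute_wa(compute_pndv(fd), sample=sample, replicate=replicate)


def wa_from_locus_counts(
    counts: Mapping[str, TrackValues],
    window_bp: int = 50_000,
    min_cpm: float = 5.0,
    sample: str | None = None,
    replicate: str | None = None,
) -> WATrack:
    """Full chain on per-locus read counts: window-sum, CPM against the
    per-fraction read totals, low-coverage filter, PNDV, WA."""
    _check_fraction_dict(counts)
    lib = {f: float(np.sum(counts[f].values[counts[f].mask])) for f in FRACTIONS}
    windowed = {f: sliding_window_sum(counts[f], window_bp) for f in FRACTIONS}
    fd = cpm_and_coverage_filter(
        windowed, min_cpm=min_cpm, library_sizes=lib,
        sample=sample, replicate=replicate,
    )
    return compute_wa(compute_pndv(fd), sample=sample, replicate=replicate)


def wa_from_reads(
    read_starts_by_fraction: Mapping[str, Mapping[str, np.ndarray]],
    grid: LocusGrid,
    window_bp: int = 50_000,
    max_reads_150bp: int = 20,
    min_cpm: float = 5.0,
    sample: str | None = None,
    replicate: str | None = None,
) -> WATrack:
    """Full per-replicate chain from raw read-start positions.

    The high-density 150 bp exclusion is derived per fraction and applied
    before windowing (the exclusion-then-filter order is configurable only
    through the lower-level functions).
    """
    raw: dict[str, TrackValues] = {}
    lib: dict[str, float] = {}
    for f in FRACTIONS:
        reads = read_starts_by_fraction[f]
        excl = mask_high_density(reads, grid, max_reads=max_reads_150bp)
        raw[f] = window_density(reads, grid, window_bp=window_bp, exclusions=excl)
        lib[f] = float(
            sum(
                _drop_excluded(np.sort(np.asarray(v)), excl, c).size
                for c, v in reads.items()
            )
        )
    fd = cpm_and_coverage_filter(
        raw, min_cpm=min_cpm, library_sizes=lib, sample=sample, replicate=replicate
    )
    return compute_wa(compute_pndv(fd), sample=sample, replicate=replicate)
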
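"""Readers and writers for the plain-text genomic formats the package uses.

BED3/4/6, bedGraph, BEDPE and two-column chromosome-size tables are all
tab-separated text; they are parsed with explicit per-line validation so a
malformed record is reported with its line number.  Writing uses a canonical
number format (``%g`` for floats), so reading a file produced by these
writers and writing it back is byte-identical.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .grid import LocusGrid, TrackValues, overlapping_loci

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]


class FormatError(ValueError):
    """A line in an input file violates its declared format."""


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return f"{value:g}"
    return str(value)


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            try:
                size = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer size {parts[1]!r}") from exc
            if parts[0] in sizes:
                raise FormatError(f"{path}:{ln}: duplicate chromosome {parts[0]}")
            sizes[parts[0]] = size
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path) -> pd.DataFrame:
    """BED3/4/6 into a DataFrame with whichever optional columns are present."""
    rows = []
    ncols = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED needs >= 3 columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
            if end <= start:
                raise FormatError(f"{path}:{ln}: end <= start ({start}, {end})")
            ncols = max(ncols or 0, len(parts))
            rows.append([parts[0], start, end] + parts[3:6])
    ncols = min(ncols or 3, 6)
    cols = BED_COLUMNS[:ncols]
    df = pd.DataFrame([r + [None] * (ncols - len(r)) for r in rows], columns=cols)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _write_frame(df: pd.DataFrame, path) -> None:
    """Tab-separated body rows with canonical %g float formatting."""
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%g")


def read_bedgraph_records(path) -> pd.DataFrame:
    """Raw bedGraph records (chrom, start, end, value)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln}: bedGraph needs 4 columns, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: malformed bedGraph record") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph_records(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in df[["chrom", "start", "end", "value"]].itertuples(
            index=False
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


def read_track(path, grid: LocusGrid) -> TrackValues:
    """A bedGraph as a per-locus track on ``grid``.

    Each record's value is assigned to every locus it overlaps; loci not
    covered by any record are masked out.  Records on chromosomes absent
    from the grid (e.g. excluded chrY/chrM) are ignored.
    """
    df = read_bedgraph_records(path)
    values = np.full(grid.n_loci, np.nan)
    mask = np.zeros(grid.n_loci, dtype=bool)
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in grid.chrom_sizes:
            continue
        idx = overlapping_loci(grid, chrom, start, end)
        values[idx] = value
        mask[idx] = True
    return TrackValues(grid, values, mask)


def write_track(track: TrackValues, path) -> None:
    """Write a per-locus track as bedGraph (one record per measured locus)."""
    grid = track.grid
    frames = []
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        m = track.mask[sl]
        if not m.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": grid.starts(chrom)[m],
                    "end": grid.ends(chrom)[m],
                    "value": track.values[sl][m],
                }
            )
        )
    body = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "value"]
    )
    _write_frame(body, path)


def read_bedpe(path) -> pd.DataFrame:
    """BEDPE breakpoint pairs; needs the 6 mandatory columns at least."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(
                    f"{path}:{ln}: BEDPE needs >= 6 mandatory columns, got {len(parts)}"
                )
            try:
                row = [
                    parts[0], int(parts[1]), int(parts[2]),
                    parts[3], int(parts[4]), int(parts[5]),
                ]
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
            row += parts[6:8]
            rows.append(row)
    ncols = max((len(r) for r in rows), default=6)
    cols = BEDPE_COLUMNS[:ncols]
    return pd.DataFrame([r + [None] * (ncols - len(r)) for r in rows], columns=cols)


def write_bedpe(df: pd.DataFrame, path) -> None:
    cols = [c for c in BEDPE_COLUMNS if c in df.columns]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
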
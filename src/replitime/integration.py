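"""Stratifying chromatin marks, methylation, promoters and LAD boundaries
by replication timing on the shared 1 kb locus grid.

Occupancy here is binary at locus resolution: a locus carries a mark when
it shares at least one base with a called peak or broad domain.  Gain/loss,
hypo/hyper-methylation and the locus-based Fisher enrichment follow the
same locus unit, so all comparisons count 1 kb loci rather than base pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .grid import LocusGrid, TrackValues, annotate_overlap, overlapping_loci
from .repliseq import WATrack


@dataclass
class MarkSet:
    """A named set of called intervals (peaks or broad domains)."""

    name: str
    intervals: pd.DataFrame  # chrom/start/end
    kind: str = "peak"       # 'peak' or 'broad_domain'

    def occupancy(self, grid: LocusGrid) -> np.ndarray:
        return annotate_overlap(grid, self.intervals).values.astype(bool)


# ------------------------------------------------------- timing percentiles

def percentile_occupancy(
    wa: WATrack, mark, n_bins: int = 100
) -> pd.DataFrame:
    """Mark occupancy within equal-count replication-timing percentile bins.

    Measured loci are ranked by WA (late to early) and split into
    ``n_bins`` bins of equal locus count (+/-1); per bin, the fraction of
    loci overlapping the mark is reported.
    """
    occupied = mark.occupancy(wa.grid) if isinstance(mark, MarkSet) else np.asarray(mark, bool)
    idx = np.flatnonzero(wa.mask)
    if idx.size < n_bins:
        raise ValueError(f"need >= {n_bins} measured loci")
    order = idx[np.argsort(wa.values[idx], kind="stable")]
    chunks = np.array_split(order, n_bins)
    rows = [
        (i + 1, len(ch), float(np.mean(occupied[ch])) if len(ch) else np.nan)
        for i, ch in enumerate(chunks)
    ]
    return pd.DataFrame(rows, columns=["percentile", "n_loci", "occupancy"])


# ------------------------------------------------------------ gain and loss

GAIN, LOSS, STABLE_PRESENT, STABLE_ABSENT = "gain", "loss", "stable-present", "stable-absent"


def mark_gain_loss(mark_case: MarkSet, mark_control: MarkSet, grid: LocusGrid) -> np.ndarray:
    """Per-locus mark change between samples.

    gain: occupied in case only; loss: occupied in control only;
    otherwise stable-present / stable-absent.
    """
    case = mark_case.occupancy(grid)
    control = mark_control.occupancy(grid)
    out = np.full(grid.n_loci, STABLE_ABSENT, dtype=object)
    out[case & control] = STABLE_PRESENT
    out[case & ~control] = GAIN
    out[~case & control] = LOSS
    return out


# --------------------------------------------------------------- methylation

HYPO, HYPER, STABLE = "hypo", "hyper", "stable"


def methylation_delta(
    meth_control: TrackValues,
    meth_case: TrackValues,
    threshold: float = 0.2,
    hypo_min_control: float = 0.2,
    hyper_max_control: float = 0.8,
) -> np.ndarray:
    """Classify loci as hypo-/hyper-methylated in the case sample.

    hypo: methylation fell by more than ``threshold`` and the control locus
    was at least ``hypo_min_control`` to begin with; hyper: rose by more
    than ``threshold`` from a control value below ``hyper_max_control``.
    Loci failing either eligibility clause, and masked loci, are stable.
    """
    if meth_control.grid != meth_case.grid:
        raise ValueError("tracks on different grids")
    mask = meth_control.mask & meth_case.mask
    d = meth_case.values - meth_control.values
    out = np.full(meth_control.grid.n_loci, STABLE, dtype=object)
    out[mask & (d < -threshold) & (meth_control.values >= hypo_min_control)] = HYPO
    out[mask & (d > threshold) & (meth_control.values < hyper_max_control)] = HYPER
    return out


# --------------------------------------------------------------- enrichment

@dataclass
class AssociationResult:
    element: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    log_odds: float
    p: float
    fdr: float = np.nan
    or_corrected: bool = False


def element_association(
    query: np.ndarray,
    element_sets,
    universe: np.ndarray,
    grid: LocusGrid | None = None,
) -> pd.DataFrame:
    """Two-sided Fisher association of a query locus set with element sets.

    For each element the 2x2 table over universe loci is
    (query & element, query & ~element, ~query & element, ~query & ~element);
    BH FDR is taken across elements.  A zero cell makes the point odds
    ratio Haldane-Anscombe corrected (flagged); the exact p is uncorrected.
    """
    query = np.asarray(query, bool)
    universe = np.asarray(universe, bool)
    if not universe.any():
        raise ValueError("empty universe")
    if not query[universe].any():
        raise ValueError("empty query within universe")
    if np.any(query & ~universe):
        raise ValueError("query must be a subset of the universe")
    results = []
    for elem in element_sets:
        if isinstance(elem, MarkSet):
            name, hit = elem.name, elem.occupancy(grid)
        else:
            name, hit = elem
            hit = np.asarray(hit, bool)
        a = int(np.sum(query & hit & universe))
        b = int(np.sum(query & ~hit & universe))
        c = int(np.sum(~query & hit & universe))
        d = int(np.sum(~query & ~hit & universe))
        res = stats.fisher_exact_2x2(a, b, c, d)
        odds, corrected = stats.odds_ratio_haldane(a, b, c, d)
        results.append(
            AssociationResult(
                name, a, b, c, d, odds, float(np.log(odds)), res.p,
                or_corrected=corrected,
            )
        )
    df = pd.DataFrame([vars(r) for r in results])
    df["fdr"] = stats.bh_fdr(df["p"].to_numpy())
    return df


# ----------------------------------------------------------------- promoters

def promoter_windows(genes: pd.DataFrame, grid: LocusGrid, flank: int = 1000) -> pd.DataFrame:
    """TSS +/- ``flank`` windows, clipped at chromosome edges (flagged).

    ``genes`` needs columns gene, chrom, tss, strand; strand locates the
    TSS but the window is strand-symmetric.
    """
    rows = []
    for g in genes.itertuples(index=False):
        if g.chrom not in grid.chrom_sizes:
            raise KeyError(f"gene {g.gene} on unknown chromosome {g.chrom}")
        size = grid.chrom_sizes[g.chrom]
        start, end = g.tss - flank, g.tss + flank
        clipped = start < 0 or end > size
        rows.append((g.gene, g.chrom, max(0, start), min(size, end), g.strand, clipped))
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "strand", "clipped"]
    )


def promoter_table(
    genes: pd.DataFrame,
    grid: LocusGrid,
    wa: WATrack | None = None,
    value_tracks: dict[str, TrackValues] | None = None,
    mark_sets: dict[str, MarkSet] | None = None,
    cgi_intervals: pd.DataFrame | None = None,
    expr: pd.DataFrame | None = None,
    early_min: float = 75.0,
    late_max: float = 20.0,
    flank: int = 1000,
) -> pd.DataFrame:
    """One row per gene with promoter-window summaries of every input.

    Columns: the window itself; mean WA over measured overlapping loci and
    the early/late label (only assigned beyond the WA limits); per
    value-track window means; per mark-set overlap flags; CpG-island
    promoter flag; any expression columns joined on gene id.
    """
    win = promoter_windows(genes, grid, flank=flank)
    records = []
    cgi_occ = (
        annotate_overlap(grid, cgi_intervals).values.astype(bool)
        if cgi_intervals is not None
        else None
    )
    mark_occ = {
        name: ms.occupancy(grid) for name, ms in (mark_sets or {}).items()
    }
    for row in win.itertuples(index=False):
        idx = overlapping_loci(grid, row.chrom, row.start, row.end)
        rec: dict = dict(row._asdict())
        if wa is not None:
            m = idx[wa.mask[idx]]
            mean_wa = float(np.mean(wa.values[m])) if m.size else np.nan
            rec["mean_wa"] = mean_wa
            rec["timing"] = (
                "early" if mean_wa > early_min
                else "late" if mean_wa < late_max
                else "intermediate"
            ) if np.isfinite(mean_wa) else "unmeasured"
        for name, track in (value_tracks or {}).items():
            m = idx[track.mask[idx]]
            rec[f"{name}_mean"] = float(np.mean(track.values[m])) if m.size else np.nan
        for name, occ in mark_occ.items():
            rec[f"{name}_overlap"] = bool(occ[idx].any())
        if cgi_occ is not None:
            rec["cgi_promoter"] = bool(cgi_occ[idx].any())
        records.append(rec)
    out = pd.DataFrame(records)
    if expr is not None:
        out = out.merge(expr, on="gene", how="left")
    return out


# --------------------------------------------------------------- state table

def combinatorial_states(
    features: dict[str, np.ndarray],
    restrict: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate joint binary feature states across loci.

    ``features`` maps feature name (e.g. ``"PrEC_LAD"``) to a boolean
    per-locus vector; ``restrict`` limits the tabulation (e.g. to late
    loci).  Combinations are ranked by descending count, ties broken by
    lexicographic state order; percentages sum to 100 over tabulated loci.
    """
    names = list(features)
    mat = np.column_stack([np.asarray(features[n], bool) for n in names])
    if restrict is not None:
        mat = mat[np.asarray(restrict, bool)]
    if mat.shape[0] == 0:
        raise ValueError("no loci to tabulate")
    combos, counts = np.unique(mat, axis=0, return_counts=True)
    order = np.lexsort([*(combos[:, i] for i in reversed(range(combos.shape[1]))), -counts])
    combos, counts = combos[order], counts[order]
    df = pd.DataFrame(combos, columns=names)
    df["count"] = counts
    df["percentage"] = 100.0 * counts / counts.sum()
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ------------------------------------------------------------- profile plots

def profile_matrix(
    track: TrackValues, regions: pd.DataFrame, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region binned averages of a locus track (regions x bins).

    Each region is split into ``n_bins`` equal-width bins; a bin's value is
    the overlap-length-weighted mean of the measured locus values it
    covers (equivalently the per-bp mean of the piecewise-constant track).
    Returns (matrix, per-region unweighted mean over bins).
    """
    if regions.empty:
        raise ValueError("empty region set")
    grid = track.grid
    mat = np.full((len(regions), n_bins), np.nan)
    for r, region in enumerate(regions.itertuples(index=False)):
        length = region.end - region.start
        if length < n_bins:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} shorter than {n_bins} bp"
            )
        edges = region.start + np.round(np.linspace(0, length, n_bins + 1)).astype(np.int64)
        for b in range(n_bins):
            lo, hi = int(edges[b]), int(edges[b + 1])
            idx = overlapping_loci(grid, region.chrom, lo, hi)
            if idx.size == 0:
                continue
            w = np.empty(idx.size)
            vals = track.values[idx]
            ok = track.mask[idx]
            for j, gi in enumerate(idx):
                loc = grid.locus(int(gi))
                w[j] = min(hi, loc.end) - max(lo, loc.start)
            w = np.where(ok, w, 0.0)
            if w.sum() > 0:
                mat[r, b] = float(np.sum(w * vals) / w.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        region_means = np.nanmean(mat, axis=1)
    return mat, region_means


# ------------------------------------------------------------ LAD boundaries

@dataclass
class LadBoundaryResult:
    boundaries: pd.DataFrame          # chrom, pos, side, distance
    wa_case: np.ndarray               # boundaries x window bins
    wa_control: np.ndarray
    bin_offsets: np.ndarray           # bp offset of each window bin centre
    zone_tests: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def _edges(lads: pd.DataFrame, chrom: str, side: str) -> np.ndarray:
    sub = lads[lads["chrom"] == chrom]
    col = "start" if side == "5p" else "end"
    return np.sort(sub[col].to_numpy(np.int64))


def lad_boundary_analysis(
    lads_control: pd.DataFrame,
    lads_case: pd.DataFrame,
    wa_control: WATrack,
    wa_case: WATrack,
    window_bp: int = 1_000_000,
) -> LadBoundaryResult:
    """Signed shift of each control LAD boundary to the nearest case boundary.

    5' boundaries (LAD starts) are compared with case 5' boundaries and 3'
    with 3'.  Negative distance: the case boundary lies upstream of the
    control one; positive: downstream.  Nearest is by absolute distance
    (ties toward upstream).  The WA matrices cover +/- ``window_bp`` around
    each control boundary at grid resolution, rows ordered by decreasing
    distance.  Zone tests compare case vs control WA (one-tailed MWW) inside
    extension zones (case LAD grew; expected later in case) and contraction
    zones (case LAD shrank; expected earlier in case).
    """
    if lads_control.empty or lads_case.empty:
        raise ValueError("LAD sets must be non-empty")
    grid = wa_control.grid
    bw = grid.bin_width
    nbins = 2 * (window_bp // bw) + 1
    rows = []
    ext_case, ext_ctrl, con_case, con_ctrl = [], [], [], []
    for side in ("5p", "3p"):
        for chrom in sorted(lads_control["chrom"].unique()):
            if chrom not in grid.chrom_sizes:
                continue
            case_edges = _edges(lads_case, chrom, side)
            if case_edges.size == 0:
                warnings.warn(f"no case LAD on {chrom}; dropping its {side} boundaries")
                continue
            for pos in _edges(lads_control, chrom, side):
                j = np.searchsorted(case_edges, pos)
                cands = case_edges[max(0, j - 1): j + 1]
                dists = cands - pos
                best = dists[np.argmin(np.abs(dists))]
                rows.append((chrom, int(pos), side, int(best)))
                # zone loci strictly between the two boundaries
                lo, hi = (pos + best, pos) if best < 0 else (pos, pos + best)
                if hi > lo:
                    idx = overlapping_loci(grid, chrom, int(lo), int(hi))
                    ok = wa_case.mask[idx] & wa_control.mask[idx]
                    idx = idx[ok]
                    # LAD membership grows where case covers the zone
                    grew = (side == "5p" and best < 0) or (side == "3p" and best > 0)
                    if grew:
                        ext_case.append(wa_case.values[idx])
                        ext_ctrl.append(wa_control.values[idx])
                    else:
                        con_case.append(wa_case.values[idx])
                        con_ctrl.append(wa_control.values[idx])
    boundaries = pd.DataFrame(rows, columns=["chrom", "pos", "side", "distance"])
    boundaries = boundaries.sort_values("distance", ascending=False, kind="stable").reset_index(
        drop=True
    )
    offsets = (np.arange(nbins) - nbins // 2) * bw
    mats = {}
    for label, wa in (("case", wa_case), ("control", wa_control)):
        mat = np.full((len(boundaries), nbins), np.nan)
        for r, row in enumerate(boundaries.itertuples(index=False)):
            centre_bin = grid.locus_index(row.chrom, min(max(row.pos, 0), grid.chrom_sizes[row.chrom] - 1))
            sl = grid.chrom_slice(row.chrom)
            lo = centre_bin - nbins // 2
            for b in range(nbins):
                gi = lo + b
                if sl.start <= gi < sl.stop and wa.mask[gi]:
                    mat[r, b] = wa.values[gi]
        mats[label] = mat
    zone_rows = []
    for name, case_parts, ctrl_parts, tail in (
        ("extension", ext_case, ext_ctrl, "less"),     # case expected later (lower WA)
        ("contraction", con_case, con_ctrl, "greater"),  # case expected earlier
    ):
        cv = np.concatenate(case_parts) if case_parts else np.empty(0)
        tv = np.concatenate(ctrl_parts) if ctrl_parts else np.empty(0)
        if cv.size and tv.size:
            res = stats.mann_whitney(cv, tv, tail=tail)
            zone_rows.append((name, cv.size, float(np.median(cv)), float(np.median(tv)), res.p))
        else:
            zone_rows.append((name, cv.size, np.nan, np.nan, np.nan))
    zone_tests = pd.DataFrame(
        zone_rows, columns=["zone", "n_loci", "median_case_wa", "median_control_wa", "p"]
    )
    return LadBoundaryResult(boundaries, mats["case"], mats["control"], offsets, zone_tests)
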
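"""Early/late cutoffs, the replicate-derived change threshold, and calling
of merged domains of earlier/later replication between two samples.

The change threshold is empirical: WA differences between replicates of the
same sample represent pure technical noise, so the largest replicate |dWA|
bounds what can occur by chance, and the change cutoff is set just above it
(rounded up to the next multiple of 5).  Loci beyond the cutoff are merged
into direction-pure domains when within 50 kb of each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import LocusGrid, TrackValues
from .repliseq import WATrack

LATER, UNCHANGED, EARLIER = -1, 0, 1


@dataclass(frozen=True)
class TimingCutoffs:
    """Early/late WA limits (e.g. 75/20 for the prostate pair, 73/17 MCF7)."""

    early_min: float
    late_max: float
    percentile: float | None = None

    def __post_init__(self) -> None:
        if self.early_min <= self.late_max:
            raise ValueError("early_min must exceed late_max")


def derive_cutoffs(
    wa_a: WATrack,
    wa_b: WATrack,
    percentile: float = 0.10,
    mode: str = "pooled",
) -> TimingCutoffs:
    """Early/late limits from the top and bottom deciles of WA in two samples.

    ``mode='pooled'`` (default) takes quantiles of the two samples' pooled
    jointly-masked WA values, yielding one cutoff pair.  ``mode='intersection'``
    requires a locus to sit in the decile of *both* samples: early_min is
    the larger of the two per-sample upper quantiles and late_max the
    smaller of the lower ones.
    """
    if wa_a.grid != wa_b.grid:
        raise ValueError("samples on different grids")
    mask = wa_a.mask & wa_b.mask
    if mask.sum() < 100:
        raise ValueError("need >= 100 jointly measured loci")
    a, b = wa_a.values[mask], wa_b.values[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate (constant) WA track")
    if mode == "pooled":
        pooled = np.concatenate([a, b])
        early = float(np.quantile(pooled, 1 - percentile))
        late = float(np.quantile(pooled, percentile))
    elif mode == "intersection":
        early = float(max(np.quantile(a, 1 - percentile), np.quantile(b, 1 - percentile)))
        late = float(min(np.quantile(a, percentile), np.quantile(b, percentile)))
    else:
        raise ValueError(f"unknown mode: {mode}")
    return TimingCutoffs(early, late, percentile)


def delta_track(case: WATrack, control: WATrack) -> TrackValues:
    """Per-locus dWA = WA(case) - WA(control) on the joint mask."""
    if case.grid != control.grid:
        raise ValueError("tracks on different grids")
    mask = case.mask & control.mask
    values = np.where(mask, case.values - control.values, np.nan)
    return TrackValues(case.grid, values, mask)


def replicate_null_max(rep1: WATrack, rep2: WATrack) -> tuple[float, float]:
    """Largest replicate |dWA| and the suggested change cutoff.

    The suggested cutoff is the smallest multiple of 5 strictly above the
    observed maximum (a max of 23 suggests 25; 25 suggests 30).
    """
    delta = delta_track(rep1, rep2)
    if not delta.mask.any():
        raise ValueError("no jointly measured loci")
    max_abs = float(np.max(np.abs(delta.values[delta.mask])))
    suggested = (np.floor(max_abs / 5.0) + 1) * 5.0
    return max_abs, float(suggested)


def classify_loci(delta: TrackValues, cutoff: float = 25.0) -> np.ndarray:
    """Label loci earlier (+1) / later (-1) / unchanged (0); strict cutoff.

    Masked loci get 0 but are distinguishable through ``delta.mask``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    labels = np.zeros(delta.grid.n_loci, dtype=np.int8)
    v = delta.values
    labels[delta.mask & (v > cutoff)] = EARLIER
    labels[delta.mask & (v < -cutoff)] = LATER
    return labels


def merge_domains(
    labels: np.ndarray,
    grid: LocusGrid,
    gap_bp: int = 50_000,
    delta: TrackValues | None = None,
) -> pd.DataFrame:
    """Merge same-direction changed loci within ``gap_bp`` into domains.

    Gap is measured from the end of one changed locus to the start of the
    next (inclusive <=).  Domains are direction-pure: earlier and later
    loci never merge even when adjacent.  Columns: chrom, start, end,
    direction, n_changed_loci, mean_delta (NaN when no delta is supplied),
    width.
    """
    labels = np.asarray(labels)
    rows = []
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        lab = labels[sl]
        starts, ends = grid.starts(chrom), grid.ends(chrom)
        for direction, name in ((LATER, "later"), (EARLIER, "earlier")):
            idx = np.flatnonzero(lab == direction)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(
                starts[idx[1:]] - ends[idx[:-1]] > gap_bp
            )
            bounds = np.concatenate([[0], breaks + 1, [idx.size]])
            for b0, b1 in zip(bounds[:-1], bounds[1:]):
                members = idx[b0:b1]
                mean_delta = np.nan
                if delta is not None:
                    mean_delta = float(np.mean(delta.values[sl][members]))
                rows.append(
                    (
                        chrom,
                        int(starts[members[0]]),
                        int(ends[members[-1]]),
                        name,
                        int(members.size),
                        mean_delta,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "direction", "n_changed_loci", "mean_delta"],
    )
    if not df.empty:
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        df["width"] = df["end"] - df["start"]
    else:
        df["width"] = pd.Series(dtype=int)
    return df


def call_timing_domains(
    case: WATrack,
    control: WATrack,
    cutoff: float = 25.0,
    gap_bp: int = 50_000,
) -> tuple[pd.DataFrame, np.ndarray, TrackValues]:
    """Convenience chain: delta -> classify -> merge.

    Returns (domains, labels, delta).
    """
    delta = delta_track(case, control)
    labels = classify_loci(delta, cutoff=cutoff)
    domains = merge_domains(labels, case.grid, gap_bp=gap_bp, delta=delta)
    return domains, labels, delta


def changed_fraction(labels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Fraction of measured loci labelled later/earlier/changed."""
    n = int(np.sum(mask))
    if n == 0:
        raise ValueError("empty mask")
    later = int(np.sum((labels == LATER) & mask))
    earlier = int(np.sum((labels == EARLIER) & mask))
    return {
        "later": later / n,
        "earlier": earlier / n,
        "changed": (later + earlier) / n,
    }
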
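"""Rearrangement breakpoints versus replication timing.

Breakpoint pairs (two breakends each) are classified cis (intra-chromosomal)
or trans (inter-chromosomal).  Enrichment of breakends in early or late
replication is tested at 1 kb locus resolution: loci bearing at least one
breakend against all measured loci, split by timing class, with a two-sided
Fisher test and BH FDR across all strata x classes.  Fusion-partner
concordance asks whether the two breakends of a pair share a timing state.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from . import stats
from .domains import TimingCutoffs
from .repliseq import WATrack, WA_MAX


class RearrangementPair(NamedTuple):
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    subtype: str | None = None
    source: str | None = None


PAIR_COLUMNS = ["chrom_a", "pos_a", "chrom_b", "pos_b", "subtype", "source"]


def pairs_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        df = pairs.copy()
    else:
        df = pd.DataFrame(list(pairs), columns=PAIR_COLUMNS[: len(pairs[0])])
    for col in PAIR_COLUMNS:
        if col not in df.columns:
            df[col] = None
    return df


def from_bedpe(bedpe: pd.DataFrame) -> pd.DataFrame:
    """BEDPE records -> pair table; breakend position = interval start."""
    df = pd.DataFrame(
        {
            "chrom_a": bedpe["chrom1"],
            "pos_a": bedpe["start1"],
            "chrom_b": bedpe["chrom2"],
            "pos_b": bedpe["start2"],
        }
    )
    df["subtype"] = bedpe["name"] if "name" in bedpe.columns else None
    df["source"] = None
    return df


def classify_cis_trans(pair) -> str:
    """cis iff both breakends share a chromosome, else trans."""
    chrom_a = pair.chrom_a if hasattr(pair, "chrom_a") else pair["chrom_a"]
    chrom_b = pair.chrom_b if hasattr(pair, "chrom_b") else pair["chrom_b"]
    if not chrom_a or not chrom_b:
        raise ValueError("breakend missing a chromosome")
    return "cis" if chrom_a == chrom_b else "trans"


def classify_pairs(pairs: pd.DataFrame) -> pd.Series:
    return pd.Series(
        np.where(pairs["chrom_a"] == pairs["chrom_b"], "cis", "trans"),
        index=pairs.index,
        name="cis_trans",
    )


def _breakend_loci(pairs: pd.DataFrame, wa: WATrack) -> tuple[np.ndarray, int]:
    """Grid indices (with repeats) of mappable breakends + dropped count."""
    loci = []
    dropped = 0
    for _, row in pairs.iterrows():
        for chrom, pos in ((row["chrom_a"], row["pos_a"]), (row["chrom_b"], row["pos_b"])):
            if chrom not in wa.grid.chrom_sizes or not (0 <= pos < wa.grid.chrom_sizes[chrom]):
                dropped += 1
                continue
            gi = wa.grid.locus_index(chrom, int(pos))
            if wa.mask[gi]:
                loci.append(gi)
            else:
                dropped += 1
    return np.asarray(loci, dtype=np.int64), dropped


def breakpoint_timing_enrichment(
    pairs: pd.DataFrame,
    wa: WATrack,
    cutoffs: TimingCutoffs,
    strata: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of breakend-bearing loci in early/late timing.

    For each stratum (all, cis, trans, plus any subtypes present unless
    ``strata`` overrides) and timing class: a = breakend-bearing loci in
    class, b = bearing not in class, c = non-bearing in class, d = rest;
    universe = measured loci.  BH FDR spans every reported test.
    """
    pairs = pairs_frame(pairs)
    ct = classify_pairs(pairs)
    if strata is None:
        strata = ["all", "cis", "trans"]
        strata += sorted(
            {s for s in pairs["subtype"].dropna().unique()} - set(strata)
        )
    universe = np.flatnonzero(wa.mask)
    wa_vals = wa.values
    early = wa.mask & (wa_vals > cutoffs.early_min)
    late = wa.mask & (wa_vals < cutoffs.late_max)
    rows = []
    _, dropped_total = _breakend_loci(pairs, wa)  # QC count, once per breakend
    for stratum in strata:
        if stratum == "all":
            sub = pairs
        elif stratum in ("cis", "trans"):
            sub = pairs[ct == stratum]
        else:
            sub = pairs[pairs["subtype"] == stratum]
        if sub.empty:
            continue
        loci, _ = _breakend_loci(sub, wa)
        bearing = np.zeros(wa.grid.n_loci, dtype=bool)
        bearing[loci] = True
        n_bearing = int(bearing[universe].sum())
        for cls, in_class in (("early", early), ("late", late)):
            a = int(np.sum(bearing & in_class))
            b = n_bearing - a
            c = int(in_class.sum()) - a
            d = universe.size - a - b - c
            res = stats.fisher_exact_2x2(a, b, c, d)
            odds, corrected = stats.odds_ratio_haldane(a, b, c, d)
            rows.append(
                (stratum, cls, int(len(sub)), a, b, c, d, odds, res.p, corrected)
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "stratum", "timing_class", "n_pairs", "a", "b", "c", "d",
            "odds_ratio", "p", "or_corrected",
        ],
    )
    out["fdr"] = stats.bh_fdr(out["p"].to_numpy()) if len(out) else pd.Series(dtype=float)
    out.attrs["dropped_breakends"] = dropped_total
    return out


def timing_distribution(
    pairs: pd.DataFrame,
    wa: WATrack,
    bandwidth: float = 2.0,
    n_grid: int = 512,
) -> dict:
    """Per-class (cis/trans) breakend WA samples plus a fixed-bandwidth KDE.

    The Gaussian KDE is evaluated on [0, WA_MAX] and renormalised to
    integrate to 1 over that support, so degenerate (single-locus) samples
    are handled.
    """
    pairs = pairs_frame(pairs)
    ct = classify_pairs(pairs)
    xs = np.linspace(0.0, WA_MAX, n_grid)
    out: dict = {"grid": xs}
    for cls in ("cis", "trans"):
        sub = pairs[ct == cls]
        loci, _ = _breakend_loci(sub, wa)
        values = wa.values[loci]
        dens = None
        if values.size >= 2:
            z = (xs[:, None] - values[None, :]) / bandwidth
            dens = np.exp(-0.5 * z**2).sum(axis=1) / (
                values.size * bandwidth * np.sqrt(2 * np.pi)
            )
            dens = dens / np.trapezoid(dens, xs)
        out[cls] = {"wa": values, "density": dens}
    return out


def _in_any(chrom: str, pos: int, domains: pd.DataFrame) -> bool:
    sub = domains[domains["chrom"] == chrom]
    return bool(((sub["start"] <= pos) & (sub["end"] > pos)).any())


def fusion_timing_concordance(
    pairs: pd.DataFrame,
    wa_normal: WATrack,
    wa_cancer: WATrack,
    changed_domains: pd.DataFrame,
    cutoffs: TimingCutoffs,
) -> tuple[pd.DataFrame, dict]:
    """Timing states of fusion partners and whether they agree.

    Per breakend: early/intermediate/late class in each sample and whether
    it falls inside an earlier/later changed domain.  A pair is concordant
    in a sample when both breakends are measured and share the class.
    Returns (per-pair table, summary with concordant fractions).
    """
    if wa_normal.grid != wa_cancer.grid:
        raise ValueError("tracks on different grids")
    pairs = pairs_frame(pairs)
    grid = wa_normal.grid

    def state(wa: WATrack, chrom, pos) -> str:
        if chrom not in grid.chrom_sizes or not (0 <= pos < grid.chrom_sizes[chrom]):
            return "unmapped"
        gi = grid.locus_index(chrom, int(pos))
        if not wa.mask[gi]:
            return "unmapped"
        v = wa.values[gi]
        if v > cutoffs.early_min:
            return "early"
        if v < cutoffs.late_max:
            return "late"
        return "intermediate"

    later = changed_domains[changed_domains["direction"] == "later"]
    earlier = changed_domains[changed_domains["direction"] == "earlier"]
    rows = []
    for i, row in pairs.iterrows():
        rec = {"pair": i, "cis_trans": classify_cis_trans(row)}
        for tag, chrom, pos in (
            ("a", row["chrom_a"], row["pos_a"]),
            ("b", row["chrom_b"], row["pos_b"]),
        ):
            rec[f"state_normal_{tag}"] = state(wa_normal, chrom, pos)
            rec[f"state_cancer_{tag}"] = state(wa_cancer, chrom, pos)
            rec[f"in_later_domain_{tag}"] = _in_any(chrom, pos, later)
            rec[f"in_earlier_domain_{tag}"] = _in_any(chrom, pos, earlier)
        for sample in ("normal", "cancer"):
            sa, sb = rec[f"state_{sample}_a"], rec[f"state_{sample}_b"]
            rec[f"concordant_{sample}"] = (
                sa == sb if "unmapped" not in (sa, sb) else None
            )
        rows.append(rec)
    table = pd.DataFrame(rows)
    summary = {}
    for sample in ("normal", "cancer"):
        flags = table[f"concordant_{sample}"].dropna()
        summary[f"concordant_fraction_{sample}"] = (
            float(flags.mean()) if len(flags) else np.nan
        )
        summary[f"n_scored_{sample}"] = int(len(flags))
    return table, summary
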
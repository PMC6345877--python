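"""Length-matched random region sets and the tests built on them.

The null model is positional: pick a chromosome at random, a uniform start
within it, a length drawn with replacement from the observed region
lengths, and reject draws that run off the chromosome end.  Observed region
sets (LRES/LREA and similar) are then compared with the null on mean
replication timing (Mann-Whitney) and on overlap with changed-timing
domains (exact binomial with the null overlap proportion as p0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .grid import overlapping_loci
from .repliseq import WATrack


@dataclass
class RandomRegionSample:
    regions: pd.DataFrame      # chrom/start/end
    source_lengths: np.ndarray
    seed: int | None


def sample_random_regions(
    source_lengths,
    chrom_sizes: dict[str, int],
    n: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    length_weighted: bool = False,
) -> RandomRegionSample:
    """Draw ``n`` random regions length-matched to ``source_lengths``.

    Chromosome choice is uniform over chromosomes by default
    (``length_weighted=True`` weights by chromosome length); the start is
    uniform on the chromosome; the length is sampled with replacement from
    the source lengths; draws that do not fit are rejected and retried.

    Sampling draws from the exact conditional distribution of that
    rejection process (chromosome-length pairs weighted by their acceptance
    probability, then a uniform fitting start), so even lengths that fit a
    chromosome at a single start position are handled without looping.
    """
    lengths = np.asarray(source_lengths, dtype=np.int64)
    if n <= 0 or lengths.size == 0:
        raise ValueError("need n > 0 and at least one source length")
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if lengths.min() > sizes.max():
        raise ValueError("no source length fits any chromosome")
    if rng is None:
        rng = np.random.default_rng(seed)
    chrom_w = sizes / sizes.sum() if length_weighted else np.full(len(chroms), 1 / len(chroms))
    ulen, ucount = np.unique(lengths, return_counts=True)
    # acceptance probability of (chrom c, length L): fitting starts / size
    fit = np.maximum(0, sizes[:, None] - ulen[None, :] + 1) / sizes[:, None]
    w = chrom_w[:, None] * (ucount / lengths.size)[None, :] * fit
    total = w.sum()
    if total <= 0:
        raise ValueError("no source length fits any chromosome")
    flat = w.ravel() / total
    picks = rng.choice(flat.size, size=n, p=flat)
    ci, li = np.unravel_index(picks, w.shape)
    starts = rng.integers(0, sizes[ci] - ulen[li] + 1)
    regions = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in ci],
            "start": starts.astype(np.int64),
            "end": (starts + ulen[li]).astype(np.int64),
        }
    )
    return RandomRegionSample(regions, lengths, seed)


def region_mean_wa(regions: pd.DataFrame, wa: WATrack, warn: bool = True) -> np.ndarray:
    """Mean WA over the measured loci each region overlaps.

    Regions overlapping no measured locus are dropped (NaN filtered) with
    a warning.
    """
    means = np.full(len(regions), np.nan)
    for i, region in enumerate(regions.itertuples(index=False)):
        if region.chrom not in wa.grid.chrom_sizes:
            continue
        idx = overlapping_loci(wa.grid, region.chrom, region.start, region.end)
        idx = idx[wa.mask[idx]]
        if idx.size:
            means[i] = float(np.mean(wa.values[idx]))
    bad = np.isnan(means)
    if bad.any() and warn:
        warnings.warn(f"dropped {int(bad.sum())} region(s) with no measured loci")
    return means[~bad]


def region_wa_null_test(
    regions: pd.DataFrame,
    random_sample: RandomRegionSample,
    wa: WATrack,
    tail: str = "two-sided",
    exact_max_n: int | None = None,
) -> dict:
    """Observed vs null per-region mean WA, compared by Mann-Whitney.

    ``exact_max_n`` forwards to the rank test's exact-enumeration switch.
    Returns the two mean-WA samples and the test result.
    """
    obs = region_mean_wa(regions, wa)
    null = region_mean_wa(random_sample.regions, wa)
    if obs.size == 0 or null.size == 0:
        raise ValueError("no scorable regions in the observed or null set")
    kwargs = {} if exact_max_n is None else {"exact_max_n": exact_max_n}
    res = stats.mann_whitney(obs, null, tail=tail, **kwargs)
    return {
        "observed_means": obs,
        "null_means": null,
        "statistic": res.statistic,
        "p": res.p,
        "tail": tail,
        "method": res.method,
        "flags": res.flags,
    }


def _overlaps_any(regions: pd.DataFrame, domains: pd.DataFrame) -> np.ndarray:
    """Boolean per region: shares >= 1 bp with any domain."""
    out = np.zeros(len(regions), dtype=bool)
    by_chrom = {c: sub for c, sub in domains.groupby("chrom", sort=False)}
    for i, region in enumerate(regions.itertuples(index=False)):
        sub = by_chrom.get(region.chrom)
        if sub is None:
            continue
        out[i] = bool(
            ((sub["start"] < region.end) & (sub["end"] > region.start)).any()
        )
    return out


def overlap_binomial_test(
    regions: pd.DataFrame,
    domains: pd.DataFrame,
    random_sample: RandomRegionSample,
) -> dict:
    """Exact binomial test of domain overlap against the randomised null.

    p0 is the proportion of random regions overlapping any domain; the
    one-sided p is P(X >= k) for k observed overlapping regions out of n.
    """
    if random_sample.regions.empty:
        raise ValueError("empty random sample")
    k = int(_overlaps_any(regions, domains).sum())
    n = len(regions)
    p0 = float(_overlaps_any(random_sample.regions, domains).mean())
    flags = []
    if p0 == 0.0 and k > 0:
        flags.append("null-never-overlaps")
        p = 0.0
    else:
        p = stats.binomial_exact(k, n, p0, tail="ge").p
    return {"k": k, "n": n, "p0": p0, "p": p, "flags": flags}
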
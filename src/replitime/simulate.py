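"""Synthetic Repli-Seq study generator with known ground truth.

Every analysis stage in the package can be exercised end-to-end on data
from this module: a piecewise-constant replication-timing landscape with
planted differential domains, six-fraction Poisson read-count tracks whose
expected fraction profile is a unimodal (Gaussian) kernel over each locus's
true timing, timing-coupled chromatin marks / methylation / LADs, biased
rearrangement breakpoints, and a multi-sample cancer vs non-cancer matrix
with planted conserved domains.

Truth timing is expressed as "earliness" e in [0, 1] (1 = earliest); the
six fraction kernel centres run from e = 1 (G1b) down to e = 0 (G2M), so a
locus's expected WA increases monotonically with e and spans roughly the
5-85 band of the 0-91.7 WA scale at the default bandwidth.

Default conditions (chosen once, as the desk-scale study design): two
50 Mb chromosomes at 1 kb bins (100k loci), expected depth 30 reads per
locus per fraction with a 15% uniform nonspecific background, replicate
timing noise sd 0.03 earliness units (after the 50 kb window the replicate
WA tracks agree at r^2 > 0.99 and their largest |dWA| stays well below the
25-unit change cutoff), early/late segment levels 0.8/0.2 with +/-0.05
per-segment jitter, planted differential domains of mean length 300 kb
shifted by 0.65 earliness units (~40 WA units).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .grid import LocusGrid, TrackValues, build_grid, intervals_from_labels
from .integration import MarkSet
from .repliseq import FRACTIONS, WATrack, average_replicates, wa_from_locus_counts


@dataclass
class SimulationConfig:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000}
    )
    bin_width: int = 1000
    segment_mean_bp: float = 1_000_000.0
    early_level: float = 0.8
    late_level: float = 0.2
    level_jitter: float = 0.05
    # planted differential domains (case vs control)
    n_later_domains: int = 12
    n_earlier_domains: int = 8
    domain_mean_bp: float = 300_000.0
    domain_min_bp: int = 150_000
    delta_timing: float = 0.65     # ~40 WA units at the default kernel
    # sequencing model
    depth: float = 30.0            # expected reads per locus per fraction
    kernel_bandwidth: float = 0.12
    background: float = 0.15       # nonspecific share of signal, spread evenly
    replicate_noise_sd: float = 0.03
    # epigenome coupling: logistic occupancy p = sigmoid(b0 + b1 * e)
    mark_coupling: dict = field(
        default_factory=lambda: {
            "normal": {"H3K9me3": (2.0, -8.0), "H3K27me3": (0.0, -4.0)},
            "cancer": {"H3K9me3": (-1.0, -4.0), "H3K27me3": (1.5, -6.0)},
        }
    )
    meth_concentration: float = 50.0
    meth_mean: dict = field(
        default_factory=lambda: {
            "normal": (0.80, 0.85),   # (late-locus mean, early-locus mean)
            "cancer": (0.45, 0.80),
        }
    )
    lad_boundary_jitter_bp: int = 0
    lad_shift_bp: int = 0            # systematic case-LAD boundary shift
    # rearrangements
    n_pairs: int = 500
    cis_fraction: float = 0.5
    cis_late_bias: float = 0.8
    trans_early_bias: float = 0.8
    breakpoint_pool_fraction: float = 0.2  # biased draws target this truth quantile
    early_e: float | None = None     # optional absolute earliness thresholds
    late_e: float | None = None      # (override the quantile pools)
    # multi-sample mode
    n_per_group: int = 5
    include_esc: bool = True
    sample_timing_sd: float = 0.02
    n_shared_ecd: int = 4
    n_shared_lcd: int = 6
    shared_delta: float = 0.55
    seed: int = 0

    def rng(self, *key: object) -> np.random.Generator:
        """Deterministic child generator for a named simulation stage."""
        digest = zlib.crc32("/".join(map(str, key)).encode())
        ss = np.random.SeedSequence([self.seed, digest % (2**31)])
        return np.random.default_rng(ss)


# ----------------------------------------------------------------- landscape

def _place_domains(
    rng: np.random.Generator,
    grid: LocusGrid,
    count: int,
    mean_bp: float,
    min_bp: int,
    taken: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    placed: list[tuple[str, int, int]] = []
    tries = 0
    while len(placed) < count:
        tries += 1
        if tries > 10_000:
            raise RuntimeError("could not place non-overlapping planted domains")
        chrom = grid.chroms[rng.integers(len(grid.chroms))]
        size = grid.chrom_sizes[chrom]
        length = int(max(min_bp, rng.exponential(mean_bp)))
        length = (length // grid.bin_width) * grid.bin_width
        if length >= size:
            continue
        start = int(rng.integers(0, size - length)) // grid.bin_width * grid.bin_width
        cand = (chrom, start, start + length)
        if any(c == chrom and s < cand[2] and e > cand[1] for c, s, e in taken + placed):
            continue
        placed.append(cand)
    return placed


def simulate_timing_landscape(
    config: SimulationConfig,
) -> tuple[TrackValues, TrackValues, pd.DataFrame]:
    """Ground-truth earliness tracks for control ("normal") and case
    ("cancer") plus the planted-domain table.

    The landscape alternates early/late segments with exponential lengths;
    the case copy differs from the control only inside planted domains,
    where timing is shifted by ``delta_timing`` later or earlier (clipped
    to [0, 1]).
    """
    grid = build_grid(config.chrom_sizes, config.bin_width, exclude=())
    rng = config.rng("landscape")
    truth = np.empty(grid.n_loci)
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        n = sl.stop - sl.start
        pos = 0
        state = bool(rng.integers(2))
        while pos < n:
            seg = max(1, int(rng.exponential(config.segment_mean_bp) / config.bin_width))
            base = config.early_level if state else config.late_level
            level = np.clip(base + rng.uniform(-config.level_jitter, config.level_jitter), 0, 1)
            truth[sl.start + pos: sl.start + min(n, pos + seg)] = level
            pos += seg
            state = not state

    normal = TrackValues(grid, truth.copy())
    cancer = TrackValues(grid, truth.copy())
    placed: list[tuple[str, int, int]] = []
    rows = []
    for direction, count in (("later", config.n_later_domains), ("earlier", config.n_earlier_domains)):
        doms = _place_domains(
            rng, grid, count, config.domain_mean_bp, config.domain_min_bp, placed
        )
        placed.extend(doms)
        sign = -1.0 if direction == "later" else 1.0
        for chrom, start, end in doms:
            off = grid.chrom_slice(chrom).start
            lo, hi = off + start // config.bin_width, off + end // config.bin_width
            # a timing change needs headroom for the full shift, so the
            # control copy inside a planted domain starts at the level the
            # shift departs from (early for later-domains, late for earlier)
            base = config.early_level if direction == "later" else config.late_level
            jitter = config.rng("domain-level", chrom, start).uniform(
                -config.level_jitter, config.level_jitter
            )
            normal.values[lo:hi] = np.clip(base + jitter, 0, 1)
            cancer.values[lo:hi] = np.clip(
                base + jitter + sign * config.delta_timing, 0, 1
            )
            rows.append((chrom, start, end, direction))
    domains = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)
    return normal, cancer, domains


# ------------------------------------------------------------ fraction model

#: kernel centres in earliness units, one per fraction, G1b first
FRACTION_CENTRES = np.linspace(1.0, 0.0, len(FRACTIONS))


def fraction_weights(
    earliness: np.ndarray, bandwidth: float, background: float = 0.0
) -> np.ndarray:
    """Expected fraction profile (6 x n, columns sum to 1).

    ``background`` mixes in a uniform share across fractions, emulating the
    nonspecific signal BrdU immunoprecipitation leaves in every sorting
    gate; without it distant fractions would carry essentially zero reads
    and the low-coverage CPM filter would reject every locus.
    """
    e = np.asarray(earliness, dtype=float)
    if bandwidth <= 0:
        w = np.zeros((len(FRACTIONS), e.size))
        nearest = np.argmin(np.abs(e[None, :] - FRACTION_CENTRES[:, None]), axis=0)
        w[nearest, np.arange(e.size)] = 1.0
    else:
        z = (e[None, :] - FRACTION_CENTRES[:, None]) / bandwidth
        w = np.exp(-0.5 * z**2)
        w = w / w.sum(axis=0, keepdims=True)
    return (1.0 - background) * w + background / len(FRACTIONS)


def simulate_fraction_counts(
    truth: TrackValues,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, TrackValues]:
    """Six per-fraction Poisson count tracks for one replicate.

    Replicate noise: Gaussian jitter (sd ``replicate_noise_sd``) on the
    earliness before kernel evaluation.  Counts are
    Poisson(6 * depth * w_f) so the expected per-fraction count at a locus
    averages ``depth``.
    """
    e = np.clip(
        truth.values + rng.normal(0.0, config.replicate_noise_sd, truth.values.size),
        0.0, 1.0,
    )
    w = fraction_weights(e, config.kernel_bandwidth, config.background)
    lam = len(FRACTIONS) * config.depth * w
    out = {}
    for i, f in enumerate(FRACTIONS):
        counts = rng.poisson(lam[i]).astype(float)
        out[f] = TrackValues(truth.grid, counts, truth.mask.copy())
    return out


def simulate_wa(
    truth: TrackValues,
    config: SimulationConfig,
    sample: str,
    replicate: str,
) -> WATrack:
    """One replicate's WA track through the full density pipeline
    (50 kb window sums, CPM against read totals, 5-CPM filter, PNDV, WA)."""
    rng = config.rng("fractions", sample, replicate)
    counts = simulate_fraction_counts(truth, config, rng)
    return wa_from_locus_counts(counts, sample=sample, replicate=replicate)


def simulate_sample_wa(
    truth: TrackValues, config: SimulationConfig, sample: str
) -> tuple[WATrack, float]:
    """Replicate-averaged WA for a sample (two replicates) plus replicate r^2."""
    rep1 = simulate_wa(truth, config, sample, "rep1")
    rep2 = simulate_wa(truth, config, sample, "rep2")
    return average_replicates(rep1, rep2)


# ----------------------------------------------------------------- epigenome

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_epigenome(
    truths: dict[str, TrackValues],
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, MarkSet]], dict[str, TrackValues], dict[str, pd.DataFrame]]:
    """Timing-coupled marks, methylation and LADs per sample.

    Mark occupancy is Bernoulli(logistic(b0 + b1 * earliness)) per locus,
    with runs of positives emitted as intervals.  Methylation is Beta with
    a timing-interpolated mean.  LADs are the late (earliness < 0.5)
    segments with optional boundary jitter/shift.
    """
    marks: dict[str, dict[str, MarkSet]] = {}
    meth: dict[str, TrackValues] = {}
    lads: dict[str, pd.DataFrame] = {}
    for sample, truth in truths.items():
        grid = truth.grid
        e = truth.values
        rng = config.rng("epigenome", sample)
        marks[sample] = {}
        for mark, (b0, b1) in config.mark_coupling.get(sample, {}).items():
            p = _sigmoid(b0 + b1 * e)
            occ = rng.random(grid.n_loci) < p
            ivs = intervals_from_labels(grid, occ.astype(np.int8), 1)
            marks[sample][mark] = MarkSet(f"{sample}_{mark}", ivs, kind="broad_domain")
        late_mu, early_mu = config.meth_mean.get(sample, (0.8, 0.8))
        mu = np.clip(late_mu + (early_mu - late_mu) * e, 1e-3, 1 - 1e-3)
        conc = config.meth_concentration
        vals = rng.beta(mu * conc, (1 - mu) * conc)
        meth[sample] = TrackValues(grid, vals, truth.mask.copy())
        lad_iv = intervals_from_labels(grid, (e < 0.5).astype(np.int8), 1)
        if config.lad_boundary_jitter_bp or (config.lad_shift_bp and sample != "normal"):
            shift = config.lad_shift_bp if sample != "normal" else 0
            jit = config.lad_boundary_jitter_bp
            starts = lad_iv["start"].to_numpy() + shift + (
                rng.integers(-jit, jit + 1, len(lad_iv)) if jit else 0
            )
            ends = lad_iv["end"].to_numpy() + shift + (
                rng.integers(-jit, jit + 1, len(lad_iv)) if jit else 0
            )
            keep = ends > starts
            lad_iv = pd.DataFrame(
                {
                    "chrom": lad_iv["chrom"][keep],
                    "start": np.maximum(0, starts[keep]),
                    "end": ends[keep],
                }
            ).reset_index(drop=True)
            for i, chrom in enumerate(lad_iv["chrom"]):
                lad_iv.loc[i, "end"] = min(lad_iv.loc[i, "end"], grid.chrom_sizes[chrom])
        lads[sample] = lad_iv
    return marks, meth, lads


# ------------------------------------------------------------ rearrangements

def simulate_rearrangements(
    truth: TrackValues,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Breakpoint pairs with configurable cis-late / trans-early bias.

    With probability ``cis_late_bias`` a cis pair draws both breakends from
    the late pool — the latest-replicating ``breakpoint_pool_fraction`` of
    loci by true timing (or, when set, loci with earliness <= ``late_e``) —
    of one chromosome, otherwise uniformly; trans pairs analogously from
    the early pool on two distinct chromosomes.
    """
    if rng is None:
        rng = config.rng("rearrangements")
    grid = truth.grid
    e = truth.values
    late_thr = (
        config.late_e if config.late_e is not None
        else float(np.quantile(e, config.breakpoint_pool_fraction))
    )
    early_thr = (
        config.early_e if config.early_e is not None
        else float(np.quantile(e, 1 - config.breakpoint_pool_fraction))
    )
    late = np.flatnonzero(e <= late_thr)
    early = np.flatnonzero(e >= early_thr)
    if (config.cis_late_bias > 0 and late.size == 0) or (
        config.trans_early_bias > 0 and early.size == 0
    ):
        raise ValueError("no late/early loci available for biased sampling")
    if len(grid.chroms) < 2 and config.n_pairs:
        raise ValueError("trans pairs need >= 2 chromosomes")

    def pos_in(locus: int) -> tuple[str, int]:
        iv = grid.locus(int(locus))
        return iv.chrom, int(rng.integers(iv.start, iv.end))

    def uniform_locus(chrom: str | None = None) -> int:
        if chrom is None:
            return int(rng.integers(grid.n_loci))
        sl = grid.chrom_slice(chrom)
        return int(rng.integers(sl.start, sl.stop))

    rows = []
    n_cis = int(round(config.n_pairs * config.cis_fraction))
    for i in range(config.n_pairs):
        cis = i < n_cis
        if cis:
            if rng.random() < config.cis_late_bias:
                chrom = grid.chroms[rng.integers(len(grid.chroms))]
                sl = grid.chrom_slice(chrom)
                pool = late[(late >= sl.start) & (late < sl.stop)]
                if pool.size >= 2:
                    la, lb = rng.choice(pool, 2)
                elif pool.size == 1:
                    la = lb = int(pool[0])
                else:  # no late locus on this chromosome; unbiased fallback
                    la = uniform_locus(chrom)
                    lb = uniform_locus(chrom)
            else:
                la = uniform_locus()
                lb = uniform_locus(grid.locus(la).chrom)
            (ca, pa), (cb, pb) = pos_in(la), pos_in(lb)
        else:
            if rng.random() < config.trans_early_bias:
                pool = early
                while True:
                    la, lb = rng.choice(pool, 2)
                    if grid.locus(int(la)).chrom != grid.locus(int(lb)).chrom:
                        break
            else:
                while True:
                    la, lb = uniform_locus(), uniform_locus()
                    if grid.locus(la).chrom != grid.locus(lb).chrom:
                        break
            (ca, pa), (cb, pb) = pos_in(la), pos_in(lb)
        subtype = (
            "translocation" if not cis
            else ("inversion" if rng.random() < 0.5 else "deletion")
        )
        rows.append((ca, pa, cb, pb, subtype, "simulated"))
    return pd.DataFrame(
        rows, columns=["chrom_a", "pos_a", "chrom_b", "pos_b", "subtype", "source"]
    )


# ------------------------------------------------------------- multi-sample

def simulate_multisample(config: SimulationConfig):
    """Cancer vs non-cancer WA matrix with planted conserved domains.

    Each sample's timing is the shared landscape plus per-sample Gaussian
    noise; cancer samples additionally share ``n_shared_ecd`` earlier and
    ``n_shared_lcd`` later planted domains of shift ``shared_delta``.  WA
    is computed per sample through the full fraction-count pipeline (two
    replicates, averaged).  Returns (SampleMatrix, planted-domain table).
    """
    from .conserved import SampleMatrix

    base_cfg = replace(
        config,
        n_later_domains=config.n_shared_lcd,
        n_earlier_domains=config.n_shared_ecd,
        delta_timing=config.shared_delta,
    )
    normal_truth, cancer_truth, planted = simulate_timing_landscape(base_cfg)
    planted["class"] = np.where(planted["direction"] == "earlier", "ECD", "LCD")
    rng = config.rng("multisample")
    tracks: dict[str, TrackValues] = {}
    groups: dict[str, str] = {}
    names = [f"cancer_{i+1}" for i in range(config.n_per_group)] + [
        f"normal_{i+1}" for i in range(config.n_per_group)
    ]
    if config.include_esc:
        names.append("ESC")
    wa_tracks = {}
    for name in names:
        base = cancer_truth if name.startswith("cancer") else normal_truth
        e = np.clip(base.values + rng.normal(0, config.sample_timing_sd, base.values.size), 0, 1)
        truth = TrackValues(base.grid, e, base.mask.copy())
        wa, _ = simulate_sample_wa(truth, config, name)
        wa_tracks[name] = TrackValues(wa.grid, wa.values, wa.mask)
        groups[name] = "cancer" if name.startswith("cancer") else "non-cancer"
    sm = SampleMatrix.from_tracks(
        wa_tracks, groups, esc="ESC" if config.include_esc else None
    )
    return sm, planted


# ------------------------------------------------------------------- dataset

def write_dataset(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write a complete synthetic study to ``out_dir`` as plain-text files.

    Emits chrom.sizes, per-fraction count bedGraphs for two replicates of
    both samples, truth/planted-domain BEDs, mark and LAD BEDs, methylation
    bedGraphs, a breakpoint BEDPE and a sample sheet.  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    normal, cancer, planted = simulate_timing_landscape(config)
    rio.write_chrom_sizes(config.chrom_sizes, out / "chrom.sizes")
    paths["chrom_sizes"] = str(out / "chrom.sizes")
    rio.write_bed(planted.assign(name=planted["direction"]), out / "planted_domains.bed")
    paths["planted_domains"] = str(out / "planted_domains.bed")
    truths = {"normal": normal, "cancer": cancer}
    for sample, truth in truths.items():
        for rep in ("rep1", "rep2"):
            rng = config.rng("fractions", sample, rep)
            counts = simulate_fraction_counts(truth, config, rng)
            for f, track in counts.items():
                p = out / f"{sample}_{rep}_{f}.bedgraph"
                rio.write_track(track, p)
                paths[f"{sample}_{rep}_{f}"] = str(p)
    marks, meth, lads = simulate_epigenome(truths, config)
    for sample in truths:
        for mark, ms in marks[sample].items():
            p = out / f"{sample}_{mark}.bed"
            rio.write_bed(ms.intervals, p)
            paths[f"{sample}_{mark}"] = str(p)
        p = out / f"{sample}_meth.bedgraph"
        rio.write_track(meth[sample], p)
        paths[f"{sample}_meth"] = str(p)
        p = out / f"{sample}_LADs.bed"
        rio.write_bed(lads[sample], p)
        paths[f"{sample}_LADs"] = str(p)
    pairs = simulate_rearrangements(normal, config)
    bedpe = pd.DataFrame(
        {
            "chrom1": pairs["chrom_a"], "start1": pairs["pos_a"], "end1": pairs["pos_a"] + 1,
            "chrom2": pairs["chrom_b"], "start2": pairs["pos_b"], "end2": pairs["pos_b"] + 1,
            "name": pairs["subtype"],
        }
    )
    rio.write_bedpe(bedpe, out / "rearrangements.bedpe")
    paths["rearrangements"] = str(out / "rearrangements.bedpe")
    sheet = pd.DataFrame(
        {
            "sample": ["normal", "cancer"],
            "group": ["non-cancer", "cancer"],
            "esc_flag": [False, False],
        }
    )
    rio.write_tsv(sheet, out / "samples.tsv")
    paths["sample_sheet"] = str(out / "samples.tsv")
    return paths
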
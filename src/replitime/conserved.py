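"""Multi-sample replication-timing comparison: normalisation, clustering
with bootstrap stability, and conserved cancer-domain calling.

WA tracks from many cell lines are joined on their shared measured loci,
quantile-normalised, and (for domain calling) standardised per sample.  A
moderated two-group t contrasts cancer against non-cancer samples per
locus; loci passing FDR < 0.05 with |logFC| >= 1 merge (within 50 kb, per
sign) into earlier-in-cancer (ECD) and later-in-cancer (LCD) domains, which
are then annotated with cross-sample variance classes and, when an
embryonic stem cell sample is present, with whether the cancer timing has
moved toward the ESC state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from . import stats
from .domains import merge_domains
from .grid import LocusGrid, TrackValues, overlapping_loci


@dataclass
class SampleMatrix:
    """Loci x samples WA values on jointly measured loci.

    ``loci`` holds the global grid indices of the retained rows; ``groups``
    maps each sample to 'cancer' or 'non-cancer'; ``esc`` optionally names
    the embryonic stem cell sample.
    """

    grid: LocusGrid
    values: pd.DataFrame           # index: locus grid index; columns: samples
    groups: dict[str, str]
    esc: str | None = None
    state: str = "raw"             # raw | quantile | quantile+scaled

    @classmethod
    def from_tracks(
        cls, tracks: dict[str, TrackValues], groups: dict[str, str], esc: str | None = None
    ) -> "SampleMatrix":
        grids = {id(t.grid) for t in tracks.values()}
        first = next(iter(tracks.values())).grid
        if any(t.grid != first for t in tracks.values()):
            raise ValueError("samples on different grids")
        mask = np.ones(first.n_loci, dtype=bool)
        for t in tracks.values():
            mask &= t.mask
        idx = np.flatnonzero(mask)
        df = pd.DataFrame({name: t.values[idx] for name, t in tracks.items()}, index=idx)
        return cls(first, df, dict(groups), esc=esc)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]


# ------------------------------------------------------------ normalisation

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-based quantile normalisation with tie averaging.

    Every column's sorted values are replaced by the row-means of the
    column-sorted matrix; tied values receive the mean of the reference
    values their ranks span.  Idempotent.
    """
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def scale_samples(matrix: pd.DataFrame, per_locus: bool = False) -> pd.DataFrame:
    """Standardise to mean 0 / sd 1 per sample (or per locus)."""
    if per_locus:
        mu = matrix.mean(axis=1)
        sd = matrix.std(axis=1, ddof=1).replace(0, 1.0)
        return matrix.sub(mu, axis=0).div(sd, axis=0)
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1).replace(0, 1.0)
    return (matrix - mu) / sd


def normalize_matrix(sm: SampleMatrix, scale: bool = True) -> SampleMatrix:
    values = quantile_normalize(sm.values)
    state = "quantile"
    if scale:
        values = scale_samples(values)
        state = "quantile+scaled"
    return SampleMatrix(sm.grid, values, sm.groups, esc=sm.esc, state=state)


# ---------------------------------------------------------------- clustering

@dataclass
class ClusterReport:
    pc_coordinates: pd.DataFrame
    variance_explained: np.ndarray
    linkage: np.ndarray
    labels: pd.Series
    bootstrap_jaccard: pd.Series


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.sum(a | b)
    return float(np.sum(a & b) / union) if union else 0.0


def embed_and_cluster(
    matrix: pd.DataFrame, k: int, B: int = 100, seed: int | None = None
) -> ClusterReport:
    """PCA + Ward (ward.D2 on Euclidean distances) + bootstrap stability.

    Samples are observations (columns of ``matrix``).  Stability: loci are
    resampled with replacement B times, samples reclustered and cut at k,
    and each original cluster matched to the most similar bootstrap cluster
    by Jaccard; the per-cluster mean Jaccard is reported.
    """
    samples = list(matrix.columns)
    if k < 2 or k > len(samples):
        raise ValueError("need 2 <= k <= number of samples")
    x = matrix.to_numpy(dtype=float).T          # samples x loci
    pca = PCA(n_components=min(len(samples), x.shape[1]))
    coords = pca.fit_transform(x - x.mean(axis=0))
    pc = pd.DataFrame(
        coords, index=samples,
        columns=[f"PC{i+1}" for i in range(coords.shape[1])],
    )
    link = hierarchy.linkage(x, method="ward")
    labels = pd.Series(hierarchy.fcluster(link, k, criterion="maxclust"), index=samples)
    rng = np.random.default_rng(seed)
    sums = np.zeros(k)
    orig_sets = [labels.to_numpy() == c for c in range(1, k + 1)]
    for _ in range(B):
        take = rng.integers(0, x.shape[1], size=x.shape[1])
        bl = hierarchy.fcluster(hierarchy.linkage(x[:, take], method="ward"), k, "maxclust")
        boot_sets = [bl == c for c in np.unique(bl)]
        for ci, orig in enumerate(orig_sets):
            sums[ci] += max(_jaccard(orig, b) for b in boot_sets)
    jac = pd.Series(sums / B, index=[f"cluster_{c}" for c in range(1, k + 1)])
    return ClusterReport(pc, pca.explained_variance_ratio_, link, labels, jac)


# ------------------------------------------------------------ domain calling

ECD, LCD = "ECD", "LCD"


def call_conserved_cancer_domains(
    sm: SampleMatrix,
    fdr: float = 0.05,
    lfc: float = 1.0,
    gap_bp: int = 50_000,
    normalize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loci consistently earlier/later in cancer, merged into ECD/LCD domains.

    Per locus: moderated t of cancer vs non-cancer on the
    quantile-normalised, per-sample-standardised scale; BH FDR.  Loci with
    FDR < ``fdr`` and |logFC| >= ``lfc`` merge within ``gap_bp`` per sign:
    positive logFC (earlier in cancer) -> ECD, negative -> LCD.

    Returns (domains, per-locus statistics).
    """
    work = normalize_matrix(sm, scale=True) if normalize else sm
    cancer = work.samples_in("cancer")
    normal = work.samples_in("non-cancer")
    if not cancer or not normal:
        raise ValueError("need samples in both groups")
    if min(len(cancer), len(normal)) == 1:
        warnings.warn("a group has a single sample; ordinary-t fallback inside moderated_t")
    res = stats.moderated_t(
        work.values[cancer].to_numpy(), work.values[normal].to_numpy()
    )
    loci = work.values.index.to_numpy()
    per_locus = pd.DataFrame(
        {"locus": loci, "logfc": res.logfc, "t": res.t, "p": res.p, "fdr": res.fdr}
    )
    passing = (res.fdr < fdr) & (np.abs(res.logfc) >= lfc)
    labels = np.zeros(work.grid.n_loci, dtype=np.int8)
    labels[loci[passing & (res.logfc > 0)]] = 1
    labels[loci[passing & (res.logfc < 0)]] = -1
    delta_full = np.zeros(work.grid.n_loci)
    delta_full[loci] = res.logfc
    fdr_full = np.ones(work.grid.n_loci)
    fdr_full[loci] = res.fdr
    delta = TrackValues(work.grid, delta_full)
    domains = merge_domains(labels, work.grid, gap_bp=gap_bp, delta=delta)
    if not domains.empty:
        domains["class"] = np.where(domains["direction"] == "earlier", ECD, LCD)
        domains = domains.rename(columns={"mean_delta": "mean_logfc"})
        min_fdr = []
        for d in domains.itertuples(index=False):
            idx = overlapping_loci(work.grid, d.chrom, d.start, d.end)
            sel = idx[labels[idx] != 0]
            min_fdr.append(float(fdr_full[sel].min()) if sel.size else np.nan)
        domains["min_fdr"] = min_fdr
    else:
        for col in ("class", "min_fdr"):
            domains[col] = pd.Series(dtype=object if col == "class" else float)
        domains = domains.rename(columns={"mean_delta": "mean_logfc"})
    return domains, per_locus


def variation_classes(sm: SampleMatrix, fraction: float = 0.20) -> pd.Series:
    """Per-locus cross-sample variance class: high / low / mid.

    High and low are the top and bottom ``fraction`` of loci by sample
    variance (ties resolved by rank, so class sizes are within 1 of the
    target).
    """
    if sm.values.shape[1] < 3:
        raise ValueError("need >= 3 samples for a variance ranking")
    var = sm.values.var(axis=1, ddof=1)
    n = len(var)
    k = int(round(fraction * n))
    order = np.argsort(var.to_numpy(), kind="stable")
    out = np.full(n, "mid", dtype=object)
    out[order[:k]] = "low"
    out[order[n - k:]] = "high"
    return pd.Series(out, index=sm.values.index, name="variation")


def annotate_variation(
    domains: pd.DataFrame, classes: pd.Series, grid: LocusGrid
) -> pd.DataFrame:
    """Flag domains overlapping (>=1 bp, i.e. >=1 locus) high/low-variance loci."""
    high = classes.index[classes == "high"].to_numpy()
    low = classes.index[classes == "low"].to_numpy()
    out = domains.copy()
    hi_flags, lo_flags = [], []
    for d in domains.itertuples(index=False):
        idx = overlapping_loci(grid, d.chrom, d.start, d.end)
        hi_flags.append(bool(np.isin(idx, high).any()))
        lo_flags.append(bool(np.isin(idx, low).any()))
    out["high_variation"] = hi_flags
    out["low_variation"] = lo_flags
    return out


def esc_association(
    domains: pd.DataFrame, sm: SampleMatrix, margin: float = 0.5
) -> pd.DataFrame:
    """Flag domains whose cancer timing sits near the ESC timing state.

    Per domain the mean over domain loci of (mean cancer - ESC) on the
    normalised/scaled scale is compared with ``margin``: an ECD is
    ESC-associated when the difference is below ``margin``, an LCD when it
    is above ``-margin``.
    """
    if sm.esc is None or sm.esc not in sm.values.columns:
        raise ValueError("no ESC sample in the matrix")
    work = sm if sm.state == "quantile+scaled" else normalize_matrix(sm, scale=True)
    cancer = work.samples_in("cancer")
    diff = work.values[cancer].mean(axis=1) - work.values[work.esc]
    out = domains.copy()
    flags, diffs = [], []
    for _, d in domains.iterrows():
        idx = overlapping_loci(work.grid, d["chrom"], d["start"], d["end"])
        vals = diff.reindex(idx).dropna()
        m = float(vals.mean()) if len(vals) else np.nan
        diffs.append(m)
        if not np.isfinite(m):
            flags.append(False)
        elif d["class"] == ECD:
            flags.append(m < margin)
        else:
            flags.append(m > -margin)
    out["esc_diff"] = diffs
    out["esc_associated"] = flags
    return out
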
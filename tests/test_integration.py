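"""Timing stratification of marks, methylation, promoters, states, LADs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from sklearn.isotonic import IsotonicRegression

from replitime.grid import TrackValues, build_grid
from replitime.integration import (
    GAIN,
    HYPER,
    HYPO,
    LOSS,
    STABLE,
    STABLE_ABSENT,
    STABLE_PRESENT,
    MarkSet,
    combinatorial_states,
    element_association,
    lad_boundary_analysis,
    mark_gain_loss,
    methylation_delta,
    percentile_occupancy,
    profile_matrix,
    promoter_table,
    promoter_windows,
)
from replitime.repliseq import WATrack
from replitime import simulate as sim


def wa_track(values, chrom="c", mask=None):
    grid = build_grid({chrom: 1000 * len(values)}, 1000, exclude=())
    return WATrack(grid, np.asarray(values, float),
                   np.ones(len(values), bool) if mask is None else np.asarray(mask, bool))


def mark_from_bool(grid, occupied, name="m"):
    rows = []
    for i in np.flatnonzero(occupied):
        loc = grid.locus(int(i))
        rows.append((loc.chrom, loc.start, loc.end))
    return MarkSet(name, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestPercentileOccupancy:
    def test_full_and_empty_mark(self, rng):
        wa = wa_track(rng.uniform(0, 91.7, 500))
        full = mark_from_bool(wa.grid, np.ones(500, bool))
        occ = percentile_occupancy(wa, full, n_bins=100)
        assert (occ["occupancy"] == 1.0).all()
        empty = MarkSet("none", pd.DataFrame(columns=["chrom", "start", "end"]))
        occ0 = percentile_occupancy(wa, empty, n_bins=100)
        assert (occ0["occupancy"] == 0.0).all()

    def test_top_half_mark_is_step_function(self, rng):
        values = rng.permutation(np.linspace(0, 91.7, 400))
        wa = wa_track(values)
        top_half = values > np.median(values)
        occ = percentile_occupancy(wa, top_half, n_bins=100)
        assert (occ["occupancy"][:50] == 0.0).all()
        assert (occ["occupancy"][50:] == 1.0).all()

    def test_equal_count_bins_partition_masked_loci(self, rng):
        n = 1037
        wa = wa_track(rng.uniform(0, 91.7, n))
        occ = percentile_occupancy(wa, np.zeros(n, bool), n_bins=100)
        counts = occ["n_loci"].to_numpy()
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1

    def test_logistic_coupling_gives_monotone_occupancy(self):
        cfg = sim.SimulationConfig(
            chrom_sizes={"chr1": 5_000_000}, seed=11,
            n_later_domains=2, n_earlier_domains=1,
        )
        normal, _, _ = sim.simulate_timing_landscape(cfg)
        wa = WATrack(normal.grid, normal.values * 91.7, normal.mask)
        rng = cfg.rng("occupancy-test")
        p = 1 / (1 + np.exp(-(2.0 - 8.0 * normal.values)))  # late-enriched
        occupied = rng.random(normal.grid.n_loci) < p
        occ = percentile_occupancy(wa, occupied, n_bins=50)
        iso = IsotonicRegression(increasing=False).fit(
            occ["percentile"], occ["occupancy"]
        )
        resid = occ["occupancy"] - iso.predict(occ["percentile"])
        assert np.sqrt(np.mean(resid**2)) < 0.05


class TestGainLoss:
    def test_rules(self):
        grid = build_grid({"c": 4000}, 1000, exclude=())
        case = mark_from_bool(grid, np.array([True, True, False, False]))
        control = mark_from_bool(grid, np.array([True, False, True, False]))
        labels = mark_gain_loss(case, control, grid)
        assert labels.tolist() == [STABLE_PRESENT, GAIN, LOSS, STABLE_ABSENT]


class TestMethylationDelta:
    @pytest.mark.parametrize(
        "control, case, expected",
        [
            (0.9, 0.6, HYPO),        # loss of 0.3, eligible
            (0.15, 0.0, STABLE),     # control below eligibility floor
            (0.5, 0.75, HYPER),      # gain 0.25 from below 0.8
            (0.9, 0.95, STABLE),     # hyper blocked: control >= 0.8
            (0.5, 0.45, STABLE),     # change below threshold
        ],
    )
    def test_rules(self, control, case, expected):
        grid = build_grid({"c": 1000}, 1000, exclude=())
        got = methylation_delta(
            TrackValues(grid, np.array([control])),
            TrackValues(grid, np.array([case])),
        )
        assert got[0] == expected

    def test_masked_locus_invariance(self, rng):
        grid = build_grid({"c": 5000}, 1000, exclude=())
        control = rng.uniform(0, 1, 5)
        case = rng.uniform(0, 1, 5)
        base = methylation_delta(
            TrackValues(grid, control), TrackValues(grid, case)
        )
        masked = np.array([True, True, False, True, True])
        got = methylation_delta(
            TrackValues(grid, control, masked), TrackValues(grid, case, masked)
        )
        assert got[2] == STABLE
        assert np.array_equal(got[masked], base[masked])


class TestElementAssociation:
    def test_independent_element_or_one(self):
        n = 400
        grid = build_grid({"c": n * 1000}, 1000, exclude=())
        universe = np.ones(n, bool)
        query = np.zeros(n, bool)
        query[: n // 2] = True
        elem = np.zeros(n, bool)
        elem[::2] = True  # exactly half of query and half of non-query
        df = element_association(query, [("e", elem)], universe)
        assert df.iloc[0]["odds_ratio"] == pytest.approx(1.0)
        assert df.iloc[0]["p"] == pytest.approx(1.0)

    def test_perfect_alignment_capped_or(self):
        n = 20
        universe = np.ones(n, bool)
        query = np.arange(n) < 10
        df = element_association(query, [("e", query.copy())], universe)
        assert df.iloc[0]["or_corrected"]
        assert df.iloc[0]["p"] == pytest.approx(2 / 184_756, rel=1e-9)

    def test_matches_hypergeometric_on_random_tables(self, rng):
        """Two-sided Fisher equals mass-<=-observed hypergeometric sums."""
        for _ in range(500):
            n = int(rng.integers(4, 30))
            universe = np.ones(n, bool)
            query = rng.random(n) < rng.uniform(0.2, 0.8)
            elem = rng.random(n) < rng.uniform(0.2, 0.8)
            if not query.any():
                continue
            df = element_association(query, [("e", elem)], universe)
            a = int((query & elem).sum()); K = int(elem.sum()); nq = int(query.sum())
            probs = hypergeom.pmf(
                np.arange(max(0, nq + K - n), min(nq, K) + 1), n, K, nq
            )
            p_obs = hypergeom.pmf(a, n, K, nq)
            want = probs[probs <= p_obs * (1 + 1e-9)].sum()
            assert df.iloc[0]["p"] == pytest.approx(min(want, 1.0), abs=1e-12)

    def test_fdr_across_elements(self, rng):
        n = 200
        universe = np.ones(n, bool)
        query = rng.random(n) < 0.5
        elems = [(f"e{i}", rng.random(n) < 0.5) for i in range(8)]
        df = element_association(query, elems, universe)
        assert (df["fdr"] >= df["p"] - 1e-12).all()

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            element_association(
                np.array([True, True]), [("e", np.array([True, False]))],
                np.array([True, False]),
            )


class TestPromoters:
    def genes(self):
        return pd.DataFrame(
            {
                "gene": ["g_plus", "g_edge"],
                "chrom": ["c", "c"],
                "tss": [10_000, 500],
                "strand": ["+", "-"],
            }
        )

    def test_window_and_clipping(self):
        grid = build_grid({"c": 50_000}, 1000, exclude=())
        win = promoter_windows(self.genes(), grid)
        assert (win.iloc[0]["start"], win.iloc[0]["end"]) == (9_000, 11_000)
        assert (win.iloc[1]["start"], win.iloc[1]["end"]) == (0, 1_500)
        assert not win.iloc[0]["clipped"] and win.iloc[1]["clipped"]

    def test_wa_labelling_and_cgi_flag(self):
        grid = build_grid({"c": 50_000}, 1000, exclude=())
        wa = WATrack(grid, np.full(grid.n_loci, 80.0), np.ones(grid.n_loci, bool))
        cgi = pd.DataFrame({"chrom": ["c"], "start": [9_500], "end": [9_600]})
        expr = pd.DataFrame({"gene": ["g_plus"], "logFC": [1.5], "mean_tpm": [12.0]})
        table = promoter_table(self.genes(), grid, wa=wa, cgi_intervals=cgi, expr=expr)
        row = table.set_index("gene").loc["g_plus"]
        assert row["mean_wa"] == pytest.approx(80.0)
        assert row["timing"] == "early"
        assert row["cgi_promoter"] == True  # noqa: E712
        assert row["logFC"] == 1.5

    def test_unknown_chromosome(self):
        grid = build_grid({"c": 50_000}, 1000, exclude=())
        bad = pd.DataFrame(
            {"gene": ["g"], "chrom": ["cX"], "tss": [100], "strand": ["+"]}
        )
        with pytest.raises(KeyError, match="cX"):
            promoter_windows(bad, grid)


class TestCombinatorialStates:
    def test_single_feature_all_positive(self):
        df = combinatorial_states({"f": np.ones(10, bool)})
        assert len(df) == 1 and df.iloc[0]["percentage"] == 100.0

    def test_two_features_multinomial_counts(self, rng):
        a = rng.random(2000) < 0.5
        b = rng.random(2000) < 0.5
        df = combinatorial_states({"a": a, "b": b})
        assert df["count"].sum() == 2000
        assert df["percentage"].sum() == pytest.approx(100.0)
        want = {
            (x, y): int(np.sum((a == x) & (b == y)))
            for x in (False, True) for y in (False, True)
        }
        for row in df.itertuples(index=False):
            assert row.count == want[(row.a, row.b)]
        assert (np.diff(df["count"].to_numpy()) <= 0).all()

    def test_restriction_filters_loci(self):
        f = np.array([True, True, False, False])
        late = np.array([True, False, True, False])
        df = combinatorial_states({"f": f}, restrict=late)
        assert df["count"].sum() == 2


class TestProfileMatrix:
    def test_bin_width_and_constant_track(self):
        grid = build_grid({"c": 10_000}, 1000, exclude=())
        track = TrackValues(grid, np.full(10, 20.0))
        regions = pd.DataFrame({"chrom": ["c"], "start": [2_000], "end": [7_000]})
        mat, means = profile_matrix(track, regions, n_bins=50)
        assert mat.shape == (1, 50)
        assert np.allclose(mat, 20.0)
        assert means[0] == pytest.approx(20.0)

    def test_linear_ramp_matches_per_bp_oracle(self):
        grid = build_grid({"c": 20_000}, 1000, exclude=())
        values = np.arange(20, dtype=float)  # per-locus ramp
        track = TrackValues(grid, values)
        regions = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [20_000]})
        mat, _ = profile_matrix(track, regions, n_bins=50)
        per_bp = np.repeat(values, 1000)
        edges = np.round(np.linspace(0, 20_000, 51)).astype(int)
        want = [per_bp[edges[b]:edges[b + 1]].mean() for b in range(50)]
        assert mat[0] == pytest.approx(want)

    def test_short_region_rejected(self):
        grid = build_grid({"c": 10_000}, 1000, exclude=())
        track = TrackValues(grid, np.zeros(10))
        short = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [30]})
        with pytest.raises(ValueError, match="shorter"):
            profile_matrix(track, short, n_bins=50)


class TestLadBoundaries:
    def lads(self, spans, chrom="c"):
        return pd.DataFrame(
            [(chrom, s, e) for s, e in spans], columns=["chrom", "start", "end"]
        )

    def test_identical_sets_zero_distance(self):
        wa = wa_track(np.linspace(0, 91.7, 300))
        lads = self.lads([(50_000, 120_000), (200_000, 260_000)])
        res = lad_boundary_analysis(lads, lads, wa, wa, window_bp=20_000)
        assert (res.boundaries["distance"] == 0).all()

    def test_sign_convention_upstream_negative(self):
        wa = wa_track(np.linspace(0, 91.7, 300))
        control = self.lads([(100_000, 200_000)])
        case = self.lads([(90_000, 200_000)])  # 5' edge moved 10 kb upstream
        res = lad_boundary_analysis(control, case, wa, wa, window_bp=20_000)
        d5 = res.boundaries.set_index("side").loc["5p", "distance"]
        assert d5 == -10_000

    def test_nearest_by_absolute_distance(self):
        wa = wa_track(np.linspace(0, 91.7, 300))
        control = self.lads([(100_000, 150_000)])
        case = self.lads([(95_000, 140_000), (107_000, 160_000)])
        res = lad_boundary_analysis(control, case, wa, wa, window_bp=20_000)
        d5 = res.boundaries.set_index("side").loc["5p", "distance"]
        assert d5 == -5_000  # candidates at -5 kb and +7 kb

    def test_extension_zone_detects_case_later(self, rng):
        n = 400
        control_vals = np.full(n, 60.0)
        case_vals = np.full(n, 60.0)
        # case LAD extends 30 kb upstream of the control 5' boundary at 200 kb
        case_vals[170:200] = 10.0  # newly lamina-associated -> late in case
        wa_control = wa_track(control_vals + rng.normal(0, 1, n))
        wa_case = wa_track(case_vals + rng.normal(0, 1, n))
        control = self.lads([(200_000, 300_000)])
        case = self.lads([(170_000, 300_000)])
        res = lad_boundary_analysis(control, case, wa_control, wa_case, window_bp=20_000)
        zone = res.zone_tests.set_index("zone").loc["extension"]
        assert zone["n_loci"] == 30
        assert zone["p"] < 1e-6
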
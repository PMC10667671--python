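"""Beta diversity: Bray-Curtis, NMDS, ANOSIM, SIMPER, time-lag, period bins."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from coresat import (
    CommunityTable,
    DistanceMatrix,
    anosim,
    bray_curtis,
    nmds,
    period_pair_dissimilarity,
    simper,
    time_lag,
)


def table(counts):
    counts = np.asarray(counts)
    return CommunityTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(counts.shape[0])],
            columns=[f"t{j}" for j in range(counts.shape[1])],
        )
    )


def dm_from_points(x, metric="euclidean", normalise=True):
    d = squareform(pdist(np.asarray(x, float), metric))
    if normalise and d.max() > 0:
        d = d / d.max()
    return DistanceMatrix(d, [f"s{i}" for i in range(len(x))])


class TestBrayCurtis:
    def test_worked_example(self):
        # x=(1,2), y=(2,1) -> (|1-2|+|2-1|)/(3+3) = 1/3
        dm = bray_curtis(table([[1, 2], [2, 1]]))
        assert dm.data[0, 1] == pytest.approx(1 / 3)

    def test_algebraic_identity(self):
        # BC = 1 - 2W/(A+B) with W the sum of elementwise minima of the
        # relative-abundance vectors
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 50, size=(5, 12))
            counts[:, 0] += 1  # no empty samples
            t = table(counts)
            rel = t.relative_abundance().to_numpy()
            dm = bray_curtis(t)
            for i in range(5):
                for j in range(i + 1, 5):
                    w = np.minimum(rel[i], rel[j]).sum()
                    expect = 1 - 2 * w / (rel[i].sum() + rel[j].sum())
                    assert dm.data[i, j] == pytest.approx(expect, abs=1e-12)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(2)
        t = table(rng.integers(1, 30, size=(8, 15)))
        dm = bray_curtis(t)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        np.testing.assert_allclose(dm.data, dm.data.T)
        assert np.diag(dm.data).max() == 0

    def test_distance_matrix_validation(self):
        bad = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(bad, ["a", "b"])


class TestNMDS:
    def test_recovers_planted_configuration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 2))
        dm = dm_from_points(pts)
        res = nmds(dm, seed=0)
        assert res.stress < 0.05
        got = pdist(np.asarray(res.coordinates))
        want = pdist(pts)
        assert stats.spearmanr(got, want).statistic > 0.99

    def test_monotone_invariance(self):
        # a monotone transform of the input distances preserves ranks, so
        # the recovered configuration has the same distance rank order
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        d = d / d.max()
        res_a = nmds(DistanceMatrix(d, [f"s{i}" for i in range(12)]), seed=1)
        res_b = nmds(DistanceMatrix(np.sqrt(d), [f"s{i}" for i in range(12)]), seed=1)
        da = pdist(np.asarray(res_a.coordinates))
        db = pdist(np.asarray(res_b.coordinates))
        assert stats.spearmanr(da, db).statistic > 0.95
        assert abs(res_a.stress - res_b.stress) < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        dm = dm_from_points(rng.normal(size=(10, 3)))
        a = nmds(dm, seed=42)
        b = nmds(dm, seed=42)
        np.testing.assert_allclose(np.asarray(a.coordinates), np.asarray(b.coordinates))


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        # two tight clusters far apart: every between-pair ranks above
        # every within-pair
        pts = np.r_[np.zeros((3, 2)), np.full((3, 2), 10.0)]
        pts += np.random.default_rng(0).normal(0, 0.01, pts.shape)
        res = anosim(dm_from_points(pts), ["a"] * 3 + ["b"] * 3, exact=True)
        assert res["R"] == pytest.approx(1.0)
        # only permutations preserving the partition reach R=1: p = 2/C(6,3)...
        # via full enumeration p counts permutations with R >= 1
        assert res["p"] == pytest.approx(72 / 720)

    def test_r_bounded_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = int(rng.integers(6, 10))
            pts = rng.normal(size=(n, 3))
            labels = rng.choice(["a", "b"], size=n)
            if len(set(labels)) < 2 or min((labels == "a").sum(), (labels == "b").sum()) < 2:
                continue
            res = anosim(dm_from_points(pts), labels, n_perm=9, seed=0)
            assert -1 - 1e-12 <= res["R"] <= 1 + 1e-12

    def test_add_one_p_floor(self):
        rng = np.random.default_rng(7)
        pts = np.r_[np.zeros((4, 2)), np.full((4, 2), 5.0)] + rng.normal(0, 0.01, (8, 2))
        res = anosim(dm_from_points(pts), ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert res["p"] >= 1 / 100


class TestSimper:
    def test_two_taxon_toy_brute_force(self):
        counts = np.array([[9, 1], [8, 2], [2, 8], [1, 9]])
        t = table(counts)
        groups = ["g1", "g1", "g2", "g2"]
        out = simper(t, groups)[("g1", "g2")]
        rel = t.relative_abundance().to_numpy()
        # brute force over the four between-group pairs
        contrib = np.zeros(2)
        bc = []
        pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
        for i, j in pairs:
            denom = (rel[i] + rel[j]).sum()
            terms = np.abs(rel[i] - rel[j]) / denom
            contrib += terms
            bc.append(terms.sum())
        contrib /= len(pairs)
        mean_bc = np.mean(bc)
        expect_pct = 100 * contrib / mean_bc
        got = out["average_contribution_pct"].reindex(["t0", "t1"]).to_numpy()
        np.testing.assert_allclose(np.sort(got), np.sort(expect_pct), rtol=1e-12)
        assert out.attrs["mean_between_group_dissimilarity"] == pytest.approx(mean_bc)

    def test_contributions_sorted_and_cumulative(self):
        rng = np.random.default_rng(8)
        t = table(rng.integers(1, 40, size=(8, 10)))
        out = simper(t, ["x"] * 4 + ["y"] * 4)[("x", "y")]
        vals = out["average_contribution_pct"].to_numpy()
        assert (np.diff(vals) <= 1e-12).all()  # descending
        np.testing.assert_allclose(out["cumulative_pct"], np.cumsum(vals), rtol=1e-12)
        assert out["cumulative_pct"].iloc[-1] == pytest.approx(100.0, abs=1e-9)


class TestTimeLag:
    def test_unit_convention(self):
        dm = DistanceMatrix(np.array([[0, 0.5], [0.5, 0]]), ["a", "b"])
        dates = pd.Timestamp("2015-01-01") + pd.to_timedelta([0.0, 30.44], unit="D")
        out = time_lag(dm, dates)
        assert out["pairs"]["lag_months"].iloc[0] == pytest.approx(1.0, rel=1e-9)

    def test_constant_dissimilarity(self):
        d = np.full((4, 4), 0.3)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, list("abcd"))
        dates = pd.date_range("2015-01-01", periods=4, freq="10D")
        out = time_lag(dm, dates)
        assert out["slope"] == 0.0
        assert out["p"] == 1.0

    def test_slope_recovery(self):
        rng = np.random.default_rng(9)
        n = 30
        dates = pd.date_range("2015-01-01", periods=n, freq="10D")
        days = (dates - dates[0]).days.to_numpy(float)
        lag_days = np.abs(days[:, None] - days[None, :])
        d = 0.01 * (lag_days / 30.44) + 0.2 + rng.normal(0, 0.005, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        d = np.clip(d, 0, 1)
        out = time_lag(DistanceMatrix(d, [f"s{i}" for i in range(n)]), dates)
        se = (out["slope"] - 0.01)
        assert abs(se) < 0.002
        assert out["p"] < 1e-6


class TestPeriodPairs:
    def test_bin_sizes(self):
        periods = ["before"] * 14 + ["mixing"] * 11 + ["after"] * 9
        rng = np.random.default_rng(10)
        t = table(rng.integers(1, 30, size=(34, 12)))
        out = period_pair_dissimilarity(bray_curtis(t), periods)
        sizes = {k: len(v) for k, v in out["bins"].items()}
        assert sizes == {
            "B-B": 91, "B-M": 154, "B-A": 126, "M-M": 55, "M-A": 99, "A-A": 36,
        }
        assert sum(sizes.values()) == 34 * 33 // 2

    def test_all_equal_distances_single_letter(self):
        d = np.full((9, 9), 0.4)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, [f"s{i}" for i in range(9)])
        periods = ["before"] * 3 + ["mixing"] * 3 + ["after"] * 3
        out = period_pair_dissimilarity(dm, periods)
        assert len(set(out["test"]["letters"].values())) == 1

    def test_surface_recovery_signature(self, default_dataset, surface_table):
        from coresat import occupancy_sets, partition_taxa

        periods = default_dataset.truth["periods"]
        core = surface_table.subset_taxa(occupancy_sets(partition_taxa(surface_table))["core"])
        bins = period_pair_dissimilarity(bray_curtis(core), periods)["bins"]
        assert np.median(bins["B-A"]) < np.median(bins["B-M"])
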
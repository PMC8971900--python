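"""Diversity metrics against hand-derived values and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from skbio import DistanceMatrix

import oralsite as o
from oralsite import ConfigurationError, OralsiteError


def brute_shannon(counts):
    p = np.asarray(counts, float)
    p = p[p > 0] / p.sum()
    return float(-(p * np.log2(p)).sum())


def brute_chao1(counts):
    c = np.asarray(counts)
    s_obs = (c > 0).sum()
    f1, f2 = (c == 1).sum(), (c == 2).sum()
    return float(s_obs + f1 * (f1 - 1) / (2 * (f2 + 1)))


def brute_simpson(counts):
    p = np.asarray(counts, float)
    p = p / p.sum()
    return float(1 - (p**2).sum())


def brute_bray_curtis(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(np.abs(x - y).sum() / (x + y).sum())


class TestAlphaMetrics:
    @pytest.mark.parametrize("counts,expected", [
        ([10, 10, 10, 10], 2.0),
        ([42], 0.0),
        ([75, 25], 0.8112781244591328),  # -0.75 log2 0.75 - 0.25 log2 0.25
    ])
    def test_shannon_values(self, counts, expected):
        assert o.shannon(counts) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("counts,expected", [
        ([5, 5, 5], 3.0),
        ([1, 1, 2, 5], 4.5),   # 4 + 2*1/(2*2)
        ([1, 1], 3.0),         # 2 + 2*1/(2*1)
    ])
    def test_chao1_values(self, counts, expected):
        assert o.chao1(counts) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("counts,expected", [
        ([1, 1], 0.5), ([7], 0.0), ([1, 1, 2], 0.625)])
    def test_simpson_values(self, counts, expected):
        assert o.simpson(counts) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("metric", ["shannon", "chao1", "simpson"])
    def test_all_zero_vector_rejected(self, metric):
        with pytest.raises(ConfigurationError):
            getattr(o, metric)([0, 0, 0])

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=20)
           .filter(lambda c: sum(c) > 0))
    @settings(max_examples=200, deadline=None)
    def test_metrics_match_brute_force(self, counts):
        assert o.shannon(counts) == pytest.approx(brute_shannon(counts), rel=1e-10)
        assert o.chao1(counts) == pytest.approx(brute_chao1(counts), rel=1e-10)
        assert o.simpson(counts) == pytest.approx(brute_simpson(counts), rel=1e-10)

    def test_shannon_maximized_by_uniform(self):
        """Grid search over small simplices never beats the uniform vector."""
        rng = np.random.default_rng(0)
        for k in (2, 3, 4, 6):
            uniform = o.shannon(np.full(k, 10.0))
            for _ in range(300):
                v = rng.dirichlet(np.ones(k)) * 1000
                assert o.shannon(v) <= uniform + 1e-9

    def test_chao1_at_least_observed_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            c = rng.integers(0, 6, size=12)
            if c.sum() == 0:
                continue
            assert o.chao1(c) >= (c > 0).sum()


class TestBrayCurtis:
    def test_identical_rows_distance_zero(self):
        rel = o.RelativeAbundanceTable(pd.DataFrame(
            [[0.5, 0.5], [0.5, 0.5]], index=["a", "b"], columns=["x", "y"]))
        assert o.bray_curtis(rel)["a", "b"] == 0.0

    def test_disjoint_supports_distance_one(self):
        rel = o.RelativeAbundanceTable(pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0]], index=["a", "b"], columns=["x", "y"]))
        assert o.bray_curtis(rel)["a", "b"] == 1.0

    def test_worked_example(self):
        rel = o.RelativeAbundanceTable(pd.DataFrame(
            [[0.6, 0.4, 0.0], [0.2, 0.4, 0.4]], index=["a", "b"],
            columns=["x", "y", "z"]))
        assert o.bray_curtis(rel)["a", "b"] == pytest.approx(0.4)

    def test_matrix_properties_on_random_data(self):
        rng = np.random.default_rng(3)
        comp = rng.dirichlet(np.ones(8), size=6)
        rel = o.RelativeAbundanceTable(pd.DataFrame(
            comp, index=[f"s{i}" for i in range(6)],
            columns=[f"f{i}" for i in range(8)]))
        dm = o.bray_curtis(rel)
        d = dm.data
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1).all()
        for i in range(6):
            for j in range(i):
                assert d[i, j] == pytest.approx(
                    brute_bray_curtis(comp[i], comp[j]), rel=1e-10)


class TestNMDS:
    def test_all_zero_distances_collapse(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = o.nmds(dm, seed=0)
        assert res.stress == 0.0
        assert np.allclose(res.coordinates.to_numpy(), 0)

    def test_recovers_exact_planar_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(18, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(18)])
        res = o.nmds(dm, seed=0)
        rho = spearmanr(pdist(pts), pdist(res.coordinates.to_numpy())).statistic
        assert rho >= 0.99
        assert res.stress < 0.05

    def test_habitats_separate_in_embedding(self, prepared_study):
        """Within-habitat embedded distances < between-habitat distances."""
        prepared, _, metadata, _ = prepared_study
        dm = o.bray_curtis(o.to_relative(prepared))
        res = o.nmds(dm, seed=0)
        coords = res.coordinates
        labels = metadata.habitat_of().loc[coords.index].to_numpy()
        d = squareform(pdist(coords.to_numpy()))
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices_from(d, k=1)
        within = d[iu][same[iu]].mean()
        between = d[iu][~same[iu]].mean()
        assert within < between


class TestGroupStatistics:
    def test_identical_groups_not_significant(self, tiny_metadata):
        values = pd.Series([1.0, 2.0, 1.0, 2.0],
                           index=["s1", "s3", "s2", "s4"])
        res = o.compare_groups(values, tiny_metadata)
        assert res.pvalue > 0.99
        assert res.means[0] == res.means[1]

    def test_sem_is_sd_over_sqrt_n(self, tiny_metadata):
        values = pd.Series([1.0, 4.0, 2.0, 8.0], index=["s1", "s3", "s2", "s4"])
        res = o.compare_groups(values, tiny_metadata)
        sal = values[["s1", "s3"]]
        assert res.sems[list(res.levels).index("saliva")] == pytest.approx(
            sal.std(ddof=1) / np.sqrt(2))

    def test_three_sd_shift_is_reliably_detected(self):
        """Power: a 3-SD mean shift at n=50/group gives p < 0.001."""
        rng = np.random.default_rng(0)
        meta = o.SampleMetadata(pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(50)] * 2,
            "habitat": ["saliva"] * 50 + ["buccal_mucosa"] * 50,
        }, index=[f"s{k}" for k in range(100)]))
        hits = 0
        for _ in range(100):
            x = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
            res = o.compare_groups(
                pd.Series(x, index=meta.sample_ids), meta)
            hits += res.pvalue < 0.001
        assert hits >= 95

    def test_small_group_rejected(self):
        meta = o.SampleMetadata(pd.DataFrame({
            "individual_id": ["a", "b", "c"],
            "habitat": ["saliva", "buccal_mucosa", "buccal_mucosa"],
        }, index=["s1", "s2", "s3"]))
        with pytest.raises(ConfigurationError):
            o.compare_groups(pd.Series([1.0, 2.0, 3.0], index=meta.sample_ids),
                             meta)


class TestSpearmanAge:
    def _meta(self, ages):
        n = len(ages)
        return o.SampleMetadata(pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(n)],
            "habitat": ["saliva"] * n,
            "age": ages,
        }, index=[f"s{k}" for k in range(n)]))

    def test_monotone_pairs(self):
        meta = self._meta([20, 30, 40, 50])
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=meta.sample_ids)
        assert o.spearman_age(values, meta)["saliva"].r == pytest.approx(1.0)
        assert o.spearman_age(-values, meta)["saliva"].r == pytest.approx(-1.0)

    def test_independent_data_uncorrelated(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(100):
            meta = self._meta(rng.integers(20, 51, size=50).tolist())
            values = pd.Series(rng.normal(size=50), index=meta.sample_ids)
            hits += abs(o.spearman_age(values, meta)["saliva"].r) < 0.3
        assert hits >= 95

    def test_constant_input_rejected(self):
        meta = self._meta([30, 30, 30, 30])
        with pytest.raises(OralsiteError):
            o.spearman_age(pd.Series([1.0, 2.0, 3.0, 4.0],
                                     index=meta.sample_ids), meta)


class TestDifferentialAbundance:
    def test_identical_groups_all_nonsignificant(self):
        comp = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        data = np.vstack([comp, comp])  # same compositions in both habitats
        rel = o.RelativeAbundanceTable(pd.DataFrame(
            data, index=[f"s{k}" for k in range(6)], columns=["a", "b", "c"]))
        meta = o.SampleMetadata(pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(6)],
            "habitat": ["saliva"] * 3 + ["buccal_mucosa"] * 3,
        }, index=rel.sample_ids))
        out = o.differential_abundance(rel, meta, top_n=None)
        assert (out["pvalue"] > 0.99).all()
        assert (out["stars"] == "ns").all()

    def test_rows_sorted_by_overall_mean(self, prepared_study):
        prepared, taxonomy, metadata, _ = prepared_study
        rel = o.to_relative(o.collapse(prepared, taxonomy, "genus"))
        out = o.differential_abundance(rel, metadata)
        assert len(out) == 10
        assert (out["overall_mean"].diff().dropna() <= 1e-12).all()

    def test_streptococcus_flagged_toward_mucosa(self):
        cfg = o.SimulationConfig(n_individuals=50, reads=20_000,
                                 n_rare_taxa=150, seed=21)
        table, tax, meta = o.generate_paired_study(cfg)
        rel = o.to_relative(o.collapse(table, tax, "genus"))
        out = o.differential_abundance(rel, meta)
        row = out.loc["Streptococcus"]
        assert row["pvalue"] < 0.001 and row["stars"] == "***"
        assert row["mean_buccal_mucosa"] > row["mean_saliva"]
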
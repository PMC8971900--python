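"""Unique-species detection, core microbiome and microbial-code matching."""

import numpy as np
import pandas as pd
import pytest

import oralsite as o
from oralsite import ConfigurationError, OralsiteError


def _meta(pairs):
    """pairs: list of (sample_id, individual_id, habitat)."""
    return o.SampleMetadata(pd.DataFrame(
        [(i, h) for _, i, h in pairs],
        index=[s for s, _, _ in pairs],
        columns=["individual_id", "habitat"]))


class TestFindUniqueTaxa:
    @pytest.fixture
    def handmade(self):
        # sp_top abundant everywhere; sp_shared in two individuals;
        # sp_i1 only in i1's samples; sp_i2 only in i2's one sample
        table = o.FeatureTable(pd.DataFrame(
            {"sp_top": [500, 480, 510, 490],
             "sp_shared": [3, 0, 2, 0],
             "sp_i1": [2, 1, 0, 0],
             "sp_i2": [0, 0, 4, 0]},
            index=["a1", "a2", "b1", "b2"]))
        meta = _meta([("a1", "i1", "saliva"), ("a2", "i1", "buccal_mucosa"),
                      ("b1", "i2", "saliva"), ("b2", "i2", "buccal_mucosa")])
        return table, meta

    def test_unique_species_confined_to_one_individual(self, handmade):
        table, meta = handmade
        res = o.find_unique_taxa(table, meta, rank_threshold=1)
        assert res.per_individual == {"i1": ["sp_i1"], "i2": ["sp_i2"]}
        assert res.fraction == 1.0

    def test_shared_species_excluded(self, handmade):
        table, meta = handmade
        res = o.find_unique_taxa(table, meta, rank_threshold=1)
        assert "sp_shared" not in [s for v in res.per_individual.values() for s in v]

    def test_top_ranked_species_excluded_even_if_unique(self):
        table = o.FeatureTable(pd.DataFrame(
            {"dominant_i1": [900, 900, 0, 0],
             "shared_x": [80, 80, 500, 500],
             "shared_y": [20, 20, 500, 500]},
            index=["a1", "a2", "b1", "b2"]))
        meta = _meta([("a1", "i1", "saliva"), ("a2", "i1", "buccal_mucosa"),
                      ("b1", "i2", "saliva"), ("b2", "i2", "buccal_mucosa")])
        res = o.find_unique_taxa(table, meta, rank_threshold=1)
        # dominant_i1 occurs only in i1 but ranks 1st -> not reported
        assert res.per_individual == {"i1": [], "i2": []}
        assert res.fraction == 0.0

    def test_planted_design_recovered_exactly(self):
        """1 planted species in 13 of 25 subjects -> fraction 13/25 = 0.52."""
        sal, muc = o.default_profiles(theta=2000.0)
        cfg = o.SimulationConfig(n_individuals=25, reads=20_000,
                                 n_rare_taxa=150, rare_logseries_x=0.9999,
                                 seed=17)
        table, tax, meta = o.generate_paired_study(cfg, sal, muc)
        table, tax, truth = o.inject_unique_species(
            table, meta, 1, rel_abundance=2e-4, seed=17, individuals=13,
            taxonomy=tax)
        assert not truth.warnings
        species = o.collapse(table, tax, "species")
        res = o.find_unique_taxa(species, meta, rank_threshold=100)
        assert res.fraction == pytest.approx(0.52)
        assert res.discriminated == sorted(truth.per_individual)


class TestCoreTaxa:
    def test_core_membership_rules(self):
        table = o.FeatureTable(pd.DataFrame(
            {"everywhere": [5, 5, 5, 5],
             "one_sample_each": [9, 0, 3, 0],
             "missing_from_i2": [4, 2, 0, 0]},
            index=["a1", "a2", "b1", "b2"]))
        meta = _meta([("a1", "i1", "saliva"), ("a2", "i1", "buccal_mucosa"),
                      ("b1", "i2", "saliva"), ("b2", "i2", "buccal_mucosa")])
        assert o.core_taxa(table, meta) == ["everywhere", "one_sample_each"]

    def test_sixteen_core_genera_by_construction(self):
        sal, muc = o.core_seeded_profiles()
        cfg = o.SimulationConfig(n_individuals=20, reads=20_000,
                                 n_rare_taxa=300, rare_tail_shape="uniform",
                                 individual_weight=0.2, seed=13)
        table, tax, meta = o.generate_paired_study(cfg, sal, muc)
        core = o.core_taxa(o.collapse(table, tax, "genus"), meta)
        assert sorted(core) == sorted(o.CORE_GENERA)

    def test_adding_individuals_never_grows_the_core(self, small_study):
        table, tax, meta = small_study
        genus = o.collapse(table, tax, "genus")
        some = meta.individuals[:6]
        ids = [s for s in meta.sample_ids
               if meta.individual_of()[s] in some]
        core_subset = o.core_taxa(genus.filter_samples(ids), meta.subset(ids))
        core_all = o.core_taxa(genus, meta)
        assert set(core_all) <= set(core_subset)


class TestMicrobialCode:
    def test_rows_sum_to_one_and_depth_invariance(self, small_study):
        table, tax, meta = small_study
        genus = o.collapse(table, tax, "genus")
        core = o.core_taxa(genus, meta)
        code = o.microbial_code(genus, meta, core, habitat="saliva")
        assert np.allclose(code.sum(axis=1), 1.0, atol=1e-9)
        doubled = o.FeatureTable(genus.data * 2)
        code2 = o.microbial_code(doubled, meta, core, habitat="saliva")
        pd.testing.assert_frame_equal(code, code2)

    def test_fully_core_community_is_unchanged(self):
        table = o.FeatureTable(pd.DataFrame(
            {"a": [6, 6], "b": [3, 3], "c": [1, 1]}, index=["s1", "s2"]))
        meta = _meta([("s1", "i1", "saliva"), ("s2", "i2", "saliva")])
        code = o.microbial_code(table, meta, ["a", "b", "c"])
        assert code.loc["i1"].tolist() == pytest.approx([0.6, 0.3, 0.1])

    def test_empty_core_rejected(self, small_study):
        table, tax, meta = small_study
        genus = o.collapse(table, tax, "genus")
        with pytest.raises(ConfigurationError):
            o.microbial_code(genus, meta, [])

    def test_zero_core_total_names_individual(self):
        table = o.FeatureTable(pd.DataFrame(
            {"a": [5, 0], "b": [0, 9]}, index=["s1", "s2"]))
        meta = _meta([("s1", "i1", "saliva"), ("s2", "i2", "saliva")])
        with pytest.raises(OralsiteError, match="i2"):
            o.microbial_code(table, meta, ["a"])


class TestMatchCode:
    @pytest.fixture
    def references(self):
        return pd.DataFrame(
            [[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.3, 0.3, 0.4]],
            index=["i1", "i2", "i3"], columns=["a", "b", "c"])

    def test_exact_match_ranks_first_at_zero(self, references):
        out = o.match_code(references.loc["i2"], references)
        assert out.index[0] == "i2"
        assert out.loc["i2", "distance"] == 0.0

    def test_disjoint_query_all_ones_ties_by_id(self, references):
        refs = pd.DataFrame([[1.0, 0.0], [1.0, 0.0]], index=["i2", "i1"],
                            columns=["a", "b"])
        query = pd.Series([0.0, 1.0], index=["a", "b"])
        out = o.match_code(query, refs)
        assert (out["distance"] == 1.0).all()
        assert list(out.index) == ["i1", "i2"]

    def test_taxon_order_mismatch_rejected(self, references):
        query = references.loc["i1"][::-1]
        with pytest.raises(ConfigurationError):
            o.match_code(query, references)

    def test_cross_habitat_self_matching_beats_chance(self, small_study):
        table, tax, meta = small_study
        genus = o.collapse(table, tax, "genus")
        core = o.core_taxa(genus, meta)
        saliva = o.microbial_code(genus, meta, core, habitat="saliva")
        mucosa = o.microbial_code(genus, meta, core, habitat="buccal_mucosa")
        hits = sum(o.match_code(saliva.loc[ind], mucosa).index[0] == ind
                   for ind in saliva.index)
        assert hits / len(saliva.index) > 1 / len(saliva.index)

    def test_report_bundle(self, small_study):
        table, tax, meta = small_study
        species = o.collapse(table, tax, "species")
        genus = o.collapse(table, tax, "genus")
        report = o.discrimination_report(species, genus, meta, habitat="saliva")
        d = report.as_dict()
        assert d["habitat"] == "saliva"
        assert 0 <= d["discriminated_fraction"] <= 1
        assert d["n_core"] == len(report.core)
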
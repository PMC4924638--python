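"""Environment panels, core/segment classification, enrichment and trends."""

import numpy as np
import pandas as pd
import pytest

from protalloc.model import (
    CatalyzedReaction,
    ConfigurationError,
    MEModel,
    ModelError,
    ProteinSpec,
    RibosomeSpec,
)
from protalloc.segmentation import (
    classify_proteome,
    enumerate_environments,
    growth_correlation_by_group,
    growth_trend,
    regulon_enrichment,
    segment_masses,
    select_top_nonme,
)
from protalloc.synthetic import ToyModelConfig, designed_membership, make_toy_model


@pytest.fixture(scope="module")
def panel(toy_model):
    return enumerate_environments(toy_model, {"C": "EX_c1", "N": "EX_n1"})


@pytest.fixture(scope="module")
def segments(toy_model, panel):
    return classify_proteome(toy_model, panel)


class TestPanel:
    def test_counts(self, panel):
        # 3 C-variants + 2 N-variants (base counted once per element)
        assert len(panel.variants) == 5
        assert len(panel.environments) == 3 + 2 - 1
        assert not panel.dropped

    def test_single_source_panel_is_base_only(self):
        model = make_toy_model(ToyModelConfig(n_carbon_sources=1, n_nitrogen_sources=1))
        panel = enumerate_environments(model, {"C": "EX_c1", "N": "EX_n1"})
        assert len(panel.environments) == 1

    def test_non_supporting_source_dropped(self, toy_model):
        """A tagged exchange whose metabolite feeds nothing is pruned."""
        dead_ex = CatalyzedReaction(
            "EX_dead", {"met_dead": 1.0}, is_exchange=True, element_tag="C"
        )
        # a sink so the metabolite appears in >= 1 non-exchange reaction
        sink = CatalyzedReaction("DEAD_SINK", {"met_dead": -1.0})
        model = MEModel(
            metabolites=toy_model.metabolites + ("met_dead",),
            proteins=toy_model.proteins,
            reactions=toy_model.reactions + (dead_ex, sink),
            ribosome=toy_model.ribosome,
            proteome_budget=toy_model.proteome_budget,
            biomass_reaction=toy_model.biomass_reaction,
        )
        panel = enumerate_environments(model, {"C": "EX_c1", "N": "EX_n1"})
        assert ("C", "EX_dead") in panel.dropped

    def test_missing_base_source_rejected(self, toy_model):
        with pytest.raises(ConfigurationError):
            enumerate_environments(toy_model, {"C": "EX_c1"})


class TestClassification:
    def test_designed_membership_recovered(self, toy_config, segments):
        designed = designed_membership(toy_config)
        assert segments.core == frozenset(designed["core"])
        assert segments.segments["C"] == frozenset(designed["C"])
        assert segments.segments["N"] == frozenset(designed["N"])

    def test_core_disjoint_from_segments(self, segments):
        for seg in segments.segments.values():
            assert not (segments.core & seg)

    def test_partition_covers_expressed_proteome(self, toy_model, segments):
        expressed_somewhere = frozenset().union(*segments.expressed_by_env.values())
        assert expressed_somewhere == segments.core | segments.noncore

    def test_single_environment_panel(self):
        config = ToyModelConfig(n_carbon_sources=1, n_nitrogen_sources=1)
        model = make_toy_model(config)
        panel = enumerate_environments(model, {"C": "EX_c1", "N": "EX_n1"})
        segs = classify_proteome(model, panel)
        assert segs.core == next(iter(segs.expressed_by_env.values()))
        assert all(not s for s in segs.segments.values())

    def test_core_shrinks_with_more_environments(self, toy_config, segments):
        smaller = ToyModelConfig(n_carbon_sources=1, n_nitrogen_sources=2)
        model = make_toy_model(smaller)
        panel = enumerate_environments(model, {"C": "EX_c1", "N": "EX_n1"})
        segs_small = classify_proteome(model, panel)
        # the wider panel's core is a subset of the narrower panel's core
        assert segments.core <= segs_small.core

    def test_shared_enzyme_lands_in_both_segments(self):
        """An enzyme used by an alt-C and an alt-N pathway joins C and N."""
        shared = ProteinSpec("E_shared", mw=1.0, length=2)
        ribo = ProteinSpec("ribosome", mw=1.0, length=2)
        dummy = ProteinSpec("unmodeled", mw=1.0, length=2, is_dummy=True)
        ec1 = ProteinSpec("E_c1", mw=1.0, length=2)
        en1 = ProteinSpec("E_n1", mw=1.0, length=2)
        model = MEModel(
            metabolites=("mc1", "mc2", "mn1", "mn2", "pc", "pn", "P"),
            proteins=(ec1, en1, shared, ribo, dummy),
            reactions=(
                CatalyzedReaction("EX_c1", {"mc1": 1.0}, is_exchange=True, element_tag="C"),
                CatalyzedReaction("EX_c2", {"mc2": 1.0}, is_exchange=True, element_tag="C"),
                CatalyzedReaction("EX_n1", {"mn1": 1.0}, is_exchange=True, element_tag="N"),
                CatalyzedReaction("EX_n2", {"mn2": 1.0}, is_exchange=True, element_tag="N"),
                CatalyzedReaction("R_c1", {"mc1": -1.0, "pc": 1.0}, {"E_c1": 10.0}),
                CatalyzedReaction("R_c2", {"mc2": -1.0, "pc": 1.0}, {"E_shared": 10.0}),
                CatalyzedReaction("R_n1", {"mn1": -1.0, "pn": 1.0}, {"E_n1": 10.0}),
                CatalyzedReaction("R_n2", {"mn2": -1.0, "pn": 1.0}, {"E_shared": 10.0}),
                CatalyzedReaction("COMBINE", {"pc": -1.0, "pn": -1.0, "P": 1.0}),
                CatalyzedReaction("BIOMASS", {"P": -1.0}),
            ),
            ribosome=RibosomeSpec("ribosome", kappa=20.0),
            proteome_budget=0.1,
            biomass_reaction="BIOMASS",
        )
        panel = enumerate_environments(model, {"C": "EX_c1", "N": "EX_n1"})
        segs = classify_proteome(model, panel)
        assert "E_shared" in segs.segments["C"]
        assert "E_shared" in segs.segments["N"]
        assert "E_shared" not in segs.core

    def test_isozyme_equality_expresses_all_isozymes(self):
        """Classification counts every capable isozyme of a used reaction."""
        iso_a = ProteinSpec("iso_a", mw=1.0, length=2)
        iso_b = ProteinSpec("iso_b", mw=1.0, length=2)
        ribo = ProteinSpec("ribosome", mw=1.0, length=2)
        dummy = ProteinSpec("unmodeled", mw=1.0, length=2, is_dummy=True)
        model = MEModel(
            metabolites=("S", "P"),
            proteins=(iso_a, iso_b, ribo, dummy),
            reactions=(
                CatalyzedReaction("EX_S", {"S": 1.0}, is_exchange=True, element_tag="C"),
                CatalyzedReaction("R1", {"S": -1.0, "P": 1.0}, {"iso_a": 10.0, "iso_b": 4.0}),
                CatalyzedReaction("BIOMASS", {"P": -1.0}),
            ),
            ribosome=RibosomeSpec("ribosome", kappa=20.0),
            proteome_budget=0.1,
            biomass_reaction="BIOMASS",
        )
        from protalloc.model import Environment
        from protalloc.solver import max_growth

        env = Environment("s", {"EX_S"})
        free = max_growth(model, env).expressed_set
        equal = max_growth(model, env, isozyme_equality=True).expressed_set
        assert free <= equal
        assert {"iso_a", "iso_b"} <= equal
        assert "iso_b" not in free  # the slower isozyme is skipped when free


class TestSegmentMasses:
    def test_hand_example(self, segments):
        core_protein = sorted(segments.core)[0]
        c_protein = sorted(segments.segments["C"])[0]
        table = pd.DataFrame(
            {"cond": {core_protein: 0.5, c_protein: 0.3, "other": 0.2}}
        )
        sets = {"cond": [frozenset({core_protein, c_protein})]}
        result = segment_masses(segments, table, sets)
        assert result.masses.loc["cond", "core"] == pytest.approx(0.5)
        assert result.masses.loc["cond", "C"] == pytest.approx(0.3)
        assert result.utilized_noncore["cond"] == pytest.approx(0.3)

    def test_empty_utilized_set(self, segments):
        table = pd.DataFrame({"cond": {sorted(segments.core)[0]: 1.0}})
        result = segment_masses(segments, table, {"cond": [frozenset()]})
        assert result.utilized_noncore["cond"] == pytest.approx(0.0)

    def test_all_mass_in_core(self, segments):
        rows = {p: 1.0 / len(segments.core) for p in segments.core}
        table = pd.DataFrame({"cond": rows})
        result = segment_masses(segments, table, {"cond": [frozenset(segments.core)]})
        assert result.masses.loc["cond", "C"] == pytest.approx(0.0)
        assert result.masses.loc["cond", "N"] == pytest.approx(0.0)


class TestTopNonME:
    table = pd.DataFrame({"cond": {"X": 0.5, "Y": 0.3, "Z": 0.2}})

    def test_eighty_percent_rule(self):
        assert select_top_nonme(self.table, me_set=set(), coverage=0.8) == ["X", "Y"]

    def test_full_coverage(self):
        assert select_top_nonme(self.table, me_set=set(), coverage=1.0) == [
            "X",
            "Y",
            "Z",
        ]

    def test_single_protein(self):
        table = pd.DataFrame({"cond": {"X": 0.1}})
        assert select_top_nonme(table, me_set=set(), coverage=0.5) == ["X"]

    def test_empty_nonme(self):
        assert select_top_nonme(self.table, me_set={"X", "Y", "Z"}) == []

    def test_union_across_conditions(self):
        table = pd.DataFrame(
            {
                "c1": {"X": 0.9, "Y": 0.05, "Z": 0.05},
                "c2": {"X": 0.05, "Y": 0.9, "Z": 0.05},
            }
        )
        assert select_top_nonme(table, me_set=set(), coverage=0.8) == ["X", "Y"]

    def test_invalid_coverage(self):
        with pytest.raises(ModelError):
            select_top_nonme(self.table, me_set=set(), coverage=0.0)


class TestEnrichment:
    def test_exact_combinatorial(self):
        """20 choose 5 universe; all-5 overlap has p = 6/15504."""
        universe = {f"p{i}" for i in range(20)}
        regulon = {f"p{i}" for i in range(6)}
        segment = {f"p{i}" for i in range(5)}
        res = regulon_enrichment(segment, regulon, universe)
        assert res.overlap == 5
        assert res.p_value == pytest.approx(6 / 15504, rel=1e-9)

    def test_empty_segment(self):
        res = regulon_enrichment(set(), {"a"}, {"a", "b"})
        assert res.overlap == 0
        assert res.p_value == pytest.approx(1.0)

    def test_segment_equals_universe(self):
        universe = {"a", "b", "c"}
        res = regulon_enrichment(universe, {"a"}, universe)
        assert res.overlap == 1
        assert res.p_value == pytest.approx(1.0)

    def test_empty_universe(self):
        with pytest.raises(ModelError):
            regulon_enrichment(set(), set(), set())


class TestTrends:
    def test_exact_line(self):
        x = {"a": 0.1, "b": 0.5, "c": 0.9}
        y = {k: 2 * v + 1 for k, v in x.items()}
        res = growth_trend(y, x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_series(self):
        x = {"a": 0.1, "b": 0.5, "c": 0.9}
        res = growth_trend({k: 0.3 for k in x}, x)
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_zero_x_variance(self):
        with pytest.raises(ModelError):
            growth_trend({"a": 1.0, "b": 2.0, "c": 3.0}, {k: 0.5 for k in "abc"})

    def test_grouped_correlation_signs(self):
        growth = {"c1": 0.2, "c2": 0.5, "c3": 0.8, "c4": 1.0}
        table = pd.DataFrame(
            {
                c: {"up": 0.1 + 0.5 * g, "down": 0.9 - 0.5 * g}
                for c, g in growth.items()
            }
        ).T.T  # protein x condition
        res = growth_correlation_by_group(
            table, growth, {"growth_linked": ["up"], "stress_linked": ["down"]}
        )
        assert res["growth_linked"] == pytest.approx(1.0)
        assert res["stress_linked"] == pytest.approx(-1.0)
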
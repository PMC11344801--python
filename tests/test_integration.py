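"""Expression-to-bound mapping and the sequential constrain/check/relax loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxcap import (
    ExpressionProfile,
    FixtureSpec,
    GrowthThreshold,
    apply_media,
    doubling_time,
    growth_rate,
    integrate,
    make_expression,
    make_toy_gem,
    optimize,
    parse_gpr,
    reaction_is_essential,
    rule_bounds,
)
from fluxcap.integration import UnsupportedRuleCategory
from fluxcap.media import media_locked_ids
from fluxcap.synthetic import chain_media

from lp_oracle import replay_integration


def profile(**values):
    return ExpressionProfile(sample_id="S", values=values)


class TestRuleBounds:
    @pytest.mark.parametrize(
        "rule, values, reversible, expected",
        [
            ("G1", {"G1": 3.0}, True, (-3.0, 3.0)),
            ("G1", {"G1": 3.0}, False, (0.0, 3.0)),
            ("G1 or G2", {"G1": 1.5, "G2": 2.5}, False, (0.0, 4.0)),
            ("G1 or G2", {"G1": 1.5, "G2": 2.5}, True, (-4.0, 4.0)),
            ("G1 and G2", {"G1": 2.0, "G2": 5.0}, True, (-2.0, 2.0)),
            ("G1 and G2", {"G1": 2.0, "G2": 5.0}, False, (0.0, 2.0)),
        ],
    )
    def test_table_formulas(self, rule, values, reversible, expected):
        assert rule_bounds(parse_gpr(rule), profile(**values), reversible) == expected

    @pytest.mark.parametrize("rule", ["(G1 and G2) or G3", ""])
    def test_unsupported_categories(self, rule):
        with pytest.raises(UnsupportedRuleCategory):
            rule_bounds(parse_gpr(rule), profile(G1=1, G2=1, G3=1), True)

    @given(
        values=st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=6),
        reversible=st.booleans(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bound_properties(self, values, reversible):
        """Sum rule dominates every component; min rule is dominated by
        every component; irreversible lower bound is always 0."""
        genes = {f"G{i}": v for i, v in enumerate(values)}
        expr = profile(**genes)
        or_rule = parse_gpr(" or ".join(genes))
        and_rule = parse_gpr(" and ".join(genes))
        lo_or, up_or = rule_bounds(or_rule, expr, reversible)
        lo_and, up_and = rule_bounds(and_rule, expr, reversible)
        assert up_or == pytest.approx(sum(values))
        assert up_or >= max(values) - 1e-12
        assert up_and == min(values)
        assert all(up_and <= v for v in values)
        if reversible:
            assert lo_or == pytest.approx(-up_or)
            assert lo_and == -up_and
        else:
            assert lo_or == 0.0 and lo_and == 0.0
        for gene, value in genes.items():
            lo1, up1 = rule_bounds(parse_gpr(gene), expr, reversible)
            assert up1 == value
            assert lo1 == (-value if reversible else 0.0)


class TestEssentiality:
    def test_sole_path_is_essential(self, single_chain):
        model, truth = single_chain
        assert reaction_is_essential(model, "R1_1")
        assert reaction_is_essential(model, truth.biomass_id)

    def test_redundant_branch_is_not(self, two_chain):
        model, _ = two_chain
        assert not reaction_is_essential(model, "R1_1")

    def test_zero_fraction_boundary(self, two_chain, single_chain):
        two_model, _ = two_chain
        one_model, _ = single_chain
        # fraction 0: only a KO optimum of exactly 0 counts... and even that
        # is not < 0, so nothing is essential
        assert not reaction_is_essential(two_model, "R1_1", essential_fraction=0.0)
        assert not reaction_is_essential(one_model, "R1_1", essential_fraction=0.0)

    def test_model_restored(self, two_chain):
        model, _ = two_chain
        before = model.reactions.get_by_id("R1_1").bounds
        reaction_is_essential(model, "R1_1")
        assert model.reactions.get_by_id("R1_1").bounds == before


class TestDoublingTime:
    def test_inverse_rule_reproduces_reported_range(self):
        assert round(doubling_time(0.22), 1) == 4.5
        assert round(doubling_time(0.11), 1) == 9.1
        assert doubling_time(1.0) == 1.0
        assert growth_rate(doubling_time(0.17)) == pytest.approx(0.17)

    def test_nonpositive_growth_rejected(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)
        with pytest.raises(ValueError):
            growth_rate(-1.0)


class TestIntegrate:
    def test_high_expression_keeps_all_constraints(self, two_chain_media):
        model, truth, _ = two_chain_media
        expr = make_expression(model, seed=2, base_level=20.0, sample_id="S1")
        threshold = GrowthThreshold("S1", doubling_time_h=1.0 / (truth.optimum / 2))
        constrained, report = integrate(model, expr, threshold)
        assert report.reopened == []
        assert report.final_growth == pytest.approx(truth.optimum)
        assert "constrained" in report.counts()

    def test_bottleneck_reopened_to_hold_threshold(self, two_chain_media):
        """A single low-expressed gene caps its reaction below the growth
        floor; exactly that reaction is reopened and the floor is held."""
        model, truth, _ = two_chain_media
        # G1 is the one-gene rule on R1_1 (first internal reaction of chain 1)
        assert truth.genes_by_reaction["R1_1"] == ["G1"]
        expr = make_expression(model, seed=2, low_genes=("G1",), low_value=0.5,
                               base_level=20.0, sample_id="S1")
        threshold = GrowthThreshold("S1", doubling_time_h=1.0 / 8.0)  # floor 8
        constrained, report = integrate(model, expr, threshold)
        assert report.reopened == ["R1_1"]
        assert report.final_growth >= threshold.growth_min - 1e-9
        # reopened reaction ends with its pre-integration bounds, bit-identical
        assert (constrained.reactions.get_by_id("R1_1").bounds
                == model.reactions.get_by_id("R1_1").bounds)

    def test_low_expression_kept_when_threshold_allows(self, two_chain_media):
        model, truth, _ = two_chain_media
        expr = make_expression(model, seed=2, low_genes=("G1",), low_value=0.5,
                               base_level=20.0, sample_id="S1")
        threshold = GrowthThreshold("S1", doubling_time_h=1.0)  # floor 1 << 5.5
        _, report = integrate(model, expr, threshold)
        assert report.reopened == []
        assert report.dispositions["R1_1"] == "constrained"

    def test_zero_floor_never_reopens(self, two_chain_media):
        model, _, _ = two_chain_media
        expr = make_expression(model, seed=5, low_genes=("G1", "G4"), low_value=0.01,
                               sample_id="S1")
        threshold = GrowthThreshold("S1", doubling_time_h=1e9)
        _, report = integrate(model, expr, threshold)
        assert report.reopened == []

    def test_unreachable_threshold_warns_and_uses_achievable_floor(self, two_chain_media):
        model, truth, _ = two_chain_media
        expr = make_expression(model, seed=2, base_level=20.0, sample_id="S1")
        threshold = GrowthThreshold("S1", doubling_time_h=1.0 / (10 * truth.optimum))
        with pytest.warns(UserWarning):
            _, report = integrate(model, expr, threshold)
        assert report.threshold_unreachable
        assert report.effective_floor == pytest.approx(truth.optimum)
        assert report.final_growth >= report.effective_floor - 1e-9

    def test_disposition_partition_and_media_lock(self, two_chain_media):
        model, _, media = two_chain_media
        expr = make_expression(model, seed=2, sample_id="S1")
        threshold = GrowthThreshold("S1", doubling_time_h=1.0)
        constrained, report = integrate(model, expr, threshold)
        assert set(report.dispositions) == {r.id for r in model.reactions}
        allowed = {"media_locked", "essential_locked", "andor_skipped",
                   "genes_missing", "constrained", "reopened"}
        assert set(report.dispositions.values()) <= allowed
        for rid in media.entries:
            assert report.dispositions[rid] == "media_locked"
            assert (constrained.reactions.get_by_id(rid).bounds
                    == model.reactions.get_by_id(rid).bounds)

    def test_determinism_double_run(self, two_chain_media):
        model, _, _ = two_chain_media
        expr = make_expression(model, seed=9, low_genes=("G1",), low_value=0.2,
                               sample_id="S1")
        threshold = GrowthThreshold("S1", doubling_time_h=0.125)
        _, first = integrate(model, expr, threshold)
        _, second = integrate(model, expr, threshold)
        assert first.dispositions == second.dispositions
        assert first.reopened == second.reopened
        assert first.final_growth == second.final_growth
        assert first.final_bounds == second.final_bounds

    def test_input_model_untouched(self, two_chain_media):
        model, _, _ = two_chain_media
        before = {r.id: r.bounds for r in model.reactions}
        expr = make_expression(model, seed=2, sample_id="S1")
        integrate(model, expr, GrowthThreshold("S1", doubling_time_h=0.2))
        assert {r.id: r.bounds for r in model.reactions} == before

    @pytest.mark.parametrize("seed, low_genes, floor_dt", [
        (2, ("G1",), 1.0 / 8.0),
        (4, ("G1", "G9"), 1.0 / 9.0),
        (6, (), 1.0 / 4.0),
        (8, ("G4",), 1.0 / 9.9),
    ])
    def test_matches_brute_force_replay(self, two_chain_media, seed, low_genes, floor_dt):
        """The sequential loop agrees with an independent step-by-step LP
        replay: identical reopened sets and dispositions, final optimum at
        or above the floor."""
        model, _, _ = two_chain_media
        expr = make_expression(model, seed=seed, low_genes=low_genes, low_value=0.3,
                               base_level=20.0, sample_id="S1")
        threshold = GrowthThreshold("S1", doubling_time_h=floor_dt)
        _, report = integrate(model, expr, threshold)
        reopened, final, dispositions = replay_integration(
            model, expr.values, threshold.growth_min, media_locked_ids(model)
        )
        assert report.reopened == reopened
        assert report.dispositions == dispositions
        assert report.final_growth == pytest.approx(final, abs=1e-6)
        assert report.final_growth >= min(threshold.growth_min,
                                          report.effective_floor) - 1e-9


def test_expression_profile_validation():
    with pytest.raises(ValueError):
        ExpressionProfile("S", {"G1": -1.0})
    with pytest.raises(ValueError):
        ExpressionProfile("S", {"G1": float("nan")})
    with pytest.raises(ValueError):
        GrowthThreshold("S", doubling_time_h=0.0)
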
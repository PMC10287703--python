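"""Propositional rule engine: firing, exclusivity, rendering, rule trees."""

import numpy as np
import pytest

from activcoach.errors import ConfigError, RenderError, SchemaError
from activcoach.records import GoalProfile
from activcoach.rules import (DecisionContext, check_exclusivity,
                              daily_rule_trees, default_kb, evaluate_daily,
                              evaluate_trees, evaluate_weekly, load_kb,
                              render_message, weekly_rule_trees)


def daily_ctx(goals, level=0, steps=4649, sedentary_s=1305, mpa_min=316 / 60,
              vpa_min=0.0, sleep_min=None):
    return DecisionContext(goals=goals, level=level, steps=steps,
                           sedentary_s=sedentary_s, mpa_min=mpa_min,
                           vpa_min=vpa_min, sleep_min=sleep_min)


def weekly_ctx(goals, **over):
    base = dict(week_id=3, sc=-20, current_deviation=9.2,
                previous_deviation=3.8, forecast_weekly_steps=32032.0,
                week_steps=4649 * 7, week_mpa_min=316 * 7 / 60,
                week_vpa_min=0.0, week_sedentary_s=1305 * 7,
                best_weeks=(1, 2))
    base.update(over)
    return DecisionContext(goals=goals, **base)


def random_daily_ctx(rng, goals):
    return daily_ctx(
        goals, level=int(rng.integers(0, 5)),
        steps=float(rng.uniform(0, 20000)),
        sedentary_s=float(rng.uniform(0, 60000)),
        mpa_min=float(rng.uniform(0, 120)), vpa_min=float(rng.uniform(0, 60)),
        sleep_min=None if rng.random() < 0.5 else float(rng.uniform(0, 600)))


def random_weekly_ctx(rng, goals):
    return weekly_ctx(
        goals, sc=int(rng.integers(-21, 8)),
        current_deviation=float(rng.uniform(0, 16)),
        previous_deviation=float(rng.uniform(0, 16)),
        forecast_weekly_steps=float(rng.uniform(0, 150000)),
        week_steps=float(rng.uniform(0, 150000)),
        week_mpa_min=float(rng.uniform(0, 800)),
        week_vpa_min=float(rng.uniform(0, 400)),
        week_sedentary_s=float(rng.uniform(0, 420000)))


class TestKnowledgeBase:
    def test_nineteen_message_variables_plus_weather(self):
        kb = default_kb()
        assert [f"A-{i}" for i in range(1, 20)] == \
            [v.id for v in kb.variables if v.id.startswith("A-")]
        assert kb.categories["weather"] == ["W-1", "W-2"]

    def test_each_variable_in_exactly_one_category(self):
        kb = default_kb()
        seen = [vid for ids in kb.categories.values() for vid in ids]
        assert sorted(seen) == sorted(kb.by_id)


class TestDailyEvaluation:
    def test_level0_day_fires_published_set(self, goals):
        fired = evaluate_daily(daily_ctx(goals, level=0))
        assert fired == {"A-1", "A-7", "A-8", "A-10", "A-15"}

    def test_level1_day_fires_published_set(self, goals):
        fired = evaluate_daily(daily_ctx(goals, level=1, steps=5200))
        assert fired == {"A-2", "A-7", "A-8", "A-10", "A-15"}

    def test_goal_meeting_day_fires_a14(self, goals):
        fired = evaluate_daily(daily_ctx(
            goals, level=4, steps=13000, sedentary_s=1000, mpa_min=30,
            vpa_min=10))
        assert "A-14" in fired and "A-15" not in fired

    def test_sleep_deficit_blocks_daily_goal(self, goals):
        fired = evaluate_daily(daily_ctx(
            goals, level=4, steps=13000, sedentary_s=1000, mpa_min=30,
            vpa_min=10, sleep_min=200.0))
        assert "A-15" in fired

    def test_missing_context_field_named(self, goals):
        ctx = daily_ctx(goals)
        ctx.steps = None
        with pytest.raises(ConfigError, match="steps"):
            evaluate_daily(ctx)


class TestWeeklyEvaluation:
    def test_week3_worked_example(self, goals):
        assert evaluate_weekly(weekly_ctx(goals)) == {"A-19", "A-17", "A-13"}

    def test_all_goals_met_and_steady(self, goals):
        ctx = weekly_ctx(goals, sc=2, current_deviation=1.0,
                         previous_deviation=2.0,
                         forecast_weekly_steps=90000.0, week_steps=90000,
                         week_mpa_min=300, week_vpa_min=60,
                         week_sedentary_s=100000)
        assert evaluate_weekly(ctx) == {"A-18", "A-16", "A-12"}

    def test_cold_start_skips_deviation_category(self, goals):
        ctx = weekly_ctx(goals, previous_deviation=None)
        fired = evaluate_weekly(ctx)
        assert not fired & {"A-16", "A-17"}

    def test_no_forecast_skips_trend_category(self, goals):
        ctx = weekly_ctx(goals, forecast_weekly_steps=None)
        fired = evaluate_weekly(ctx)
        assert not fired & {"A-12", "A-13"}
        assert fired & {"A-16", "A-17"} and fired & {"A-18", "A-19"}

    def test_strict_mode_keeps_printed_conjuncts(self, goals):
        # SC = -20 satisfies neither printed trend rule: category unresolved
        fired = evaluate_weekly(weekly_ctx(goals), strict=True)
        assert not fired & {"A-16", "A-17"}


class TestExclusivity:
    def test_published_daily_set_passes(self, goals):
        fired = evaluate_daily(daily_ctx(goals))
        ok, bad = check_exclusivity({v: True for v in fired})
        assert ok and bad == []

    def test_two_in_one_category_fails(self):
        ok, bad = check_exclusivity({"A-14": True, "A-15": True})
        assert not ok and bad == ["daily_goal"]

    def test_all_false_violates_every_category(self):
        ok, bad = check_exclusivity({"A-1": False})
        assert not ok and len(bad) == 8 and "weather" not in bad

    def test_unknown_variable_rejected(self):
        with pytest.raises(SchemaError):
            check_exclusivity({"A-99": True})

    def test_exclusivity_over_random_contexts(self, goals):
        """10 000 random daily+weekly contexts all satisfy exactly-one."""
        rng = np.random.default_rng(2024)
        for _ in range(5000):
            fired = evaluate_daily(random_daily_ctx(rng, goals))
            ok, _ = check_exclusivity({v: True for v in fired})
            assert ok
        for _ in range(5000):
            fired = evaluate_weekly(random_weekly_ctx(rng, goals))
            ok, _ = check_exclusivity({v: True for v in fired})
            assert ok

    def test_polarity_flip_changes_only_its_category(self, goals):
        base = daily_ctx(goals, level=2, steps=8000, sedentary_s=40000,
                         mpa_min=5, vpa_min=0)
        fired = evaluate_daily(base)
        flipped = daily_ctx(goals, level=2, steps=8000, sedentary_s=1000,
                            mpa_min=5, vpa_min=0)
        fired2 = evaluate_daily(flipped)
        assert fired ^ fired2 == {"A-6", "A-7"}


class TestRendering:
    def test_step_deficit_substitution(self):
        text = render_message("A-8", {"x": 2000, "x1": 70000})
        assert "2000 steps" in text and "70000 steps" in text

    def test_week_indices_substitution(self):
        text = render_message("A-13", {"N": 3, "XX": 1, "XY": 2})
        assert "Week-3" in text and "Week-1" in text and "Week-2" in text

    def test_no_placeholder_template_is_verbatim(self):
        kb = default_kb()
        assert render_message("A-18", {}) == kb.by_id["A-18"].template

    def test_float_values_rendered_as_integers(self):
        text = render_message("A-6", {"z": 2.6})
        assert "{" not in text and "3 h." in text

    def test_missing_placeholder_named(self):
        with pytest.raises(RenderError, match="x1"):
            render_message("A-8", {"x": 2000})


class TestRuleTrees:
    def test_daily_tree_equals_flat_evaluation(self, goals):
        rng = np.random.default_rng(77)
        trees = daily_rule_trees()
        for _ in range(500):
            ctx = random_daily_ctx(rng, goals)
            assert evaluate_trees(trees, ctx) == evaluate_daily(ctx)

    def test_weekly_tree_equals_flat_evaluation(self, goals):
        rng = np.random.default_rng(78)
        for _ in range(500):
            ctx = random_weekly_ctx(rng, goals)
            trees = weekly_rule_trees(ctx)
            assert evaluate_trees(trees, ctx) == evaluate_weekly(ctx)

    def test_leaves_are_knowledge_base_variables(self):
        kb = default_kb()

        def leaves(node):
            if node is None:
                return []
            if node.is_leaf:
                return [node.variable]
            return leaves(node.true_branch) + leaves(node.false_branch)

        for tree in daily_rule_trees():
            assert all(v in kb.by_id for v in leaves(tree))
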
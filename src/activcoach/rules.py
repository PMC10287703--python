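"""Propositional rule engine for personalized activity recommendations.

Nineteen propositional variables (ids ``A-1`` … ``A-19``), each belonging to
exactly one once-a-day message *category*:

========  =================================================================
category  variables
========  =================================================================
level             A-1..A-5   (one per activity level 0-4)
sedentary         A-6 (over goal) / A-7 (within goal)
steps             A-8 (below daily goal) / A-9 (at/above)
activity_minutes  A-10 (below) / A-11 (at/above moderate-equivalent goal)
forecast_trend    A-12 (weekly forecast meets goal) / A-13 (misses)
daily_goal        A-14 / A-15
weekly_deviation  A-16 / A-17
weekly_goal       A-18 / A-19
========  =================================================================

Daily evaluation fires exactly one variable from each of the five daily
categories; weekly evaluation one from each weekly category that is
applicable (the deviation trend needs two completed weeks; the forecast
category needs a forecast).  The satisfiability constraint — no two
once-a-day messages of the same kind simultaneously — is enforced as a
per-category exactly-one check.

Two readings of the deviation-trend rules are provided.  The default fires
the negative trend when the cumulative deviation grew *and* the weekly goal
was missed (similarity score < 0), which matches observed end-to-end
behaviour; ``strict=True`` keeps the literal printed conjuncts
(``SC > 0`` / ``SC == 0``), under which the category may fire nothing.

Sleep terms are treated as satisfied when no sleep data exists (hip-worn
sensors record none).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from string import Formatter
from typing import Callable, Mapping, Sequence

import yaml

from ._rounding import half_up_int
from .errors import ConfigError, RenderError, SchemaError
from .records import GoalProfile

# ---------------------------------------------------------------------------
# knowledge base of variables and message templates


@dataclass(frozen=True)
class PropositionalVariable:
    id: str
    name: str
    category: str
    template: str

    @property
    def placeholders(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(
            f for _, f, _, _ in Formatter().parse(self.template)
            if f is not None))


@dataclass
class RuleKB:
    """The editable store of propositional variables and message templates."""

    variables: list[PropositionalVariable]
    by_id: dict[str, PropositionalVariable] = field(init=False)
    by_name: dict[str, PropositionalVariable] = field(init=False)
    categories: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.by_id = {v.id: v for v in self.variables}
        if len(self.by_id) != len(self.variables):
            raise SchemaError("duplicate variable ids in knowledge base")
        self.by_name = {v.name: v for v in self.variables}
        self.categories = {}
        for v in self.variables:
            self.categories.setdefault(v.category, []).append(v.id)

    @property
    def rule_categories(self) -> list[str]:
        """Categories the engine can actually fire (weather has no input)."""
        return [c for c in self.categories if c != "weather"]


def load_kb(path: str | Path | None = None) -> RuleKB:
    """Load the variable/message store (package default or a user file)."""
    if path is None:
        text = (resources.files("activcoach") / "data"
                / "knowledge_base.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return RuleKB([PropositionalVariable(**v) for v in raw["variables"]])


_DEFAULT_KB: RuleKB | None = None


def default_kb() -> RuleKB:
    global _DEFAULT_KB
    if _DEFAULT_KB is None:
        _DEFAULT_KB = load_kb()
    return _DEFAULT_KB


# ---------------------------------------------------------------------------
# decision context


@dataclass
class DecisionContext:
    """Everything the rules may inspect for one participant on one day/week."""

    goals: GoalProfile
    # daily operands
    level: int | None = None
    steps: float | None = None
    sedentary_s: float | None = None
    mpa_min: float | None = None
    vpa_min: float | None = None
    sleep_min: float | None = None           # None = no sleep sensor
    # weekly operands
    week_id: int | None = None
    sc: int | None = None
    current_deviation: float | None = None
    previous_deviation: float | None = None  # None until two weeks completed
    forecast_weekly_steps: float | None = None
    week_steps: float | None = None
    week_mpa_min: float | None = None
    week_vpa_min: float | None = None
    week_sedentary_s: float | None = None
    week_sleep_min: float | None = None
    best_weeks: tuple[int, int] | None = None

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise ConfigError(f"decision context is missing {name!r}")


# ---------------------------------------------------------------------------
# rule predicates (shared by the flat rule list and the rule tree)


def _sedentary_ok(ctx: DecisionContext) -> bool:
    return ctx.sedentary_s - ctx.goals.daily_sedentary_goal_s <= 0


def _steps_ok(ctx: DecisionContext) -> bool:
    return ctx.steps - ctx.goals.daily_step_goal >= 0


def _minutes_ok(ctx: DecisionContext) -> bool:
    g = ctx.goals
    return (ctx.mpa_min - g.daily_mpa_goal_min >= 0
            or 2 * ctx.vpa_min - g.daily_vpa_goal_min >= 0)


def _sleep_ok(ctx: DecisionContext) -> bool:
    if ctx.sleep_min is None:
        return True  # no sleep sensor: term vacuously satisfied
    return ctx.sleep_min >= ctx.goals.daily_sleep_goal_h * 60


def _daily_goal_ok(ctx: DecisionContext) -> bool:
    return (_steps_ok(ctx) and _minutes_ok(ctx) and _sleep_ok(ctx)
            and _sedentary_ok(ctx))


def _forecast_ok(ctx: DecisionContext) -> bool:
    return ctx.forecast_weekly_steps - ctx.goals.weekly_step_goal >= 0


def _week_sleep_ok(ctx: DecisionContext) -> bool:
    if ctx.week_sleep_min is None:
        return True
    return ctx.week_sleep_min >= ctx.goals.weekly_sleep_goal_h * 60


def _weekly_goal_ok(ctx: DecisionContext) -> bool:
    g = ctx.goals
    return (ctx.week_steps - g.weekly_step_goal >= 0
            and (ctx.week_mpa_min - g.weekly_mpa_goal_min >= 0
                 or 2 * ctx.week_vpa_min - g.weekly_vpa_goal_min >= 0)
            and _week_sleep_ok(ctx)
            and ctx.week_sedentary_s - g.weekly_sedentary_goal_s <= 0)


def _deviation_trend_negative(ctx: DecisionContext, strict: bool) -> bool | None:
    """True -> A-17, False -> A-16, None -> category unresolved (strict only)."""
    if strict:
        if (ctx.current_deviation > ctx.previous_deviation and ctx.sc > 0):
            return True
        if (ctx.current_deviation <= ctx.previous_deviation and ctx.sc == 0):
            return False
        return None
    return ctx.current_deviation > ctx.previous_deviation and ctx.sc < 0


# ---------------------------------------------------------------------------
# evaluation

_LEVEL_VARS = ("A-1", "A-2", "A-3", "A-4", "A-5")


def evaluate_daily(ctx: DecisionContext) -> set[str]:
    """Fire exactly one variable from each daily category.

    Categories: level, sedentary, steps, activity_minutes, daily_goal.
    """
    ctx.require("level", "steps", "sedentary_s", "mpa_min", "vpa_min")
    if not 0 <= ctx.level <= 4:
        raise ConfigError(f"activity level {ctx.level} outside 0-4")
    return {
        _LEVEL_VARS[ctx.level],
        "A-7" if _sedentary_ok(ctx) else "A-6",
        "A-9" if _steps_ok(ctx) else "A-8",
        "A-11" if _minutes_ok(ctx) else "A-10",
        "A-14" if _daily_goal_ok(ctx) else "A-15",
    }


def evaluate_weekly(ctx: DecisionContext, strict: bool = False) -> set[str]:
    """Fire one variable from each applicable weekly category.

    * forecast_trend — only when a weekly step forecast is present;
    * weekly_deviation — only after two completed weeks (cold start
      otherwise); under ``strict=True`` the literal printed conjuncts are
      used and may resolve to no variable;
    * weekly_goal — always (weekly totals required).
    """
    ctx.require("week_steps", "week_mpa_min", "week_vpa_min",
                "week_sedentary_s")
    fired: set[str] = set()
    if ctx.forecast_weekly_steps is not None:
        fired.add("A-12" if _forecast_ok(ctx) else "A-13")
    if ctx.previous_deviation is not None:
        ctx.require("current_deviation", "sc")
        trend = _deviation_trend_negative(ctx, strict)
        if trend is not None:
            fired.add("A-17" if trend else "A-16")
    fired.add("A-18" if _weekly_goal_ok(ctx) else "A-19")
    return fired


def check_exclusivity(
        state: Mapping[str, bool],
        categories: Sequence[str] | None = None,
        kb: RuleKB | None = None) -> tuple[bool, list[str]]:
    """Check the once-a-day satisfiability constraint.

    Within every checked category exactly one variable must be true.  When
    ``categories`` is omitted they are inferred as the categories holding at
    least one true variable; a state with no true variable at all violates
    every rule category.  Unknown variable names raise :class:`SchemaError`.
    """
    kb = kb or default_kb()
    for var in state:
        if var not in kb.by_id and var not in kb.by_name:
            raise SchemaError(f"unknown propositional variable {var!r}")
    truths: dict[str, int] = {c: 0 for c in kb.categories}
    for var, value in state.items():
        v = kb.by_id.get(var) or kb.by_name[var]
        if value:
            truths[v.category] += 1
    if categories is None:
        active = [c for c, n in truths.items() if n > 0]
        categories = active if active else kb.rule_categories
    violating = [c for c in categories if truths.get(c, 0) != 1]
    return (not violating), violating


def render_message(variable: str | PropositionalVariable,
                   values: Mapping[str, object],
                   kb: RuleKB | None = None) -> str:
    """Substitute placeholder values into a variable's message template.

    Numeric values are rendered as whole numbers (half-up).  A placeholder
    with no value raises :class:`RenderError` naming it.
    """
    kb = kb or default_kb()
    if isinstance(variable, str):
        if variable not in kb.by_id:
            raise SchemaError(f"unknown propositional variable {variable!r}")
        variable = kb.by_id[variable]
    subs: dict[str, object] = {}
    for ph in variable.placeholders:
        if ph not in values:
            raise RenderError(f"no value supplied for placeholder {ph!r}")
        val = values[ph]
        subs[ph] = half_up_int(val) if isinstance(val, float) else val
    return variable.template.format(**subs)


# ---------------------------------------------------------------------------
# binary rule tree — same logic, explicit tree structure


@dataclass
class RuleNode:
    """Binary tree node: internal nodes test a condition, leaves fire a variable."""

    condition: Callable[[DecisionContext], bool] | None = None
    true_branch: "RuleNode | None" = None
    false_branch: "RuleNode | None" = None
    variable: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is not None

    def evaluate(self, ctx: DecisionContext) -> str | None:
        node = self
        while not node.is_leaf:
            branch = node.true_branch if node.condition(ctx) else node.false_branch
            if branch is None:
                return None
            node = branch
        return node.variable


def _leaf(var: str) -> RuleNode:
    return RuleNode(variable=var)


def daily_rule_trees() -> list[RuleNode]:
    """One binary tree per daily category; internal nodes hold the rules."""
    level_tree = _leaf("A-5")
    for lvl in (3, 2, 1, 0):
        level_tree = RuleNode(
            condition=(lambda c, lvl=lvl: c.level == lvl),
            true_branch=_leaf(_LEVEL_VARS[lvl]), false_branch=level_tree)
    return [
        level_tree,
        RuleNode(_sedentary_ok, _leaf("A-7"), _leaf("A-6")),
        RuleNode(_steps_ok, _leaf("A-9"), _leaf("A-8")),
        RuleNode(_minutes_ok, _leaf("A-11"), _leaf("A-10")),
        RuleNode(_daily_goal_ok, _leaf("A-14"), _leaf("A-15")),
    ]


def weekly_rule_trees(ctx: DecisionContext,
                      strict: bool = False) -> list[RuleNode]:
    """Binary trees for the weekly categories applicable to ``ctx``."""
    trees: list[RuleNode] = []
    if ctx.forecast_weekly_steps is not None:
        trees.append(RuleNode(_forecast_ok, _leaf("A-12"), _leaf("A-13")))
    if ctx.previous_deviation is not None:
        def trend(c, strict=strict):
            return _deviation_trend_negative(c, strict)

        if strict:
            # unresolved strict outcomes fall off the tree (no leaf)
            trees.append(RuleNode(
                lambda c: _deviation_trend_negative(c, True) is True,
                _leaf("A-17"),
                RuleNode(lambda c: _deviation_trend_negative(c, True) is False,
                         _leaf("A-16"), None)))
        else:
            trees.append(RuleNode(trend, _leaf("A-17"), _leaf("A-16")))
    trees.append(RuleNode(_weekly_goal_ok, _leaf("A-18"), _leaf("A-19")))
    return trees


def evaluate_trees(trees: Sequence[RuleNode],
                   ctx: DecisionContext) -> set[str]:
    fired = {tree.evaluate(ctx) for tree in trees}
    fired.discard(None)
    return fired
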
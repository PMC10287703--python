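"""End-to-end orchestration: sensing → monitoring → recommendation.

For every participant with at least two weeks of data the pipeline

* aggregates minute records to daily records and fills calendar gaps;
* classifies each day with the deterministic level rules and fires the daily
  rule categories, rendering one message per fired variable;
* at every completed-week boundary computes the weekly summary (feature
  means, APV, similarity and performance scores, cumulative deviation);
  after the two-week cold-start window it additionally trains the step
  forecaster on the history, builds the 7-day interval table, and fires the
  weekly rule categories;
* annotates every level, prediction, statistic and recommendation into the
  RDF knowledge base.

The weekly stage re-derives the cumulative statistics from the whole history
at each boundary (the nested loop that makes the orchestration quadratic in
the number of days); ``RunResult.work_units`` counts the (week, prior-week)
pairs it touches so the growth rate is observable.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .errors import InsufficientDataError
from .intervals import naive_residual_sd, weekly_interval_table
from .io import aggregate_to_daily, fill_missing
from .kb import KnowledgeBase
from .levels import classify_record
from .models.forecaster import CNNStepForecaster
from .records import DailyActivityRecord, GoalProfile, MinuteActivityRecord
from .rules import (DecisionContext, RuleKB, default_kb, evaluate_daily,
                    evaluate_weekly, render_message)
from .weekly import WeeklySummary, summarize_week

COLD_START_DAYS = 14


@dataclass
class RunResult:
    daily_logs: list[dict] = field(default_factory=list)
    weekly_logs: list[dict] = field(default_factory=list)
    summaries: dict[str, list[WeeklySummary]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    kb: KnowledgeBase | None = None
    work_units: int = 0

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for log in self.daily_logs + self.weekly_logs:
                fh.write(json.dumps(log) + "\n")


def _gap_filled_daily(
        records: Sequence[DailyActivityRecord]) -> list[DailyActivityRecord]:
    frame = pd.DataFrame({
        "steps": [r.steps for r in records],
        "sedentary_s": [r.sedentary_s for r in records],
        "lpa_s": [r.lpa_s for r in records],
        "mpa_s": [r.mpa_s for r in records],
        "vpa_s": [r.vpa_s for r in records],
    }, index=pd.to_datetime([r.date for r in records]))
    filled = frame.apply(fill_missing)
    return [DailyActivityRecord(
        date=ts.date(), steps=int(row["steps"]),
        sedentary_s=int(row["sedentary_s"]), lpa_s=int(row["lpa_s"]),
        mpa_s=int(row["mpa_s"]), vpa_s=int(row["vpa_s"]))
        for ts, row in filled.iterrows()]


def _daily_placeholder_values(ctx: DecisionContext, day: DailyActivityRecord,
                              goals: GoalProfile) -> dict[str, object]:
    step_gap = abs(goals.daily_step_goal - day.steps)
    minute_gap = abs(goals.daily_mpa_goal_min - day.mpa_s / 60.0)
    return {
        "x": step_gap, "x1": goals.weekly_step_goal,
        "z": abs(day.sedentary_s - goals.daily_sedentary_goal_s) / 3600.0,
        "m": minute_gap, "n": minute_gap,
        "n1": goals.weekly_mpa_goal_min,
        "X": day.steps,
        "Y": (ctx.sleep_min or 0.0) / 60.0,
        "Z": day.sedentary_s / 3600.0,
        "M": day.mpa_s / 60.0,
        "N": day.vpa_s / 60.0,
    }


def _best_weeks(summaries: Sequence[WeeklySummary]) -> tuple[int, int]:
    ranked = sorted(summaries, key=lambda s: (-s.mean_s, s.week_id))
    ids = [s.week_id for s in ranked[:2]]
    return (ids[0], ids[-1]) if ids else (1, 1)


def run_pipeline(
        participants: Mapping[str, Sequence[MinuteActivityRecord]] |
        Mapping[str, Sequence[DailyActivityRecord]],
        goals: GoalProfile | None = None,
        forecaster: CNNStepForecaster | None = None,
        interval_c: float = 1.28,
        seed: int = 0,
        kb_defs: RuleKB | None = None,
        annotate: bool = True) -> RunResult:
    """Run the full daily/weekly recommendation pipeline over a cohort.

    ``participants`` maps ids to minute records (aggregated internally) or
    directly to daily records.  Participants with fewer than 14 days are
    skipped with a logged reason.  ``forecaster`` is used as a prototype:
    a fresh clone is fitted per participant and week boundary.
    """
    goals = goals or GoalProfile()
    kb_defs = kb_defs or default_kb()
    proto = forecaster or CNNStepForecaster()
    result = RunResult(kb=KnowledgeBase() if annotate else None)

    for pid, records in participants.items():
        records = list(records)
        if records and isinstance(records[0], MinuteActivityRecord):
            daily = aggregate_to_daily(records)
        else:
            daily = sorted(records, key=lambda r: r.date)
        try:
            daily = _gap_filled_daily(daily)
        except InsufficientDataError:
            result.skipped[pid] = "no observed days"
            continue
        if len(daily) < COLD_START_DAYS:
            result.skipped[pid] = (
                f"only {len(daily)} days; {COLD_START_DAYS} needed "
                "(cold-start window)")
            continue
        if result.kb is not None:
            result.kb.add_participant(pid)
        _run_participant(pid, daily, goals, proto, interval_c, seed,
                         kb_defs, result)
    return result


def _run_participant(pid: str, daily: list[DailyActivityRecord],
                     goals: GoalProfile, proto: CNNStepForecaster,
                     interval_c: float, seed: int, kb_defs: RuleKB,
                     result: RunResult) -> None:
    summaries: list[WeeklySummary] = []
    mean_s_history: list[float] = []
    n_weeks = len(daily) // 7

    for i, day in enumerate(daily):
        level = classify_record(day)
        ctx = DecisionContext(
            goals=goals, level=int(level), steps=day.steps,
            sedentary_s=day.sedentary_s, mpa_min=day.mpa_s / 60.0,
            vpa_min=day.vpa_s / 60.0, sleep_min=day.sleep_minutes)
        fired = evaluate_daily(ctx)
        values = _daily_placeholder_values(ctx, day, goals)
        messages = {v: render_message(v, values, kb_defs) for v in sorted(fired)}
        result.daily_logs.append({
            "participant": pid, "date": day.date.isoformat(),
            "level": int(level), "fired": sorted(fired),
            "messages": messages})
        if result.kb is not None:
            result.kb.annotate_level(pid, day.date, int(level))
            for vid, text in messages.items():
                result.kb.annotate_recommendation(pid, day.date, vid, text)

    for w in range(1, n_weeks + 1):
        week = daily[(w - 1) * 7: w * 7]
        summary = summarize_week(week, goals, w, mean_s_history)
        # nested pass over the history: the quadratic orchestration loop
        for _prior in summaries:
            result.work_units += 1
        result.work_units += 1
        summaries.append(summary)
        mean_s_history.append(summary.mean_s)
        if result.kb is not None:
            result.kb.annotate_stats(pid, summary)

        if w * 7 <= COLD_START_DAYS:
            continue  # the first two weeks are observation-only (cold start)

        history = np.asarray([r.steps for r in daily[: w * 7]], dtype=float)
        model = proto.__class__(**proto.get_params())
        model.set_params(random_state=seed)
        model.fit(history)
        points = model.forecast(7)
        table, mean_point = weekly_interval_table(
            list(points), interval_c, naive_residual_sd(history))

        prev_dev = summaries[-2].sd if len(summaries) >= 2 else None
        ctx = DecisionContext(
            goals=goals, week_id=w, sc=summary.sc,
            current_deviation=summary.sd, previous_deviation=prev_dev,
            forecast_weekly_steps=float(np.sum(points)),
            week_steps=summary.total_steps,
            week_mpa_min=summary.total_mpa_min,
            week_vpa_min=summary.total_vpa_min,
            week_sedentary_s=summary.total_sedentary_s,
            week_sleep_min=summary.total_sleep_min,
            best_weeks=_best_weeks(summaries))
        fired = evaluate_weekly(ctx)
        xx, xy = ctx.best_weeks
        values = {"N": w, "XX": xx, "XY": xy}
        messages = {v: render_message(v, values, kb_defs) for v in sorted(fired)}
        log = {"participant": pid, "week": w, "fired": sorted(fired),
               "messages": messages, "sc": summary.sc,
               "mean_s": summary.mean_s, "sd": summary.sd,
               "forecast_weekly_steps": round_half_up(float(np.sum(points)), 1),
               "forecast_mean": mean_point,
               "intervals": [[iv.lower, iv.upper] for iv in table]}
        if prev_dev is None:
            log["weekly_deviation"] = "cold-start"
        result.weekly_logs.append(log)
        if result.kb is not None:
            result.kb.annotate_prediction(pid, w, table)
            last_date = week[-1].date
            for vid, text in messages.items():
                result.kb.annotate_recommendation(pid, last_date, vid, text)

    result.summaries[pid] = summaries
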
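"""CSV readers/writers and missing-data handling.

Two plain-text formats are supported:

* minute-level sensor CSV with header
  ``Date,Time,UploadStatus,IMA,WeightBearing,Sedentary,Standing,LPA,MPA,VPA,Steps``
  (case-insensitive), ISO-8601 dates;
* daily CSV with header ``date,steps,sedentary_s,lpa_s,mpa_s,vpa_s[,sleep_minutes]``.

Day boundaries are calendar midnights in the record's local timestamps.
Duplicate minutes are summed during aggregation.
"""

from __future__ import annotations

import datetime as dt
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataFormatError, InsufficientDataError, RowParseError
from .records import (DAILY_COLUMNS, MINUTE_BUDGET_S, MOX_COLUMNS,
                      DailyActivityRecord, MinuteActivityRecord)

_INT_MINUTE_FIELDS = ("IMA", "WeightBearing", "Sedentary", "Standing",
                      "LPA", "MPA", "VPA", "Steps")


def _parse_time(value: str) -> dt.time:
    value = str(value).strip()
    for fmt in ("%H:%M:%S", "%H:%M"):
        try:
            return dt.datetime.strptime(value, fmt).time()
        except ValueError:
            continue
    raise ValueError(f"unparseable time {value!r}")


def read_mox_csv(path: str | Path) -> list[MinuteActivityRecord]:
    """Read a minute-level sensor CSV into chronological records.

    Raises
    ------
    DataFormatError
        if a mandatory column is absent (the message names it).
    RowParseError
        if any row holds a non-numeric second/step field; ``.lines`` carries
        the 1-based file line numbers of all malformed rows.

    Rows whose second fields do not sum to the 60-second minute budget are
    accepted but reported through a ``UserWarning`` listing the line numbers.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    colmap = {c.lower().strip(): c for c in raw.columns}
    missing = [c for c in MOX_COLUMNS if c.lower() not in colmap]
    if missing:
        raise DataFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    raw = raw.rename(columns={colmap[c.lower()]: c for c in MOX_COLUMNS})

    records: list[tuple[int, MinuteActivityRecord]] = []
    bad_lines: list[int] = []
    bad_budget: list[int] = []
    for idx, row in raw.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            date = dt.date.fromisoformat(str(row["Date"]).strip())
            time = _parse_time(row["Time"])
            fields = {name: int(float(row[name])) for name in _INT_MINUTE_FIELDS}
        except (ValueError, TypeError):
            bad_lines.append(line_no)
            continue
        rec = MinuteActivityRecord(
            date=date, time=time,
            upload_status=str(row["UploadStatus"]).strip(),
            ima=fields["IMA"], weight_bearing_s=fields["WeightBearing"],
            sedentary_s=fields["Sedentary"], standing_s=fields["Standing"],
            lpa_s=fields["LPA"], mpa_s=fields["MPA"], vpa_s=fields["VPA"],
            steps=fields["Steps"])
        if not rec.is_budget_consistent():
            bad_budget.append(line_no)
        if not rec.upload_flag_known:
            warnings.warn(f"line {line_no}: unknown UploadStatus "
                          f"{rec.upload_status!r} (expected H or L)")
        records.append((line_no, rec))

    if bad_lines:
        raise RowParseError(
            f"non-numeric or malformed values on line(s) {bad_lines}",
            lines=bad_lines)
    if bad_budget:
        warnings.warn(
            f"second fields do not sum to {MINUTE_BUDGET_S} s on "
            f"line(s) {bad_budget}")
    records.sort(key=lambda pair: pair[1].timestamp)
    return [rec for _, rec in records]


def write_mox_csv(records: Iterable[MinuteActivityRecord],
                  path: str | Path) -> None:
    rows = [{
        "Date": r.date.isoformat(),
        "Time": r.time.strftime("%H:%M:%S"),
        "UploadStatus": r.upload_status,
        "IMA": r.ima,
        "WeightBearing": r.weight_bearing_s,
        "Sedentary": r.sedentary_s,
        "Standing": r.standing_s,
        "LPA": r.lpa_s,
        "MPA": r.mpa_s,
        "VPA": r.vpa_s,
        "Steps": r.steps,
    } for r in records]
    pd.DataFrame(rows, columns=list(MOX_COLUMNS)).to_csv(path, index=False)


def read_daily_csv(path: str | Path) -> list[DailyActivityRecord]:
    df = pd.read_csv(path)
    missing = [c for c in DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        sleep = row.get("sleep_minutes")
        sleep = None if sleep is None or pd.isna(sleep) else float(sleep)
        out.append(DailyActivityRecord(
            date=dt.date.fromisoformat(str(row["date"])),
            steps=int(row["steps"]), sedentary_s=int(row["sedentary_s"]),
            lpa_s=int(row["lpa_s"]), mpa_s=int(row["mpa_s"]),
            vpa_s=int(row["vpa_s"]), sleep_minutes=sleep))
    out.sort(key=lambda r: r.date)
    return out


def write_daily_csv(records: Iterable[DailyActivityRecord],
                    path: str | Path) -> None:
    records = list(records)
    with_sleep = any(r.sleep_minutes is not None for r in records)
    rows = []
    for r in records:
        row = {"date": r.date.isoformat(), "steps": r.steps,
               "sedentary_s": r.sedentary_s, "lpa_s": r.lpa_s,
               "mpa_s": r.mpa_s, "vpa_s": r.vpa_s}
        if with_sleep:
            row["sleep_minutes"] = r.sleep_minutes
        rows.append(row)
    cols = list(DAILY_COLUMNS) + (["sleep_minutes"] if with_sleep else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def aggregate_to_daily(
        records: Sequence[MinuteActivityRecord]) -> list[DailyActivityRecord]:
    """Sum minute records into one record per calendar date.

    Empty input yields an empty list.  Duplicate minutes are summed.
    """
    if not records:
        return []
    df = pd.DataFrame({
        "date": [r.date for r in records],
        "steps": [r.steps for r in records],
        "sedentary_s": [r.sedentary_s for r in records],
        "lpa_s": [r.lpa_s for r in records],
        "mpa_s": [r.mpa_s for r in records],
        "vpa_s": [r.vpa_s for r in records],
    })
    grouped = df.groupby("date", sort=True).sum()
    return [DailyActivityRecord(date=date, **{k: int(v) for k, v in row.items()})
            for date, row in grouped.iterrows()]


def fill_missing(series: pd.Series) -> pd.Series:
    """Fill gaps in an ordered daily series.

    The index must be datetime-like (or date-like); the output covers the full
    calendar span at daily resolution.  Leading gaps are filled backward from
    the first observation; all other gaps forward from the most recent one.

    Raises :class:`InsufficientDataError` when every value is missing.
    """
    if series.dropna().empty:
        raise InsufficientDataError("series holds no observed value to anchor filling")
    s = series.copy()
    s.index = pd.to_datetime(s.index)
    s = s.sort_index()
    full = pd.date_range(s.index.min(), s.index.max(), freq="D")
    s = s.reindex(full)
    return s.ffill().bfill()
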
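"""Dust-storm event calendar: event parsing, period labelling, day-of-week design.

Every study day is assigned exactly one of three labels:

* ``ADS`` — the day falls inside a declared dust-storm event interval;
* ``POST_ADS`` — the day falls in the window of ``post_window`` days
  immediately following an event's end (and is not itself an event day);
* ``OTHER`` — everything else.

Label precedence is ADS > POST_ADS > OTHER, so the labels always partition
the study range even when a new event starts inside the post window of a
previous one.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

ADS = "ADS"
POST_ADS = "POST_ADS"
OTHER = "OTHER"
PERIODS = (ADS, POST_ADS, OTHER)

#: Weekday abbreviations indexed by ``date.weekday()`` (Monday == 0).
WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: Dummy columns for the day-of-week design, Monday through Saturday.
DOW_COLUMNS = ("dow_Mon", "dow_Tue", "dow_Wed", "dow_Thu", "dow_Fri", "dow_Sat")

STUDY_START = dt.date(2002, 1, 1)
STUDY_END = dt.date(2007, 12, 31)


@dataclass(frozen=True, order=True)
class ADSEvent:
    """A dust-storm event as an inclusive date interval."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"event end {self.end} precedes start {self.start}"
            )

    @property
    def days(self) -> list[dt.date]:
        """All dates covered by the event, endpoints inclusive."""
        n = (self.end - self.start).days + 1
        return [self.start + dt.timedelta(days=i) for i in range(n)]

    def __len__(self) -> int:
        return (self.end - self.start).days + 1


class ExposureCalendar:
    """Per-day period labels and weekday names over a contiguous date range."""

    def __init__(self, frame: pd.DataFrame):
        required = {"date", "dow", "period"}
        if not required.issubset(frame.columns):
            raise ValidationError(f"calendar frame must have columns {required}")
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def dates(self) -> pd.Series:
        return self._frame["date"]

    @property
    def periods(self) -> pd.Series:
        return self._frame["period"]

    def __len__(self) -> int:
        return len(self._frame)

    def period_of(self, day: dt.date) -> str:
        hit = self._frame.loc[self._frame["date"] == day, "period"]
        if hit.empty:
            raise KeyError(f"{day} outside calendar range")
        return hit.iloc[0]

    def counts(self) -> dict[str, int]:
        c = self._frame["period"].value_counts().to_dict()
        return {p: int(c.get(p, 0)) for p in PERIODS}

    def to_csv(self, path: str | Path) -> None:
        out = self._frame.copy()
        out["date"] = out["date"].map(lambda d: d.isoformat())
        out.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExposureCalendar):
            return NotImplemented
        return self._frame.equals(other._frame)


def _parse_month_day(token: str, year: int) -> dt.date:
    parts = token.strip().split("/")
    if len(parts) != 2:
        raise ParseError(f"malformed date token {token!r}: expected 'M/D'")
    try:
        month, day = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ParseError(f"malformed date token {token!r}: non-numeric") from exc
    try:
        return dt.date(year, month, day)
    except ValueError as exc:
        raise ParseError(f"invalid date {token!r} for year {year}") from exc


def parse_interval(text: str, year: int) -> ADSEvent:
    """Parse one ``"M/D-M/D"`` interval string into an :class:`ADSEvent`."""
    pieces = text.strip().split("-")
    if len(pieces) != 2 or not pieces[0].strip() or not pieces[1].strip():
        raise ParseError(f"malformed interval {text!r}: expected 'M/D-M/D'")
    start = _parse_month_day(pieces[0], year)
    end = _parse_month_day(pieces[1], year)
    if end < start:
        raise ValidationError(
            f"interval {text!r} in {year} ends before it starts "
            "(year-crossing intervals are not supported)"
        )
    return ADSEvent(start, end)


def parse_ads_events(rows: Iterable[tuple[int | str, str]]) -> list[ADSEvent]:
    """Parse rows of ``(year, "M/D-M/D, M/D-M/D, ...")`` into sorted events.

    Raises :class:`ParseError` naming the offending token on malformed input
    and :class:`ValidationError` if intervals overlap or end before they start.
    """
    events: list[ADSEvent] = []
    for year_raw, intervals in rows:
        try:
            year = int(year_raw)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"malformed year {year_raw!r}") from exc
        for token in str(intervals).split(","):
            if not token.strip():
                continue
            events.append(parse_interval(token, year))
    events.sort()
    for prev, cur in zip(events, events[1:]):
        if cur.start <= prev.end:
            raise ValidationError(
                f"overlapping events {prev} and {cur}; event lists must be disjoint"
            )
    return events


def load_event_fixture(path: str | Path | None = None) -> list[ADSEvent]:
    """Load the packaged 2002–2007 event table (or a user CSV of the same shape)."""
    if path is None:
        src = resources.files("ads_star.data") / "ads_events_2002_2007.csv"
        with resources.as_file(src) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    return parse_ads_events(zip(table["year"], table["intervals"]))


def expand_events(events: Sequence[ADSEvent]) -> set[dt.date]:
    """Union of all dates covered by the events."""
    days: set[dt.date] = set()
    for ev in events:
        days.update(ev.days)
    return days


def label_periods(
    start: dt.date,
    end: dt.date,
    events: Sequence[ADSEvent],
    post_window: int = 7,
) -> ExposureCalendar:
    """Label every day in ``[start, end]`` as ADS, POST_ADS, or OTHER.

    The post window covers days ``event.end + 1 .. event.end + post_window``;
    an event's own days are never POST_ADS, and ADS takes precedence when a
    new event begins inside an earlier event's post window.  Days outside the
    range are dropped.
    """
    if end < start:
        raise ValidationError(f"empty date range {start}..{end}")
    if post_window < 0:
        raise ValidationError("post_window must be >= 0")

    ads_days = expand_events(events)
    post_days: set[dt.date] = set()
    for ev in events:
        for k in range(1, post_window + 1):
            day = ev.end + dt.timedelta(days=k)
            if day not in ads_days:
                post_days.add(day)
    post_days -= ads_days

    n = (end - start).days + 1
    records = []
    for i in range(n):
        day = start + dt.timedelta(days=i)
        if day in ads_days:
            period = ADS
        elif day in post_days:
            period = POST_ADS
        else:
            period = OTHER
        records.append((day, WEEKDAYS[day.weekday()], period))
    frame = pd.DataFrame(records, columns=["date", "dow", "period"])
    return ExposureCalendar(frame)


def calendar_from_csv(path: str | Path) -> ExposureCalendar:
    """Read a calendar previously written by :meth:`ExposureCalendar.to_csv`."""
    frame = pd.read_csv(path)
    frame["date"] = pd.to_datetime(frame["date"]).dt.date
    return ExposureCalendar(frame)


def dow_design(calendar: ExposureCalendar, reference: str = "Sun") -> pd.DataFrame:
    """Six Monday..Saturday dummy columns, all zero on the reference weekday."""
    if reference not in WEEKDAYS:
        raise ValidationError(f"unknown weekday {reference!r}; use one of {WEEKDAYS}")
    dummies = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat")
    if reference in dummies:
        # keep six columns: swap the reference out for Sunday
        dummies = tuple(d for d in dummies if d != reference) + ("Sun",)
    data = {
        f"dow_{d}": (calendar.frame["dow"] == d).astype(float) for d in dummies
    }
    out = pd.DataFrame(data)
    out.index = calendar.frame.index
    return out


def period_design(calendar: ExposureCalendar) -> pd.DataFrame:
    """ADS / post-ADS indicator columns (OTHER is the reference level)."""
    return pd.DataFrame(
        {
            "I_ADS": (calendar.periods == ADS).astype(float),
            "I_POST_ADS": (calendar.periods == POST_ADS).astype(float),
        },
        index=calendar.frame.index,
    )
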
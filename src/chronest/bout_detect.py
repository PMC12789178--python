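"""On/off-bout detection from nest-temperature logger traces.

An incubating female keeps the nest near her body temperature; when she
leaves (an off-bout) the nest cools toward ambient and re-warms on her
return.  Off-bouts are detected as cumulative temperature declines that
exceed a nest- and day-specific threshold and point toward ambient; the
daily activity onset is the start of the first off-bout after the long
nocturnal on-bout.

Conventions
-----------
* Days run midnight to midnight (local logger time); the "night" of a
  date is the window from 21:00 of the previous evening to 05:00.
* Dates are reported as April days (1 April = day 1).
* A bout boundary is placed on the sample *preceding* the sample at
  which the cumulative change crosses the threshold: the departure (or
  return) happened somewhere inside that sampling interval, so this
  convention keeps the timing error within one sampling interval.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureTrace",
    "Bout",
    "BoutSeries",
    "Thresholds",
    "parse_logger_export",
    "detect_incubation_start",
    "derive_thresholds",
    "detect_bouts",
    "extract_daily_onsets",
    "detect_onsets_for_trace",
    "april_day",
]

NIGHT_START_HOUR = 21.0
NIGHT_END_HOUR = 5.0
DROP_FLOOR = 0.5  # deg C; real departures always drop more than this


class TraceError(ValueError):
    """Raised for malformed logger exports or traces."""


def april_day(d: dt.date | pd.Timestamp) -> int:
    """Date coordinate with 1 April = day 1 (March dates are <= 0)."""
    if isinstance(d, pd.Timestamp):
        d = d.date()
    return (d - dt.date(d.year, 3, 31)).days


@dataclass
class TemperatureTrace:
    """One nest's quantised temperature series plus aligned ambient.

    ``temp`` and ``ambient`` are degrees Celsius on the same regular
    sampling grid (default 3-minute step).  ``accuracy`` is the logger
    quantisation step.
    """

    nest_id: str
    times: pd.DatetimeIndex
    temp: np.ndarray
    accuracy: float
    ambient: np.ndarray

    def __post_init__(self) -> None:
        self.temp = np.asarray(self.temp, dtype=float)
        self.ambient = np.asarray(self.ambient, dtype=float)
        if len(self.times) != len(self.temp) or len(self.temp) != len(self.ambient):
            raise TraceError("times, temp and ambient must have equal length")
        if len(self.times) < 2:
            raise TraceError("trace needs at least two samples")
        diffs = np.diff(self.times.asi8)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0)) + 1
            raise TraceError(f"timestamps not strictly increasing at row {bad}")
        if not np.all(np.isfinite(self.temp)):
            raise TraceError("non-finite temperatures in trace")
        if self.accuracy <= 0:
            raise TraceError("accuracy must be positive")

    @property
    def step(self) -> pd.Timedelta:
        """Modal sampling interval."""
        vals, counts = np.unique(np.diff(self.times.asi8), return_counts=True)
        return pd.Timedelta(int(vals[np.argmax(counts)]), unit="ns")

    def dates(self) -> list[dt.date]:
        return sorted({t.date() for t in self.times})

    def window(self, start: pd.Timestamp, end: pd.Timestamp) -> np.ndarray:
        """Boolean mask of samples in [start, end)."""
        return (self.times >= start) & (self.times < end)

    def gap_dates(self) -> set[dt.date]:
        """Dates whose coverage has a hole of >= 2 sampling intervals."""
        step_ns = self.step.value
        gaps = np.diff(self.times.asi8)
        bad = set()
        for i in np.nonzero(gaps >= 2 * step_ns)[0]:
            bad.add(self.times[i].date())
            bad.add(self.times[i + 1].date())
        return bad


@dataclass(frozen=True)
class Bout:
    start: pd.Timestamp
    end: pd.Timestamp
    label: str  # "on" | "off"

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start


@dataclass
class BoutSeries:
    """Per-day ordered on/off-bout partition for one nest."""

    nest_id: str
    days: dict[dt.date, list[Bout]] = field(default_factory=dict)
    invalid_days: dict[dt.date, str] = field(default_factory=dict)

    def add_day(self, date: dt.date, bouts: list[Bout]) -> None:
        for a, b in zip(bouts, bouts[1:]):
            if a.end != b.start:
                raise TraceError(f"bouts not contiguous on {date}")
            if a.label == b.label:
                raise TraceError(f"bout labels do not alternate on {date}")
        self.days[date] = bouts


@dataclass(frozen=True)
class Thresholds:
    drop: float
    rise: float
    date: dt.date
    fallback: bool = False  # True when pooled across nights (sparse night)


# ---------------------------------------------------------------------------
# parsing


def parse_logger_export(
    path,
    ambient: "pd.Series | None" = None,
    accuracy: float | None = None,
    nest_id: str | None = None,
) -> TemperatureTrace:
    """Read a two-column (ISO-8601 datetime, temperature) logger export.

    ``ambient`` is a temperature series indexed by time (e.g. the
    30-minute binned reference); it is linearly interpolated onto the
    trace grid.  When ``accuracy`` is not given it is inferred as the
    minimal positive step between distinct recorded temperatures.
    """
    df = pd.read_csv(path, header=0)
    if df.shape[1] < 2:
        raise TraceError(f"{path}: expected two columns (datetime, temperature)")
    times = pd.to_datetime(df.iloc[:, 0], errors="coerce", format="ISO8601")
    temps = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = sorted(
        (np.nonzero(times.isna().to_numpy() | temps.isna().to_numpy())[0] + 2).tolist()
    )  # +2: header line + 1-based
    if bad:
        raise TraceError(f"{path}: unparseable rows at lines {bad}")
    idx = pd.DatetimeIndex(times)
    diffs = np.diff(idx.asi8)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 2
        raise TraceError(f"{path}: non-monotone or duplicate timestamp at line {row + 1}")
    temp = temps.to_numpy(dtype=float)
    if accuracy is None:
        accuracy = infer_accuracy(temp)
    if ambient is not None:
        amb = interpolate_ambient(ambient, idx)
    else:
        amb = np.full(len(idx), np.nan)
    name = nest_id if nest_id is not None else str(path)
    return TemperatureTrace(name, idx, temp, float(accuracy), amb)


def infer_accuracy(temp: np.ndarray) -> float:
    """Minimal positive step between distinct recorded values."""
    uniq = np.unique(np.round(np.asarray(temp, dtype=float), 6))
    if len(uniq) < 2:
        return 0.0625
    return float(np.min(np.diff(uniq)))


def interpolate_ambient(ambient: pd.Series, times: pd.DatetimeIndex) -> np.ndarray:
    """Linear interpolation of an ambient series onto the trace grid."""
    src_t = pd.DatetimeIndex(ambient.index).asi8.astype(float)
    return np.interp(times.asi8.astype(float), src_t, ambient.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# incubation start


def _night_window(date: dt.date) -> tuple[pd.Timestamp, pd.Timestamp]:
    prev = date - dt.timedelta(days=1)
    start = pd.Timestamp(prev) + pd.Timedelta(hours=NIGHT_START_HOUR)
    end = pd.Timestamp(date) + pd.Timedelta(hours=NIGHT_END_HOUR)
    return start, end


def detect_incubation_start(
    trace: TemperatureTrace,
    margin: float = 5.0,
    fraction: float = 0.75,
) -> dt.date | None:
    """First date whose preceding night shows sustained nest warming.

    Nocturnal full incubation makes the day-night activity pattern
    visible; before it the nest sits at ambient overnight.  Returns the
    first date whose night window holds nest - ambient >= ``margin``
    for at least ``fraction`` of the night samples, or None when no
    night qualifies ("not started").
    """
    if np.all(np.isnan(trace.ambient)):
        raise TraceError("ambient reference required for incubation-start detection")
    dates = trace.dates()
    if len(dates) < 2:
        raise TraceError("trace must span at least two nights")
    excess = trace.temp - trace.ambient
    for date in dates:
        start, end = _night_window(date)
        mask = trace.window(start, end)
        n = int(mask.sum())
        if n < 10:
            continue
        if np.mean(excess[mask] >= margin) >= fraction:
            return date
    return None


# ---------------------------------------------------------------------------
# thresholds


def derive_thresholds(
    trace: TemperatureTrace,
    date: dt.date,
    floor: float = DROP_FLOOR,
    quantile: float = 0.95,
    min_night_samples: int = 10,
) -> Thresholds:
    """Nest- and day-specific drop/rise thresholds.

    The drop threshold is the larger of the floor (real departures drop
    the nest temperature by more than 0.5 degC) and the ``quantile`` of
    absolute successive differences over that date's night window, so
    noisy nests demand larger excursions.  The rise threshold is
    derived symmetrically from quiet daytime (on-bout-like) samples.
    Nights with fewer than ``min_night_samples`` samples fall back to
    all nights of the trace pooled, flagged in the result.
    """
    start, end = _night_window(date)
    night = trace.temp[trace.window(start, end)]
    fallback = False
    if len(night) < min_night_samples:
        fallback = True
        chunks = []
        for d in trace.dates():
            s, e = _night_window(d)
            chunks.append(trace.temp[trace.window(s, e)])
        night = np.concatenate(chunks) if chunks else np.array([])
    if len(night) >= 2:
        drop = max(floor, float(np.quantile(np.abs(np.diff(night)), quantile)))
    else:
        drop = floor

    day_start = pd.Timestamp(date) + pd.Timedelta(hours=NIGHT_END_HOUR)
    day_end = pd.Timestamp(date) + pd.Timedelta(hours=NIGHT_START_HOUR)
    day = trace.temp[trace.window(day_start, day_end)]
    # keep only on-bout-like samples: within 1 degC of the daytime median,
    # so excursion transients do not inflate the rise threshold
    if len(day) >= 2:
        quiet = day[np.abs(day - np.median(day)) <= 1.0]
        if len(quiet) >= 2:
            rise = max(floor, float(np.quantile(np.abs(np.diff(quiet)), quantile)))
        else:
            rise = drop
    else:
        rise = drop
    return Thresholds(drop=drop, rise=rise, date=date, fallback=fallback)


# ---------------------------------------------------------------------------
# bout detection


def detect_bouts(
    trace: TemperatureTrace,
    thresholds: Thresholds,
    date: dt.date,
) -> list[Bout]:
    """Partition one day (midnight to midnight) into on/off-bouts.

    State machine: during an on-bout the baseline is the running
    maximum since the bout opened; an off-bout opens when the cumulative
    decline from the baseline exceeds the drop threshold *and* the
    decline is toward ambient (nest - ambient smaller than at the
    baseline sample).  During an off-bout the trough is the running
    minimum; the bout closes when the cumulative rise exceeds the rise
    threshold.  Boundaries are backdated by one sample (see module
    docstring).
    """
    if np.all(np.isnan(trace.ambient)):
        raise TraceError("ambient reference required for bout detection")
    day_start = pd.Timestamp(date)
    day_end = day_start + pd.Timedelta(days=1)
    mask = trace.window(day_start, day_end)
    idx = np.nonzero(mask)[0]
    if len(idx) < 2:
        raise TraceError(f"no samples on {date}")
    times = trace.times[idx]
    temp = trace.temp[idx]
    amb = trace.ambient[idx]

    boundaries = _scan_boundaries(temp, amb, thresholds.drop, thresholds.rise)
    bouts: list[Bout] = []
    prev = 0
    state = "on"
    for b in boundaries:
        bouts.append(Bout(times[prev], times[b], state))
        prev = b
        state = "off" if state == "on" else "on"
    bouts.append(Bout(times[prev], times[-1], state))
    return [b for b in bouts if b.duration > pd.Timedelta(0)]


def _scan_boundaries(
    temp: np.ndarray, amb: np.ndarray, drop: float, rise: float
) -> list[int]:
    """Indices at which the bout state flips, starting from on-bout.

    Each boundary index is the (backdated) sample on which the new bout
    begins.  Kept as a plain sequential loop; the brute-force oracle in
    the tests recomputes every running extremum from scratch instead.
    """
    boundaries: list[int] = []
    state = "on"
    bout_start = 0
    ref = temp[0]  # running max (on) / running min (off)
    ref_i = 0
    for k in range(1, len(temp)):
        if state == "on":
            if temp[k] > ref:
                ref, ref_i = temp[k], k
            elif ref - temp[k] > drop and (temp[k] - amb[k]) < (ref - amb[ref_i]):
                # departure happened within the preceding interval
                j = max(k - 1, bout_start + 1)
                boundaries.append(j)
                state = "off"
                bout_start = j
                off = int(np.argmin(temp[j : k + 1]))
                ref, ref_i = temp[j + off], j + off
        else:
            if temp[k] < ref:
                ref, ref_i = temp[k], k
            elif temp[k] - ref > rise:
                j = max(k - 1, bout_start + 1)
                boundaries.append(j)
                state = "on"
                bout_start = j
                off = int(np.argmax(temp[j : k + 1]))
                ref, ref_i = temp[j + off], j + off
    return boundaries


# ---------------------------------------------------------------------------
# onset extraction


def extract_daily_onsets(
    bouts: BoutSeries,
    brood: "pd.Series | dict",
    max_chick_day: int = 13,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily activity onsets: first off-bout after the long night sit.

    For each analysed date the longest on-bout overlapping the night
    window (midnight to 05:00) is taken as the nocturnal sit; the onset
    is the start of the first off-bout after it, in decimal hours since
    midnight.  Dates later than ``max_chick_day`` days after (expected)
    hatch are excluded; when hatch was not observed it is expected 13
    days after clutch completion (incubation day 14).

    Returns ``(onsets, qc)`` where ``qc`` lists skipped dates and the
    reason.
    """
    brood = dict(brood)
    hatch = brood.get("hatch_date")
    if hatch is None or (isinstance(hatch, float) and np.isnan(hatch)):
        hatch = int(brood["incubation_start"]) + 13
    hatch = int(hatch)

    records = []
    qc = []
    for date in sorted(set(bouts.days) | set(bouts.invalid_days)):
        aday = april_day(date)
        if date in bouts.invalid_days:
            qc.append({"date": aday, "reason": bouts.invalid_days[date]})
            continue
        bday = aday - hatch
        if bday > max_chick_day:
            qc.append({"date": aday, "reason": "past max chick day"})
            continue
        day_bouts = bouts.days[date]
        night_end = pd.Timestamp(date) + pd.Timedelta(hours=NIGHT_END_HOUR)
        night_on = [b for b in day_bouts if b.label == "on" and b.start < night_end]
        if not night_on:
            qc.append({"date": aday, "reason": "no nocturnal on-bout"})
            continue
        sit = max(night_on, key=lambda b: b.duration)
        after = [b for b in day_bouts if b.label == "off" and b.start >= sit.end]
        if not after:
            qc.append({"date": aday, "reason": "no off-bout"})
            continue
        first = min(after, key=lambda b: b.start)
        onset = (first.start - pd.Timestamp(date)).total_seconds() / 3600.0
        records.append(
            {
                "female_id": brood.get("female_id"),
                "brood_id": brood.get("brood_id"),
                "nest_box": brood.get("nest_box"),
                "year": brood.get("year", date.year),
                "date": aday,
                "onset": onset,
                "breeding_day": bday,
                "stage": "incubation" if bday < 0 else "provisioning",
            }
        )
    cols = [
        "female_id",
        "brood_id",
        "nest_box",
        "year",
        "date",
        "onset",
        "breeding_day",
        "stage",
    ]
    onsets = pd.DataFrame(records, columns=cols)
    return onsets, pd.DataFrame(qc, columns=["date", "reason"])


def detect_onsets_for_trace(
    trace: TemperatureTrace,
    brood: "pd.Series | dict",
    margin: float = 5.0,
    fraction: float = 0.75,
    max_chick_day: int = 13,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-nest chain: incubation start, thresholds, bouts, onsets."""
    start = detect_incubation_start(trace, margin=margin, fraction=fraction)
    series = BoutSeries(trace.nest_id)
    if start is None:
        return extract_daily_onsets(series, brood, max_chick_day)
    gap_dates = trace.gap_dates()
    for date in trace.dates():
        if date < start:
            continue
        if date in gap_dates:
            series.invalid_days[date] = "gap in trace"
            continue
        day_mask = trace.window(
            pd.Timestamp(date), pd.Timestamp(date) + pd.Timedelta(days=1)
        )
        if day_mask.sum() < 2:
            series.invalid_days[date] = "too few samples"
            continue
        th = derive_thresholds(trace, date)
        series.add_day(date, detect_bouts(trace, th, date))
    return extract_daily_onsets(series, brood, max_chick_day)
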
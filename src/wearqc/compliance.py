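"""Participant wear-compliance and interaction analytics.

Turns raw sample timestamps into data sessions, apportions wear time to
local calendar days, flags days below the study's minimum daily wear
duration (8 h by default), computes coverage ratios over analysis windows,
time-of-day × weekday coverage heatmaps, complementary cumulative
distributions of window data ratios, per-day questionnaire interaction
rates, and sanity-check violations on participant event logs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .events import EventLog
from .timebase import IntervalSet, ValidationError

__all__ = [
    "ComplianceConfig",
    "DailySummary",
    "Violation",
    "sessions_from_timestamps",
    "daily_summary",
    "coverage_ratio",
    "tod_weekday_matrix",
    "ccdf_points",
    "interaction_rate",
    "validate_event_log",
]

_UTC = dt.timezone.utc


@dataclass
class ComplianceConfig:
    """Study-level compliance settings.

    ``min_daily_wear_s`` defaults to 8 hours; a day meeting it exactly
    counts as compliant.  Local days are defined by a fixed UTC offset.
    """

    min_daily_wear_s: float = 28800.0
    session_gap_s: float = 60.0
    utc_offset_min: int = 0
    heatmap_bin_min: int = 30

    def __post_init__(self) -> None:
        if self.min_daily_wear_s <= 0 or self.session_gap_s <= 0:
            raise ValidationError("durations must be positive")
        if abs(self.utc_offset_min) > 840:
            raise ValidationError("|utc_offset_min| must be <= 840")
        if self.heatmap_bin_min <= 0 or 1440 % self.heatmap_bin_min:
            raise ValidationError("heatmap_bin_min must divide 1440")


@dataclass
class DailySummary:
    date: dt.date
    wear_seconds: float
    compliant: bool
    session_count: int
    alerts: list = field(default_factory=list)


@dataclass
class Violation:
    rule: str          # overlap | future_dated | backdated
    entries: list      # offending entry indices within the log
    message: str


def _day_start_epoch(day: dt.date, cfg: ComplianceConfig) -> float:
    """Epoch seconds of local midnight for ``day`` at the configured offset."""
    midnight_utc = dt.datetime(day.year, day.month, day.day, tzinfo=_UTC)
    return midnight_utc.timestamp() - cfg.utc_offset_min * 60.0


def _epoch_to_local_date(t: float, cfg: ComplianceConfig) -> dt.date:
    return dt.datetime.fromtimestamp(
        t + cfg.utc_offset_min * 60.0, tz=_UTC
    ).date()


def sessions_from_timestamps(
    sample_times,
    gap_s: float = 60.0,
    nominal_period_s: float | None = None,
) -> IntervalSet:
    """Merge sample timestamps into data sessions.

    Consecutive samples spaced at most ``gap_s`` apart belong to one
    session; each session is extended by one nominal sample period at its
    end so a sample owns the time until the next one would be due.  The
    nominal period is inferred as the median within-session spacing when
    not given (1 s if no spacing is observable).
    """
    t = np.asarray(sample_times, dtype=float)
    if t.size == 0:
        return IntervalSet("sessions")
    d = np.diff(t)
    if np.any(d < 0):
        raise ValidationError("sample timestamps must be sorted")
    if nominal_period_s is None:
        within = d[d <= gap_s]
        nominal_period_s = float(np.median(within)) if within.size else 1.0
    breaks = np.flatnonzero(d > gap_s)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    iv = np.column_stack([t[starts], t[ends] + nominal_period_s])
    return IntervalSet("sessions", iv)


def daily_summary(
    sessions: IntervalSet,
    cfg: ComplianceConfig | None = None,
    study_days=None,
) -> list[DailySummary]:
    """Per-day wear seconds, compliance flag and alerts.

    Sessions are apportioned to local days by clipping at midnight, so the
    per-day wear seconds sum exactly to the total session duration over the
    covered span.  Days with no data raise a ``no_data`` alert; days with
    some data under the threshold raise ``below_minimum``.
    """
    cfg = cfg or ComplianceConfig()
    if study_days is None:
        if not len(sessions):
            return []
        first = _epoch_to_local_date(sessions.intervals[0, 0], cfg)
        last = _epoch_to_local_date(sessions.intervals[-1, 1] - 1e-3, cfg)
        study_days = [first + dt.timedelta(days=i)
                      for i in range((last - first).days + 1)]
    out = []
    for day in study_days:
        d0 = _day_start_epoch(day, cfg)
        d1 = d0 + 86400.0
        wear = sessions.intersect_length(d0, d1)
        n_sess = len(sessions.clip(d0, d1))
        alerts = []
        if wear == 0.0:
            alerts.append("no_data")
        elif wear < cfg.min_daily_wear_s:
            alerts.append("below_minimum")
        out.append(DailySummary(
            date=day,
            wear_seconds=wear,
            compliant=wear >= cfg.min_daily_wear_s,
            session_count=n_sess,
            alerts=alerts,
        ))
    return out


def coverage_ratio(sessions: IntervalSet, window) -> float:
    """Fraction of the window ``[start, end)`` covered by sessions."""
    start, end = float(window[0]), float(window[1])
    if end <= start:
        raise ValidationError("window must have positive length")
    return sessions.intersect_length(start, end) / (end - start)


def tod_weekday_matrix(
    sessions: IntervalSet,
    cfg: ComplianceConfig | None = None,
    study_days=None,
) -> np.ndarray:
    """7 × K matrix of mean coverage ratios (rows Mon..Sun, K daily bins).

    Cell (d, k) averages the coverage ratio of time-of-day bin k over every
    occurrence of weekday d within the study span (derived from the
    sessions when ``study_days`` is not given).  Weekdays with no
    occurrence yield 0.
    """
    cfg = cfg or ComplianceConfig()
    k_bins = 1440 // cfg.heatmap_bin_min
    if study_days is None:
        if not len(sessions):
            return np.zeros((7, k_bins))
        first = _epoch_to_local_date(sessions.intervals[0, 0], cfg)
        last = _epoch_to_local_date(sessions.intervals[-1, 1] - 1e-3, cfg)
        study_days = [first + dt.timedelta(days=i)
                      for i in range((last - first).days + 1)]
    sums = np.zeros((7, k_bins))
    counts = np.zeros((7, k_bins))
    bin_s = cfg.heatmap_bin_min * 60.0
    for day in study_days:
        d0 = _day_start_epoch(day, cfg)
        wd = day.weekday()
        for k in range(k_bins):
            ratio = sessions.intersect_length(d0 + k * bin_s,
                                              d0 + (k + 1) * bin_s) / bin_s
            sums[wd, k] += ratio
            counts[wd, k] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return out


def ccdf_points(ratios) -> list[tuple[float, int]]:
    """Complementary cumulative distribution of window data ratios.

    For each distinct threshold x (plus 0 and 1), the count of ratios
    ≥ x; counts are non-increasing in x and the count at 0 equals N.
    """
    r = np.asarray(list(ratios), dtype=float)
    if r.size and (r.min() < 0 or r.max() > 1):
        raise ValidationError("data ratios must lie in [0, 1]")
    thresholds = np.unique(np.concatenate([[0.0, 1.0], r]))
    return [(float(x), int(np.sum(r >= x))) for x in thresholds]


def interaction_rate(
    log: EventLog, day: dt.date, cfg: ComplianceConfig | None = None
) -> float | None:
    """Answered-or-reviewed over prompted entries for a local day.

    Returns None (missing, not 0) for days without any prompt.
    """
    cfg = cfg or ComplianceConfig()
    d0 = _day_start_epoch(day, cfg)
    d1 = d0 + 86400.0
    prompted = sum(
        1 for e in log.of_kind("questionnaire_prompted", "timeline_prompted")
        if d0 <= e.entry_time < d1
    )
    if prompted == 0:
        return None
    answered = sum(
        1 for e in log.of_kind("questionnaire_answered", "timeline_reviewed")
        if d0 <= e.entry_time < d1
    )
    return answered / prompted


def validate_event_log(
    log: EventLog, now: float, max_backdate_s: float = 1_209_600.0
) -> list[Violation]:
    """Sanity-check rules on participant entries.

    Violations flagged: (a) two same-kind events with overlapping
    ``[start, end)`` spans; (b) an event dated after the moment it was
    entered (future-dated); (c) an event dated more than ``max_backdate_s``
    (two weeks by default) before it was entered.
    """
    violations: list[Violation] = []
    entries = list(log)
    for i, e in enumerate(entries):
        if e.event_time_start > e.entry_time:
            violations.append(Violation(
                "future_dated", [i],
                f"entry {i} ({e.kind}): event start is after the entry time",
            ))
        if e.entry_time - e.event_time_start > max_backdate_s:
            violations.append(Violation(
                "backdated", [i],
                f"entry {i} ({e.kind}): event backdated more than "
                f"{max_backdate_s / 86400:.0f} days",
            ))
    by_kind: dict[str, list[int]] = {}
    for i, e in enumerate(entries):
        by_kind.setdefault(e.kind, []).append(i)
    for kind, idxs in by_kind.items():
        spanned = [i for i in idxs if entries[i].event_time_end is not None]
        spanned.sort(key=lambda i: entries[i].event_time_start)
        max_end_idx = None
        for b in spanned:
            if (max_end_idx is not None
                    and entries[b].event_time_start < entries[max_end_idx].event_time_end):
                violations.append(Violation(
                    "overlap", [max_end_idx, b],
                    f"entries {max_end_idx} and {b}: concurrent {kind} events",
                ))
            if (max_end_idx is None
                    or entries[b].event_time_end > entries[max_end_idx].event_time_end):
                max_end_idx = b
    return violations
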
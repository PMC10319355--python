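"""Defecation motor program (DMP) rhythm analysis from behavioral event logs.

The DMP is a rhythmic behavior with a period of roughly 50 s in wild-type
*C. elegans*: a posterior body-wall muscle contraction (pBoc) starts each
cycle, often followed by an anterior contraction (aBoc) and an expulsion
(Exp). Logs are scored in BORIS and exported as CSV; this module computes
per-animal cycle lengths (time between successive pBocs), the 10-cycle mean
cycle length, and aBoc/expulsion frequencies as event-count ratios over
pBoc counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EventLogError

__all__ = [
    "Event",
    "EventLog",
    "DefecationSummary",
    "PBOC",
    "ABOC",
    "EXP",
    "DEFAULT_ALIASES",
    "parse_boris_csv",
    "write_boris_csv",
    "cycle_lengths",
    "mean_cycle_length",
    "aboc_frequency",
    "expulsion_frequency",
    "summarize_animal",
    "summarize_group",
]

PBOC = "pBoc"
ABOC = "aBoc"
EXP = "Exp"
LABELS = (PBOC, ABOC, EXP)

# Alias map applied after lowercasing/stripping the raw behavior label.
DEFAULT_ALIASES: dict[str, str] = {
    "pboc": PBOC,
    "posterior body contraction": PBOC,
    "posterior body wall muscle contraction": PBOC,
    "aboc": ABOC,
    "anterior body contraction": ABOC,
    "anterior body wall muscle contraction": ABOC,
    "exp": EXP,
    "expulsion": EXP,
    "emc": EXP,
    "enteric muscle contraction": EXP,
}


@dataclass(frozen=True)
class Event:
    time_s: float
    label: str
    animal: str = ""

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("event time must be >= 0")
        if self.label not in LABELS:
            raise ValueError(f"unknown behavior label {self.label!r}")


@dataclass(frozen=True)
class EventLog:
    """Time-sorted labeled events for one animal."""

    animal: str
    events: tuple[Event, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("events must be time-sorted")
        if not any(e.label == PBOC for e in self.events):
            raise ValueError("event log must contain at least one pBoc")

    def times(self, label: str) -> np.ndarray:
        return np.array([e.time_s for e in self.events if e.label == label])

    def count(self, label: str) -> int:
        return sum(e.label == label for e in self.events)


@dataclass(frozen=True)
class DefecationSummary:
    animal: str
    condition: str
    n_cycles: int
    cycle_lengths_s: tuple[float, ...]
    mean_cycle_length_s: float
    aboc_frequency: float
    expulsion_frequency: float


def _sort_events(events: list[Event]) -> list[Event]:
    # at identical timestamps pBoc sorts first: it delimits the cycle
    prio = {PBOC: 0, ABOC: 1, EXP: 2}
    return sorted(events, key=lambda e: (e.time_s, prio[e.label]))


def parse_boris_csv(
    path,
    aliases: dict[str, str] | None = None,
    observation_col: str | None = None,
    time_col: str | None = None,
    behavior_col: str = "Behavior",
) -> list[EventLog]:
    """Parse a BORIS aggregated-events CSV export into per-animal event logs.

    One :class:`EventLog` is produced per observation id, events sorted by
    time. Behavior labels pass through the alias map (case-insensitive);
    unknown labels are skipped with a single warning reporting the count.
    State events (rows with a "Behavior type" of STATE/START/STOP) are
    collapsed to their start time with a warning, since all DMP steps are
    scored as point events.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    obs = observation_col or _pick(df, ["Observation id", "Observation", "observation_id"])
    tcol = time_col or _pick(df, ["Time", "Start (s)", "time_s", "time"])
    if obs is None or tcol is None or behavior_col not in df.columns:
        raise EventLogError(
            "missing required columns: need observation id, time, and "
            f"{behavior_col!r}; found {list(df.columns)}"
        )
    btype = _pick(df, ["Behavior type", "Status"])
    if btype is not None:
        state_rows = df[btype].astype(str).str.upper().isin(["STATE", "START", "STOP"])
        if state_rows.any():
            warnings.warn(
                f"{int(state_rows.sum())} state-event rows collapsed to their start time",
                stacklevel=2,
            )
            df = df[~df[btype].astype(str).str.upper().eq("STOP")]
    logs: list[EventLog] = []
    n_unknown = 0
    for animal, grp in df.groupby(obs, sort=True):
        events: list[Event] = []
        for row_idx, row in grp.iterrows():
            try:
                t = float(row[tcol])
            except (TypeError, ValueError) as exc:
                raise EventLogError(f"unparseable time at row {row_idx}: {row[tcol]!r}") from exc
            label = aliases.get(str(row[behavior_col]).strip().lower())
            if label is None:
                n_unknown += 1
                continue
            events.append(Event(time_s=t, label=label, animal=str(animal)))
        if events:
            logs.append(EventLog(animal=str(animal), events=tuple(_sort_events(events))))
    if n_unknown:
        warnings.warn(f"skipped {n_unknown} events with unknown behavior labels", stacklevel=2)
    return logs


def _pick(df: pd.DataFrame, candidates: list[str]) -> str | None:
    for c in candidates:
        if c in df.columns:
            return c
    return None


def write_boris_csv(logs: list[EventLog], path) -> None:
    """Write event logs in the BORIS aggregated-events CSV dialect."""
    rows = [
        {
            "Observation id": log.animal,
            "Subject": log.animal,
            "Behavior": e.label,
            "Behavior type": "POINT",
            "Time": e.time_s,
        }
        for log in logs
        for e in log.events
    ]
    # %.17g round-trips float64 times exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def cycle_lengths(log: EventLog) -> np.ndarray:
    """Successive differences of pBoc times: one DMP cycle per interval."""
    t = log.times(PBOC)
    if len(t) < 2:
        raise EventLogError(f"animal {log.animal!r}: need >= 2 pBoc events, got {len(t)}")
    return np.diff(t)


def mean_cycle_length(log: EventLog, n_cycles: int = 10) -> float:
    """Mean of the first ``n_cycles`` cycle lengths (consecutive-cycle rule)."""
    iv = cycle_lengths(log)
    if len(iv) < n_cycles:
        raise EventLogError(
            f"animal {log.animal!r}: only {len(iv)} cycles observed, "
            f"{n_cycles} consecutive cycles required"
        )
    return float(np.mean(iv[:n_cycles]))


def aboc_frequency(log: EventLog) -> float:
    """aBoc frequency: ratio of aBoc count over pBoc count."""
    n_p = log.count(PBOC)
    if n_p == 0:
        raise EventLogError(f"animal {log.animal!r}: no pBoc events")
    return log.count(ABOC) / n_p


def expulsion_frequency(log: EventLog) -> float:
    """Expulsion frequency: ratio of Exp count over pBoc count."""
    n_p = log.count(PBOC)
    if n_p == 0:
        raise EventLogError(f"animal {log.animal!r}: no pBoc events")
    return log.count(EXP) / n_p


def summarize_animal(log: EventLog, n_cycles: int = 10) -> DefecationSummary:
    iv = cycle_lengths(log)
    return DefecationSummary(
        animal=log.animal,
        condition=log.condition,
        n_cycles=min(len(iv), n_cycles),
        cycle_lengths_s=tuple(float(x) for x in iv),
        mean_cycle_length_s=mean_cycle_length(log, n_cycles),
        aboc_frequency=aboc_frequency(log),
        expulsion_frequency=expulsion_frequency(log),
    )


def summarize_group(
    logs: list[EventLog],
    condition_map: dict[str, str] | None = None,
    n_cycles: int = 10,
) -> pd.DataFrame:
    """Per-condition boxplot summary of the three DMP statistics.

    ``condition_map`` maps animal id to condition label (the unblinding
    step); unmapped animals keep their log's condition or fall back to
    their own id. Quantiles use linear interpolation between order
    statistics. Returns one row per (condition, statistic) with
    n, mean, min, q25, median, q75, max.
    """
    if not logs:
        raise EventLogError("no event logs to summarize")
    from .summaries import group_summary

    rows = []
    for log in logs:
        cond = (condition_map or {}).get(log.animal, log.condition or log.animal)
        s = summarize_animal(log, n_cycles)
        rows.append(
            {
                "condition": cond,
                "animal": log.animal,
                "mean_cycle_length_s": s.mean_cycle_length_s,
                "aboc_frequency": s.aboc_frequency,
                "expulsion_frequency": s.expulsion_frequency,
            }
        )
    per_animal = pd.DataFrame(rows)
    parts = []
    for stat in ("mean_cycle_length_s", "aboc_frequency", "expulsion_frequency"):
        t = group_summary(per_animal, value_col=stat, group_col="condition")
        t.insert(1, "statistic", stat)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)
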
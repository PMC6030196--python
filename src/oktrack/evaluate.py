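"""Event-level comparison of detector output against observer judgments.

Each projected stimulus is one event.  Detector and observer verdicts are
compared with a four-outcome taxonomy: success (both report no tracking,
or both report tracking in the same direction), false positive (software
tracking, observer none), false negative (observer tracking, software
none), wrong (both tracking, opposite directions).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

from .classify import CLOCKWISE, COUNTERCLOCKWISE, TrackingEvent

__all__ = [
    "EventAnnotation",
    "EvaluationSummary",
    "classify_event_pair",
    "summarize",
    "interobserver_agreement",
    "software_verdict",
    "read_annotations",
]

OUTCOMES = ("success", "false_positive", "false_negative", "wrong")
_DIRECTIONS = (CLOCKWISE, COUNTERCLOCKWISE)


@dataclass(frozen=True)
class EventAnnotation:
    """One observer judgment for one projected stimulus."""

    event_id: int
    observer_tracking: bool
    observer_direction: Optional[str]  # clockwise/counterclockwise/None
    stimulus_direction: Optional[str] = None
    stim_start: Optional[int] = None  # frame interval of the stimulus,
    stim_end: Optional[int] = None  # when mapping detector events onto it

    def __post_init__(self) -> None:
        if self.observer_tracking != (self.observer_direction in _DIRECTIONS):
            raise ValueError(
                "observer_direction must be a direction iff observer_tracking"
            )


@dataclass(frozen=True)
class EvaluationSummary:
    n_events: int
    success: int
    false_positive: int
    false_negative: int
    wrong: int
    success_pct: float
    false_positive_pct: float
    false_negative_pct: float
    wrong_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def classify_event_pair(
    software_direction: Optional[str], observer: EventAnnotation
) -> str:
    """Assign one of the four outcomes to a (software, observer) pair.

    ``software_direction`` is the detector's verdict for the stimulus:
    a direction string or None for no tracking detected.
    """
    if software_direction not in (None, *_DIRECTIONS):
        raise ValueError(f"bad software direction: {software_direction!r}")
    obs = observer.observer_direction if observer.observer_tracking else None
    if software_direction is None and obs is None:
        return "success"
    if software_direction is not None and obs is None:
        return "false_positive"
    if software_direction is None and obs is not None:
        return "false_negative"
    return "success" if software_direction == obs else "wrong"


def summarize(outcomes: Sequence[str]) -> EvaluationSummary:
    """Counts and one-decimal percentages over the four-outcome taxonomy."""
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    bad = set(outcomes) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcomes: {sorted(bad)}")
    n = len(outcomes)
    counts = {k: sum(1 for o in outcomes if o == k) for k in OUTCOMES}
    pct = {k: round(100.0 * c / n, 1) for k, c in counts.items()}
    return EvaluationSummary(
        n_events=n,
        success=counts["success"],
        false_positive=counts["false_positive"],
        false_negative=counts["false_negative"],
        wrong=counts["wrong"],
        success_pct=pct["success"],
        false_positive_pct=pct["false_positive"],
        false_negative_pct=pct["false_negative"],
        wrong_pct=pct["wrong"],
    )


def interobserver_agreement(
    obs1: Sequence[EventAnnotation], obs2: Sequence[EventAnnotation]
) -> tuple[float, float, float]:
    """Percent agreement between two observers over the same events.

    Returns (same_behavior, opposite_direction, presence_disagreement)
    percentages, one-decimal rounded; same + opposite + presence = 100 up
    to rounding.
    """
    if len(obs1) != len(obs2):
        raise ValueError("annotation lists must cover the same events")
    if not obs1:
        raise ValueError("no annotations")
    same = opposite = presence = 0
    for a, b in zip(obs1, obs2):
        da = a.observer_direction if a.observer_tracking else None
        db = b.observer_direction if b.observer_tracking else None
        if da == db:
            same += 1
        elif da is not None and db is not None:
            opposite += 1
        else:
            presence += 1
    n = len(obs1)
    return (
        round(100.0 * same / n, 1),
        round(100.0 * opposite / n, 1),
        round(100.0 * presence / n, 1),
    )


def software_verdict(
    events: Sequence[TrackingEvent], stim_start: int, stim_end: int
) -> Optional[str]:
    """Detector verdict for one stimulus interval.

    The detector can split one bout into several events; the verdict is
    the direction of the longest event (most samples) overlapping the
    interval, or None when no event does.
    """
    overlapping = [
        e for e in events if e.start_frame <= stim_end and e.end_frame >= stim_start
    ]
    if not overlapping:
        return None
    longest = max(overlapping, key=lambda e: (e.n_samples, -e.start_frame))
    return longest.direction


def read_annotations(path) -> list[EventAnnotation]:
    """Read observer annotations from CSV (EventAnnotation field names as
    header; empty/'none' observer_direction means no tracking)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"event_id", "observer_tracking", "observer_direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV is missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        direction = row["observer_direction"]
        if isinstance(direction, str):
            direction = direction.strip().lower()
        if direction in ("", "none", "nan") or direction != direction:
            direction = None
        tracking = row["observer_tracking"]
        if isinstance(tracking, str):
            tracking = tracking.strip().lower() in ("1", "true", "yes", "y")
        out.append(
            EventAnnotation(
                event_id=int(row["event_id"]),
                observer_tracking=bool(tracking),
                observer_direction=direction,
                stimulus_direction=_opt_str(row.get("stimulus_direction")),
                stim_start=_opt_int(row.get("stim_start")),
                stim_end=_opt_int(row.get("stim_end")),
            )
        )
    return out


def _opt_str(v):
    if v is None or v != v or v == "":
        return None
    return str(v).strip().lower() or None


def _opt_int(v):
    if v is None or v != v or v == "":
        return None
    return int(v)
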
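"""Two-color colocalization and the 11-class assembly/disassembly taxonomy.

Two tracked events in different channels colocalize at a pair of data points
when those points are closer than 200 nm in position and 400 ms in time (both
strict).  Each event (or colocalized pair) is then sorted into one of 11
classes:

===== =============================================
class meaning
===== =============================================
1     A alone (no partner in channel B)
2     B alone
3     A arrives first, A departs first
4     A arrives first, depart together
5     A arrives first, B departs first
6     arrive together, A departs first
7     arrive together, depart together
8     arrive together, B departs first
9     B arrives first, A departs first
10    B arrives first, depart together
11    B arrives first, B departs first
===== =============================================

"Together" means within the colocalization time window (0.4 s by default).
Classes 3-11 enumerate arrival order × departure order row-major; the
numbering is frozen so that class 7 is arrive-and-depart-together and class 9
is B-first assembly with A-first departure (the two classes observed most
prominently for the DDB1/DDB2 heterodimer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "EventTrace",
    "ColocalizationEvent",
    "CLASS_LABELS",
    "colocalized_points",
    "classify_event",
    "colocalization_summary",
    "tracks_to_traces",
]

CLASS_LABELS: dict[int, str] = {
    1: "A alone",
    2: "B alone",
    3: "A first, A leaves first",
    4: "A first, leave together",
    5: "A first, B leaves first",
    6: "arrive together, A leaves first",
    7: "arrive and dissociate together",
    8: "arrive together, B leaves first",
    9: "B first, A leaves first",
    10: "B first, leave together",
    11: "B first, B leaves first",
}


@dataclass
class EventTrace:
    """Minimal per-event trace: sample times (s) and positions (µm)."""

    track_id: int
    channel: int
    times: np.ndarray
    positions_um: np.ndarray

    @property
    def start(self) -> float:
        return float(self.times[0])

    @property
    def end(self) -> float:
        return float(self.times[-1])


@dataclass
class ColocalizationEvent:
    """One classified event: a single track or a colocalized pair."""

    track_a: int | None
    track_b: int | None
    class_id: int
    label: str
    n_colocalized_points: int = 0
    overlap: float = 0.0   # s of matched time span


def tracks_to_traces(tracks) -> list[EventTrace]:
    """Adapt :class:`~kymotrace.tracking.Track` objects (or a track table)."""
    if isinstance(tracks, pd.DataFrame):
        out = []
        for tid, sub in tracks.groupby("track_id"):
            out.append(EventTrace(
                track_id=int(tid),
                channel=int(sub["channel"].iloc[0]),
                times=sub["time_s"].to_numpy(),
                positions_um=sub["position_um"].to_numpy(),
            ))
        return out
    return [
        EventTrace(track_id=i, channel=t.channel, times=t.times,
                   positions_um=t.positions_um)
        for i, t in enumerate(tracks)
    ]


def colocalized_points(
    track_a: EventTrace,
    track_b: EventTrace,
    dist_window: float = 200.0,  # nm
    time_window: float = 0.4,    # s
) -> list[tuple[int, int]]:
    """All point pairs (i, j) with |Δposition| < dist_window and |Δt| < time_window.

    Both inequalities are strict.  A pair of events that starts apart and
    diffuses together is matched from the approach onward.
    """
    dt = np.abs(track_a.times[:, None] - track_b.times[None, :])
    dx = np.abs(track_a.positions_um[:, None] - track_b.positions_um[None, :]) * 1000.0
    ii, jj = np.nonzero((dt < time_window) & (dx < dist_window))
    return list(zip(ii.tolist(), jj.tolist()))


def _order(first: float, second: float, window: float) -> int:
    """-1 if first precedes by > window, +1 if second does, 0 if together."""
    if first < second - window:
        return -1
    if second < first - window:
        return 1
    return 0


def classify_event(
    track_a: EventTrace | None,
    track_b: EventTrace | None,
    dist_window: float = 200.0,
    time_window: float = 0.4,
) -> ColocalizationEvent:
    """Assign one of the 11 classes to a single event or event pair."""
    if track_a is None and track_b is None:
        raise InvalidInputError("at least one track required")
    if track_b is None:
        return ColocalizationEvent(track_a.track_id, None, 1, CLASS_LABELS[1])
    if track_a is None:
        return ColocalizationEvent(None, track_b.track_id, 2, CLASS_LABELS[2])

    pts = colocalized_points(track_a, track_b, dist_window, time_window)
    arrival = _order(track_a.start, track_b.start, time_window)   # -1 A first
    departure = _order(track_a.end, track_b.end, time_window)     # -1 A leaves first
    row = {-1: 0, 0: 1, 1: 2}[arrival]
    col = {-1: 0, 0: 1, 1: 2}[departure]
    class_id = 3 + 3 * row + col
    overlap = max(
        0.0,
        min(track_a.end, track_b.end) - max(track_a.start, track_b.start),
    )
    return ColocalizationEvent(
        track_a.track_id, track_b.track_id, class_id, CLASS_LABELS[class_id],
        n_colocalized_points=len(pts), overlap=overlap,
    )


def colocalization_summary(
    tracks_a: list[EventTrace],
    tracks_b: list[EventTrace],
    dist_window: float = 200.0,
    time_window: float = 0.4,
) -> tuple[list[ColocalizationEvent], pd.DataFrame]:
    """Pair tracks across channels and tabulate per-class counts and fractions.

    Each track participates in exactly one event.  Candidate pairs (those with
    at least one colocalized point pair) are accepted greedily by descending
    temporal overlap, one partner per track; leftovers become single-color
    events.  Returns the event list and a table with columns
    ``class_id, label, count, fraction``.
    """
    candidates = []
    for a in tracks_a:
        for b in tracks_b:
            pts = colocalized_points(a, b, dist_window, time_window)
            if pts:
                overlap = min(a.end, b.end) - max(a.start, b.start)
                candidates.append((overlap, a, b, len(pts)))
    candidates.sort(key=lambda c: -c[0])
    paired_a: set[int] = set()
    paired_b: set[int] = set()
    events: list[ColocalizationEvent] = []
    for overlap, a, b, npts in candidates:
        if a.track_id in paired_a or b.track_id in paired_b:
            continue
        paired_a.add(a.track_id)
        paired_b.add(b.track_id)
        events.append(classify_event(a, b, dist_window, time_window))
    for a in tracks_a:
        if a.track_id not in paired_a:
            events.append(classify_event(a, None))
    for b in tracks_b:
        if b.track_id not in paired_b:
            events.append(classify_event(None, b))

    counts = {cid: 0 for cid in CLASS_LABELS}
    for e in events:
        counts[e.class_id] += 1
    total = max(len(events), 1)
    table = pd.DataFrame({
        "class_id": list(CLASS_LABELS),
        "label": [CLASS_LABELS[c] for c in CLASS_LABELS],
        "count": [counts[c] for c in CLASS_LABELS],
        "fraction": [counts[c] / total for c in CLASS_LABELS],
    })
    return events, table
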
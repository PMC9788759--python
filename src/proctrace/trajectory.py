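"""Piecewise-constant state paths (ground truth and inferred).

A :class:`StateTrajectory` is an ordered, contiguous list of
``(state, start, end)`` segments in seconds.  Two state spaces are used:

* processing assay: ``unbound``, ``bound_preinsert``, ``inserted_highFRET``,
  ``translocating``, ``unfolding``, ``s1_excursion`` (a motor slip during
  unfolding), ``post_translocation``;
* conformational assay: ``s1``, ``non_s1`` (``s1_excursion`` counts as s1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

PROCESSING_STATES = (
    "unbound",
    "bound_preinsert",
    "inserted_highFRET",
    "translocating",
    "unfolding",
    "s1_excursion",
    "post_translocation",
)
CONFORMATIONAL_STATES = ("s1", "non_s1")

#: states during which the substrate-attached donor dye is present
DONOR_PRESENT_STATES = frozenset(s for s in PROCESSING_STATES if s != "unbound")

#: conformational-assay states that read out as the low-FRET s1 conformation
S1_LIKE_STATES = frozenset({"s1", "s1_excursion"})


@dataclass(frozen=True)
class Segment:
    state: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StateTrajectory:
    """Contiguous, strictly increasing sequence of state segments."""

    segments: List[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = None
        for seg in self.segments:
            if not seg.end > seg.start:
                raise ValueError(
                    f"segment {seg} has non-positive duration")
            if prev_end is not None and not np.isclose(seg.start, prev_end):
                raise ValueError("segments must be contiguous")
            prev_end = seg.end

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    def states(self) -> set:
        return {seg.state for seg in self.segments}

    def durations_of(self, state: str) -> np.ndarray:
        return np.array([s.duration for s in self.segments if s.state == state])

    def state_at(self, t: float) -> str:
        if not self.start <= t <= self.end:
            raise ValueError(f"t={t} outside trajectory [{self.start}, {self.end}]")
        for seg in self.segments:
            if seg.start <= t < seg.end:
                return seg.state
        return self.segments[-1].state

    def append(self, state: str, duration: float) -> None:
        start = self.end if self.segments else 0.0
        self.segments.append(Segment(state, start, start + duration))

    def as_arrays(self) -> Tuple[np.ndarray, np.ndarray, List[str]]:
        starts = np.array([s.start for s in self.segments])
        ends = np.array([s.end for s in self.segments])
        labels = [s.state for s in self.segments]
        return starts, ends, labels

    def to_records(self) -> List[dict]:
        return [
            {"state": s.state, "start": s.start, "end": s.end}
            for s in self.segments
        ]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "StateTrajectory":
        return cls([Segment(r["state"], float(r["start"]), float(r["end"]))
                    for r in records])

    @classmethod
    def from_durations(cls, states: Sequence[str], durations: Sequence[float],
                       t0: float = 0.0) -> "StateTrajectory":
        segs = []
        t = t0
        for st, d in zip(states, durations):
            segs.append(Segment(st, t, t + d))
            t += d
        return cls(segs)


def merge_adjacent(traj: StateTrajectory) -> StateTrajectory:
    """Fuse consecutive segments that share a state label."""
    merged: List[Segment] = []
    for seg in traj.segments:
        if merged and merged[-1].state == seg.state:
            merged[-1] = Segment(seg.state, merged[-1].start, seg.end)
        else:
            merged.append(seg)
    return StateTrajectory(merged)
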
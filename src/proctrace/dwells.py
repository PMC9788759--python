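"""Dwell-time collections shared by the event, HMM and kinetics layers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import numpy as np


@dataclass
class DwellSet:
    """Durations of visits to one state, with censoring flags.

    A censored dwell was truncated by the trace start/end or by
    photobleaching; naive fits on censored dwells are biased, so fitting
    routines exclude (or explicitly model) them.
    """

    state_label: str
    durations: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise ValueError("durations and censored must have equal length")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")

    @property
    def n(self) -> int:
        return self.durations.size

    @property
    def uncensored(self) -> np.ndarray:
        return self.durations[~self.censored]

    def __len__(self) -> int:
        return self.n

    @classmethod
    def from_durations(
        cls,
        durations: Iterable[float],
        state_label: str = "",
        censored: Optional[Iterable[bool]] = None,
    ) -> "DwellSet":
        d = np.asarray(list(durations), dtype=float)
        c = (np.zeros(d.size, dtype=bool) if censored is None
             else np.asarray(list(censored), dtype=bool))
        return cls(state_label, d, c)

    @classmethod
    def concat(cls, sets: Iterable["DwellSet"]) -> "DwellSet":
        sets = list(sets)
        if not sets:
            raise ValueError("nothing to concatenate")
        return cls(
            sets[0].state_label,
            np.concatenate([s.durations for s in sets]),
            np.concatenate([s.censored for s in sets]),
        )
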
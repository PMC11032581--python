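"""The raw unit of behavioral analysis: one trial's walked path.

A :class:`Trajectory` holds the timestamped 2D positions sampled at 0.1 s by
the VR tracking system, the cone geometry of the trial, labeled events
(cone arrivals, out-of-border warnings, the response trigger), the return
condition, and the arena the trial ran in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import ArenaSpec

__all__ = ["Trajectory", "EVENT_LABELS", "CONDITIONS"]

EVENT_LABELS = (
    "cone1_reached",
    "cone2_reached",
    "cone3_reached",
    "oob_warning",
    "trigger",
)

#: Return conditions: A = all cues, B = no optic flow, C = no distal cues.
CONDITIONS = ("A", "B", "C")


@dataclass
class Trajectory:
    """One trial's path, geometry and events.

    ``events`` is a list of ``(sample_index, label)`` pairs; cone events must
    appear in order 1, 2, 3 and at most one trigger is allowed. The response
    (the participant's estimate of cone1) is the position at the trigger
    sample, or absent when the return path was never completed.
    """

    times: np.ndarray  # (n,) seconds, strictly increasing
    xy: np.ndarray  # (n, 2) meters, arena-centered
    cones: np.ndarray  # (3, 2) cone1..cone3
    condition: str
    events: list[tuple[int, str]]
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    meta: dict = field(default_factory=dict)  # pid, trial, environment id...

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.cones = np.asarray(self.cones, dtype=float)
        if self.xy.shape != (self.times.size, 2):
            raise ValueError("xy must be (n, 2) matching times")
        if self.cones.shape != (3, 2):
            raise ValueError("cones must be (3, 2)")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for idx, label in self.events:
            if label not in EVENT_LABELS:
                raise ValueError(f"unknown event label {label!r}")
            if not (0 <= idx < self.times.size):
                raise ValueError(f"event index {idx} out of range")
        cone_idx = [self._event_index(f"cone{k}_reached") for k in (1, 2, 3)]
        present = [i for i in cone_idx if i is not None]
        if present != sorted(present):
            raise ValueError("cone events must occur in order 1, 2, 3")
        if sum(1 for _, lab in self.events if lab == "trigger") > 1:
            raise ValueError("at most one trigger event per trial")

    def _event_index(self, label: str) -> int | None:
        for idx, lab in self.events:
            if lab == label:
                return idx
        return None

    @property
    def trigger_index(self) -> int | None:
        return self._event_index("trigger")

    @property
    def response(self) -> np.ndarray | None:
        """Estimated cone1 location (trigger position), or None."""
        i = self.trigger_index
        return None if i is None else self.xy[i]

    @property
    def cone3_index(self) -> int:
        i = self._event_index("cone3_reached")
        if i is None:
            raise ValueError("trajectory has no cone3_reached event")
        return i

    def return_path(self) -> np.ndarray:
        """Samples of the return path (from cone3 arrival onward), (m, 2)."""
        return self.xy[self.cone3_index :]
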
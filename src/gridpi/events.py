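"""Translation-event tables driving the directional GLMs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._angles import circular_mean_deg

__all__ = ["EventTable"]


@dataclass
class EventTable:
    """Ordered translation events (onset, duration, heading).

    ``partition`` labels each event ``estimation`` or ``test``; the default
    alternates by event index (odd/even interleaving), which is what makes
    the cross-validated magnitude robust to slow signal drift. The
    first-half/second-half split is reserved for temporal stability and is
    exposed through :meth:`temporal_halves`.
    """

    onset_s: np.ndarray
    duration_s: np.ndarray
    heading_deg: np.ndarray
    partition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        self.heading_deg = np.asarray(self.heading_deg, dtype=float)
        n = self.onset_s.size
        if self.duration_s.size != n or self.heading_deg.size != n:
            raise ValueError("onset, duration and heading must have equal length")
        if n and np.any(np.diff(self.onset_s) < 0):
            raise ValueError("event onsets must be non-decreasing")
        if not np.all(np.isfinite(self.heading_deg)):
            raise ValueError("event headings must be finite")
        if self.partition is None:
            labels = np.where(np.arange(n) % 2 == 0, "estimation", "test")
            self.partition = labels
        else:
            self.partition = np.asarray(self.partition)
            if self.partition.size != n:
                raise ValueError("partition labels must match the event count")
            bad = set(np.unique(self.partition)) - {"estimation", "test"}
            if bad:
                raise ValueError(f"unknown partition labels {sorted(bad)}")
        if n and (
            not (self.partition == "estimation").any()
            or not (self.partition == "test").any()
        ):
            raise ValueError("both partitions must be non-empty")

    def __len__(self) -> int:
        return int(self.onset_s.size)

    def subset(self, mask) -> "EventTable":
        mask = np.asarray(mask, dtype=bool)
        sub = EventTable.__new__(EventTable)
        sub.onset_s = self.onset_s[mask]
        sub.duration_s = self.duration_s[mask]
        sub.heading_deg = self.heading_deg[mask]
        sub.partition = self.partition[mask]
        return sub

    def half(self, which: str) -> "EventTable":
        """The odd/even partition subset, ``estimation`` or ``test``."""
        if which not in ("estimation", "test"):
            raise ValueError("which must be 'estimation' or 'test'")
        return self.subset(self.partition == which)

    def swap_partition(self) -> "EventTable":
        labels = np.where(self.partition == "estimation", "test", "estimation")
        return EventTable(self.onset_s, self.duration_s, self.heading_deg, labels)

    def temporal_halves(self) -> tuple["EventTable", "EventTable"]:
        """Split by time (first vs. second half of events, in onset order)."""
        n = len(self)
        if n < 4:
            raise ValueError("need at least 4 events to split temporally")
        first = np.arange(n) < n // 2
        return self.subset(first), self.subset(~first)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": self.onset_s,
                "duration": self.duration_s,
                "heading_deg": self.heading_deg,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        required = ["onset", "duration", "heading_deg"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"events table is missing column(s) {missing}")
        return cls(
            df["onset"].to_numpy(float),
            df["duration"].to_numpy(float),
            df["heading_deg"].to_numpy(float),
        )

    @staticmethod
    def heading_from_samples(sample_headings_deg) -> float:
        """Reduce continuously sampled headings within one translation event
        (tracked every ~20 ms) to a single event heading: circular mean."""
        return circular_mean_deg(sample_headings_deg)
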
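"""Event containers shared by every detector.

An :class:`EventSeries` holds the ordered heel-strike and toe-off timestamps
produced by one method for one foot ("left", "right") or, for the sacral-IMU
methods that cannot attribute events to a side, ``foot="unassigned"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

VALID_FEET = ("left", "right", "unassigned")


def _strictly_increasing(x) -> bool:
    a = np.asarray(x, dtype=float)
    return a.size < 2 or bool(np.all(np.diff(a) > 0))


@dataclass
class EventSeries:
    """Ordered heel-strike / toe-off timestamps from one method and foot."""

    method: str
    foot: str
    heel_strikes: list[float] = field(default_factory=list)
    toe_offs: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.foot not in VALID_FEET:
            raise ConfigurationError(f"foot must be one of {VALID_FEET}, got {self.foot!r}")
        self.heel_strikes = [float(t) for t in self.heel_strikes]
        self.toe_offs = [float(t) for t in self.toe_offs]
        if not _strictly_increasing(self.heel_strikes):
            raise ConfigurationError(f"{self.method}/{self.foot}: heel strikes not strictly increasing")
        if not _strictly_increasing(self.toe_offs):
            raise ConfigurationError(f"{self.method}/{self.foot}: toe-offs not strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.heel_strikes) + len(self.toe_offs)

    def shifted(self, delta: float) -> "EventSeries":
        """The same events shifted rigidly in time by ``delta`` seconds."""
        return EventSeries(self.method, self.foot,
                           [t + delta for t in self.heel_strikes],
                           [t + delta for t in self.toe_offs])

    def merged(self) -> list[tuple[float, str]]:
        """All events as a time-sorted list of (time, 'HS'|'TO') tuples."""
        ev = [(t, "HS") for t in self.heel_strikes] + [(t, "TO") for t in self.toe_offs]
        return sorted(ev)

    def alternates(self) -> bool:
        """True if the merged sequence strictly alternates HS/TO starting with HS."""
        merged = self.merged()
        if not merged:
            return True
        expected = "HS"
        for _, kind in merged:
            if kind != expected:
                return False
            expected = "TO" if expected == "HS" else "HS"
        return True


@dataclass
class GroundTruthEvents:
    """Simulator-emitted true event timestamps, per foot."""

    heel_strikes_left: list[float]
    toe_offs_left: list[float]
    heel_strikes_right: list[float]
    toe_offs_right: list[float]

    def series(self, foot: str) -> EventSeries:
        if foot == "left":
            return EventSeries("truth", "left", self.heel_strikes_left, self.toe_offs_left)
        if foot == "right":
            return EventSeries("truth", "right", self.heel_strikes_right, self.toe_offs_right)
        raise ConfigurationError(f"unknown foot {foot!r}")

    def merged_series(self) -> EventSeries:
        """Both feet merged into one side-agnostic series (for sacral-IMU
        comparisons, where the detector cannot attribute events to a side)."""
        hs = sorted(self.heel_strikes_left + self.heel_strikes_right)
        to = sorted(self.toe_offs_left + self.toe_offs_right)
        return EventSeries("truth", "unassigned", hs, to)

    @property
    def n_steps(self) -> int:
        return len(self.heel_strikes_left) + len(self.heel_strikes_right)
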
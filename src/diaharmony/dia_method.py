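"""Isolation-window tiling and cycle-timing model of the DIA acquisition method.

The method is described by a precursor m/z range tiled with fixed-width
isolation windows, grouped into subcycles anchored on survey (MS1) scans.
Two wall-clock periods matter downstream: the survey-scan repeat time and the
full fragmentation-cycle repeat time, which set how many quantitative data
points fall across a chromatographic elution peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .errors import InvalidParameterError, MzRangeError, SchemeMismatchError

__all__ = [
    "IsolationWindow",
    "DIAMethod",
    "build_window_scheme",
    "points_per_peak",
    "expected_points",
    "window_for_mz",
]


@dataclass(frozen=True, slots=True)
class IsolationWindow:
    """One fragmentation isolation window: ``[low, high)`` in Th."""

    index: int
    center_mz: float
    width: float
    subcycle: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise InvalidParameterError(f"window index must be >= 1, got {self.index}")
        if self.width <= 0:
            raise InvalidParameterError(f"window width must be > 0, got {self.width}")
        if self.subcycle < 1:
            raise InvalidParameterError(f"subcycle must be >= 1, got {self.subcycle}")

    @property
    def low(self) -> float:
        return self.center_mz - self.width / 2.0

    @property
    def high(self) -> float:
        return self.center_mz + self.width / 2.0

    def contains(self, mz: float) -> bool:
        """Half-open membership test: ``low <= mz < high``."""
        return self.low <= mz < self.high


@dataclass(frozen=True)
class DIAMethod:
    """Acquisition structure: window tiling plus MS1/MS2 cycle timing.

    ``ms1_cycle_time`` is the survey-scan repeat period; ``ms2_cycle_time``
    is the period after which the same isolation window is fragmented again
    (one pass through all subcycles).
    """

    mz_start: float
    mz_end: float
    window_width: float
    scans_per_subcycle: int
    n_subcycles: int
    ms1_cycle_time: float
    ms2_cycle_time: float
    windows: tuple[IsolationWindow, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.mz_end <= self.mz_start:
            raise InvalidParameterError("mz_end must exceed mz_start")
        if self.ms2_cycle_time < self.ms1_cycle_time:
            raise InvalidParameterError(
                "ms2_cycle_time must be >= ms1_cycle_time "
                f"({self.ms2_cycle_time} < {self.ms1_cycle_time})"
            )
        if len(self.windows) > self.scans_per_subcycle * self.n_subcycles:
            raise InvalidParameterError(
                "window count exceeds scans_per_subcycle * n_subcycles"
            )
        if len(self.windows) * self.window_width < (self.mz_end - self.mz_start) - 1e-9:
            raise InvalidParameterError("windows do not cover the precursor range")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def describe(self) -> list[dict]:
        """Window table rows (index, low, high, center, subcycle)."""
        return [
            {
                "index": w.index,
                "low": w.low,
                "high": w.high,
                "center": w.center_mz,
                "subcycle": w.subcycle,
            }
            for w in self.windows
        ]


def build_window_scheme(
    mz_start: float,
    mz_end: float,
    window_width: float,
    scans_per_subcycle: int,
    ms1_cycle_time: float = 1.7,
    ms2_cycle_time: float = 5.2,
    allow_padding: bool = False,
) -> DIAMethod:
    """Tile ``[mz_start, mz_end]`` with contiguous isolation windows.

    Windows are assigned to subcycles in contiguous low-to-high m/z blocks
    of ``scans_per_subcycle`` windows each. When the range is not an exact
    multiple of ``window_width * scans_per_subcycle`` the call fails unless
    ``allow_padding`` is set, in which case the final window may extend past
    ``mz_end`` and the final subcycle may be partial.
    """
    if window_width <= 0:
        raise InvalidParameterError(f"window_width must be > 0, got {window_width}")
    if scans_per_subcycle < 1:
        raise InvalidParameterError("scans_per_subcycle must be >= 1")
    if mz_end <= mz_start:
        raise InvalidParameterError("mz_end must exceed mz_start")

    span = mz_end - mz_start
    n_exact = span / window_width
    n_windows = int(round(n_exact))
    exact = math.isclose(n_exact, n_windows, rel_tol=0, abs_tol=1e-9)
    if not exact:
        if not allow_padding:
            raise SchemeMismatchError(
                f"range {span} Th is not an integer multiple of the "
                f"{window_width} Da window width; pass allow_padding=True"
            )
        n_windows = math.ceil(n_exact - 1e-9)
    if not exact or n_windows % scans_per_subcycle != 0:
        if not allow_padding and n_windows % scans_per_subcycle != 0:
            raise SchemeMismatchError(
                f"{n_windows} windows cannot be split into full subcycles of "
                f"{scans_per_subcycle}; pass allow_padding=True"
            )
    n_subcycles = math.ceil(n_windows / scans_per_subcycle)

    windows = tuple(
        IsolationWindow(
            index=i + 1,
            center_mz=mz_start + (i + 0.5) * window_width,
            width=window_width,
            subcycle=i // scans_per_subcycle + 1,
        )
        for i in range(n_windows)
    )
    return DIAMethod(
        mz_start=mz_start,
        mz_end=mz_end,
        window_width=window_width,
        scans_per_subcycle=scans_per_subcycle,
        n_subcycles=n_subcycles,
        ms1_cycle_time=ms1_cycle_time,
        ms2_cycle_time=ms2_cycle_time,
        windows=windows,
    )


def points_per_peak(peak_width: float, cycle_time: float) -> int:
    """Guaranteed number of complete cycles within an elution peak.

    Uses the floor so the count holds under arbitrary cycle phase relative
    to the peak; see :func:`expected_points` for the real-valued density.
    """
    if peak_width <= 0:
        raise InvalidParameterError(f"peak_width must be > 0, got {peak_width}")
    if cycle_time <= 0:
        raise InvalidParameterError(f"cycle_time must be > 0, got {cycle_time}")
    return int(math.floor(peak_width / cycle_time))


def expected_points(peak_width: float, cycle_time: float) -> float:
    """Real-valued sampling density ``peak_width / cycle_time``."""
    if peak_width <= 0 or cycle_time <= 0:
        raise InvalidParameterError("peak_width and cycle_time must be > 0")
    return peak_width / cycle_time


def window_for_mz(method: DIAMethod, mz: float) -> IsolationWindow:
    """Return the unique window whose half-open interval contains ``mz``."""
    if not (method.mz_start <= mz < method.mz_end):
        raise MzRangeError(
            f"m/z {mz} outside precursor range [{method.mz_start}, {method.mz_end})"
        )
    idx = int((mz - method.mz_start) // method.window_width)
    idx = min(idx, method.n_windows - 1)
    window = method.windows[idx]
    # floating-point division can land one window off at exact edges
    if not window.contains(mz):
        for cand in (idx - 1, idx + 1):
            if 0 <= cand < method.n_windows and method.windows[cand].contains(mz):
                return method.windows[cand]
        raise MzRangeError(f"no window contains m/z {mz}")
    return window
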
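"""Screen geometry and drag mechanics of the number-line scrolling task.

The scrollable object is a vertical number line of uniformly spaced squares,
centered horizontally on the screen. All lengths are expressed in screen
heights: y = 0 is the bottom edge of the screen, y = 1 the top edge. While
the mouse button is held on the line, the line moves vertically in synchrony
with the cursor, so a single drag can displace the line by at most the
distance between the click position and the screen border in the drag
direction. Larger displacements require releasing, travelling back with the
cursor, and re-clicking.

Two task instances are provided as presets: ``exp1`` (9 squares, edge 0.2,
numbers 1..9 top to bottom) and ``exp2`` (11 squares, edge 0.14, numbers
10..20 top to bottom).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

__all__ = [
    "TaskConfig",
    "ScrollRequirement",
    "LineState",
    "EXP1",
    "EXP2",
    "get_config",
    "required_displacement",
    "one_go_interval",
    "scroll_path_cost",
]


@dataclass(frozen=True)
class TaskConfig:
    """Full geometry of one experiment.

    Parameters
    ----------
    square_edge : float
        Edge length of each number-line square, in screen heights.
    n_squares : int
        Number of squares on the line.
    top_number, bottom_number : int
        Numbers printed on the topmost and bottommost squares. Numbering is
        contiguous top to bottom.
    center_number : int
        The number whose square sits at the screen center (y = 0.5) when the
        line is in its initial position.
    visible_numbers : tuple of int
        Inclusive (lo, hi) range of numbers fully visible at trial onset.
    target_tolerance : float
        Maximal distance between target-square center and screen center for
        the trial to count as completed ("snap" tolerance).
    start_offsets_vertical : tuple of float
        Signed vertical offsets of possible start squares from screen center.
    start_offset_horizontal : float
        Unsigned horizontal offset of the start square from screen center
        (start squares appear on the left or on the right).
    line_half_width : float
        Half the horizontal extent of the line strip around x = 0.5.
    start_square_edge : float
        Edge length of the start square.
    """

    square_edge: float
    n_squares: int
    top_number: int
    bottom_number: int
    center_number: int
    visible_numbers: tuple
    target_tolerance: float
    start_offsets_vertical: tuple
    start_offset_horizontal: float
    line_half_width: float
    start_square_edge: float = 0.1

    def __post_init__(self):
        if self.bottom_number - self.top_number + 1 != self.n_squares:
            raise ValueError("numbering must be contiguous top to bottom")

    @property
    def numbers(self) -> range:
        """All numbers on the line, top to bottom."""
        return range(self.top_number, self.bottom_number + 1)

    def square_center_y(self, number: int, offset: float = 0.0) -> float:
        """On-screen y of the center of square ``number`` at line ``offset``."""
        if number not in self.numbers:
            raise ValueError(f"number {number} is not on the line "
                             f"({self.top_number}..{self.bottom_number})")
        return 0.5 + (self.center_number - number) * self.square_edge + offset

    @property
    def line_top(self) -> float:
        """y of the top edge of the line at offset 0 (may exceed 1)."""
        return (0.5 + (self.center_number - self.top_number) * self.square_edge
                + self.square_edge / 2.0)

    @property
    def line_bottom(self) -> float:
        """y of the bottom edge of the line at offset 0 (may be negative)."""
        return (0.5 + (self.center_number - self.bottom_number) * self.square_edge
                - self.square_edge / 2.0)

    def strip_x_interval(self) -> tuple:
        """Horizontal extent of the clickable strip."""
        return (0.5 - self.line_half_width, 0.5 + self.line_half_width)

    # -- flat key/value serialization -------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["visible_numbers"] = list(self.visible_numbers)
        d["start_offsets_vertical"] = list(self.start_offsets_vertical)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TaskConfig keys: {sorted(unknown)}")
        d = dict(d)
        d["visible_numbers"] = tuple(d["visible_numbers"])
        d["start_offsets_vertical"] = tuple(d["start_offsets_vertical"])
        return cls(**d)


EXP1 = TaskConfig(
    square_edge=0.2,
    n_squares=9,
    top_number=1,
    bottom_number=9,
    center_number=5,
    visible_numbers=(3, 7),
    target_tolerance=0.02,
    start_offsets_vertical=(-0.4, 0.0, 0.4),
    start_offset_horizontal=0.4,
    line_half_width=0.1,
    start_square_edge=0.1,
)

EXP2 = TaskConfig(
    square_edge=0.14,
    n_squares=11,
    top_number=10,
    bottom_number=20,
    center_number=15,
    visible_numbers=(12, 18),
    target_tolerance=0.014,
    start_offsets_vertical=(0.0,),
    start_offset_horizontal=0.29,
    line_half_width=0.07,
    start_square_edge=0.1,
)

_PRESETS = {"exp1": EXP1, "exp2": EXP2}


def get_config(name: str) -> TaskConfig:
    """Return a named preset configuration (``"exp1"`` or ``"exp2"``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown task preset {name!r}; "
                         f"choose from {sorted(_PRESETS)}") from None


@dataclass(frozen=True)
class LineState:
    """Current vertical shift of the line from its initial position."""

    offset: float = 0.0

    def clickable_interval(self, config: TaskConfig) -> tuple:
        """On-screen y range currently covered by the line, as (lo, hi)."""
        lo = max(0.0, config.line_bottom + self.offset)
        hi = min(1.0, config.line_top + self.offset)
        return (lo, hi)


INITIAL_STATE = LineState(0.0)


@dataclass(frozen=True)
class ScrollRequirement:
    """What a trial asks for: center ``target_number`` on the screen center.

    ``displacement`` is the signed line movement needed from the line's
    initial position; positive means the line must move up (an "upward
    scroll", needed for targets below the center).
    """

    target_number: int
    displacement: float

    @property
    def direction(self) -> str:
        if self.displacement > 0:
            return "up"
        if self.displacement < 0:
            return "down"
        raise ValueError("direction undefined for zero displacement")

    @classmethod
    def for_target(cls, target: int, config: TaskConfig,
                   state: LineState = INITIAL_STATE) -> "ScrollRequirement":
        return cls(target, required_displacement(target, config, state))


def required_displacement(target: int, config: TaskConfig,
                          state: LineState = INITIAL_STATE) -> float:
    """Signed vertical line movement that centers ``target`` on the screen.

    Positive values move the line up. From the initial state this equals
    ``(target - center_number) * square_edge``.
    """
    return 0.5 - config.square_center_y(target, state.offset)


def one_go_interval(d: float, config: TaskConfig,
                    state: LineState = INITIAL_STATE) -> Optional[tuple]:
    """Click positions from which displacement ``d`` completes in one drag.

    A click at y can drag the line down by at most y (cursor reaches the
    bottom border) and up by at most 1 - y. Returns the (lo, hi) interval
    intersected with the line's clickable extent, or ``None`` when empty.
    For d = 0 the whole clickable extent qualifies.
    """
    if abs(d) > 1:
        raise ValueError("|d| > 1 cannot be realized in one go on any screen")
    lo, hi = state.clickable_interval(config)
    if d > 0:
        hi = min(hi, 1.0 - d)
    elif d < 0:
        lo = max(lo, -d)
    if lo > hi + 1e-12:
        return None
    return (lo, hi)


def scroll_path_cost(click_y: float, d: float, config: TaskConfig,
                     state: LineState = INITIAL_STATE,
                     _max_drags: int = 64) -> tuple:
    """Vertical cursor distance to realize displacement ``d`` from ``click_y``.

    Follows the no-unnecessary-movement policy: drag toward the border until
    the border is reached or the displacement is complete; if incomplete,
    release, travel to the re-click position within the line's new clickable
    extent that minimizes the remaining path, and repeat. Drag distances sum
    exactly to |d|.

    Returns
    -------
    (cost, n_drags) : (float, int)
        Total vertical cursor path length and the number of drags.
        ``cost >= |d|`` always, with equality iff ``click_y`` lies in
        ``one_go_interval(d)``.
    """
    lo0, hi0 = state.clickable_interval(config)
    if not (lo0 - 1e-9 <= click_y <= hi0 + 1e-9):
        raise ValueError(f"click_y={click_y} outside clickable interval "
                         f"[{lo0}, {hi0}]")
    if d == 0:
        return (0.0, 0)

    sign = 1.0 if d > 0 else -1.0
    remaining = abs(d)
    y = click_y
    offset = state.offset
    cost = 0.0
    drags = 0
    for _ in range(_max_drags):
        capacity = (1.0 - y) if sign > 0 else y
        step = min(remaining, capacity)
        if step > 1e-12:
            cost += step
            y += sign * step
            offset += sign * step
            remaining -= step
            drags += 1
        if remaining <= 1e-12:
            return (cost, drags)
        lo, hi = LineState(offset).clickable_interval(config)
        if hi - lo <= 1e-12:
            raise ValueError("line no longer clickable; displacement "
                             "unreachable from this state")
        # nearest re-click position with enough capacity for the remainder,
        # falling back to the maximal-capacity end of the line
        if sign < 0:
            target_y = min(max(remaining, lo), hi)
        else:
            target_y = max(min(1.0 - remaining, hi), lo)
        cost += abs(target_y - y)
        y = target_y
    raise RuntimeError("scroll did not converge (degenerate geometry)")
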
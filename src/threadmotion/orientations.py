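"""The nine-head-orientation taxonomy and its axis structure.

Head position is described along two axes that share the front-facing
position: the horizontal axis (rotation) runs left, front-left, front,
front-right, right; the vertical axis (flexion) runs down, front-down,
front, front-up, up.  The four "front-*" positions are intermediate: they
are traversed while the head is actually moving, so windows labelled with
them show steep slopes and a large within-window range.
"""

from __future__ import annotations

from enum import Enum


class Orientation(str, Enum):
    """One of the nine recognised head positions."""

    LEFT = "left"
    FRONT_LEFT = "front_left"
    FRONT = "front"
    FRONT_RIGHT = "front_right"
    RIGHT = "right"
    UP = "up"
    FRONT_UP = "front_up"
    FRONT_DOWN = "front_down"
    DOWN = "down"

    def __str__(self) -> str:  # so f-strings and CSV cells show the bare name
        return self.value


#: Canonical ordering used for confusion-matrix rows/columns and reports.
ORIENTATION_ORDER: tuple[Orientation, ...] = (
    Orientation.LEFT,
    Orientation.FRONT_LEFT,
    Orientation.FRONT,
    Orientation.FRONT_RIGHT,
    Orientation.RIGHT,
    Orientation.FRONT_UP,
    Orientation.UP,
    Orientation.FRONT_DOWN,
    Orientation.DOWN,
)

#: The horizontal (rotation) axis from left to right; front is shared.
HORIZONTAL_AXIS: tuple[Orientation, ...] = (
    Orientation.LEFT,
    Orientation.FRONT_LEFT,
    Orientation.FRONT,
    Orientation.FRONT_RIGHT,
    Orientation.RIGHT,
)

#: The vertical (flexion) axis from down to up; front is shared.
VERTICAL_AXIS: tuple[Orientation, ...] = (
    Orientation.DOWN,
    Orientation.FRONT_DOWN,
    Orientation.FRONT,
    Orientation.FRONT_UP,
    Orientation.UP,
)

#: Positions passed through while the head is moving (steep-slope windows).
INTERMEDIATE: frozenset[Orientation] = frozenset(
    {
        Orientation.FRONT_LEFT,
        Orientation.FRONT_RIGHT,
        Orientation.FRONT_UP,
        Orientation.FRONT_DOWN,
    }
)

#: The four extreme (largest-excursion) positions.
EXTREMES: frozenset[Orientation] = frozenset(
    {Orientation.LEFT, Orientation.RIGHT, Orientation.UP, Orientation.DOWN}
)


def _axis_pairs(axis: tuple[Orientation, ...]) -> set[frozenset[Orientation]]:
    return {frozenset({a, b}) for a, b in zip(axis, axis[1:])}


#: Unordered pairs of orientations that are neighbours along either axis.
ADJACENT_PAIRS: frozenset[frozenset[Orientation]] = frozenset(
    _axis_pairs(HORIZONTAL_AXIS) | _axis_pairs(VERTICAL_AXIS)
)


def are_adjacent(a: Orientation, b: Orientation) -> bool:
    """True if ``a`` and ``b`` are neighbours along the horizontal or vertical axis."""
    return frozenset({a, b}) in ADJACENT_PAIRS


def axis_of(orientation: Orientation) -> str:
    """Return ``"horizontal"``, ``"vertical"``, or ``"both"`` (for front)."""
    if orientation is Orientation.FRONT:
        return "both"
    return "horizontal" if orientation in HORIZONTAL_AXIS else "vertical"


def intermediate_between(a: Orientation, b: Orientation) -> Orientation | None:
    """The intermediate orientation traversed when moving between ``a`` and ``b``.

    Defined only for front <-> extreme moves (e.g. front <-> right passes
    through front-right); returns None otherwise.
    """
    pair = {a, b}
    if Orientation.FRONT not in pair:
        return None
    other = (pair - {Orientation.FRONT}).pop()
    mapping = {
        Orientation.LEFT: Orientation.FRONT_LEFT,
        Orientation.RIGHT: Orientation.FRONT_RIGHT,
        Orientation.UP: Orientation.FRONT_UP,
        Orientation.DOWN: Orientation.FRONT_DOWN,
    }
    return mapping.get(other)
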
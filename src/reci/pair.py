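"""Core container for a bivariate cause-effect observation set."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InsufficientDataError, ReciError

MIN_PAIR_SIZE = 10


class Direction(enum.Enum):
    """Causal direction between the two observed columns.

    ``NONE`` doubles as "unknown ground truth" on inputs and "no decision"
    on outputs.
    """

    X_CAUSES_Y = "x_causes_y"
    Y_CAUSES_X = "y_causes_x"
    NONE = "none"

    def flipped(self) -> "Direction":
        if self is Direction.X_CAUSES_Y:
            return Direction.Y_CAUSES_X
        if self is Direction.Y_CAUSES_X:
            return Direction.X_CAUSES_Y
        return Direction.NONE


@dataclass(frozen=True)
class ObservedPair:
    """Two equal-length numeric samples, optionally with ground truth.

    Parameters
    ----------
    x, y : array_like
        The two observed samples, equal length ``n >= 10``, all finite.
    name : str
        Label used in benchmark reports.
    truth : Direction
        Ground-truth causal direction if known.
    weight : float
        Nonnegative weight used by the weighted-accuracy measure (near
        duplicate datasets in curated benchmarks receive weights < 1).
    """

    x: np.ndarray
    y: np.ndarray
    name: str = ""
    truth: Direction = Direction.NONE
    weight: float = 1.0
    # free-form provenance (generator parameters etc.); not validated
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ReciError("pair samples must be one-dimensional")
        if x.shape != y.shape:
            raise ReciError(
                f"x and y must have identical length, got {x.size} and {y.size}"
            )
        if x.size < MIN_PAIR_SIZE:
            raise InsufficientDataError(
                f"pair needs at least {MIN_PAIR_SIZE} observations, got {x.size}"
            )
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ReciError("pair contains non-finite entries")
        if self.weight < 0:
            raise ReciError("weight must be nonnegative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    def swapped(self) -> "ObservedPair":
        """Exchange the roles of x and y (ground truth flips accordingly)."""
        return ObservedPair(
            x=self.y.copy(),
            y=self.x.copy(),
            name=self.name,
            truth=self.truth.flipped(),
            weight=self.weight,
            meta=dict(self.meta),
        )

    def subset(self, index: np.ndarray) -> "ObservedPair":
        """Return the sub-sample at ``index`` (order as given), keeping metadata.

        Bypasses the minimum-size check deliberately: train/test splits of a
        valid pair may be smaller than 10.
        """
        out = object.__new__(ObservedPair)
        object.__setattr__(out, "x", self.x[index])
        object.__setattr__(out, "y", self.y[index])
        object.__setattr__(out, "name", self.name)
        object.__setattr__(out, "truth", self.truth)
        object.__setattr__(out, "weight", self.weight)
        object.__setattr__(out, "meta", dict(self.meta))
        return out
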
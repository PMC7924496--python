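"""Scaling conventions and kernel-density based outlier removal.

Both variables must live on a common scale before regression errors in the
two directions can be compared; the theory assumes both attain values in
[0, 1], so min-max normalization is the default, with z-scoring as the
alternative for unbounded data. Isolated points in low-density regions of
the joint distribution can dominate the mean squared error, so an optional
preprocessing step estimates the joint density with a Gaussian kernel and
drops points below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    EmptyResultError,
    InsufficientDataError,
    ReciError,
)
from .pair import ObservedPair

SCALING_MODES = ("minmax", "zscore")


@dataclass(frozen=True)
class ScalingSpec:
    """Which common-scale convention to apply to both variables."""

    mode: str = "minmax"

    def __post_init__(self) -> None:
        if self.mode not in SCALING_MODES:
            raise ReciError(f"unknown scaling mode {self.mode!r}; use one of {SCALING_MODES}")


@dataclass(frozen=True)
class DensityFilterSpec:
    """Gaussian-kernel density filter configuration.

    ``threshold`` is compared against the joint density normalized to
    integrate to one; ``bandwidth_rule`` is passed to the kernel density
    estimator (any rule scipy's ``gaussian_kde`` accepts).
    """

    threshold: float = 0.1
    bandwidth_rule: str = "scott"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ReciError("density threshold must be nonnegative")


def normalize_minmax(v: np.ndarray) -> np.ndarray:
    """Affinely map ``v`` onto [0, 1].

    Raises
    ------
    DegenerateInputError
        If ``v`` is constant (the direction would be undecidable).
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need at least 2 values to normalize")
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise DegenerateInputError("cannot min-max normalize a constant vector")
    return (v - lo) / (hi - lo)


def standardize(v: np.ndarray) -> np.ndarray:
    """Center ``v`` and scale to unit variance (population convention, divisor n)."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need at least 2 values to standardize")
    sd = v.std()  # ddof=0
    if sd <= 0:
        raise DegenerateInputError("cannot standardize a zero-variance vector")
    return (v - v.mean()) / sd


def scale_vector(v: np.ndarray, spec: ScalingSpec | str = "minmax") -> np.ndarray:
    if isinstance(spec, str):
        spec = ScalingSpec(spec)
    if spec.mode == "minmax":
        return normalize_minmax(v)
    return standardize(v)


def scale_pair(pair: ObservedPair, spec: ScalingSpec | str = "minmax") -> ObservedPair:
    """Apply the chosen scaling to both coordinates of a pair."""
    return ObservedPair(
        x=scale_vector(pair.x, spec),
        y=scale_vector(pair.y, spec),
        name=pair.name,
        truth=pair.truth,
        weight=pair.weight,
        meta=dict(pair.meta),
    )


def density_scores(pair: ObservedPair, spec: DensityFilterSpec | None = None) -> np.ndarray:
    """Joint-density estimate at each observed point.

    Uses a bivariate Gaussian kernel density estimate (bandwidth by the
    spec's plug-in rule, scaled by the sample covariance) evaluated at the
    sample points themselves. The returned densities integrate to one over
    the plane, which fixes the meaning of the removal threshold.
    """
    if spec is None:
        spec = DensityFilterSpec()
    if pair.n < 5:
        raise InsufficientDataError("need at least 5 points for a density estimate")
    data = np.vstack([pair.x, pair.y])
    try:
        kde = stats.gaussian_kde(data, bw_method=spec.bandwidth_rule)
    except np.linalg.LinAlgError as exc:  # singular sample covariance
        raise DegenerateInputError(f"degenerate joint sample: {exc}") from exc
    return kde(data)


def remove_low_density(
    pair: ObservedPair, spec: DensityFilterSpec | None = None
) -> ObservedPair:
    """Drop points whose estimated joint density falls below the threshold.

    Surviving points keep their original order; name, ground truth and
    weight carry over.

    Raises
    ------
    EmptyResultError
        If every point falls below the threshold.
    """
    if spec is None:
        spec = DensityFilterSpec()
    scores = density_scores(pair, spec)
    keep = scores >= spec.threshold
    if not keep.any():
        raise EmptyResultError(
            f"density threshold {spec.threshold} removed all {pair.n} points"
        )
    return pair.subset(np.flatnonzero(keep))


def preprocess_pair(
    pair: ObservedPair,
    scaling: ScalingSpec | str = "minmax",
    density_filter: DensityFilterSpec | None = None,
) -> ObservedPair:
    """Full preprocessing pipeline: scale, optionally filter, rescale survivors.

    The density filter runs on the scaled pair, and survivors are rescaled so
    the working domain stays [0, 1] (or centered, for z-scoring) after removal.
    """
    scaled = scale_pair(pair, scaling)
    if density_filter is None:
        return scaled
    filtered = remove_low_density(scaled, density_filter)
    if filtered.n < 2:
        raise EmptyResultError("density filter left fewer than 2 points")
    return scale_pair(filtered, scaling)
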
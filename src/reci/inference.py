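"""Regression Error based Causal Inference (RECI).

The decision procedure: put both variables on a common scale, fit the same
least-squares regression family in both directions on a random train/test
split, record the two test MSEs, repeat over many splits and average. The
direction with the smaller averaged error is declared causal; the error
ratio provides a confidence score in [0, 1] that can be used to reject
uncertain decisions.

Functional primitives (``split``, ``directional_errors``, ``confidence``,
``decide`` ...) are exposed directly; :class:`RECI` wraps them in a
model-object interface whose :meth:`RECI.fit` returns a
:class:`RECIResults` carrying the estimates and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import regressors
from .exceptions import (
    ConfigurationError,
    FitFailureError,
    UndefinedConfidenceError,
)
from .pair import Direction, ObservedPair
from .preprocess import DensityFilterSpec, ScalingSpec, preprocess_pair
from .regressors import FamilySpec

#: families expensive enough to warrant per-run subsampling by default
EXPENSIVE_FAMILIES = ("SVR_LIN", "NN")
DEFAULT_SUBSAMPLE_CAP = 500


@dataclass(frozen=True)
class RunProtocol:
    """How the repeated split/fit/score runs are organized.

    ``train_fraction`` of the data is used for fitting, the rest for the
    error estimate; each of ``n_runs`` runs draws one fresh random split.
    ``subsample_cap``, when set, caps the per-run sample size by drawing a
    uniform subsample without replacement first (used for the expensive
    families).
    """

    n_runs: int = 100
    train_fraction: float = 0.7
    subsample_cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.subsample_cap is not None and self.subsample_cap < 4:
            raise ConfigurationError("subsample_cap too small")


@dataclass(frozen=True)
class DirectionalErrors:
    """Per-run test MSEs for both regression directions and their averages."""

    mse_y_given_x_runs: np.ndarray
    mse_x_given_y_runs: np.ndarray

    def __post_init__(self) -> None:
        yx = np.asarray(self.mse_y_given_x_runs, dtype=float)
        xy = np.asarray(self.mse_x_given_y_runs, dtype=float)
        if yx.shape != xy.shape or yx.ndim != 1 or yx.size < 1:
            raise ConfigurationError("run vectors must be equal-length and nonempty")
        object.__setattr__(self, "mse_y_given_x_runs", yx)
        object.__setattr__(self, "mse_x_given_y_runs", xy)

    @property
    def mean_y_given_x(self) -> float:
        return float(self.mse_y_given_x_runs.mean())

    @property
    def mean_x_given_y(self) -> float:
        return float(self.mse_x_given_y_runs.mean())

    @property
    def n_runs(self) -> int:
        return self.mse_y_given_x_runs.size

    def swapped(self) -> "DirectionalErrors":
        return DirectionalErrors(
            mse_y_given_x_runs=self.mse_x_given_y_runs.copy(),
            mse_x_given_y_runs=self.mse_y_given_x_runs.copy(),
        )


@dataclass(frozen=True)
class CausalDecision:
    """Inferred direction with its error-ratio confidence and threshold."""

    direction: Direction
    confidence: float
    threshold: float = 0.0


def split(
    pair: ObservedPair, protocol: RunProtocol, run_index: int
) -> tuple[ObservedPair, ObservedPair]:
    """Disjoint exhaustive train/test partition for one run.

    The partition is a pure function of ``(protocol.seed, run_index)``.
    """
    rng = np.random.default_rng([abs(protocol.seed), run_index, 0x5E17])
    n = pair.n
    perm = rng.permutation(n)
    n_train = int(round(protocol.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)  # both sides nonempty
    return pair.subset(perm[:n_train]), pair.subset(perm[n_train:])


def _run_rng(protocol: RunProtocol, run_index: int) -> np.random.Generator:
    return np.random.default_rng([abs(protocol.seed), run_index, 0x5B5A])


def directional_errors(
    pair: ObservedPair, spec: FamilySpec, protocol: RunProtocol
) -> DirectionalErrors:
    """Run-averaged test MSEs of the family fitted in both directions.

    Per run: (optionally subsample to the cap,) split, fit ``spec`` on the
    training part in both directions, score each fit on the held-out part.
    """
    cap = protocol.subsample_cap
    mse_yx = np.empty(protocol.n_runs)
    mse_xy = np.empty(protocol.n_runs)
    for r in range(protocol.n_runs):
        sub = pair
        if cap is not None and pair.n > cap:
            idx = _run_rng(protocol, r).choice(pair.n, size=cap, replace=False)
            sub = pair.subset(idx)
        train, test = split(sub, protocol, r)
        fwd = regressors.fit(spec, train.x, train.y)
        rev = regressors.fit(spec, train.y, train.x)
        mse_yx[r] = regressors.mse(fwd, test.x, test.y)
        mse_xy[r] = regressors.mse(rev, test.y, test.x)
    return DirectionalErrors(mse_y_given_x_runs=mse_yx, mse_x_given_y_runs=mse_xy)


def select_family(
    pair: ObservedPair,
    candidates: Sequence[FamilySpec],
    protocol: RunProtocol,
) -> tuple[FamilySpec, DirectionalErrors]:
    """Pick the candidate with the smallest summed direction-averaged test MSE.

    The criterion sums both directions' averaged errors so the selection is
    direction-symmetric and cannot itself leak the answer. Ties break by
    candidate order. Candidates whose fits fail in every run are skipped; if
    all fail, a :class:`FitFailureError` aggregates the causes.
    """
    if not candidates:
        raise ConfigurationError("need at least one candidate family")
    best: tuple[FamilySpec, DirectionalErrors] | None = None
    best_score = np.inf
    failures: list[str] = []
    for cand in candidates:
        try:
            errs = directional_errors(pair, cand, protocol)
        except FitFailureError as exc:
            failures.append(f"{cand.label}: {exc}")
            continue
        score = errs.mean_y_given_x + errs.mean_x_given_y
        if score < best_score:  # strict: first wins ties
            best, best_score = (cand, errs), score
    if best is None:
        raise FitFailureError("all candidate families failed: " + "; ".join(failures))
    return best


def confidence(mean_y_given_x: float, mean_x_given_y: float) -> float:
    """Error-ratio confidence: 1 - min(e1, e2) / max(e1, e2), in [0, 1]."""
    if mean_y_given_x < 0 or mean_x_given_y < 0:
        raise ConfigurationError("mean errors must be nonnegative")
    hi = max(mean_y_given_x, mean_x_given_y)
    if hi == 0:
        raise UndefinedConfidenceError("both directional errors are zero")
    return 1.0 - min(mean_y_given_x, mean_x_given_y) / hi


def decide(errors: DirectionalErrors) -> CausalDecision:
    """Declare the direction with the smaller run-averaged test error.

    Exact equality of the two means yields no decision (confidence 0).
    """
    e_yx, e_xy = errors.mean_y_given_x, errors.mean_x_given_y
    if e_yx == e_xy:
        return CausalDecision(direction=Direction.NONE, confidence=0.0, threshold=0.0)
    xi = confidence(e_yx, e_xy)
    direction = Direction.X_CAUSES_Y if e_yx < e_xy else Direction.Y_CAUSES_X
    return CausalDecision(direction=direction, confidence=xi, threshold=0.0)


def decide_with_threshold(errors: DirectionalErrors, t: float) -> CausalDecision:
    """As :func:`decide`, but reject (direction NONE) when confidence < t.

    With ``t = 0`` this is identical to :func:`decide`.
    """
    if not 0.0 <= t <= 1.0:
        raise ConfigurationError("threshold must lie in [0, 1]")
    base = decide(errors)
    if base.direction is Direction.NONE or base.confidence >= t:
        return replace(base, threshold=t)
    return CausalDecision(direction=Direction.NONE, confidence=base.confidence, threshold=t)


def default_candidates(
    families: Sequence[str] = ("LOG", "MON", "POLY"), seed: int = 0
) -> list[FamilySpec]:
    """Expand family names into the full candidate menu (all orders/layouts)."""
    out: list[FamilySpec] = []
    for fam in families:
        fam = fam.upper()
        if fam == "MON":
            out += [FamilySpec("MON", order=n, seed=seed) for n in range(2, 10)]
        elif fam == "POLY":
            out += [FamilySpec("POLY", order=k, seed=seed) for k in range(1, 10)]
        elif fam == "NN":
            out += [FamilySpec("NN", hidden_layout=l, seed=seed) for l in regressors.NN_LAYOUTS]
        else:
            out.append(FamilySpec(fam, seed=seed))
    return out


def _effective_protocol(protocol: RunProtocol, spec: FamilySpec) -> RunProtocol:
    if protocol.subsample_cap is None and spec.family in EXPENSIVE_FAMILIES:
        return replace(protocol, subsample_cap=DEFAULT_SUBSAMPLE_CAP)
    return protocol


class RECI:
    """Causal-direction model for one observed pair.

    Parameters
    ----------
    pair : ObservedPair or array_like
        The observations. Alternatively pass ``RECI(x, y)``.
    candidates : sequence of FamilySpec, optional
        Regression families to consider; default POLY degrees 1-9.
    protocol : RunProtocol, optional
        Split/averaging protocol (default 100 runs at 70% training data).
    scaling : {"minmax", "zscore"}
        Common-scale convention applied before any regression.
    density_filter : DensityFilterSpec, optional
        When given, low-density points are removed before scaling back.

    Examples
    --------
    >>> model = RECI(x, y, candidates=default_candidates(["POLY"]))
    >>> res = model.fit()
    >>> res.direction, res.confidence
    """

    def __init__(
        self,
        pair,
        y=None,
        *,
        candidates: Sequence[FamilySpec] | None = None,
        protocol: RunProtocol | None = None,
        scaling: ScalingSpec | str = "minmax",
        density_filter: DensityFilterSpec | None = None,
    ) -> None:
        if not isinstance(pair, ObservedPair):
            if y is None:
                raise ConfigurationError("pass an ObservedPair or both x and y")
            pair = ObservedPair(x=np.asarray(pair), y=np.asarray(y))
        elif y is not None:
            raise ConfigurationError("y given alongside an ObservedPair")
        self.pair = pair
        self.candidates = list(candidates) if candidates is not None else default_candidates(["POLY"])
        if not self.candidates:
            raise ConfigurationError("candidate list is empty")
        self.protocol = protocol if protocol is not None else RunProtocol()
        self.scaling = scaling
        self.density_filter = density_filter

    @classmethod
    def from_dataframe(cls, df, x_col, y_col, **kwargs) -> "RECI":
        """Build a model from two columns of a DataFrame."""
        pair = ObservedPair(
            x=df[x_col].to_numpy(dtype=float),
            y=df[y_col].to_numpy(dtype=float),
            name=f"{x_col}~{y_col}",
        )
        return cls(pair, **kwargs)

    def fit(self) -> "RECIResults":
        """Preprocess, select the best family, and score both directions."""
        working = preprocess_pair(self.pair, self.scaling, self.density_filter)
        if len(self.candidates) == 1:
            spec = self.candidates[0]
            errors = directional_errors(working, spec, _effective_protocol(self.protocol, spec))
            family, errs = spec, errors
        else:
            scored: list[tuple[FamilySpec, DirectionalErrors, float]] = []
            failures: list[str] = []
            for cand in self.candidates:
                try:
                    e = directional_errors(
                        working, cand, _effective_protocol(self.protocol, cand)
                    )
                except FitFailureError as exc:
                    failures.append(f"{cand.label}: {exc}")
                    continue
                scored.append((cand, e, e.mean_y_given_x + e.mean_x_given_y))
            if not scored:
                raise FitFailureError(
                    "all candidate families failed: " + "; ".join(failures)
                )
            family, errs, _ = min(scored, key=lambda t: t[2])
        return RECIResults(model=self, family=family, errors=errs, working_pair=working)


@dataclass
class RECIResults:
    """Fit results: selected family, directional errors, and the decision."""

    model: RECI
    family: FamilySpec
    errors: DirectionalErrors
    working_pair: ObservedPair = field(repr=False)

    @property
    def decision(self) -> CausalDecision:
        return decide(self.errors)

    @property
    def direction(self) -> Direction:
        return self.decision.direction

    @property
    def confidence(self) -> float:
        return self.decision.confidence

    def decide(self, threshold: float = 0.0) -> CausalDecision:
        """Decision with the error-ratio rejection threshold applied."""
        return decide_with_threshold(self.errors, threshold)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        e = self.errors
        se_yx = e.mse_y_given_x_runs.std(ddof=1) / np.sqrt(e.n_runs) if e.n_runs > 1 else 0.0
        se_xy = e.mse_x_given_y_runs.std(ddof=1) / np.sqrt(e.n_runs) if e.n_runs > 1 else 0.0
        d = self.decision
        name = self.model.pair.name or "<unnamed pair>"
        lines = [
            "RECI causal direction inference",
            "=" * 46,
            f"pair:              {name}  (n={self.model.pair.n})",
            f"scaling:           {getattr(self.model.scaling, 'mode', self.model.scaling)}",
            f"family:            {self.family.label}",
            f"runs:              {e.n_runs} (train fraction "
            f"{self.model.protocol.train_fraction})",
            "-" * 46,
            f"mean MSE y|x:      {e.mean_y_given_x:.6g} (se {se_yx:.2g})",
            f"mean MSE x|y:      {e.mean_x_given_y:.6g} (se {se_xy:.2g})",
            f"direction:         {d.direction.value}",
            f"confidence (xi):   {d.confidence:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)
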
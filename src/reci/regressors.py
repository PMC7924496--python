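"""Regression families used to estimate conditional expectations.

The causal-direction score only needs a least-squares estimate of
E[Y|X] and E[X|Y]; the menu of function classes deliberately spans very
simple, likely-underfitting families (a four-parameter logistic curve,
shifted monomials) through flexible ones (polynomials up to degree 9,
linear-kernel support vector regression, small feedforward networks).
Underfitting is not necessarily harmful here: a simple model that fits
well in the causal direction typically inflates the anticausal error even
more.

All fits minimize the mean squared error on the training sample. The
nonconvex families (LOG, NN) use seeded multi-start / seeded
initialization so a fit is a pure function of (spec, data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .exceptions import ConfigurationError, FitFailureError

FAMILY_NAMES = ("LOG", "MON", "POLY", "SVR_LIN", "NN")
NN_LAYOUTS = ((2,), (5,), (10,), (20,), (2, 4), (4, 8))

#: number of seeded random restarts for nonconvex least-squares fits
N_RESTARTS = 5
#: full-batch training iteration budget for the neural networks
NN_MAX_ITER = 2000
#: fixed linear-SVR hyperparameters (regularization, tube width)
SVR_C = 1.0
SVR_EPSILON = 0.1


@dataclass(frozen=True)
class FamilySpec:
    """A regression family instance.

    ``order`` is the monomial exponent (MON, in [2, 9]) or polynomial degree
    (POLY, in [1, 9]); ``hidden_layout`` is the hidden-layer width tuple for
    NN, one of ``(2,), (5,), (10,), (20,), (2, 4), (4, 8)``.
    """

    family: str
    order: int | None = None
    hidden_layout: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILY_NAMES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; use one of {FAMILY_NAMES}"
            )
        if self.family == "MON":
            if self.order is None or not 2 <= self.order <= 9:
                raise ConfigurationError("MON requires an exponent in [2, 9]")
        elif self.family == "POLY":
            if self.order is None or not 1 <= self.order <= 9:
                raise ConfigurationError("POLY requires a degree in [1, 9]")
        elif self.order is not None:
            raise ConfigurationError(f"{self.family} takes no order")
        if self.family == "NN":
            layout = tuple(self.hidden_layout or ())
            if layout not in NN_LAYOUTS:
                raise ConfigurationError(
                    f"NN hidden layout must be one of {NN_LAYOUTS}, got {layout}"
                )
            object.__setattr__(self, "hidden_layout", layout)
        elif self.hidden_layout is not None:
            raise ConfigurationError(f"{self.family} takes no hidden layout")

    @classmethod
    def parse(cls, text: str, seed: int = 0) -> "FamilySpec":
        """Parse a config string such as ``"POLY:3"``, ``"NN:4-8"`` or ``"LOG"``."""
        head, _, tail = text.strip().partition(":")
        head = head.upper()
        if head == "NN":
            if not tail:
                raise ConfigurationError("NN spec needs a layout, e.g. NN:4-8")
            layout = tuple(int(w) for w in tail.split("-"))
            return cls(family="NN", hidden_layout=layout, seed=seed)
        if head in ("MON", "POLY"):
            if not tail:
                raise ConfigurationError(f"{head} spec needs an order, e.g. {head}:3")
            return cls(family=head, order=int(tail), seed=seed)
        if tail:
            raise ConfigurationError(f"{head} takes no parameter (got {text!r})")
        return cls(family=head, seed=seed)

    @property
    def label(self) -> str:
        if self.family == "NN":
            return "NN:" + "-".join(str(w) for w in self.hidden_layout)
        if self.order is not None:
            return f"{self.family}:{self.order}"
        return self.family


@dataclass(frozen=True)
class FittedModel:
    """A fitted regression-family instance with a prediction contract."""

    spec: FamilySpec
    parameters: np.ndarray
    train_mse: float
    _predict: Callable[[np.ndarray], np.ndarray] = field(compare=False, repr=False)

    def __post_init__(self) -> None:
        params = np.atleast_1d(np.asarray(self.parameters, dtype=float))
        if not np.isfinite(params).all():
            raise FitFailureError(f"{self.spec.label} fit produced non-finite parameters")
        if self.train_mse < 0:
            raise FitFailureError("negative training MSE")
        object.__setattr__(self, "parameters", params)


def _logistic(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    # a + (b - a) / (1 + exp(c (d - x))); clip the exponent to stay finite
    z = np.clip(c * (d - x), -500.0, 500.0)
    return a + (b - a) / (1.0 + np.exp(z))


def _fit_logistic(x: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, Callable]:
    ylo, yhi = float(y.min()), float(y.max())
    span = max(yhi - ylo, 1e-12)
    xmid = float(np.median(x))
    slope_sign = 1.0 if np.corrcoef(x, y)[0, 1] >= 0 else -1.0

    best = None
    for k in range(N_RESTARTS):
        rng = np.random.default_rng([abs(seed) + 1, k])
        if k == 0:
            p0 = np.array([ylo, yhi, 10.0 * slope_sign, xmid])
        else:
            p0 = np.array(
                [
                    ylo + span * rng.normal(0, 0.2),
                    yhi + span * rng.normal(0, 0.2),
                    rng.uniform(-40.0, 40.0),
                    rng.uniform(float(x.min()), float(x.max())),
                ]
            )
        for method in ("lm", "trf"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(
                        _logistic, x, y, p0=p0, maxfev=5000, method=method
                    )
            except (RuntimeError, optimize.OptimizeWarning, ValueError):
                continue
            if not np.isfinite(popt).all():
                continue
            resid = y - _logistic(x, *popt)
            m = float(np.mean(resid**2))
            if np.isfinite(m) and (best is None or m < best[1]):
                best = (popt, m)
            break  # lm converged; no need for the bounded fallback
    if best is None:
        raise FitFailureError("logistic fit failed to converge in all restarts")
    popt = best[0]
    return popt, lambda t: _logistic(np.asarray(t, dtype=float), *popt)


def _fit_monomial(x: np.ndarray, y: np.ndarray, n: int) -> tuple[np.ndarray, Callable]:
    # a x^n + b is linear in (a, b): solve exactly by linear least squares
    design = np.column_stack([x**n, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    return np.array([a, b]), lambda t: a * np.asarray(t, dtype=float) ** n + b


def _fit_polynomial(x: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, Callable]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coef = np.polynomial.polynomial.polyfit(x, y, deg=k)
    return coef, lambda t: np.polynomial.polynomial.polyval(
        np.asarray(t, dtype=float), coef
    )


def _fit_svr(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, Callable]:
    est = SVR(kernel="linear", C=SVR_C, epsilon=SVR_EPSILON)
    est.fit(x.reshape(-1, 1), y)
    params = np.array([float(est.coef_[0, 0]), float(est.intercept_[0])])
    return params, lambda t: est.predict(np.asarray(t, dtype=float).reshape(-1, 1))


def _fit_nn(
    x: np.ndarray, y: np.ndarray, layout: tuple[int, ...], seed: int
) -> tuple[np.ndarray, Callable]:
    est = MLPRegressor(
        hidden_layer_sizes=layout,
        activation="logistic",
        solver="lbfgs",  # full-batch quasi-Newton training
        max_iter=NN_MAX_ITER,
        random_state=abs(seed) % (2**32),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(x.reshape(-1, 1), y)
    params = np.concatenate(
        [w.ravel() for w in est.coefs_] + [b.ravel() for b in est.intercepts_]
    )
    return params, lambda t: est.predict(np.asarray(t, dtype=float).reshape(-1, 1))


def fit(spec: FamilySpec, x: np.ndarray, y: np.ndarray) -> FittedModel:
    """Least-squares fit of the family's functional form to (x, y).

    Deterministic given ``spec.seed``. Raises :class:`FitFailureError` if no
    restart converges (nonconvex families only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    min_n = (spec.order or 0) + 2
    if x.size != y.size or x.size < min_n:
        raise ConfigurationError(
            f"{spec.label} needs equal-length x, y with at least {min_n} points"
        )
    if spec.family == "LOG":
        params, predict = _fit_logistic(x, y, spec.seed)
    elif spec.family == "MON":
        params, predict = _fit_monomial(x, y, spec.order)
    elif spec.family == "POLY":
        params, predict = _fit_polynomial(x, y, spec.order)
    elif spec.family == "SVR_LIN":
        params, predict = _fit_svr(x, y)
    else:  # NN
        params, predict = _fit_nn(x, y, spec.hidden_layout, spec.seed)
    train_mse = float(np.mean((y - predict(x)) ** 2))
    return FittedModel(spec=spec, parameters=params, train_mse=train_mse, _predict=predict)


def model_from_parameters(spec: FamilySpec, parameters) -> FittedModel:
    """Build a model with explicitly supplied parameters (no fitting).

    Supported for the closed-form families (LOG, MON, POLY, SVR_LIN); useful
    for evaluating hand-chosen parameter vectors. ``train_mse`` is set to 0
    as a placeholder.
    """
    params = np.atleast_1d(np.asarray(parameters, dtype=float))
    if spec.family == "LOG":
        a, b, c, d = params
        pred = lambda t: _logistic(np.asarray(t, dtype=float), a, b, c, d)
    elif spec.family == "MON":
        a, b = params
        n = spec.order
        pred = lambda t: a * np.asarray(t, dtype=float) ** n + b
    elif spec.family == "POLY":
        pred = lambda t: np.polynomial.polynomial.polyval(
            np.asarray(t, dtype=float), params
        )
    elif spec.family == "SVR_LIN":
        w, b = params
        pred = lambda t: w * np.asarray(t, dtype=float) + b
    else:
        raise ConfigurationError("explicit parameters are not supported for NN")
    return FittedModel(spec=spec, parameters=params, train_mse=0.0, _predict=pred)


def predict(model: FittedModel, x: np.ndarray) -> np.ndarray:
    """Evaluate the fitted functional form elementwise at ``x``."""
    return np.asarray(model._predict(np.asarray(x, dtype=float)), dtype=float)


def mse(model: FittedModel, x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared prediction residual of ``model`` on (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 1:
        raise ConfigurationError("mse needs equal-length, nonempty x and y")
    return float(np.mean((y - predict(model, x)) ** 2))
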
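"""Synthetic cause-effect pair generators.

Two families of generators are provided:

* :func:`generate_dependent_pair` builds pairs where cause and noise are
  *dependent*: two hidden source variables are mixed (with random weights)
  into both the cause and the noise, after which the effect is produced as
  ``E = phi(C) + alpha * N`` with the cause min-max normalized to [0, 1]
  and the noise standardized to unit variance. The mechanism ``phi`` is
  linear, a random strictly-increasing mixture of Gaussian CDFs
  (invertible), or a simple non-invertible map, depending on the suite.

* :func:`generate_theorem_pair` builds pairs in the small-noise regime the
  error-asymmetry theory analyzes: ``E_alpha = phi(C) + alpha * N`` with a
  strictly monotone twice-differentiable mechanism on [0, 1] fixing
  phi(0)=0, phi(1)=1, a compact-support cause distribution, and a
  compact-support conditional noise law (uniform here) whose
  conditional-variance profile is renormalized so E[Var[N|C]] = 1. The
  returned generator record retains the mechanism, noise profile and cause
  density so the theory module can compare empirical ratios against
  quadrature values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate, stats

from .exceptions import ConfigurationError, DegenerateInputError, ReciError
from .pair import Direction, ObservedPair
from .preprocess import normalize_minmax, standardize

__all__ = [
    "CdfMixtureSpec",
    "cdf_mixture",
    "random_cdf_mixture",
    "rescale_interval",
    "tilde_rescale",
    "Mechanism",
    "MECHANISMS",
    "DependentPairConfig",
    "generate_dependent_pair",
    "TheoremPairConfig",
    "TheoremRecord",
    "generate_theorem_pair",
]


# ---------------------------------------------------------------------------
# monotone functions built from Gaussian CDFs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CdfMixtureSpec:
    """Convex combination of Gaussian CDFs: s(c) = sum_i beta_i Psi(c | mu_i, sigma_i).

    Each component CDF is increasing, so any convex combination is strictly
    increasing with range inside [0, 1]; with small sigmas the mixture can
    take an essentially arbitrary monotone shape.
    """

    betas: tuple[float, ...]
    mus: tuple[float, ...]
    sigmas: tuple[float, ...]

    def __post_init__(self) -> None:
        betas = tuple(float(b) for b in self.betas)
        mus = tuple(float(m) for m in self.mus)
        sigmas = tuple(float(s) for s in self.sigmas)
        k = len(betas)
        if not (k >= 1 and len(mus) == k and len(sigmas) == k):
            raise ConfigurationError("betas, mus, sigmas must have equal positive length")
        if any(b < 0 or b > 1 for b in betas) or abs(sum(betas) - 1.0) > 1e-12:
            raise ConfigurationError("betas must lie in [0, 1] and sum to 1")
        if any(not 0.0 <= m <= 1.0 for m in mus):
            raise ConfigurationError("mus must lie in [0, 1]")
        if any(not 0.0 < s <= 0.1 for s in sigmas):
            raise ConfigurationError("sigmas must lie in (0, 0.1]")
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "mus", mus)
        object.__setattr__(self, "sigmas", sigmas)

    @property
    def n_components(self) -> int:
        return len(self.betas)


def cdf_mixture(spec: CdfMixtureSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Return the strictly increasing mixture-of-Gaussian-CDFs function."""
    betas = np.asarray(spec.betas)
    mus = np.asarray(spec.mus)
    sigmas = np.asarray(spec.sigmas)

    def s(c):
        c = np.asarray(c, dtype=float)
        vals = stats.norm.cdf((c[..., None] - mus) / sigmas)
        return vals @ betas

    return s


def random_cdf_mixture(
    rng: np.random.Generator, n_components: int = 5
) -> CdfMixtureSpec:
    """Draw a random mixture spec: betas uniform then normalized to sum 1,
    means uniform on [0, 1], spreads uniform on (0, 0.1]."""
    raw = rng.uniform(0.0, 1.0, n_components)
    total = raw.sum()
    if total <= 0:  # astronomically unlikely; keep the contract total
        raw = np.full(n_components, 1.0)
        total = raw.sum()
    betas = raw / total
    betas[-1] = 1.0 - betas[:-1].sum()  # exact sum despite rounding
    mus = rng.uniform(0.0, 1.0, n_components)
    sigmas = rng.uniform(0.0, 0.1, n_components)
    sigmas[sigmas <= 1e-4] = 1e-4
    return CdfMixtureSpec(betas=tuple(betas), mus=tuple(mus), sigmas=tuple(sigmas))


def rescale_interval(v: np.ndarray, a: float, b: float) -> np.ndarray:
    """Affinely map ``v`` onto [a, b]."""
    if not a < b:
        raise ConfigurationError("need a < b")
    return a + (b - a) * normalize_minmax(v)


def tilde_rescale(
    e: np.ndarray, alpha: float, n_minus: float, n_plus: float
) -> np.ndarray:
    """Shift/rescale the effect so its support becomes [0, 1].

    Maps ``alpha * n_minus`` to 0 and ``1 + alpha * n_plus`` to 1; at
    ``alpha = 0`` this is the identity.
    """
    if alpha < 0:
        raise ConfigurationError("alpha must be nonnegative")
    if not n_minus < n_plus:
        raise ConfigurationError("need n_minus < n_plus")
    e = np.asarray(e, dtype=float)
    return (e - alpha * n_minus) / (1.0 + alpha * n_plus - alpha * n_minus)


# ---------------------------------------------------------------------------
# dependent-noise suites (shared hidden sources)
# ---------------------------------------------------------------------------

PAIR_KINDS = ("linear", "invertible", "noninvertible")
SOURCE_MENU = ("uniform", "gauss0", "gauss05", "gauss1", "gauss_mixture")
FUNC_MENU = ("identity", "exp", "cdf_mixture")
#: the Gaussian-mixture source: two components at 0.3 / 0.7, sd 0.1, weights 1/2
GM_MUS = (0.3, 0.7)
GM_SIGMA = 0.1


@dataclass(frozen=True)
class DependentPairConfig:
    """Configuration for the shared-source (dependent-noise) generator."""

    kind: str = "invertible"
    alpha: float = 0.1
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PAIR_KINDS:
            raise ConfigurationError(f"kind must be one of {PAIR_KINDS}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.n_samples < 10:
            raise ConfigurationError("n_samples must be at least 10")


def _sample_source(name: str, rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    if name == "uniform":
        return rng.uniform(0.0, 1.0, n)
    if name == "gauss0":
        return rng.normal(0.0, sigma, n)
    if name == "gauss05":
        return rng.normal(0.5, sigma, n)
    if name == "gauss1":
        return rng.normal(1.0, sigma, n)
    if name == "gauss_mixture":
        comp = rng.integers(0, 2, n)
        return rng.normal(np.asarray(GM_MUS)[comp], GM_SIGMA)
    raise ConfigurationError(f"unknown source distribution {name!r}")


def _apply_func(name: str, v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if name == "identity":
        return v
    if name == "exp":
        return np.exp(v)
    if name == "cdf_mixture":
        # the mixture needs inputs in [0, 1], so map the source there first
        s = cdf_mixture(random_cdf_mixture(rng))
        return s(normalize_minmax(v))
    raise ConfigurationError(f"unknown menu function {name!r}")


def generate_dependent_pair(config: DependentPairConfig) -> ObservedPair:
    """Generate one cause-effect pair with shared-source dependent noise.

    Two hidden sources are mixed with uniform random weights into both the
    cause and the noise; the cause is min-max normalized, the noise is
    standardized and scaled by ``alpha``, and the effect is
    ``phi(cause) + noise`` with ``phi`` chosen by the suite kind.
    """
    last_err: Exception | None = None
    for attempt in range(5):
        rng = np.random.default_rng([abs(config.seed), attempt, 0xD3B])
        try:
            return _generate_dependent_once(config, rng)
        except DegenerateInputError as exc:
            last_err = exc
    raise DegenerateInputError(
        f"dependent-pair generation degenerate after 5 attempts: {last_err}"
    )


def _generate_dependent_once(
    config: DependentPairConfig, rng: np.random.Generator
) -> ObservedPair:
    n = config.n_samples
    w1, w2 = rng.uniform(0.0, 1.0, 2)
    sigma = rng.uniform(0.5, 1.5)  # spread of the Gaussian sources, per dataset
    dist1, dist2 = rng.choice(SOURCE_MENU, 2, replace=True)
    funcs = list(rng.choice(FUNC_MENU, 4, replace=True))

    s1 = _sample_source(dist1, rng, n, sigma)
    s2 = _sample_source(dist2, rng, n, sigma)
    s1 = s1 - s1.mean()
    s2 = s2 - s2.mean()

    c_raw = w1 * _apply_func(funcs[0], s1, rng) + (1.0 - w1) * _apply_func(funcs[1], s2, rng)
    n_raw = w2 * _apply_func(funcs[2], s1, rng) + (1.0 - w2) * _apply_func(funcs[3], s2, rng)

    cause = normalize_minmax(c_raw)  # raises DegenerateInputError if constant
    if config.alpha == 0.0:
        noise = np.zeros(n)
    else:
        noise = config.alpha * standardize(n_raw)

    phi_desc: str
    if config.kind == "linear":
        effect_mean = cause
        phi_desc = "identity"
    elif config.kind == "invertible":
        s5 = cdf_mixture(random_cdf_mixture(rng))
        effect_mean = s5(cause)
        phi_desc = "cdf_mixture(5)"
    else:
        choice = int(rng.integers(0, 3))
        if choice == 0:
            effect_mean = rescale_interval(cause, -2.0, 2.0) ** 2
            phi_desc = "rescale(-2,2)^2"
        elif choice == 1:
            effect_mean = rescale_interval(cause, -2.0, 2.0) ** 4
            phi_desc = "rescale(-2,2)^4"
        else:
            effect_mean = np.sin(rescale_interval(cause, -2.0 * math.pi, 2.0 * math.pi))
            phi_desc = "sin(rescale(-2pi,2pi))"

    effect = effect_mean + noise
    meta = {
        "effect_mean": effect_mean,  # phi(C) before noise, for diagnostics
        "kind": config.kind,
        "alpha": config.alpha,
        "seed": config.seed,
        "w1": float(w1),
        "w2": float(w2),
        "sources": (str(dist1), str(dist2)),
        "source_sigma": float(sigma),
        "funcs": tuple(str(f) for f in funcs),
        "phi": phi_desc,
    }
    return ObservedPair(
        x=cause,
        y=effect,
        name=f"{config.kind}-a{config.alpha:g}-s{config.seed}",
        truth=Direction.X_CAUSES_Y,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# theorem-regime generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mechanism:
    """A strictly increasing, twice differentiable map on [0, 1] with
    phi(0) = 0 and phi(1) = 1, together with its derivative."""

    name: str
    phi: Callable[[np.ndarray], np.ndarray]
    phi_prime: Callable[[np.ndarray], np.ndarray]


_E = math.e

MECHANISMS: dict[str, Mechanism] = {
    "linear": Mechanism("linear", lambda c: np.asarray(c, float), lambda c: np.ones_like(np.asarray(c, float))),
    "quadratic-mix": Mechanism(
        "quadratic-mix", lambda c: (c + c**2) / 2.0, lambda c: (1.0 + 2.0 * c) / 2.0
    ),
    "cubic-mix": Mechanism(
        "cubic-mix", lambda c: (c + c**3) / 2.0, lambda c: (1.0 + 3.0 * c**2) / 2.0
    ),
    "exp-norm": Mechanism(
        "exp-norm",
        lambda c: (np.exp(c) - 1.0) / (_E - 1.0),
        lambda c: np.exp(c) / (_E - 1.0),
    ),
    # amplitude 0.1 keeps the slope in [1 - 0.2*pi, 1 + 0.2*pi] (~[0.37, 1.63]),
    # well away from the slope-zero singularity of the anticausal limit
    "sin-mix": Mechanism(
        "sin-mix",
        lambda c: c + 0.1 * np.sin(2.0 * math.pi * c),
        lambda c: 1.0 + 0.2 * math.pi * np.cos(2.0 * math.pi * c),
    ),
}


def _as_mechanism(phi) -> Mechanism:
    if isinstance(phi, Mechanism):
        return phi
    if isinstance(phi, str):
        try:
            return MECHANISMS[phi]
        except KeyError:
            raise ConfigurationError(
                f"unknown mechanism {phi!r}; available: {sorted(MECHANISMS)}"
            ) from None
    raise ConfigurationError("phi must be a Mechanism or a registered name")


@dataclass(frozen=True)
class TheoremPairConfig:
    """Configuration of the small-noise generator E_alpha = phi(C) + alpha N.

    ``cause_dist`` is a frozen scipy distribution supported on [0, 1]
    (default uniform). ``cond_sd_profile`` gives the conditional noise
    standard deviation as a function of the cause *before* the internal
    renormalization that enforces E[Var[N|C]] = 1.
    """

    phi: Mechanism | str = "quadratic-mix"
    cause_dist: object = None  # frozen scipy rv; None -> Uniform(0, 1)
    cond_sd_profile: Callable[[np.ndarray], np.ndarray] | None = None  # None -> constant
    alpha: float = 0.05
    n_samples: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError("alpha must be nonnegative")
        if self.n_samples < 10:
            raise ConfigurationError("n_samples must be at least 10")


@dataclass(frozen=True)
class TheoremRecord:
    """What the theorem-regime generator actually used, for the theory module."""

    mechanism: Mechanism
    cond_sd: Callable[[np.ndarray], np.ndarray]  # renormalized profile
    cause_pdf: Callable[[np.ndarray], np.ndarray]
    alpha: float
    n_minus: float
    n_plus: float

    def cond_var(self, c: np.ndarray) -> np.ndarray:
        s = self.cond_sd(np.asarray(c, dtype=float))
        return np.asarray(s, dtype=float) ** 2


_NORM_GRID = 20001


def _renormalize_profile(
    profile: Callable[[np.ndarray], np.ndarray],
    cause_pdf: Callable[[np.ndarray], np.ndarray],
) -> tuple[Callable[[np.ndarray], np.ndarray], float, float]:
    """Scale the sd profile so E[Var[N|C]] = 1; return it with noise bounds."""
    grid = np.linspace(0.0, 1.0, _NORM_GRID)
    s = np.asarray(profile(grid), dtype=float)
    if np.any(s < 0) or not np.isfinite(s).all():
        raise ConfigurationError("conditional sd profile must be finite and nonnegative")
    expected_var = float(integrate.simpson(s**2 * cause_pdf(grid), x=grid))
    if expected_var <= 0:
        raise ConfigurationError("conditional sd profile has zero expected variance")
    scale = 1.0 / math.sqrt(expected_var)

    def s_norm(c):
        return scale * np.asarray(profile(np.asarray(c, dtype=float)), dtype=float)

    half_width = math.sqrt(3.0) * scale * float(s.max())
    return s_norm, -half_width, half_width


def generate_theorem_pair(config: TheoremPairConfig) -> tuple[ObservedPair, TheoremRecord]:
    """Sample a pair from E_alpha = phi(C) + alpha N in the small-noise regime.

    The conditional noise law given C = c is uniform on
    [-sqrt(3) s(c), sqrt(3) s(c)] (centered, compact support, variance
    s(c)^2) with the profile s renormalized so E[Var[N|C]] = 1. Returns
    the pair together with a :class:`TheoremRecord` describing exactly what
    was generated.
    """
    mech = _as_mechanism(config.phi)
    dist = config.cause_dist if config.cause_dist is not None else stats.uniform(0.0, 1.0)
    pdf = dist.pdf
    profile = config.cond_sd_profile or (lambda c: np.ones_like(np.asarray(c, dtype=float)))
    s_norm, n_minus, n_plus = _renormalize_profile(profile, pdf)

    rng = np.random.default_rng([abs(config.seed), 0x7E0])
    c = np.asarray(dist.rvs(size=config.n_samples, random_state=rng), dtype=float)
    if c.min() < -1e-9 or c.max() > 1.0 + 1e-9:
        raise ConfigurationError("cause_dist must be supported on [0, 1]")
    half = math.sqrt(3.0) * s_norm(c)
    noise = rng.uniform(-half, half)
    effect = np.asarray(mech.phi(c), dtype=float) + config.alpha * noise

    # sanity on the mechanism contract
    ends = np.asarray(mech.phi(np.array([0.0, 1.0])), dtype=float)
    if abs(ends[0]) > 1e-9 or abs(ends[1] - 1.0) > 1e-9:
        raise ConfigurationError("mechanism must satisfy phi(0)=0, phi(1)=1")

    record = TheoremRecord(
        mechanism=mech,
        cond_sd=s_norm,
        cause_pdf=pdf,
        alpha=config.alpha,
        n_minus=n_minus,
        n_plus=n_plus,
    )
    pair = ObservedPair(
        x=c,
        y=effect,
        name=f"theorem-{mech.name}-a{config.alpha:g}-s{config.seed}",
        truth=Direction.X_CAUSES_Y,
        meta={"alpha": config.alpha, "mechanism": mech.name, "seed": config.seed},
    )
    return pair, record
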
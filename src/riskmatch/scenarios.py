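"""Scenario configuration for the illness-death cohort simulator.

A scenario is defined by three transition intensities (initial state ->
exposure, initial state -> final event, exposure -> final event), a set of
covariate log-effects per transition, a censoring scheme and the cohort
layout (250 subjects in each of the 2^3 = 8 binary covariate profiles by
default, administrative horizon at t = 1000).

Each transition intensity is specified *at the average covariate value*
``Zbar = (0.5, 0.5, 0.5)``: the hazard for a subject with profile ``z`` is

    lambda_uv(t, z) = lambda_uv(t, Zbar) * exp(beta_uv' (z - Zbar)),

so the tabulated parameters describe the population-average intensity under
the balanced profile allocation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TransitionSpec",
    "CensoringScheme",
    "ScenarioConfig",
    "PROFILES",
    "ZBAR",
    "TMAX_DEFAULT",
    "hr_configuration",
    "described_scenario",
]

#: the 8 binary covariate profiles, in lexicographic order
PROFILES: tuple[tuple[int, int, int], ...] = tuple(itertools.product((0, 1), repeat=3))

#: average covariate value under equal allocation over the 8 profiles
ZBAR = (0.5, 0.5, 0.5)

#: administrative follow-up horizon (time units)
TMAX_DEFAULT = 1000.0

_FAMILIES = ("exponential", "weibull", "loglogistic")


@dataclass(frozen=True)
class TransitionSpec:
    """One transition intensity and its covariate log-effects.

    Parameters
    ----------
    family : {"exponential", "weibull", "loglogistic"}
        Parametric family of the average-covariate intensity.
    params : tuple of float
        ``(lam,)`` for exponential (constant hazard ``lam``);
        ``(lam0, gamma)`` for Weibull with hazard
        ``gamma * lam0 * (lam0 * t)**(gamma - 1)`` (rate parametrization);
        ``(mu, sigma)`` for log-logistic with survival
        ``1 / (1 + exp((log t - mu) / sigma))``.
    beta : tuple of float
        Three covariate log-effects (per unit of ``z_k``), acting
        proportionally on the hazard.
    """

    family: str
    params: tuple[float, ...]
    beta: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        n_expected = 1 if self.family == "exponential" else 2
        if len(self.params) != n_expected:
            raise ValueError(f"{self.family} expects {n_expected} parameter(s), got {len(self.params)}")
        if self.family == "loglogistic":
            if self.params[1] <= 0:
                raise ValueError("log-logistic sigma must be > 0")
        elif any(p <= 0 for p in self.params):
            raise ValueError(f"{self.family} parameters must be > 0, got {self.params}")
        if len(self.beta) != 3:
            raise ValueError("beta must have 3 components")

    # -- average-covariate (Zbar) functions ---------------------------------

    def base_hazard(self, t):
        """Hazard at the average covariate value, vectorized over ``t``."""
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            (lam,) = self.params
            return np.full_like(t, lam)
        if self.family == "weibull":
            lam0, gamma = self.params
            with np.errstate(divide="ignore"):
                return gamma * lam0 * np.power(lam0 * t, gamma - 1.0)
        mu, sigma = self.params
        alpha = math.exp(mu)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            u = np.power(t / alpha, 1.0 / sigma)
            h = u / (sigma * t * (1.0 + u))
        # limit at t = 0: 0 when sigma < 1, 1/(sigma*alpha) at sigma = 1, inf otherwise
        if np.any(t == 0):
            lim = 0.0 if sigma < 1 else (1.0 / (sigma * alpha) if sigma == 1 else math.inf)
            h = np.where(t == 0, lim, h)
        return h

    def base_cum_hazard(self, t):
        """Cumulative hazard at the average covariate value."""
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            (lam,) = self.params
            return lam * t
        if self.family == "weibull":
            lam0, gamma = self.params
            return np.power(lam0 * t, gamma)
        mu, sigma = self.params
        alpha = math.exp(mu)
        return np.log1p(np.power(t / alpha, 1.0 / sigma))

    def base_inv_cum_hazard(self, h):
        """Inverse of :meth:`base_cum_hazard` (used for inverse-CDF sampling)."""
        h = np.asarray(h, dtype=float)
        if self.family == "exponential":
            (lam,) = self.params
            return h / lam
        if self.family == "weibull":
            lam0, gamma = self.params
            return np.power(h, 1.0 / gamma) / lam0
        mu, sigma = self.params
        alpha = math.exp(mu)
        return alpha * np.power(np.expm1(h), sigma)

    # -- profile-specific functions -----------------------------------------

    def log_relative_hazard(self, profile) -> float:
        """``beta' (z - Zbar)`` for one profile."""
        z = np.asarray(profile, dtype=float)
        return float(np.dot(self.beta, z - np.asarray(ZBAR)))

    def hazard(self, t, profile):
        """Hazard for a subject with covariate profile ``profile``."""
        return self.base_hazard(t) * math.exp(self.log_relative_hazard(profile))

    def cum_hazard(self, t, profile):
        return self.base_cum_hazard(t) * math.exp(self.log_relative_hazard(profile))

    def survival(self, t, profile=ZBAR):
        return np.exp(-self.cum_hazard(t, profile))

    def density(self, t, profile=ZBAR):
        return self.hazard(t, profile) * self.survival(t, profile)

    def sample(self, rng: np.random.Generator, profile, size: int):
        """Inverse-CDF draw of event times for one covariate profile."""
        u = rng.uniform(size=size)
        c = math.exp(self.log_relative_hazard(profile))
        return self.base_inv_cum_hazard(-np.log(u) / c)


@dataclass(frozen=True)
class CensoringScheme:
    """Independent censoring-time distribution.

    ``kind="none"`` means no random censoring (C = +inf before the
    administrative horizon); ``kind="uniform"`` draws C ~ U(0, cmax).
    """

    kind: str = "none"
    cmax: float = math.inf

    def __post_init__(self) -> None:
        if self.kind not in ("none", "uniform"):
            raise ValueError(f"unknown censoring kind {self.kind!r}")
        if self.kind == "uniform" and not (0 < self.cmax < math.inf):
            raise ValueError("uniform censoring needs a finite positive cmax")

    def sample(self, rng: np.random.Generator, size: int):
        if self.kind == "none":
            return np.full(size, math.inf)
        return rng.uniform(0.0, self.cmax, size=size)

    def survival(self, t):
        """Gbar(t) = P(C > t)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "none":
            return np.ones_like(t)
        return np.clip(1.0 - t / self.cmax, 0.0, 1.0)

    def density(self, t):
        """g(t), the censoring-time density."""
        t = np.asarray(t, dtype=float)
        if self.kind == "none":
            return np.zeros_like(t)
        return np.where((t >= 0) & (t <= self.cmax), 1.0 / self.cmax, 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """A complete simulation scenario (intensities, effects, censoring, layout)."""

    spec12: TransitionSpec
    spec13: TransitionSpec
    spec23: TransitionSpec
    censoring: CensoringScheme = field(default_factory=CensoringScheme)
    n_per_profile: int = 250
    tmax: float = TMAX_DEFAULT
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_per_profile < 1:
            raise ValueError("n_per_profile must be >= 1")
        if self.tmax <= 0:
            raise ValueError("tmax must be > 0")

    @property
    def n_subjects(self) -> int:
        return 8 * self.n_per_profile

    def with_betas(self, beta12, beta13, beta23) -> "ScenarioConfig":
        return replace(
            self,
            spec12=replace(self.spec12, beta=tuple(beta12)),
            spec13=replace(self.spec13, beta=tuple(beta13)),
            spec23=replace(self.spec23, beta=tuple(beta23)),
        )


# ---------------------------------------------------------------------------
# Tabulated HR(t) configurations (average-covariate intensities)
# ---------------------------------------------------------------------------

_CONFIGURATIONS = {
    "constant": dict(
        spec12=("exponential", (0.0050,)),
        spec13=("weibull", (0.0039, 1.1881)),
        spec23=("weibull", (0.0039, 1.1881)),
    ),
    "increasing": dict(
        spec12=("exponential", (0.0075,)),
        spec13=("weibull", (0.0022, 1.1881)),
        spec23=("weibull", (0.0028, 1.5439)),
    ),
    "decreasing": dict(
        spec12=("exponential", (0.0025,)),
        spec13=("loglogistic", (5.7146, 0.2390)),
        spec23=("loglogistic", (5.6778, 0.2463)),
    ),
    "increasing-decreasing": dict(
        spec12=("exponential", (0.0020,)),
        spec13=("weibull", (0.0018, 1.1881)),
        spec23=("loglogistic", (5.9858, 0.4971)),
    ),
}


def hr_configuration(
    name: str,
    beta12=(0.0, 0.0, 0.0),
    beta13=(0.0, 0.0, 0.0),
    beta23=(0.0, 0.0, 0.0),
    censoring: CensoringScheme | None = None,
    n_per_profile: int = 250,
    tmax: float = TMAX_DEFAULT,
) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from one of the named HR(t) shapes.

    ``name`` is one of ``constant``, ``increasing``, ``decreasing`` or
    ``increasing-decreasing``.
    """
    try:
        raw = _CONFIGURATIONS[name]
    except KeyError:
        raise ValueError(f"unknown configuration {name!r}; choose from {sorted(_CONFIGURATIONS)}") from None
    betas = {"spec12": tuple(beta12), "spec13": tuple(beta13), "spec23": tuple(beta23)}
    specs = {k: TransitionSpec(fam, params, betas[k]) for k, (fam, params) in raw.items()}
    return ScenarioConfig(
        censoring=censoring or CensoringScheme(),
        n_per_profile=n_per_profile,
        tmax=tmax,
        label=name,
        **specs,
    )


def described_scenario(n_per_profile: int = 250, censoring: CensoringScheme | None = None) -> ScenarioConfig:
    """The reference scenario of the simulation study.

    Increasing-then-decreasing HR(t), no censoring,
    ``beta12 = (-0.2, -0.4, -0.8)``, ``beta13 = -beta12`` and
    ``beta23 = -beta13`` (a "healthy exposed" selection with a forced
    exposure-by-covariate interaction).
    """
    b12 = (-0.2, -0.4, -0.8)
    b13 = tuple(-b for b in b12)
    b23 = tuple(-b for b in b13)
    return hr_configuration(
        "increasing-decreasing",
        beta12=b12,
        beta13=b13,
        beta23=b23,
        censoring=censoring,
        n_per_profile=n_per_profile,
    )
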
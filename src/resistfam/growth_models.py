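"""Untreated tumor-growth ODEs and the analytic exponential fit.

Five single-equation growth laws: exponential, logistic, Allee, surface
(proliferating rim), and von Bertalanffy. All are integrated with an adaptive
explicit Runge-Kutta scheme; the exponential model is additionally fit in
closed form by log-linear least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

from .cohort import TumorTimecourse
from .exceptions import DomainError, IntegrationError

GROWTH_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("r", "V0"),
    "logistic": ("r", "K", "V0"),
    "allee": ("r", "K", "m", "V0"),
    "surface": ("a", "b", "V0"),
    "von_bertalanffy": ("a", "b", "V0"),
}

GROWTH_MODEL_NAMES = tuple(GROWTH_PARAM_NAMES)


@dataclass(frozen=True)
class GrowthSpec:
    """Identifies one growth law and its free-parameter list."""

    name: str

    def __post_init__(self):
        if self.name not in GROWTH_PARAM_NAMES:
            raise DomainError(
                f"unknown growth model {self.name!r}; "
                f"choose from {GROWTH_MODEL_NAMES}"
            )

    @property
    def free_params(self) -> tuple[str, ...]:
        return GROWTH_PARAM_NAMES[self.name]

    @property
    def k(self) -> int:
        return len(self.free_params)


def _require(params: Mapping[str, float], spec: GrowthSpec, *names: str) -> list[float]:
    out = []
    for name in names:
        if name not in params:
            raise DomainError(f"model {spec.name!r}: missing parameter {name!r}")
        out.append(float(params[name]))
    return out


def growth_rhs(spec: GrowthSpec, V: float, params: Mapping[str, float]) -> float:
    """dV/dt for the given growth law at volume ``V`` (mm^3/day)."""
    if V < 0:
        raise DomainError(f"negative volume V={V}")
    if spec.name == "exponential":
        (r,) = _require(params, spec, "r")
        return r * V
    if spec.name == "logistic":
        r, K = _require(params, spec, "r", "K")
        return r * V * (1 - V / K)
    if spec.name == "allee":
        r, K, m = _require(params, spec, "r", "K", "m")
        return r * V * (1 - V / K) * (V / m - 1)
    if spec.name == "surface":
        a, b = _require(params, spec, "a", "b")
        if b < 0:
            raise DomainError("surface model requires b >= 0")
        return a * V * (V + b) ** (-1.0 / 3.0)
    # von Bertalanffy
    a, b = _require(params, spec, "a", "b")
    return a * V ** (2.0 / 3.0) - b * V


def solve_growth(
    spec: GrowthSpec,
    params: Mapping[str, float],
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the growth IVP from V0 at ``times[0]`` to each time point."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise DomainError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise DomainError("times must be strictly increasing")
    (V0,) = _require(params, spec, "V0")
    if len(times) == 1:
        return np.array([V0])
    sol = solve_ivp(
        lambda t, y: [growth_rhs(spec, max(y[0], 0.0), params)],
        (times[0], times[-1]),
        [V0],
        t_eval=times,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else float(times[0])
        raise IntegrationError(
            f"growth model {spec.name!r} integration failed at t={last}: "
            f"{sol.message}",
            last_time=last,
        )
    return sol.y[0]


class ExponentialFit(NamedTuple):
    r: float
    V0: float
    sse: float


def fit_exponential_analytic(tc: TumorTimecourse) -> ExponentialFit:
    """Closed-form exponential fit: OLS of ln(volume) on time.

    Returns the growth rate (slope), V0 (exp of the intercept), and the sum
    of squared errors evaluated on the original volume scale so information
    criteria are comparable across models.
    """
    times, volumes = tc.observed()
    if len(times) < 2:
        raise DomainError(
            f"mouse {tc.mouse_id}: need >= 2 non-censored points for the fit"
        )
    slope, intercept = np.polyfit(times, np.log(volumes), 1)
    pred = np.exp(intercept + slope * times)
    sse = float(((volumes - pred) ** 2).sum())
    return ExponentialFit(r=float(slope), V0=float(math.exp(intercept)), sse=sse)


def doubling_time(r: float) -> float:
    """Volume doubling time ln(2)/r for an exponential growth rate r."""
    if r <= 0:
        raise DomainError(f"doubling time undefined for r={r}")
    return math.log(2) / r
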
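"""Sensitive/resistant/drug compartment models under impulsive weekly dosing.

The family has six members indexed ``family.pre`` (1.1 ... 3.2):

* family 1 — no acquired resistance (transition flux f = 0)
* family 2 — randomly acquired resistance (f = g*S)
* family 3 — drug-induced acquired resistance (f = g*S*D)
* ``x.1`` — no pre-existing resistance (R(0) = 0); ``x.2`` — R(0) > 0 fitted

Dynamics between doses::

    dS/dt = r_S*S - f(S, D) - lam_S*D*S
    dR/dt = r_R*R + f(S, D) - lam_R*D*R
    dD/dt = -gamma*D

Doses are hard impulses: at each administration D jumps by the dose and the
integration restarts. Between doses D is a pure exponential decay, so S has a
closed form and R reduces to a one-dimensional quadrature with a smooth
integrand; :func:`predict_volumes` exploits this to evaluate whole batches of
candidate parameter sets at once. An adaptive Runge-Kutta route
(``method="rk"``) is kept as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import DomainError, IntegrationError

CETUXIMAB_HALF_LIFE_DAYS = 4.75

#: Canonical ordering of every parameter the family can use.
PARAM_ORDER = ("r_S", "r_R", "lam_S", "lam_R", "g", "S0", "R0")

MODEL_IDS = ("1.1", "1.2", "2.1", "2.2", "3.1", "3.2")

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)


class Transition(str, Enum):
    none = "none"
    random = "random"
    drug_induced = "drug_induced"


_TRANSITION_BY_FAMILY = {1: Transition.none, 2: Transition.random, 3: Transition.drug_induced}


def default_gamma() -> float:
    """Drug elimination rate ln(2)/half-life, ~0.1459 /day for cetuximab."""
    return math.log(2) / CETUXIMAB_HALF_LIFE_DAYS


@dataclass(frozen=True)
class ResistanceSpec:
    """Identifies one member of the treatment model family."""

    model_id: str

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise DomainError(
                f"unknown model {self.model_id!r}; choose from {MODEL_IDS}"
            )

    @property
    def family(self) -> int:
        return int(self.model_id.split(".")[0])

    @property
    def pre_existing(self) -> bool:
        return self.model_id.endswith(".2")

    @property
    def transition(self) -> Transition:
        return _TRANSITION_BY_FAMILY[self.family]

    @property
    def has_resistant_dynamics(self) -> bool:
        """Whether the R compartment can ever be non-zero."""
        return self.pre_existing or self.transition is not Transition.none

    @property
    def free_params(self) -> tuple[str, ...]:
        names = ["r_S"]
        if self.has_resistant_dynamics:
            names += ["r_R"]
        names += ["lam_S"]
        if self.has_resistant_dynamics:
            names += ["lam_R"]
        if self.transition is not Transition.none:
            names += ["g"]
        names += ["S0"]
        if self.pre_existing:
            names += ["R0"]
        return tuple(names)

    @property
    def k(self) -> int:
        return len(self.free_params)


@dataclass(frozen=True)
class DoseSchedule:
    """Impulsive bolus schedule: ``n_doses`` doses of ``dose`` mg/kg every
    ``interval`` days starting at ``start``."""

    dose: float
    interval: float = 7.0
    n_doses: int = 1
    start: float = 0.0

    def __post_init__(self):
        if self.dose < 0:
            raise DomainError(f"dose must be >= 0, got {self.dose}")
        if self.interval <= 0:
            raise DomainError(f"interval must be positive, got {self.interval}")

    def dose_times(self) -> np.ndarray:
        return self.start + self.interval * np.arange(self.n_doses)

    @classmethod
    def weekly(cls, dose: float = 5.0, until: float = 56.0) -> "DoseSchedule":
        """Weekly dosing from day 0 covering [0, until]."""
        return cls(dose=dose, interval=7.0, n_doses=int(math.floor(until / 7.0)) + 1)


def _get(params: Mapping[str, float], name: str, spec: ResistanceSpec) -> float:
    if name not in params:
        raise DomainError(f"model {spec.model_id}: missing parameter {name!r}")
    return float(params[name])


def treatment_rhs(
    spec: ResistanceSpec,
    state: tuple[float, float, float],
    params: Mapping[str, float],
    gamma: float | None = None,
) -> tuple[float, float, float]:
    """(dS/dt, dR/dt, dD/dt) at the given state. For model 1.1 the R
    equation is identically zero."""
    S, R, D = state
    if min(S, R, D) < 0:
        raise DomainError(f"negative state (S, R, D) = ({S}, {R}, {D})")
    gamma = default_gamma() if gamma is None else gamma
    r_S = _get(params, "r_S", spec)
    lam_S = _get(params, "lam_S", spec)
    if spec.transition is Transition.none:
        f = 0.0
    elif spec.transition is Transition.random:
        f = _get(params, "g", spec) * S
    else:
        f = _get(params, "g", spec) * S * D
    dS = r_S * S - f - lam_S * D * S
    if spec.has_resistant_dynamics:
        r_R = _get(params, "r_R", spec)
        lam_R = _get(params, "lam_R", spec)
        dR = r_R * R + f - lam_R * D * R
    else:
        dR = 0.0
    return dS, dR, -gamma * D


def is_viable(spec: ResistanceSpec, params: Mapping[str, float]) -> bool:
    """Biological viability: all parameters non-negative, r_S >= r_R, and
    lam_S > lam_R wherever both members are present; R0 forced to 0 for
    ``x.1`` models. Constraints on absent parameters hold vacuously."""
    for name in spec.free_params:
        if _get(params, name, spec) < 0:
            return False
    if not spec.pre_existing and float(params.get("R0", 0.0)) != 0.0:
        return False
    if "r_R" in spec.free_params and params["r_S"] < params["r_R"]:
        return False
    if "lam_R" in spec.free_params and not params["lam_S"] > params["lam_R"]:
        return False
    return True


def initial_resistance_fraction(params: Mapping[str, float]) -> float:
    """R(0) / (S(0) + R(0))."""
    S0 = float(params.get("S0", 0.0))
    R0 = float(params.get("R0", 0.0))
    if S0 + R0 <= 0:
        raise DomainError("S0 + R0 must be positive")
    return R0 / (S0 + R0)


def params_to_array(spec: ResistanceSpec, params: Mapping[str, float]) -> np.ndarray:
    return np.array([_get(params, n, spec) for n in spec.free_params], dtype=float)


def array_to_params(spec: ResistanceSpec, vec: np.ndarray) -> dict[str, float]:
    return {n: float(v) for n, v in zip(spec.free_params, vec)}


def drug_concentration(
    schedule: DoseSchedule,
    times: np.ndarray,
    gamma: float | None = None,
    pre_dose: bool = False,
) -> np.ndarray:
    """Closed-form D(t) under impulsive dosing and exponential decay.

    At dose instants the post-jump value is reported unless ``pre_dose``.
    """
    gamma = default_gamma() if gamma is None else gamma
    times = np.asarray(times, dtype=float)
    D = np.zeros_like(times)
    for td in schedule.dose_times():
        active = times > td if pre_dose else times >= td
        D[active] += schedule.dose * np.exp(-gamma * (times[active] - td))
    return D


def _segment_starts(schedule: DoseSchedule, t_end: float) -> np.ndarray:
    dts = schedule.dose_times()
    starts = np.unique(np.concatenate(([0.0], dts[(dts > 0) & (dts <= t_end)])))
    return starts


def _int_decay(D0, gamma: float, tau):
    """integral of D over [0, tau] with D(u) = D0*exp(-gamma*u)."""
    if gamma == 0.0:
        return D0 * tau
    return D0 * (1.0 - np.exp(-gamma * tau)) / gamma


def simulate_batch(
    spec: ResistanceSpec,
    P: np.ndarray,
    times: np.ndarray,
    schedule: DoseSchedule,
    gamma: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-analytic (S, R, D) for a batch of parameter sets.

    ``P`` has shape (n_sets, k) in ``spec.free_params`` order; returns S and R
    of shape (n_sets, n_times) plus D of shape (n_times,). Values at dose
    instants are post-jump. Exact for S and D; R uses 16-node Gauss-Legendre
    quadrature per inter-dose segment (integrand is smooth, so the error is
    far below solver tolerances).
    """
    gamma = default_gamma() if gamma is None else gamma
    P = np.atleast_2d(np.asarray(P, dtype=float))
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise DomainError("times must be strictly increasing")
    if len(times) == 0 or times[0] < 0:
        raise DomainError("times must be non-empty and non-negative")
    names = spec.free_params
    col = {n: P[:, i] for i, n in enumerate(names)}
    n_sets = P.shape[0]
    zeros = np.zeros(n_sets)
    r_S = col["r_S"]
    lam_S = col["lam_S"]
    r_R = col.get("r_R", zeros)
    lam_R = col.get("lam_R", zeros)
    g = col.get("g", zeros)
    S = col["S0"].copy()
    R = col.get("R0", zeros).copy()

    t_end = float(times[-1])
    starts = _segment_starts(schedule, t_end)
    dose_set = set(np.round(schedule.dose_times(), 12))
    seg_idx = np.searchsorted(starts, times, side="right") - 1

    S_out = np.empty((n_sets, len(times)))
    R_out = np.empty((n_sets, len(times)))
    D_out = np.empty(len(times))

    trans = spec.transition
    D = 0.0
    for i, a in enumerate(starts):
        if round(float(a), 12) in dose_set:
            D = D + schedule.dose
        b = starts[i + 1] if i + 1 < len(starts) else t_end
        obs = np.flatnonzero(seg_idx == i)
        taus = times[obs] - a  # >= 0, may include 0 (post-jump)
        # evaluation points: observations plus the segment end for propagation
        ev = np.concatenate((taus, [b - a]))
        E = _int_decay(D, gamma, ev)  # (m,)
        if trans is Transition.none:
            cs1, cs2 = r_S, lam_S
        elif trans is Transition.random:
            cs1, cs2 = r_S - g, lam_S
        else:
            cs1, cs2 = r_S, g + lam_S
        S_ev = S[:, None] * np.exp(cs1[:, None] * ev[None, :] - cs2[:, None] * E[None, :])
        Phi = np.exp(r_R[:, None] * ev[None, :] - lam_R[:, None] * E[None, :])
        if trans is Transition.none:
            R_ev = R[:, None] * Phi
        else:
            # R(tau) = Phi(tau) * (R_a + g*S_a * I(tau)),
            # I(tau) = int_0^tau h(u) du by Gauss-Legendre
            u = 0.5 * ev[:, None] * (_GL_NODES[None, :] + 1.0)  # (m, q)
            Eu = _int_decay(D, gamma, u)
            if trans is Transition.random:
                ch1 = (r_S - g - r_R)[:, None, None]
                ch2 = (lam_S - lam_R)[:, None, None]
                h = np.exp(ch1 * u[None, :, :] - ch2 * Eu[None, :, :])
            else:
                ch1 = (r_S - r_R)[:, None, None]
                ch2 = (g + lam_S - lam_R)[:, None, None]
                h = D * np.exp(-gamma * u[None, :, :]) * np.exp(
                    ch1 * u[None, :, :] - ch2 * Eu[None, :, :]
                )
            I = 0.5 * ev[None, :] * (h * _GL_WEIGHTS[None, None, :]).sum(axis=2)
            R_ev = Phi * (R[:, None] + g[:, None] * S[:, None] * I)
        S_out[:, obs] = S_ev[:, :-1]
        R_out[:, obs] = R_ev[:, :-1]
        D_out[obs] = D * np.exp(-gamma * taus)
        S = S_ev[:, -1].copy()
        R = R_ev[:, -1].copy()
        D = D * math.exp(-gamma * (b - a))
    return S_out, R_out, D_out


def predict_volumes(
    spec: ResistanceSpec,
    P: np.ndarray,
    times: np.ndarray,
    schedule: DoseSchedule,
    gamma: float | None = None,
) -> np.ndarray:
    """Total volume V = S + R, shape (n_sets, n_times)."""
    S, R, _ = simulate_batch(spec, P, times, schedule, gamma=gamma)
    return S + R


class Trajectory(NamedTuple):
    times: np.ndarray
    S: np.ndarray
    R: np.ndarray
    D: np.ndarray
    V: np.ndarray


def simulate_treatment(
    spec: ResistanceSpec,
    params: Mapping[str, float],
    schedule: DoseSchedule,
    times: np.ndarray,
    gamma: float | None = None,
    method: str = "analytic",
    rtol: float = 1e-9,
    atol: float = 1e-10,
    pre_dose: bool = False,
) -> Trajectory:
    """Simulate one parameter set under the dosing schedule.

    ``method="analytic"`` uses the exact piecewise solution (default);
    ``method="rk"`` integrates each inter-dose segment with adaptive
    Runge-Kutta and serves as an independent cross-check. Values at dose
    instants are post-jump unless ``pre_dose``.
    """
    times = np.asarray(times, dtype=float)
    vec = params_to_array(spec, params)
    if method == "analytic":
        S, R, D = simulate_batch(spec, vec[None, :], times, schedule, gamma=gamma)
        S, R = S[0], R[0]
    elif method == "rk":
        S, R, D = _simulate_rk(spec, params, times, schedule, gamma, rtol, atol)
    else:
        raise DomainError(f"unknown method {method!r}")
    if pre_dose:
        D = drug_concentration(schedule, times, gamma=gamma, pre_dose=True)
    return Trajectory(times=times, S=S, R=R, D=D, V=S + R)


def _simulate_rk(spec, params, times, schedule, gamma, rtol, atol):
    gamma_v = default_gamma() if gamma is None else gamma
    t_end = float(times[-1])
    starts = _segment_starts(schedule, t_end)
    dose_set = set(np.round(schedule.dose_times(), 12))
    seg_idx = np.searchsorted(starts, times, side="right") - 1
    S = float(params["S0"])
    R = float(params.get("R0", 0.0))
    D = 0.0
    S_out = np.empty(len(times))
    R_out = np.empty(len(times))
    D_out = np.empty(len(times))

    def rhs(t, y):
        s, r, d = y
        return treatment_rhs(spec, (max(s, 0.0), max(r, 0.0), max(d, 0.0)), params, gamma_v)

    for i, a in enumerate(starts):
        if round(float(a), 12) in dose_set:
            D += schedule.dose
        b = starts[i + 1] if i + 1 < len(starts) else t_end
        obs = np.flatnonzero(seg_idx == i)
        t_eval = times[obs]
        if b > a:
            sol = solve_ivp(
                rhs,
                (a, b),
                [S, R, D],
                t_eval=np.unique(np.concatenate((t_eval, [b]))),
                rtol=rtol,
                atol=atol,
                method="RK45",
            )
            if not sol.success:
                last = float(sol.t[-1]) if len(sol.t) else a
                raise IntegrationError(
                    f"model {spec.model_id} integration failed at t={last}",
                    last_time=last,
                )
            lookup = {round(float(t), 12): j for j, t in enumerate(sol.t)}
            for j, t in zip(obs, t_eval):
                jj = lookup[round(float(t), 12)]
                S_out[j], R_out[j], D_out[j] = sol.y[:, jj]
            S, R, D = sol.y[:, -1]
        else:
            for j in obs:
                S_out[j], R_out[j], D_out[j] = S, R, D
    return S_out, R_out, D_out
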
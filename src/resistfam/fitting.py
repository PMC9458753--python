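"""Two-step per-mouse model fitting.

Step one covers parameter space with a Sobol low-discrepancy sequence,
scales each point into per-parameter bounds, discards biologically
non-viable sets, and keeps the SSE minimizer. Step two refines that point by
stochastic gradient descent: every parameter is perturbed by an independent
uniform draw scaled to its order of magnitude, and a move is accepted only
if it does not increase the SSE. The whole procedure is repeated from
independent starts and the best final SSE wins.

The fitter is model-agnostic: it operates on a :class:`FitProblem` whose
``predict`` evaluates a batch of parameter vectors. Factories are provided
for the resistance family (vectorized piecewise-analytic simulation) and the
growth laws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import qmc

from .cohort import TumorTimecourse
from .exceptions import DomainError, FitError, IntegrationError
from .growth_models import GrowthSpec, solve_growth
from .resistance_models import (
    DoseSchedule,
    ResistanceSpec,
    predict_volumes,
)

#: Default search budgets (paper-scale). Tests and desk runs pass smaller ones.
DEFAULT_N_QMC = 1_500_000
DEFAULT_N_ITER = 500_000
DEFAULT_N_STARTS = 15

_QMC_CHUNK = 32_768


@dataclass(frozen=True)
class FitConfig:
    """Search budgets and seed for one fit."""

    n_qmc: int = DEFAULT_N_QMC
    n_iter: int = DEFAULT_N_ITER
    n_starts: int = DEFAULT_N_STARTS
    seed: int | None = None

    def __post_init__(self):
        if min(self.n_qmc, self.n_starts) < 1 or self.n_iter < 0:
            raise DomainError("fit budgets must be >= 1 (n_iter >= 0)")


@dataclass(frozen=True)
class FitProblem:
    """A self-contained SSE-minimization problem.

    ``predict(P)`` maps an (n, k) batch of parameter vectors to (n, T)
    predicted volumes at the (non-censored) observation times; ``viable(P)``
    returns a boolean mask of biologically admissible rows.
    """

    param_names: tuple[str, ...]
    lo: np.ndarray
    hi: np.ndarray
    predict: Callable[[np.ndarray], np.ndarray]
    viable: Callable[[np.ndarray], np.ndarray]
    observed: np.ndarray

    @property
    def k(self) -> int:
        return len(self.param_names)

    def sse_batch(self, P: np.ndarray) -> np.ndarray:
        """SSE per row; prediction failures and overflows map to +inf."""
        P = np.atleast_2d(P)
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                pred = self.predict(P)
                out = ((pred - self.observed[None, :]) ** 2).sum(axis=1)
        except (IntegrationError, FloatingPointError, OverflowError):
            return np.full(P.shape[0], np.inf)
        return np.where(np.isfinite(out), out, np.inf)


def sse(predicted: np.ndarray, observed) -> float:
    """Sum of squared volume errors over non-censored points.

    ``observed`` is a :class:`TumorTimecourse` or a plain volume array. A
    prediction aligned to all time points has its censored entries dropped;
    one already aligned to the non-censored points is used as is.
    """
    predicted = np.asarray(predicted, dtype=float)
    if isinstance(observed, TumorTimecourse):
        if len(predicted) == len(observed.times):
            keep = ~observed.censored
            predicted = predicted[keep]
            target = observed.volumes[keep]
        elif len(predicted) == observed.n_obs:
            target = observed.observed()[1]
        else:
            raise DomainError(
                f"predicted length {len(predicted)} matches neither all "
                f"({len(observed.times)}) nor non-censored ({observed.n_obs}) points"
            )
    else:
        target = np.asarray(observed, dtype=float)
        if len(predicted) != len(target):
            raise DomainError("predicted/observed length mismatch")
    return float(((predicted - target) ** 2).sum())


# ---------------------------------------------------------------------------
# Sampling bounds

_RATE_BOUNDS = (0.0, 0.1)
_RS_BOUNDS = (0.0, 0.2)


def default_bounds(spec, v0: float) -> dict[str, tuple[float, float]]:
    """Per-parameter Sobol scaling ranges, resolved for one mouse's V0.

    Rate-like parameters scale to [0, 0.1] except r_S in [0, 0.2]; initial
    volumes to [0, 2*V0]; carrying capacity K to [V0, 1e5]; Allee threshold
    m to [0, 10*V0].
    """
    if v0 <= 0:
        raise DomainError(f"V0 must be positive, got {v0}")
    out: dict[str, tuple[float, float]] = {}
    for name in spec.free_params:
        if name == "r_S":
            out[name] = _RS_BOUNDS
        elif name in ("r_R", "lam_S", "lam_R", "g", "r", "a", "b"):
            out[name] = _RATE_BOUNDS
        elif name in ("S0", "R0", "V0", "T0"):
            out[name] = (0.0, 2.0 * v0)
        elif name == "K":
            out[name] = (v0, 1e5)
        elif name == "m":
            out[name] = (0.0, 10.0 * v0)
        else:  # pragma: no cover - new parameter names are a coding error
            raise DomainError(f"no default bounds for parameter {name!r}")
    return out


def scale_sobol_point(
    unit_point: np.ndarray, bounds: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Affine map of a [0,1]^k point into the per-parameter bounds."""
    unit_point = np.asarray(unit_point, dtype=float)
    if np.any(unit_point < 0) or np.any(unit_point > 1):
        raise DomainError("Sobol point coordinates must lie in [0, 1]")
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    return lo + unit_point * (hi - lo)


# ---------------------------------------------------------------------------
# Problem factories


def make_resistance_problem(
    spec: ResistanceSpec,
    tc: TumorTimecourse,
    schedule: DoseSchedule | None = None,
    gamma: float | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FitProblem:
    times, volumes = tc.observed()
    v0 = tc.v0
    if schedule is None:
        schedule = DoseSchedule.weekly(5.0, until=float(times[-1]))
    bmap = dict(default_bounds(spec, v0))
    if bounds:
        bmap.update(bounds)
    names = spec.free_params
    lo = np.array([bmap[n][0] for n in names])
    hi = np.array([bmap[n][1] for n in names])
    idx = {n: i for i, n in enumerate(names)}

    def viable(P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        ok = (P >= 0).all(axis=1)
        if "r_R" in idx:
            ok &= P[:, idx["r_S"]] >= P[:, idx["r_R"]]
        if "lam_R" in idx:
            ok &= P[:, idx["lam_S"]] > P[:, idx["lam_R"]]
        total = P[:, idx["S0"]] + (P[:, idx["R0"]] if "R0" in idx else 0.0)
        ok &= (total > 0) & (total <= 2.0 * v0)
        return ok

    def predict(P: np.ndarray) -> np.ndarray:
        return predict_volumes(spec, P, times, schedule, gamma=gamma)

    return FitProblem(
        param_names=names, lo=lo, hi=hi, predict=predict, viable=viable,
        observed=volumes,
    )


def make_growth_problem(
    spec: GrowthSpec,
    tc: TumorTimecourse,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FitProblem:
    """Growth-law problem. Exponential and logistic use vectorized closed
    forms; the other laws fall back to per-candidate integration, so keep
    QMC budgets modest for them."""
    times, volumes = tc.observed()
    v0 = tc.v0
    bmap = dict(default_bounds(spec, v0))
    if bounds:
        bmap.update(bounds)
    names = spec.free_params
    lo = np.array([bmap[n][0] for n in names])
    hi = np.array([bmap[n][1] for n in names])
    idx = {n: i for i, n in enumerate(names)}

    def viable(P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        ok = (P >= 0).all(axis=1) & (P[:, idx["V0"]] > 0)
        if "K" in idx:
            ok &= P[:, idx["K"]] > 0
        if "m" in idx:
            ok &= P[:, idx["m"]] > 0
        return ok

    def predict(P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        t = times[None, :] - times[0]
        if spec.name == "exponential":
            return P[:, idx["V0"]][:, None] * np.exp(P[:, idx["r"]][:, None] * t)
        if spec.name == "logistic":
            V0 = P[:, idx["V0"]][:, None]
            K = P[:, idx["K"]][:, None]
            r = P[:, idx["r"]][:, None]
            return K / (1.0 + (K - V0) / V0 * np.exp(-r * t))
        out = np.empty((P.shape[0], len(times)))
        for i, row in enumerate(P):
            params = dict(zip(names, row))
            try:
                out[i] = solve_growth(spec, params, times)
            except IntegrationError:
                out[i] = np.inf
        return out

    return FitProblem(
        param_names=names, lo=lo, hi=hi, predict=predict, viable=viable,
        observed=volumes,
    )


# ---------------------------------------------------------------------------
# Step 1: Sobol quasi-Monte Carlo search


@dataclass(frozen=True)
class QMCResult:
    params: np.ndarray
    sse: float
    n_viable: int


def qmc_search(
    problem: FitProblem,
    n_points: int = DEFAULT_N_QMC,
    seed: int | np.random.Generator | None = None,
    scramble: bool = False,
) -> QMCResult:
    """Sobol sweep of the scaled parameter box, keeping the viable minimizer.

    Deterministic given (seed, n_points, bounds); with ``scramble=False`` the
    raw (unscrambled) sequence is used and the seed is irrelevant. Raises
    :class:`FitError` if no sampled point is viable.
    """
    if n_points < 1:
        raise DomainError("n_points must be >= 1")
    sampler = qmc.Sobol(d=problem.k, scramble=scramble, seed=seed)
    bounds = list(zip(problem.lo, problem.hi))
    best_sse = np.inf
    best = None
    n_viable = 0
    remaining = int(n_points)
    while remaining > 0:
        m = min(remaining, _QMC_CHUNK)
        remaining -= m
        with warnings.catch_warnings():
            # chunk sizes are deliberate; the balance note is irrelevant here
            warnings.filterwarnings("ignore", message=".*balance properties.*")
            unit = sampler.random(m)
        P = scale_sobol_point(unit, bounds)
        mask = problem.viable(P)
        n_viable += int(mask.sum())
        if not mask.any():
            continue
        cand = P[mask]
        vals = problem.sse_batch(cand)
        j = int(np.argmin(vals))
        if vals[j] < best_sse:
            best_sse = float(vals[j])
            best = cand[j].copy()
    if best is None:
        raise FitError(
            f"no viable parameter set among {n_points} Sobol points; "
            "increase n_points or relax bounds"
        )
    return QMCResult(params=best, sse=best_sse, n_viable=n_viable)


# ---------------------------------------------------------------------------
# Step 2: stochastic gradient descent


def perturbation_range(p: float) -> tuple[float, float]:
    """Symmetric perturbation range one decade below p's order of magnitude.

    alpha = floor(log10(|p|)) gives the range [-10**(alpha-1), 10**(alpha-1)];
    p = 0 uses alpha = -3 (the smallest scale among the default bounds).
    """
    if not math.isfinite(p):
        raise DomainError(f"parameter must be finite, got {p}")
    alpha = -3 if p == 0 else math.floor(math.log10(abs(p)))
    half = 10.0 ** (alpha - 1)
    return (-half, half)


def _perturbation_scales(p: np.ndarray) -> np.ndarray:
    scales = np.empty_like(p)
    for i, v in enumerate(p):
        scales[i] = perturbation_range(v)[1]
    return scales


@dataclass(frozen=True)
class GDResult:
    params: np.ndarray
    sse: float
    trace: np.ndarray  # accepted-SSE sequence, trace[0] is the start


def gradient_descent(
    problem: FitProblem,
    start: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    rng: np.random.Generator | int | None = None,
) -> GDResult:
    """Downhill-only random-perturbation refinement from ``start``.

    Each iteration perturbs every parameter by an independent uniform draw
    from its :func:`perturbation_range`; the move is rejected if any proposed
    parameter is negative, the proposal is non-viable, or the SSE increases.
    The accepted-SSE trace is therefore non-increasing.
    """
    rng = np.random.default_rng(rng)
    p = np.asarray(start, dtype=float).copy()
    if not problem.viable(p[None, :])[0]:
        raise DomainError("gradient descent start is not viable")
    cur = float(problem.sse_batch(p[None, :])[0])
    trace = [cur]
    k = len(p)
    for _ in range(int(n_iter)):
        scales = _perturbation_scales(p)
        proposal = p + rng.uniform(-1.0, 1.0, size=k) * scales
        if (proposal < 0).any():
            continue
        if not problem.viable(proposal[None, :])[0]:
            continue
        val = float(problem.sse_batch(proposal[None, :])[0])
        if val - cur > 0:  # uphill: reject
            continue
        p = proposal
        cur = val
        trace.append(cur)
    return GDResult(params=p, sse=cur, trace=np.asarray(trace))


# ---------------------------------------------------------------------------
# Multistart wrapper


@dataclass(frozen=True)
class StartRecord:
    start_index: int
    qmc_sse: float
    final_sse: float
    final_params: dict[str, float]


@dataclass(frozen=True)
class FitResult:
    """Best parameters for one mouse x model with a per-start audit trail."""

    mouse_id: str
    model_id: str
    best_params: dict[str, float]
    sse: float
    n_points: int
    k: int
    per_start: tuple[StartRecord, ...]
    seed: int | None

    def params_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.best_params[n] for n in names])


def multistart(
    problem: FitProblem,
    config: FitConfig,
) -> tuple[np.ndarray, float, tuple[StartRecord, ...]]:
    """Run (QMC -> gradient descent) ``n_starts`` times from independent
    sub-seeds; return the best final parameters, SSE, and the audit trail.

    Starts differ through scrambled Sobol sub-sequences and independent
    perturbation streams; the whole procedure is deterministic given
    ``config.seed``. A start whose QMC stage finds no viable point is
    recorded with infinite SSE; only if all starts fail is the error raised.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_starts)
    records: list[StartRecord] = []
    best_params, best_sse = None, np.inf
    failures: list[FitError] = []
    for i, child in enumerate(children):
        qmc_ss, gd_ss = child.spawn(2)
        try:
            q = qmc_search(
                problem,
                n_points=config.n_qmc,
                seed=np.random.default_rng(qmc_ss),
                scramble=True,
            )
        except FitError as exc:
            failures.append(exc)
            records.append(
                StartRecord(i, math.inf, math.inf, {})
            )
            continue
        g = gradient_descent(
            problem, q.params, n_iter=config.n_iter,
            rng=np.random.default_rng(gd_ss),
        )
        records.append(
            StartRecord(
                start_index=i,
                qmc_sse=q.sse,
                final_sse=g.sse,
                final_params=dict(zip(problem.param_names, map(float, g.params))),
            )
        )
        if g.sse < best_sse:
            best_sse = g.sse
            best_params = g.params
    if best_params is None:
        raise FitError(f"all {config.n_starts} starts failed: {failures[0]}")
    return best_params, best_sse, tuple(records)


def multistart_fit(
    spec: ResistanceSpec,
    tc: TumorTimecourse,
    config: FitConfig = FitConfig(),
    schedule: DoseSchedule | None = None,
    gamma: float | None = None,
) -> FitResult:
    """Fit one resistance model to one mouse with the full two-step
    multistart procedure."""
    problem = make_resistance_problem(spec, tc, schedule=schedule, gamma=gamma)
    best, best_sse, records = multistart(problem, config)
    return FitResult(
        mouse_id=tc.mouse_id,
        model_id=spec.model_id,
        best_params=dict(zip(problem.param_names, map(float, best))),
        sse=best_sse,
        n_points=tc.n_obs,
        k=spec.k,
        per_start=records,
        seed=config.seed,
    )


def multistart_fit_growth(
    spec: GrowthSpec,
    tc: TumorTimecourse,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Fit one growth law to one mouse (same machinery, growth problem)."""
    problem = make_growth_problem(spec, tc)
    best, best_sse, records = multistart(problem, config)
    return FitResult(
        mouse_id=tc.mouse_id,
        model_id=spec.name,
        best_params=dict(zip(problem.param_names, map(float, best))),
        sse=best_sse,
        n_points=tc.n_obs,
        k=spec.k,
        per_start=records,
        seed=config.seed,
    )
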
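"""Profile-likelihood scan of the initial resistance fraction.

For each fixed fraction v on a grid in [0, 1] the initial conditions are
constrained to R0 = v*T, S0 = (1-v)*T with the total T still fitted, all
remaining parameters are re-optimized, and the optimal SSE is recorded. A
parameter is practically identifiable when the resulting profile has a clear
interior minimum; a flat or one-sided profile is not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cohort import TumorTimecourse
from .exceptions import DomainError
from .fitting import (
    FitConfig,
    FitProblem,
    gradient_descent,
    make_resistance_problem,
    multistart,
)
from .resistance_models import DoseSchedule, ResistanceSpec

IDENTIFIABLE = "identifiable"
NON_IDENTIFIABLE = "non_identifiable"


def default_grid(step: float = 0.05) -> np.ndarray:
    """Fraction grid 0, step, ..., 1 (21 points at the default step)."""
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


@dataclass(frozen=True)
class ProfileCurve:
    """Re-optimized SSE at each fixed initial-resistance-fraction value."""

    mouse_id: str
    model_id: str
    grid: np.ndarray
    sse_profile: np.ndarray
    argmin: float
    verdict: str

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        prof = np.asarray(self.sse_profile, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "sse_profile", prof)
        if len(grid) != len(prof):
            raise DomainError("grid and sse_profile length mismatch")
        if np.any((grid < 0) | (grid > 1)):
            raise DomainError("grid values must lie in [0, 1]")


def constrained_problem(
    spec: ResistanceSpec,
    tc: TumorTimecourse,
    fraction: float,
    schedule: DoseSchedule | None = None,
    gamma: float | None = None,
) -> FitProblem:
    """FitProblem with S0, R0 replaced by a single fitted total T0.

    The full vector is reconstructed as S0 = (1-v)*T0, R0 = v*T0, so the
    constrained family at the unconstrained optimum's fraction nests the
    unconstrained problem.
    """
    if not 0.0 <= fraction <= 1.0:
        raise DomainError(f"fraction must be in [0, 1], got {fraction}")
    base = make_resistance_problem(spec, tc, schedule=schedule, gamma=gamma)
    names = tuple(n for n in base.param_names if n not in ("S0", "R0")) + ("T0",)
    full_idx = {n: i for i, n in enumerate(base.param_names)}
    keep = [full_idx[n] for n in names[:-1]]

    def expand(P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        full = np.empty((P.shape[0], len(base.param_names)))
        full[:, keep] = P[:, :-1]
        T = P[:, -1]
        full[:, full_idx["S0"]] = (1.0 - fraction) * T
        full[:, full_idx["R0"]] = fraction * T
        return full

    lo = np.append(base.lo[keep], 0.0)
    hi = np.append(base.hi[keep], 2.0 * tc.v0)
    return FitProblem(
        param_names=names,
        lo=lo,
        hi=hi,
        predict=lambda P: base.predict(expand(P)),
        viable=lambda P: base.viable(expand(P)) & (np.atleast_2d(P) >= 0).all(axis=1),
        observed=base.observed,
    )


def profile_rfrac(
    spec: ResistanceSpec,
    tc: TumorTimecourse,
    fit_config: FitConfig,
    grid: np.ndarray | None = None,
    schedule: DoseSchedule | None = None,
    gamma: float | None = None,
    rel_rise: float = 0.10,
    continuation: bool = True,
) -> ProfileCurve:
    """Profile the initial resistance fraction for one mouse x model.

    Intended for the pre-existing-resistance members (1.2 and 3.2; 2.2 is
    permitted but not profiled by default). Each grid point gets its own
    multistart refit of the remaining parameters with a sub-seed derived
    from ``fit_config.seed``. With ``continuation`` (the standard profile-
    likelihood practice) each grid point additionally refines from the
    neighboring point's optimum, in a forward and a backward sweep, which
    suppresses spurious optimizer noise at reduced budgets; the recorded
    value is the best found, so the profile can only move toward the true
    envelope.
    """
    if not spec.pre_existing:
        raise DomainError(
            f"model {spec.model_id} has no pre-existing resistance to profile"
        )
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise DomainError("profile grid is empty")
    root = np.random.SeedSequence(fit_config.seed)
    children = root.spawn(2 * len(grid))
    profile = np.full(len(grid), np.inf)
    best_params: list[np.ndarray | None] = [None] * len(grid)
    problems = [
        constrained_problem(spec, tc, float(v), schedule=schedule, gamma=gamma)
        for v in grid
    ]
    for i, child in enumerate(children[: len(grid)]):
        cfg = replace(fit_config, seed=int(child.generate_state(1)[0]))
        params, best_sse, _ = multistart(problems[i], cfg)
        profile[i] = best_sse
        best_params[i] = params
    if continuation and len(grid) > 1:
        order = list(range(1, len(grid))) + list(range(len(grid) - 2, -1, -1))
        for j, i in enumerate(order):
            prev = i - 1 if j < len(grid) - 1 else i + 1
            start = best_params[prev]
            if start is None or not problems[i].viable(start[None, :])[0]:
                continue
            rng = np.random.default_rng(children[len(grid) + i])
            res = gradient_descent(
                problems[i], start, n_iter=fit_config.n_iter, rng=rng
            )
            if res.sse < profile[i]:
                profile[i] = res.sse
                best_params[i] = res.params
    curve = ProfileCurve(
        mouse_id=tc.mouse_id,
        model_id=spec.model_id,
        grid=grid,
        sse_profile=profile,
        argmin=float(grid[int(np.argmin(profile))]),
        verdict="",
    )
    return replace(curve, verdict=classify_identifiability(curve, rel_rise=rel_rise))


def classify_identifiability(curve: ProfileCurve, rel_rise: float = 0.10) -> str:
    """Identifiable iff the minimum is interior and both endpoints rise by
    at least ``rel_rise`` relative to it (a clear, two-sided minimum)."""
    prof = curve.sse_profile
    j = int(np.argmin(prof))
    if j == 0 or j == len(prof) - 1:
        return NON_IDENTIFIABLE
    floor = max(prof[j], np.finfo(float).tiny)
    if (prof[0] - prof[j]) / floor < rel_rise:
        return NON_IDENTIFIABLE
    if (prof[-1] - prof[j]) / floor < rel_rise:
        return NON_IDENTIFIABLE
    return IDENTIFIABLE
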
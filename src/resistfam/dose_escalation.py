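"""In-silico dose escalation: fold reduction after two weeks of weekly dosing.

Each mouse's best-fit parameters are re-simulated at escalated doses; the
fold reduction is the model's initial volume divided by its volume after the
study duration. Cohort medians per dose and the average rate of change of the
median across the dose range summarize the study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DomainError
from .fitting import FitResult
from .resistance_models import (
    DoseSchedule,
    ResistanceSpec,
    is_viable,
    params_to_array,
    predict_volumes,
)

DEFAULT_DOSES = tuple(float(d) for d in range(16, 21))


def fold_reduction(
    spec: ResistanceSpec,
    params: Mapping[str, float],
    dose: float,
    duration: float = 14.0,
    interval: float = 7.0,
    gamma: float | None = None,
) -> float:
    """V(0) / V(duration) with one bolus of ``dose`` every ``interval`` days.

    A fold of 4 means the tumor is four times smaller after the study; a
    fold below 1 means it grew. V(0) is the model's S0 + R0.
    """
    if dose < 0:
        raise DomainError(f"dose must be >= 0, got {dose}")
    if not is_viable(spec, params):
        raise DomainError("parameters are not viable for this model")
    n_doses = int(np.ceil(duration / interval))
    schedule = DoseSchedule(dose=dose, interval=interval, n_doses=max(n_doses, 1))
    vec = params_to_array(spec, params)
    V = predict_volumes(spec, vec[None, :], np.array([0.0, duration]), schedule, gamma=gamma)[0]
    if V[1] <= 0 or not np.isfinite(V[1]):
        raise DomainError(f"non-positive final volume V({duration}) = {V[1]}")
    return float(V[0] / V[1])


@dataclass(frozen=True)
class EscalationResult:
    """Per-mouse fold reductions over a dose grid with cohort medians."""

    model_id: str
    doses: np.ndarray
    per_mouse_fold: dict[str, np.ndarray]  # mouse_id -> fold per dose
    median_fold: np.ndarray
    avg_rate_of_change: float  # fold per (mg/kg) across the dose range


def escalation_study(
    fits: Sequence[FitResult],
    spec: ResistanceSpec,
    doses: Sequence[float] = DEFAULT_DOSES,
    duration: float = 14.0,
    interval: float = 7.0,
    gamma: float | None = None,
) -> EscalationResult:
    """Escalate every fitted mouse across ``doses`` and summarize medians."""
    if not fits:
        raise DomainError("need at least one fit")
    if any(f.model_id != spec.model_id for f in fits):
        raise DomainError("all fits must be for the escalated model")
    doses = np.asarray(sorted(float(d) for d in doses))
    if len(doses) < 2:
        raise DomainError("need at least two doses for a rate of change")
    per_mouse: dict[str, np.ndarray] = {}
    for fit in fits:
        per_mouse[fit.mouse_id] = np.array(
            [
                fold_reduction(
                    spec, fit.best_params, d,
                    duration=duration, interval=interval, gamma=gamma,
                )
                for d in doses
            ]
        )
    stacked = np.vstack(list(per_mouse.values()))
    medians = np.median(stacked, axis=0)
    rate = float((medians[-1] - medians[0]) / (doses[-1] - doses[0]))
    return EscalationResult(
        model_id=spec.model_id,
        doses=doses,
        per_mouse_fold=per_mouse,
        median_fold=medians,
        avg_rate_of_change=rate,
    )
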
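"""Tumor-volume time courses: data model, CSV I/O, and preprocessing.

A cohort is a list of per-mouse :class:`TumorTimecourse` objects. Preprocessing
covers caliper volume computation, censoring of implausible transient spikes,
endpoint-based trajectory classification, and the cohort-level Fisher exact
test of response (decreasing vs. not-decreasing by group).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, ParseError

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ("mouse_id", "group", "time_days", "volume_mm3", "censored")


class Group(str, Enum):
    control = "control"
    treatment = "treatment"


class Trajectory(str, Enum):
    increasing = "increasing"
    decreasing = "decreasing"
    stable = "stable"


def compute_volume(l: float, w: float) -> float:
    """Ellipsoid-approximation tumor volume ``l * w**2 * pi / 6`` in mm^3.

    Parameters
    ----------
    l : float
        Tumor length in mm (longest axis).
    w : float
        Tumor width in mm.
    """
    if l < 0 or w < 0:
        raise DomainError(f"negative caliper measurement: l={l}, w={w}")
    return l * w * w * math.pi / 6.0


@dataclass(frozen=True)
class TumorTimecourse:
    """One mouse's (time, volume) series with censor flags and group label.

    Times are days with t=0 at treatment start and must be strictly
    increasing; volumes are positive mm^3. ``censored`` marks points excluded
    from all downstream fitting and classification (they are kept in files
    for audit).
    """

    mouse_id: str
    group: Group
    times: np.ndarray
    volumes: np.ndarray
    censored: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        censored = (
            np.zeros(times.shape, dtype=bool)
            if self.censored is None
            else np.asarray(self.censored, dtype=bool)
        )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        object.__setattr__(self, "censored", censored)
        if times.ndim != 1 or not (len(times) == len(volumes) == len(censored)):
            raise DomainError(
                f"mouse {self.mouse_id}: times/volumes/censored length mismatch"
            )
        if len(times) and times[0] < 0:
            raise DomainError(f"mouse {self.mouse_id}: negative time {times[0]}")
        if np.any(np.diff(times) <= 0):
            raise DomainError(f"mouse {self.mouse_id}: times not strictly increasing")
        if np.any(volumes <= 0):
            raise DomainError(f"mouse {self.mouse_id}: non-positive volume")

    @property
    def n_obs(self) -> int:
        """Number of non-censored observations (the n_i of the IC formulas)."""
        return int((~self.censored).sum())

    @property
    def v0(self) -> float:
        """Initial volume: first non-censored measurement."""
        keep = ~self.censored
        if not keep.any():
            raise DomainError(f"mouse {self.mouse_id}: all points censored")
        return float(self.volumes[keep][0])

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, volumes) restricted to non-censored points."""
        keep = ~self.censored
        return self.times[keep], self.volumes[keep]


@dataclass(frozen=True)
class ResponseCounts:
    """Per-group tally of trajectory classes."""

    n_increasing: int
    n_decreasing: int
    n_stable: int

    def __post_init__(self):
        if min(self.n_increasing, self.n_decreasing, self.n_stable) < 0:
            raise DomainError("negative response count")

    @property
    def total(self) -> int:
        return self.n_increasing + self.n_decreasing + self.n_stable


def censor_timecourse(
    tc: TumorTimecourse,
    max_fold: float = 2.0,
    window: float = 4.0,
    sustain_tol: float = 1.0,
) -> TumorTimecourse:
    """Flag isolated implausible spikes as censored.

    Point *j* is censored when the volume more than ``max_fold``-doubles
    relative to point *j-1* within ``window`` days AND the jump is not
    sustained (``volumes[j+1] < sustain_tol * volumes[j]``). The first and
    last points are never censored: there is no preceding/subsequent point
    to judge them by. Existing flags are preserved; values are untouched.
    """
    if max_fold <= 1:
        raise DomainError(f"max_fold must exceed 1, got {max_fold}")
    if window <= 0:
        raise DomainError(f"window must be positive, got {window}")
    n = len(tc.times)
    if n < 3:
        logger.warning(
            "mouse %s: %d point(s), too few to censor; returning unchanged",
            tc.mouse_id,
            n,
        )
        return tc
    flags = tc.censored.copy()
    t, v = tc.times, tc.volumes
    for j in range(1, n - 1):
        spike = v[j] / v[j - 1] > max_fold and (t[j] - t[j - 1]) <= window
        if spike and v[j + 1] < sustain_tol * v[j]:
            flags[j] = True
    return replace(tc, censored=flags)


def classify_trajectory(tc: TumorTimecourse, stable_band: float = 0.2) -> Trajectory:
    """Endpoint classification: last vs. first non-censored volume.

    A final/initial ratio within ``1 +/- stable_band`` is *stable*; above is
    *increasing*; below is *decreasing*.
    """
    times, volumes = tc.observed()
    if len(volumes) < 2:
        raise DomainError(
            f"mouse {tc.mouse_id}: need >= 2 non-censored points to classify"
        )
    ratio = volumes[-1] / volumes[0]
    if ratio > 1 + stable_band:
        return Trajectory.increasing
    if ratio < 1 - stable_band:
        return Trajectory.decreasing
    return Trajectory.stable


def response_counts(
    cohort: Sequence[TumorTimecourse], stable_band: float = 0.2
) -> dict[Group, ResponseCounts]:
    """Tally trajectory classes for each group present in the cohort."""
    tallies: dict[Group, dict[Trajectory, int]] = {}
    for tc in cohort:
        cls = classify_trajectory(tc, stable_band=stable_band)
        tallies.setdefault(tc.group, {k: 0 for k in Trajectory})[cls] += 1
    return {
        g: ResponseCounts(
            n_increasing=t[Trajectory.increasing],
            n_decreasing=t[Trajectory.decreasing],
            n_stable=t[Trajectory.stable],
        )
        for g, t in tallies.items()
    }


def fisher_exact_response(
    control: ResponseCounts, treatment: ResponseCounts
) -> float:
    """Two-sided Fisher exact p-value for decreasing vs. not-decreasing.

    The 2x2 table crosses group (control/treatment) with response
    (decreasing / not-decreasing); the two-sided p-value sums all tables with
    hypergeometric probability <= that of the observed table.
    """
    if control.total == 0 or treatment.total == 0:
        raise DomainError("empty group in Fisher exact test")
    table = [
        [control.n_decreasing, control.total - control.n_decreasing],
        [treatment.n_decreasing, treatment.total - treatment.n_decreasing],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def write_cohort(cohort: Iterable[TumorTimecourse], path) -> None:
    """Write a cohort to tidy CSV, one row per observation."""
    rows = []
    for tc in cohort:
        for t, v, c in zip(tc.times, tc.volumes, tc.censored):
            rows.append(
                {
                    "mouse_id": tc.mouse_id,
                    "group": tc.group.value,
                    "time_days": t,
                    "volume_mm3": v,
                    "censored": bool(c),
                }
            )
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def read_cohort(path) -> list[TumorTimecourse]:
    """Read a cohort CSV, validating schema and per-mouse invariants.

    Violations raise :class:`ParseError` naming the offending row (1-based,
    counting the header as row 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    cohort: list[TumorTimecourse] = []
    for mouse_id, sub in df.groupby("mouse_id", sort=False):
        rows = sub.index.to_numpy() + 2  # CSV line numbers
        times = sub["time_days"].to_numpy(dtype=float)
        volumes = sub["volume_mm3"].to_numpy(dtype=float)
        censored = sub["censored"].astype(bool).to_numpy()
        bad = np.flatnonzero(volumes <= 0)
        if bad.size:
            raise ParseError(
                f"{path} row {rows[bad[0]]}: non-positive volume {volumes[bad[0]]}"
            )
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size:
            raise ParseError(
                f"{path} row {rows[bad[0] + 1]}: time not strictly increasing "
                f"for mouse {mouse_id}"
            )
        groups = set(sub["group"])
        if len(groups) != 1:
            raise ParseError(f"{path}: mouse {mouse_id} has mixed group labels")
        try:
            group = Group(groups.pop())
        except ValueError as exc:
            raise ParseError(f"{path} row {rows[0]}: {exc}") from exc
        cohort.append(
            TumorTimecourse(
                mouse_id=str(mouse_id),
                group=group,
                times=times,
                volumes=volumes,
                censored=censored,
            )
        )
    return cohort
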
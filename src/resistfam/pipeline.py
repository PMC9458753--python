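"""End-to-end orchestration: preprocess -> fit -> select -> profile -> escalate.

A single :class:`RunConfig` (loadable from YAML) drives all stages, writes
CSV/JSON artifacts into the output directory, and records a manifest with
per-file checksums, seeds, budgets, and stage timings. The master seed is
split deterministically per mouse/model/stage so changing the cohort size
does not reshuffle unrelated fits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    Group,
    censor_timecourse,
    fisher_exact_response,
    read_cohort,
    response_counts,
    write_cohort,
)
from .dose_escalation import escalation_study
from .exceptions import DomainError
from .fitting import FitConfig, multistart_fit, multistart_fit_growth
from .growth_models import GROWTH_MODEL_NAMES, GrowthSpec, fit_exponential_analytic
from .identifiability import default_grid, profile_rfrac
from .model_selection import cohort_selection_summary, rank_models
from .resistance_models import MODEL_IDS, ResistanceSpec
from .synthetic_data import default_recipe, generate_cohort

logger = logging.getLogger(__name__)


def subseed(master: int | None, *keys) -> int:
    """Deterministic sub-seed from a master seed and a stable key path.

    Strings are hashed with crc32 so per-mouse seeds do not depend on cohort
    order or size.
    """
    parts = [0 if master is None else int(master)]
    for key in keys:
        if isinstance(key, str):
            parts.append(zlib.crc32(key.encode()))
        else:
            parts.append(int(key))
    return int(np.random.SeedSequence(parts).generate_state(1)[0])


@dataclass
class RunConfig:
    """Configuration for one full analysis run."""

    out_dir: str = "results/run"
    input_path: str | None = None
    recipe_model: str | None = None  # synthetic generating model id
    n_mice: int = 10
    noise_cv: float = 0.05
    outlier_rate: float = 0.02
    n_qmc: int = 4096
    n_iter: int = 2000
    n_starts: int = 3
    profile_n_qmc: int = 1024
    profile_n_iter: int = 500
    profile_n_starts: int = 2
    profile_grid_step: float = 0.05
    profile_rel_rise: float = 0.10
    profile_models: tuple[str, ...] = ("1.2", "3.2")
    escalation_models: tuple[str, ...] = ("1.2", "2.1", "3.1", "3.2")
    dose_min: float = 16.0
    dose_max: float = 20.0
    dose_step: float = 1.0
    max_fold: float = 2.0
    window_days: float = 4.0
    sustain_tol: float = 1.0
    stable_band: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.recipe_model is None):
            raise DomainError(
                "exactly one of input_path / recipe_model must be given"
            )
        if min(self.n_qmc, self.n_iter, self.n_starts) < 1:
            raise DomainError("fit budgets must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("profile_models", "escalation_models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_to_record(fit) -> dict:
    rec = dataclasses.asdict(fit)
    rec["per_start"] = [dataclasses.asdict(s) for s in fit.per_start]
    return rec


def run_full_analysis(config: RunConfig) -> Path:
    """Run every stage, writing artifacts and a manifest; returns out_dir.

    On stage failure, partial outputs are retained and the manifest records
    the failure point.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": [],
        "files": {},
        "failure": None,
    }
    stage = "start"
    try:
        # -- cohort -------------------------------------------------------
        stage = "cohort"
        t0 = time.perf_counter()
        if config.recipe_model is not None:
            recipe = default_recipe(
                config.recipe_model,
                n_mice=config.n_mice,
                noise_cv=config.noise_cv,
                outlier_rate=config.outlier_rate,
                seed=subseed(config.seed, "synth"),
            )
            synth = generate_cohort(recipe)
            cohort = list(synth.cohort)
            with open(out / "truth.json", "w") as fh:
                json.dump(synth.truth, fh, indent=1)
        else:
            cohort = read_cohort(config.input_path)
        write_cohort(cohort, out / "cohort.csv")
        _done(manifest, "cohort", t0)

        # -- preprocess ---------------------------------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        cohort = [
            censor_timecourse(
                tc,
                max_fold=config.max_fold,
                window=config.window_days,
                sustain_tol=config.sustain_tol,
            )
            for tc in cohort
        ]
        write_cohort(cohort, out / "cohort_censored.csv")
        counts = response_counts(cohort, stable_band=config.stable_band)
        summary = {
            g.value: dataclasses.asdict(c) for g, c in counts.items()
        }
        if Group.control in counts and Group.treatment in counts:
            summary["fisher_p"] = fisher_exact_response(
                counts[Group.control], counts[Group.treatment]
            )
        with open(out / "response_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        _done(manifest, "preprocess", t0)

        control = [tc for tc in cohort if tc.group is Group.control]
        treated = [tc for tc in cohort if tc.group is Group.treatment]

        # -- control growth models ---------------------------------------
        if control:
            stage = "fit-control"
            t0 = time.perf_counter()
            rows = []
            for tc in control:
                exp_fit = fit_exponential_analytic(tc)
                rows.append(
                    {
                        "mouse_id": tc.mouse_id,
                        "model": "exponential",
                        "k": 2,
                        "n": tc.n_obs,
                        "sse": exp_fit.sse,
                        **{"r": exp_fit.r, "V0": exp_fit.V0},
                    }
                )
                for name in GROWTH_MODEL_NAMES:
                    if name == "exponential":
                        continue
                    cfg = FitConfig(
                        n_qmc=config.n_qmc,
                        n_iter=config.n_iter,
                        n_starts=config.n_starts,
                        seed=subseed(config.seed, "control", tc.mouse_id, name),
                    )
                    fit = multistart_fit_growth(GrowthSpec(name), tc, cfg)
                    rows.append(
                        {
                            "mouse_id": tc.mouse_id,
                            "model": name,
                            "k": fit.k,
                            "n": fit.n_points,
                            "sse": fit.sse,
                            **fit.best_params,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "control_fits.csv", index=False)
            _done(manifest, "fit-control", t0)

        # -- treatment fits ----------------------------------------------
        all_fits: dict[str, dict[str, object]] = {}
        if treated:
            stage = "fit"
            t0 = time.perf_counter()
            rows = []
            fit_dir = out / "fits"
            fit_dir.mkdir(exist_ok=True)
            for tc in treated:
                per_model = {}
                for model_id in MODEL_IDS:
                    cfg = FitConfig(
                        n_qmc=config.n_qmc,
                        n_iter=config.n_iter,
                        n_starts=config.n_starts,
                        seed=subseed(config.seed, "fit", tc.mouse_id, model_id),
                    )
                    fit = multistart_fit(ResistanceSpec(model_id), tc, cfg)
                    per_model[model_id] = fit
                    rows.append(
                        {
                            "mouse_id": tc.mouse_id,
                            "model": model_id,
                            "k": fit.k,
                            "n": fit.n_points,
                            "sse": fit.sse,
                        }
                    )
                all_fits[tc.mouse_id] = per_model
                with open(fit_dir / f"{tc.mouse_id}.json", "w") as fh:
                    json.dump(
                        {m: _fit_to_record(f) for m, f in per_model.items()},
                        fh,
                        indent=1,
                    )
            pd.DataFrame(rows).to_csv(out / "fits.csv", index=False)
            _done(manifest, "fit", t0)

            # -- selection ------------------------------------------------
            stage = "select"
            t0 = time.perf_counter()
            tables = [rank_models(list(pm.values())) for pm in all_fits.values()]
            table_rows = []
            for table in tables:
                for row in table.rows:
                    table_rows.append(
                        {"mouse_id": table.mouse_id, **dataclasses.asdict(row)}
                    )
            pd.DataFrame(table_rows).to_csv(out / "ic_tables.csv", index=False)
            with open(out / "selection_summary.json", "w") as fh:
                json.dump(cohort_selection_summary(tables), fh, indent=1)
            _done(manifest, "select", t0)

            # -- identifiability ------------------------------------------
            stage = "profile"
            t0 = time.perf_counter()
            grid = default_grid(config.profile_grid_step)
            prof_rows, verdicts = [], {}
            for tc in treated:
                for model_id in config.profile_models:
                    cfg = FitConfig(
                        n_qmc=config.profile_n_qmc,
                        n_iter=config.profile_n_iter,
                        n_starts=config.profile_n_starts,
                        seed=subseed(config.seed, "profile", tc.mouse_id, model_id),
                    )
                    curve = profile_rfrac(
                        ResistanceSpec(model_id), tc, cfg, grid=grid,
                        rel_rise=config.profile_rel_rise,
                    )
                    verdicts[f"{tc.mouse_id}:{model_id}"] = {
                        "argmin": curve.argmin,
                        "verdict": curve.verdict,
                    }
                    for v, s in zip(curve.grid, curve.sse_profile):
                        prof_rows.append(
                            {
                                "mouse_id": tc.mouse_id,
                                "model": model_id,
                                "rfrac": v,
                                "sse": s,
                            }
                        )
            pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)
            with open(out / "profile_verdicts.json", "w") as fh:
                json.dump(verdicts, fh, indent=1)
            _done(manifest, "profile", t0)

            # -- escalation -----------------------------------------------
            stage = "escalate"
            t0 = time.perf_counter()
            doses = np.arange(
                config.dose_min, config.dose_max + config.dose_step / 2,
                config.dose_step,
            )
            esc_rows = []
            for model_id in config.escalation_models:
                fits = [pm[model_id] for pm in all_fits.values()]
                res = escalation_study(fits, ResistanceSpec(model_id), doses=doses)
                for d, m in zip(res.doses, res.median_fold):
                    esc_rows.append(
                        {
                            "model": model_id,
                            "dose": d,
                            "median_fold": m,
                            "avg_rate_of_change": res.avg_rate_of_change,
                        }
                    )
            pd.DataFrame(esc_rows).to_csv(out / "escalation.csv", index=False)
            _done(manifest, "escalate", t0)
    except Exception as exc:  # record the failure point, keep partial output
        manifest["failure"] = {"stage": stage, "error": repr(exc)}
        _write_manifest(out, manifest)
        raise
    _write_manifest(out, manifest)
    return out


def _done(manifest: dict, stage: str, t0: float) -> None:
    dt = time.perf_counter() - t0
    manifest["stages"].append({"stage": stage, "seconds": round(dt, 3)})
    logger.info("stage %s finished in %.2fs", stage, dt)


def _write_manifest(out: Path, manifest: dict) -> None:
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
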
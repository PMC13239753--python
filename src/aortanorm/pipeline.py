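"""End-to-end orchestration: simulate/load -> match -> split -> fit -> evaluate.

``run_pipeline`` drives the whole indexing workflow for one or more
populations: build the cohorts (from synthetic specs or subject tables),
optionally propensity-match the first two, optionally pool them into a
combined cohort, split each population 7:3 into construction and
validation groups, fit one allometric equation per aortic parameter on
group A, and judge both the fitted correction and guideline-style BSA
indexation on group B.  Reference intervals for the corrected values are
estimated on the full cohort.  All randomness flows from a single master
seed through named per-stage seeds, so two runs with the same
configuration produce byte-identical outputs.

``calculator`` is the single-subject entry point mirroring the published
web calculator: given an equation set and one person's covariates and
measured diameters it returns the predicted value Yp, corrected value Yc
and, when the set carries reference intervals, the normal / decreased /
increased classification.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import propensity_match, split_ab, split_subjects
from .core import AorticParam, EquationSet, Subject, correct_yc, index_bsa, predict_yp
from .evaluation import (
    EfficacyReport,
    ReferenceInterval,
    assess_efficacy,
    classify_subject,
    efficacy_table,
    reference_interval,
    success_rate,
)
from .io import read_subjects, write_equation_set
from .model import AorticAllometryModel, FitConfig
from .synthetic import PopulationSpec, generate_population

__all__ = ["PipelineConfig", "PipelineBundle", "run_pipeline", "calculator"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    specs: Sequence[PopulationSpec] = ()
    tables: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0
    ratio: float = 0.7
    fit: FitConfig = field(default_factory=FitConfig)
    match: bool = False
    caliper_sd: float | None = None
    pool_combined: bool = True
    combined_name: str = "combined"
    interval_method: str = "percentile"

    def __post_init__(self) -> None:
        if not (0.0 < self.ratio < 1.0):
            raise ValueError(
                f"split ratio must lie strictly in (0, 1) so the validation "
                f"group is non-empty, got {self.ratio}"
            )
        if not self.specs and not self.tables:
            raise ValueError("config must name population specs or subject tables")


@dataclass
class PipelineBundle:
    """All artifacts of one run, with convenience accessors."""

    cohorts: dict[str, list[Subject]]
    splits: dict[str, object]
    equation_sets: dict[str, EquationSet]
    reports: list[EfficacyReport]
    intervals: dict[str, dict[AorticParam, ReferenceInterval]]
    yc_validation: dict[tuple[str, AorticParam], np.ndarray]
    run_log: dict

    def reports_for(self, method: str) -> list[EfficacyReport]:
        return [r for r in self.reports if r.method == method]

    def success_rate(self, method: str) -> float:
        return success_rate(self.reports_for(method))

    def max_residual_r(self, method: str = "omam") -> float:
        return max(
            abs(e.r) for r in self.reports_for(method) for e in r.residual_entries()
        )

    def mean_yc(self, population: str, param: AorticParam | str) -> float:
        return float(self.yc_validation[(population, AorticParam.coerce(param))].mean())

    def save(self, out_dir: str | Path) -> None:
        """Write the report bundle as JSON/CSV files plus a run log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, eq_set in sorted(self.equation_sets.items()):
            write_equation_set(eq_set, out / f"equations_{name}.json")
        payload = [r.to_dict() for r in self.reports]
        (out / "efficacy.json").write_text(json.dumps(payload, indent=2) + "\n")
        efficacy_table(self.reports).to_csv(out / "efficacy_table.csv", index=False)
        intervals = {
            name: {p.value: iv.to_dict() for p, iv in sorted(ivs.items(), key=lambda kv: kv[0].value)}
            for name, ivs in sorted(self.intervals.items())
        }
        (out / "intervals.json").write_text(json.dumps(intervals, indent=2) + "\n")
        (out / "run_log.json").write_text(json.dumps(self.run_log, indent=2, sort_keys=True) + "\n")


@contextmanager
def _stage(name: str, context: str = ""):
    try:
        yield
    except Exception as exc:
        where = f"{name} ({context})" if context else name
        raise RuntimeError(f"pipeline stage {where!r} failed: {exc}") from exc


def _derived_seeds(master: int, names: Sequence[str]) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(len(names))
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Execute the full workflow described by ``config``."""
    pop_names = [s.name for s in config.specs] + list(config.tables)
    seed_names = [f"generate:{n}" for n in pop_names] + ["match"] + [
        f"split:{n}" for n in [*pop_names, config.combined_name]
    ]
    seeds = _derived_seeds(config.seed, seed_names)

    cohorts: dict[str, list[Subject]] = {}
    for spec in config.specs:
        with _stage("generate", spec.name):
            cohorts[spec.name] = generate_population(spec, seed=seeds[f"generate:{spec.name}"])
    for name, path in config.tables.items():
        with _stage("load", name):
            cohorts[name] = read_subjects(path)

    match_result = None
    if config.match:
        if len(cohorts) < 2:
            raise RuntimeError("pipeline stage 'match' failed: needs two populations")
        first, second = list(cohorts)[:2]
        with _stage("match", f"{first} vs {second}"):
            match_result = propensity_match(
                cohorts[first], cohorts[second],
                seed=seeds["match"], caliper_sd=config.caliper_sd,
            )
            ids1, ids2 = match_result.matched_ids()
            cohorts[first] = [s for s in cohorts[first] if s.id in set(ids1)]
            cohorts[second] = [s for s in cohorts[second] if s.id in set(ids2)]

    if config.pool_combined and len(cohorts) >= 2:
        pooled = [s for name in cohorts for s in cohorts[name]]
        cohorts = {**cohorts, config.combined_name: pooled}

    splits: dict[str, object] = {}
    equation_sets: dict[str, EquationSet] = {}
    reports: list[EfficacyReport] = []
    intervals: dict[str, dict[AorticParam, ReferenceInterval]] = {}
    yc_validation: dict[tuple[str, AorticParam], np.ndarray] = {}

    for name, cohort in cohorts.items():
        with _stage("split", name):
            split = split_ab(cohort, ratio=config.ratio, seed=seeds[f"split:{name}"])
            group_a, group_b = split_subjects(cohort, split)
            splits[name] = split

        fitted: dict[AorticParam, object] = {}
        pop_intervals: dict[AorticParam, ReferenceInterval] = {}
        for param in AorticParam:
            with _stage("fit", f"{name}/{param.value}"):
                results = AorticAllometryModel(group_a, param, config.fit).fit()
                fitted[param] = results.equation

            with _stage("evaluate", f"{name}/{param.value}"):
                yu_b = np.array([s.dims[param] for s in group_b])
                yc_b = results.correct(group_b)
                yc_validation[(name, param)] = yc_b
                reports.append(
                    assess_efficacy(yc_b, yu_b, group_b, param, population=name, method="omam")
                )
                bsa_b = np.array([index_bsa(s.dims[param], s.bsa) for s in group_b])
                reports.append(
                    assess_efficacy(bsa_b, yu_b, group_b, param, population=name, method="bsa")
                )

            with _stage("reference_interval", f"{name}/{param.value}"):
                yc_full = np.array(
                    [correct_yc(s.dims[param], predict_yp(fitted[param], s)) for s in cohort]
                )
                pop_intervals[param] = reference_interval(yc_full, method=config.interval_method)

        equation_sets[name] = EquationSet(
            population=name, equations=fitted, intervals=pop_intervals
        )
        intervals[name] = pop_intervals

    run_log = {
        "seed": config.seed,
        "derived_seeds": seeds,
        "ratio": config.ratio,
        "p_enter": config.fit.p_enter,
        "p_remove": config.fit.p_remove,
        "interval_method": config.interval_method,
        "match": config.match,
        "populations": {name: len(c) for name, c in cohorts.items()},
        "match_pairs": match_result.n_pairs if match_result else None,
    }
    return PipelineBundle(
        cohorts=cohorts,
        splits=splits,
        equation_sets=equation_sets,
        reports=reports,
        intervals=intervals,
        yc_validation=yc_validation,
        run_log=run_log,
    )


def calculator(
    eq_set: EquationSet,
    gender: int,
    age: float,
    height: float | None = None,
    weight: float | None = None,
    dims: Mapping[AorticParam | str, float] | None = None,
) -> dict[str, dict]:
    """Single-subject predicted/corrected values and classification.

    Returns, per measured parameter, ``{"yp": ..., "yc": ...,
    "classification": ...}``; the classification is ``"unavailable"``
    when the equation set carries no reference interval for a parameter.
    """
    if not dims:
        raise ValueError("at least one measured aortic dimension is required")
    out: dict[str, dict] = {}
    for key, measured in dims.items():
        param = AorticParam.coerce(key)
        if measured is None:
            continue
        if measured <= 0:
            raise ValueError(f"measured {param.value} must be positive, got {measured}")
        eq = eq_set[param]
        yp = eq.predict(gender, age, height, weight)
        yc = correct_yc(measured, yp)
        interval = eq_set.interval_for(param)
        out[param.value] = {
            "yp": yp,
            "yc": yc,
            "classification": classify_subject(yc, interval) if interval else "unavailable",
        }
    return out
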
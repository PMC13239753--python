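"""Correction-efficacy machinery.

A body-size correction of an aortic diameter is judged successful when

1. the corrected values show no residual correlation with any
   physiological variable (age, height, weight, BSA, BMI) that is both
   biologically relevant (|r| > 0.20) and statistically significant
   (p < 0.05), and
2. the corrected values remain significantly correlated (p < 0.05) with
   the uncorrected measurements, i.e. the correction rescales rather than
   destroys the signal.

Independently of that success gate, each residual correlation is annotated
as *overcorrected* (r < 0, p < 0.05), *undercorrected* (r > 0, p < 0.05)
or *acceptable*.  The annotation and the gate are deliberately separate
layers: a small but significant negative correlation (say r = -0.13,
p = 0.03) is labelled overcorrected yet does not fail criterion 1, because
|r| <= 0.20 is biologically negligible.

The module also hosts the descriptive comparisons used around that gate
(two-sample t-test between genders, one-way ANOVA across age groups) and
reference-interval estimation for corrected values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MAN, WOMAN, AorticParam, Subject

__all__ = [
    "CorrelationEntry",
    "EfficacyReport",
    "ReferenceInterval",
    "RESIDUAL_VARIABLES",
    "pearson_with_p",
    "residual_profile",
    "classify_residual",
    "assess_efficacy",
    "success_rate",
    "gender_difference_test",
    "age_group_anova",
    "reference_interval",
    "classify_subject",
    "efficacy_table",
    "format_p",
]

#: Residual-correlation gate: a variable fails when BOTH hold.
R_BIOLOGICAL = 0.20
P_SIGNIFICANT = 0.05

#: Physiological variables profiled against corrected values.
RESIDUAL_VARIABLES = ("age", "height", "weight", "bsa", "bmi")


@dataclass(frozen=True)
class CorrelationEntry:
    """Pearson correlation of corrected values with one variable."""

    variable: str
    r: float
    p: float
    n: int


@dataclass
class ReferenceInterval:
    """Normal limits for corrected values: mean +/- SD and a central-95% range."""

    mean: float
    sd: float
    lower: float
    upper: float
    method: str
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (self.lower < self.mean < self.upper):
            raise ValueError(
                f"invalid interval: lower={self.lower}, mean={self.mean}, upper={self.upper}"
            )

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "lower": self.lower,
            "upper": self.upper,
            "method": self.method,
            "n": self.n,
            "degenerate": self.degenerate,
        }


@dataclass
class EfficacyReport:
    """Residual-correlation profile and success verdict for one
    parameter x population x correction method."""

    param: AorticParam
    population: str
    method: str  # "omam" or "bsa"
    entries: list[CorrelationEntry]
    classification: dict[str, str] = field(default_factory=dict)
    criterion1_pass: bool = False
    criterion2_pass: bool = False

    @property
    def success(self) -> bool:
        return self.criterion1_pass and self.criterion2_pass

    @property
    def uncorrected_entry(self) -> CorrelationEntry | None:
        for e in self.entries:
            if e.variable == "uncorrected":
                return e
        return None

    def residual_entries(self) -> list[CorrelationEntry]:
        return [e for e in self.entries if e.variable in RESIDUAL_VARIABLES]

    def to_dict(self) -> dict:
        return {
            "param": self.param.value,
            "population": self.population,
            "method": self.method,
            "entries": [
                {"variable": e.variable, "r": e.r, "p": e.p, "n": e.n} for e in self.entries
            ],
            "classification": dict(self.classification),
            "criterion1_pass": self.criterion1_pass,
            "criterion2_pass": self.criterion2_pass,
            "success": self.success,
        }


def pearson_with_p(
    xs: Sequence[float], ys: Sequence[float], variable: str = ""
) -> CorrelationEntry:
    """Pearson r with a two-sided p-value from the t distribution (n-2 df)."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series must be 1-d and equal length, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant series")
    res = stats.pearsonr(x, y)
    return CorrelationEntry(variable=variable, r=float(res.statistic), p=float(res.pvalue), n=x.size)


def _covariate_frame(subjects: Sequence[Subject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [s.age for s in subjects],
            "height": [s.height for s in subjects],
            "weight": [s.weight for s in subjects],
            "bsa": [s.bsa for s in subjects],
            "bmi": [s.bmi for s in subjects],
        }
    )


def residual_profile(
    values: Sequence[float],
    subjects: Sequence[Subject],
    uncorrected: Sequence[float] | None = None,
) -> list[CorrelationEntry]:
    """Correlations of corrected values with age, height, weight, BSA, BMI,
    plus (when ``uncorrected`` is given) the corrected-vs-uncorrected entry."""
    vals = np.asarray(values, dtype=float)
    if len(vals) != len(subjects):
        raise ValueError(f"{len(vals)} values for {len(subjects)} subjects")
    cov = _covariate_frame(subjects)
    entries = [pearson_with_p(cov[v].to_numpy(), vals, variable=v) for v in RESIDUAL_VARIABLES]
    if uncorrected is not None:
        entries.insert(0, pearson_with_p(np.asarray(uncorrected, float), vals, "uncorrected"))
    return entries


def classify_residual(entry: CorrelationEntry) -> str:
    """Over-/under-correction annotation for one residual correlation."""
    if entry.p < P_SIGNIFICANT:
        if entry.r < 0:
            return "overcorrected"
        if entry.r > 0:
            return "undercorrected"
    return "acceptable"


def assess_efficacy(
    corrected: Sequence[float],
    uncorrected: Sequence[float],
    subjects: Sequence[Subject],
    param: AorticParam | str,
    population: str = "",
    method: str = "omam",
) -> EfficacyReport:
    """Profile residual correlations and apply both success criteria."""
    entries = residual_profile(corrected, subjects, uncorrected=uncorrected)
    residuals = [e for e in entries if e.variable in RESIDUAL_VARIABLES]
    criterion1 = all(
        not (abs(e.r) > R_BIOLOGICAL and e.p < P_SIGNIFICANT) for e in residuals
    )
    unc = next(e for e in entries if e.variable == "uncorrected")
    criterion2 = unc.p < P_SIGNIFICANT
    return EfficacyReport(
        param=AorticParam.coerce(param),
        population=population,
        method=method,
        entries=entries,
        classification={e.variable: classify_residual(e) for e in residuals},
        criterion1_pass=criterion1,
        criterion2_pass=criterion2,
    )


def success_rate(reports: Iterable[EfficacyReport]) -> float:
    """Percentage of reports whose correction met both criteria."""
    reports = list(reports)
    if not reports:
        raise ValueError("success_rate requires at least one report")
    return 100.0 * sum(r.success for r in reports) / len(reports)


def gender_difference_test(
    values: Sequence[float], genders: Sequence[int], welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test of men vs women; returns (mean_men, mean_women, p).

    The pooled-variance (Student) form is the default; set ``welch=True``
    for unequal variances.  Identical degenerate groups (zero variance,
    equal means) return p = 1.
    """
    vals = np.asarray(values, dtype=float)
    gen = np.asarray(genders)
    men = vals[gen == MAN]
    women = vals[gen == WOMAN]
    if men.size < 2 or women.size < 2:
        raise ValueError(
            f"both genders need n >= 2, got {men.size} men and {women.size} women"
        )
    mean_men, mean_women = float(men.mean()), float(women.mean())
    if np.ptp(men) == 0 and np.ptp(women) == 0:
        p = 1.0 if mean_men == mean_women else 0.0
        return mean_men, mean_women, p
    res = stats.ttest_ind(men, women, equal_var=not welch)
    return mean_men, mean_women, float(res.pvalue)


def age_group_anova(
    values: Sequence[float], age_groups: Sequence[str]
) -> tuple[float, float]:
    """One-way ANOVA of values across age groups; returns (F, p)."""
    vals = np.asarray(values, dtype=float)
    labels = np.asarray(age_groups)
    groups = [vals[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2 each")
    if np.ptp(vals) == 0:
        return 0.0, 1.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def reference_interval(
    values: Sequence[float], method: str = "percentile"
) -> ReferenceInterval:
    """Reference limits for corrected values.

    ``percentile`` (default) takes the empirical 2.5th / 97.5th percentiles
    and requires n >= 40; ``normal_theory`` uses mean +/- 1.96 SD and
    requires n >= 2.  A constant series yields a degenerate, flagged
    interval.
    """
    vals = np.asarray(values, dtype=float)
    if method not in ("percentile", "normal_theory"):
        raise ValueError(f"unknown method {method!r}")
    n_min = 40 if method == "percentile" else 2
    if vals.size < n_min:
        raise ValueError(f"method {method!r} requires n >= {n_min}, got {vals.size}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if np.ptp(vals) == 0:
        return ReferenceInterval(mean, 0.0, mean, mean, method, vals.size, degenerate=True)
    if method == "percentile":
        lower, upper = (float(q) for q in np.percentile(vals, [2.5, 97.5]))
    else:
        lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
    return ReferenceInterval(mean, sd, lower, upper, method, int(vals.size))


def classify_subject(yc: float, interval: ReferenceInterval) -> str:
    """Classify a corrected value against reference limits (closed bounds:
    a value equal to a limit counts as normal)."""
    if yc < interval.lower:
        return "decreased"
    if yc > interval.upper:
        return "increased"
    return "normal"


def format_p(p: float, ndigits: int = 3) -> str:
    """Report-style p-value formatting: values below 0.001 print as '<0.001'."""
    if p < 10 ** -ndigits:
        return f"<{10 ** -ndigits:.{ndigits}f}"
    return f"{p:.{ndigits}f}"


def efficacy_table(reports: Sequence[EfficacyReport]) -> pd.DataFrame:
    """Delimited-table view of efficacy reports: one row per indexation,
    'r, p' cells for the uncorrected and each physiological variable."""
    rows = []
    for rep in reports:
        row: dict[str, str] = {
            "indexation": f"{rep.param.value} [{rep.method}, {rep.population}]",
        }
        for e in rep.entries:
            row[e.variable] = f"{e.r:.3f}, {format_p(e.p)}"
        row["success"] = "yes" if rep.success else "no"
        rows.append(row)
    cols = ["indexation", "uncorrected", *RESIDUAL_VARIABLES, "success"]
    return pd.DataFrame(rows, columns=cols)
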
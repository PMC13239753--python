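"""Fitting allometric equations by stepwise log-linear regression.

Taking logs of the multiplicative model gives a linear regression

    ln(Yu) = ln(a) + gender*ln(b) + x*ln(age) + y*ln(height) + z*ln(weight) + e,

with e ~ N(0, sigma^2), i.e. multiplicative lognormal measurement error.
Candidate terms are selected by forward stepwise regression with backward
elimination: at each step the most significant not-yet-included candidate
enters if its coefficient p-value (two-sided t-test when added to the
current model) is below ``p_enter``; after every entry, any included term
whose p-value has risen to ``p_remove`` or above is dropped; iteration
continues to a fixed point.  The intercept is always retained.  Ties in
entry p-values break toward the fixed candidate order (gender, ln age,
ln height, ln weight) so fits are deterministic.

BMI and BSA are never candidates: both are functions of height and weight
and would confound the original covariates.

The public surface follows the statsmodels idiom: build an
:class:`AorticAllometryModel` from subjects or a DataFrame, call
:meth:`~AorticAllometryModel.fit`, and read the estimates, uncertainties
and back-transformed :class:`~aortanorm.core.AllometricEquation` off the
returned :class:`AorticAllometryResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import AllometricEquation, AorticParam, Subject

__all__ = [
    "TERM_ORDER",
    "FitConfig",
    "FitResult",
    "build_log_design",
    "fit_ols",
    "stepwise_fit",
    "AorticAllometryModel",
    "AorticAllometryResults",
]

#: Fixed candidate order; also the tie-break order at entry.
TERM_ORDER = ("gender", "ln_age", "ln_height", "ln_weight")

_TERM_TO_EXPONENT = {"ln_age": "x", "ln_height": "y", "ln_weight": "z"}


@dataclass(frozen=True)
class FitConfig:
    """Stepwise-selection thresholds and candidate pool.

    Defaults (p_enter = 0.05, p_remove = 0.10) are the conventional
    stepwise defaults of mainstream statistical packages.
    """

    p_enter: float = 0.05
    p_remove: float = 0.10
    candidates: tuple[str, ...] = TERM_ORDER
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.p_enter < 1.0):
            raise ValueError(f"p_enter must lie in (0, 1), got {self.p_enter}")
        if self.p_remove < self.p_enter:
            raise ValueError(
                f"p_remove ({self.p_remove}) must be >= p_enter ({self.p_enter})"
            )
        unknown = set(self.candidates) - set(TERM_ORDER)
        if unknown:
            raise ValueError(f"unknown candidate terms: {sorted(unknown)}")


@dataclass
class LogFit:
    """OLS fit on the log scale for one term subset (intercept always included)."""

    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma: float
    rsquared: float
    nobs: int
    sm_results: object = field(repr=False, default=None)


@dataclass
class FitResult:
    """Outcome of a stepwise fit: the back-transformed equation plus the
    log-scale coefficient table, residual SD and fit statistics."""

    equation: AllometricEquation
    coef_table: pd.DataFrame
    sigma: float
    rsquared: float
    nobs: int
    selected: tuple[str, ...]


def build_log_design(
    subjects: Sequence[Subject], param: AorticParam | str
) -> pd.DataFrame:
    """Log-transformed regression table for one aortic parameter.

    Columns: ``ln_y`` (response, ln Yu), ``gender`` (0/1), ``ln_age``,
    ``ln_height``, ``ln_weight``.  The parameter label is stored in
    ``DataFrame.attrs['param']``.
    """
    param = AorticParam.coerce(param)
    if len(subjects) == 0:
        raise ValueError("cannot build a design from an empty subject list")
    rows = []
    for s in subjects:
        if s.age <= 0 or s.height <= 0 or s.weight <= 0:
            raise ValueError(f"subject {s.id!r} has a non-positive covariate")
        yu = s.dims.get(param)
        if yu is None:
            raise ValueError(f"subject {s.id!r} lacks a {param.value} measurement")
        if yu <= 0:
            raise ValueError(f"subject {s.id!r} has non-positive {param.value} = {yu}")
        rows.append(
            {
                "ln_y": math.log(yu),
                "gender": float(s.gender),
                "ln_age": math.log(s.age),
                "ln_height": math.log(s.height),
                "ln_weight": math.log(s.weight),
            }
        )
    table = pd.DataFrame(rows, index=[s.id for s in subjects])
    table.attrs["param"] = param.value
    return table


def fit_ols(table: pd.DataFrame, terms: Sequence[str]) -> LogFit:
    """OLS of ln_y on the given terms plus an intercept.

    p-values are two-sided t-tests on the coefficients.  Raises on a
    rank-deficient design or when n <= len(terms) + 1.
    """
    terms = tuple(terms)
    n = len(table)
    if n <= len(terms) + 1:
        raise ValueError(f"need n > {len(terms) + 1} observations, got {n}")
    X = sm.add_constant(table[list(terms)].to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design is rank-deficient for terms {terms}")
    res = sm.OLS(table["ln_y"].to_numpy(), X).fit()
    names = ["const", *terms]
    return LogFit(
        terms=terms,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        sigma=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        rsquared=float(res.rsquared),
        nobs=int(res.nobs),
        sm_results=res,
    )


def _usable_candidates(table: pd.DataFrame, candidates: Sequence[str]) -> list[str]:
    # Degenerate columns (e.g. a single-gender cohort) are silently dropped.
    return [
        c for c in TERM_ORDER
        if c in candidates and table[c].nunique() > 1
    ]


def entry_pvalue(table: pd.DataFrame, selected: Sequence[str], candidate: str) -> float:
    """p-value of ``candidate``'s coefficient when added to the current model."""
    fit = fit_ols(table, [*selected, candidate])
    return float(fit.pvalues[candidate])


def stepwise_fit(
    table: pd.DataFrame,
    config: FitConfig | None = None,
    param: AorticParam | str | None = None,
) -> FitResult:
    """Forward stepwise selection with backward elimination, to a fixed point.

    The result is back-transformed into an :class:`AllometricEquation`:
    a = exp(intercept), b = exp(gender coefficient) (1 if gender was not
    retained), exponents = retained log-covariate coefficients (0 if not
    retained).
    """
    config = config or FitConfig()
    if param is None:
        param = table.attrs.get("param")
    if param is None:
        raise ValueError("aortic parameter must be given (or stored in table.attrs)")
    param = AorticParam.coerce(param)

    candidates = _usable_candidates(table, config.candidates)
    selected: list[str] = []
    for _ in range(config.max_iterations):
        changed = False
        # Entry: most significant remaining candidate with p < p_enter;
        # ties keep the earlier term in TERM_ORDER (strict < on p).
        best: tuple[str, float] | None = None
        for cand in candidates:
            if cand in selected:
                continue
            p = entry_pvalue(table, selected, cand)
            if p < config.p_enter and (best is None or p < best[1]):
                best = (cand, p)
        if best is not None:
            selected.append(best[0])
            selected.sort(key=TERM_ORDER.index)
            changed = True
        # Elimination: repeatedly drop the worst included term with p >= p_remove.
        while selected:
            fit = fit_ols(table, selected)
            pvals = fit.pvalues[list(selected)]
            worst = pvals.idxmax()
            if float(pvals[worst]) >= config.p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    else:
        raise RuntimeError(
            f"stepwise selection did not converge in {config.max_iterations} iterations"
        )

    final = fit_ols(table, selected)
    coef = final.params
    eq = AllometricEquation(
        param=param,
        a=math.exp(float(coef["const"])),
        b=math.exp(float(coef["gender"])) if "gender" in selected else 1.0,
        x=float(coef.get("ln_age", 0.0)),
        y=float(coef.get("ln_height", 0.0)),
        z=float(coef.get("ln_weight", 0.0)),
        provenance="fitted",
    )
    coef_table = pd.DataFrame(
        {
            "estimate": final.params,
            "se": final.bse,
            "p": final.pvalues,
        }
    )
    return FitResult(
        equation=eq,
        coef_table=coef_table,
        sigma=final.sigma,
        rsquared=final.rsquared,
        nobs=final.nobs,
        selected=tuple(selected),
    )


class AorticAllometryModel:
    """Allometric scaling model for one aortic parameter on a cohort.

    Parameters
    ----------
    subjects : sequence of Subject
        Training cohort; every subject must carry the measurement.
    param : AorticParam or str
        Which diameter to model ("ao_a", "ao_s" or "ao_asc").
    config : FitConfig, optional
        Stepwise-selection settings.

    Examples
    --------
    >>> model = AorticAllometryModel(cohort, "ao_a")       # doctest: +SKIP
    >>> results = model.fit()                              # doctest: +SKIP
    >>> results.equation.formula()                         # doctest: +SKIP
    """

    def __init__(
        self,
        subjects: Sequence[Subject],
        param: AorticParam | str,
        config: FitConfig | None = None,
    ):
        self.param = AorticParam.coerce(param)
        self.subjects = list(subjects)
        self.config = config or FitConfig()
        self.design = build_log_design(self.subjects, self.param)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        param: AorticParam | str,
        config: FitConfig | None = None,
    ) -> "AorticAllometryModel":
        """Build from a subject table (columns as written by
        :func:`aortanorm.io.write_subjects`)."""
        from .io import subjects_from_dataframe

        return cls(subjects_from_dataframe(data), param, config)

    def fit(self) -> "AorticAllometryResults":
        return AorticAllometryResults(self, stepwise_fit(self.design, self.config, self.param))


class AorticAllometryResults:
    """Fitted allometric equation with its log-scale inference."""

    def __init__(self, model: AorticAllometryModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    @property
    def equation(self) -> AllometricEquation:
        return self.fit_result.equation

    @property
    def params(self) -> pd.Series:
        """Log-scale coefficients (intercept = ln a)."""
        return self.fit_result.coef_table["estimate"]

    @property
    def bse(self) -> pd.Series:
        return self.fit_result.coef_table["se"]

    @property
    def pvalues(self) -> pd.Series:
        return self.fit_result.coef_table["p"]

    @property
    def sigma(self) -> float:
        """Residual SD on the log scale (the multiplicative noise scale)."""
        return self.fit_result.sigma

    @property
    def rsquared(self) -> float:
        return self.fit_result.rsquared

    @property
    def nobs(self) -> int:
        return self.fit_result.nobs

    def predict(self, subjects: Sequence[Subject]) -> np.ndarray:
        """Predicted diameters Yp (mm)."""
        eq = self.equation
        return np.array([eq.predict(s.gender, s.age, s.height, s.weight) for s in subjects])

    def correct(self, subjects: Sequence[Subject]) -> np.ndarray:
        """Corrected ratios Yc = Yu / Yp for subjects carrying the measurement."""
        yp = self.predict(subjects)
        yu = np.array([s.dims[self.model.param] for s in subjects])
        return yu / yp

    def summary(self) -> str:
        fr = self.fit_result
        lines = [
            f"Allometric scaling model: {self.model.param.value}",
            f"n = {fr.nobs}, R^2 = {fr.rsquared:.3f}, residual log-SD = {fr.sigma:.4f}",
            f"selected terms: {', '.join(fr.selected) if fr.selected else '(intercept only)'}",
            f"equation: {self.model.param.value} = {fr.equation.formula()}",
            "",
            fr.coef_table.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<AorticAllometryResults {self.model.param.value} "
            f"n={self.nobs} terms={self.fit_result.selected}>"
        )
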
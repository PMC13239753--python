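"""Built-in published allometric equation sets.

Three read-only equation sets ship with the package, as reported by the
international multicenter reference study that fitted them: one from a
Chinese healthy-adult cohort, one from an Italian cohort, and one from the
pooled (combined) cohort (n = 910 per population, ages 18-79, BMI < 30).
Each set carries one equation per aortic parameter; the Chinese and
Italian sets additionally carry the published 95% reference intervals of
the corrected values, which the calculator uses to classify a subject's
corrected diameter as decreased / normal / increased.

These constants are reference data, not fitted at run time; use
:mod:`aortanorm.model` to fit new equations to your own cohort.
"""

from __future__ import annotations

from .core import AllometricEquation, AorticParam, EquationSet
from .evaluation import ReferenceInterval

__all__ = ["CHINESE", "ITALIAN", "COMBINED", "BUILTIN_SETS", "builtin_set"]

_N_REFERENCE = 910


def _interval(mean: float, sd: float, lower: float, upper: float) -> ReferenceInterval:
    return ReferenceInterval(
        mean=mean, sd=sd, lower=lower, upper=upper, method="published", n=_N_REFERENCE
    )


CHINESE = EquationSet(
    population="chinese",
    equations={
        AorticParam.AO_A: AllometricEquation(
            AorticParam.AO_A, a=9.593, b=0.943, x=0.054, z=0.142, provenance="published:chinese"
        ),
        AorticParam.AO_S: AllometricEquation(
            AorticParam.AO_S, a=8.085, b=0.949, x=0.113, z=0.210, provenance="published:chinese"
        ),
        AorticParam.AO_ASC: AllometricEquation(
            AorticParam.AO_ASC, a=5.028, b=0.966, x=0.161, z=0.261, provenance="published:chinese"
        ),
    },
    intervals={
        AorticParam.AO_A: _interval(1.002, 0.112, 0.794, 1.246),
        AorticParam.AO_S: _interval(1.003, 0.105, 0.792, 1.213),
        AorticParam.AO_ASC: _interval(1.006, 0.122, 0.747, 1.262),
    },
)

ITALIAN = EquationSet(
    population="italian",
    equations={
        AorticParam.AO_A: AllometricEquation(
            AorticParam.AO_A, a=1.042, b=0.944, x=0.054, y=0.472, z=0.081,
            provenance="published:italian",
        ),
        AorticParam.AO_S: AllometricEquation(
            AorticParam.AO_S, a=2.268, b=0.925, x=0.164, y=0.317, z=0.090,
            provenance="published:italian",
        ),
        AorticParam.AO_ASC: AllometricEquation(
            AorticParam.AO_ASC, a=6.385, b=0.956, x=0.204, z=0.175,
            provenance="published:italian",
        ),
    },
    intervals={
        AorticParam.AO_A: _interval(1.007, 0.086, 0.854, 1.188),
        AorticParam.AO_S: _interval(1.004, 0.090, 0.834, 1.185),
        AorticParam.AO_ASC: _interval(1.006, 0.099, 0.802, 1.195),
    },
)

COMBINED = EquationSet(
    population="combined",
    equations={
        AorticParam.AO_A: AllometricEquation(
            AorticParam.AO_A, a=2.948, b=0.928, x=0.060, y=0.338,
            provenance="published:combined",
        ),
        AorticParam.AO_S: AllometricEquation(
            AorticParam.AO_S, a=2.689, b=0.950, x=0.137, y=0.210, z=0.198,
            provenance="published:combined",
        ),
        AorticParam.AO_ASC: AllometricEquation(
            AorticParam.AO_ASC, a=4.375, b=0.974, x=0.180, z=0.280,
            provenance="published:combined",
        ),
    },
)

BUILTIN_SETS: dict[str, EquationSet] = {
    "chinese": CHINESE,
    "italian": ITALIAN,
    "combined": COMBINED,
}


def builtin_set(name: str) -> EquationSet:
    """Return a built-in equation set by population name."""
    try:
        return BUILTIN_SETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown equation set {name!r}; available: {sorted(BUILTIN_SETS)}"
        ) from None
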
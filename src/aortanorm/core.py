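"""Core allometric model arithmetic for aortic root dimensions.

Aortic root diameters (annulus, sinuses of Valsalva, proximal ascending
aorta) in healthy adults vary systematically with gender, age and body
size.  The multivariate allometric model predicts a diameter as a product
of power laws,

    Yp = a * b**gender * age**x * height**y * weight**z,

with gender coded as a dummy (man = 0, woman = 1), so that the corrected
value Yc = Yu / Yp is a dimensionless ratio centred near 1 in a healthy
reference population.  This module holds the subject record, the equation
container and the elementary operations (Du Bois body surface area, BMI,
prediction, correction, ratiometric BSA indexation) that every later stage
builds on.

Units are fixed throughout the package: age in years, height in cm, weight
in kg, diameters in mm.  Callers holding data in other units must convert
at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .evaluation import ReferenceInterval

__all__ = [
    "MAN",
    "WOMAN",
    "AorticParam",
    "Subject",
    "AllometricEquation",
    "EquationSet",
    "compute_bsa",
    "compute_bmi",
    "predict_yp",
    "correct_yc",
    "index_bsa",
]

#: Dummy coding of gender used in every equation and data table.
MAN = 0
WOMAN = 1

#: Eligible age range (years) for reference-cohort subjects.
AGE_MIN = 18.0
AGE_MAX = 79.0

#: Obesity exclusion threshold (kg/m^2); eligible subjects have BMI below it.
BMI_EXCLUSION = 30.0


class AorticParam(str, Enum):
    """The three aortic root diameters measured at end-diastole."""

    AO_A = "ao_a"      #: aortic annulus
    AO_S = "ao_s"      #: sinuses of Valsalva
    AO_ASC = "ao_asc"  #: proximal ascending aorta

    @classmethod
    def coerce(cls, value: "AorticParam | str") -> "AorticParam":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


def compute_bsa(height: float, weight: float) -> float:
    """Body surface area (m^2) by the Du Bois formula.

    BSA = 0.007184 * weight**0.425 * height**0.725, height in cm and
    weight in kg.  Strictly increasing in both arguments.

    Raises
    ------
    ValueError
        If height or weight is not strictly positive.
    """
    if height <= 0 or weight <= 0:
        raise ValueError(
            f"height and weight must be positive, got height={height}, weight={weight}"
        )
    return 0.007184 * weight**0.425 * height**0.725


def compute_bmi(height: float, weight: float) -> float:
    """Body mass index (kg/m^2) from height in cm and weight in kg."""
    if height <= 0:
        raise ValueError(f"height must be positive, got {height}")
    return weight / (height / 100.0) ** 2


@dataclass
class Subject:
    """One person's demographics and measured aortic diameters.

    ``dims`` maps :class:`AorticParam` to the measured (uncorrected)
    diameter Yu in mm.  Blood pressures are optional and descriptive only.
    """

    id: str
    population: str
    gender: int
    age: float
    height: float
    weight: float
    sbp: float | None = None
    dbp: float | None = None
    dims: dict[AorticParam, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in (MAN, WOMAN):
            raise ValueError(f"gender must be {MAN} (man) or {WOMAN} (woman), got {self.gender}")
        self.dims = {AorticParam.coerce(k): float(v) for k, v in self.dims.items()}

    @property
    def bmi(self) -> float:
        return compute_bmi(self.height, self.weight)

    @property
    def bsa(self) -> float:
        return compute_bsa(self.height, self.weight)

    def eligibility_errors(self) -> list[str]:
        """Violations of the reference-cohort inclusion rules, empty if eligible.

        Eligible subjects are 18-79 years old, non-obese (BMI < 30 kg/m^2)
        and carry positive covariates and measurements.
        """
        errs: list[str] = []
        if self.height <= 0:
            errs.append(f"height must be positive (got {self.height})")
        if self.weight <= 0:
            errs.append(f"weight must be positive (got {self.weight})")
        if not (AGE_MIN <= self.age <= AGE_MAX):
            errs.append(f"age must lie in [{AGE_MIN:g}, {AGE_MAX:g}] (got {self.age})")
        if self.height > 0 and self.weight > 0 and self.bmi >= BMI_EXCLUSION:
            errs.append(f"BMI must be < {BMI_EXCLUSION:g} (got {self.bmi:.1f})")
        for param, value in self.dims.items():
            if value <= 0:
                errs.append(f"{param.value} must be positive (got {value})")
        return errs

    @property
    def is_eligible(self) -> bool:
        return not self.eligibility_errors()


@dataclass(frozen=True)
class AllometricEquation:
    """Coefficients of one allometric prediction equation.

    ``a`` is the scaling constant (mm), ``b`` the multiplicative gender
    factor applied as ``b**gender``, and ``x``, ``y``, ``z`` the exponents
    of age, height and weight.  A covariate excluded from the model is
    represented by an exponent of exactly 0 (gender exclusion by b = 1).
    """

    param: AorticParam
    a: float
    b: float = 1.0
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "param", AorticParam.coerce(self.param))
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"a and b must be positive, got a={self.a}, b={self.b}")

    def predict(
        self,
        gender: int,
        age: float,
        height: float | None = None,
        weight: float | None = None,
    ) -> float:
        """Evaluate Yp (mm) for the given covariates.

        Covariates whose exponent is 0 may be omitted; a missing covariate
        required by a nonzero exponent raises ``ValueError``.
        """
        if gender not in (MAN, WOMAN):
            raise ValueError(f"gender must be {MAN} or {WOMAN}, got {gender}")
        if age <= 0:
            raise ValueError(f"age must be positive, got {age}")
        yp = self.a * self.b**gender * age**self.x
        for exponent, value, name in ((self.y, height, "height"), (self.z, weight, "weight")):
            if exponent != 0.0:
                if value is None:
                    raise ValueError(f"equation for {self.param.value} requires {name}")
                if value <= 0:
                    raise ValueError(f"{name} must be positive, got {value}")
                yp *= value**exponent
        return yp

    def formula(self, ndigits: int = 3) -> str:
        """Human-readable product form, e.g. ``9.593 x 0.943^gender x age^0.054 ...``."""
        parts = [f"{self.a:.{ndigits}f}"]
        if self.b != 1.0:
            parts.append(f"{self.b:.{ndigits}f}^gender")
        for exponent, name in ((self.x, "age"), (self.y, "height"), (self.z, "weight")):
            if exponent != 0.0:
                parts.append(f"{name}^{exponent:.{ndigits}f}")
        return " x ".join(parts)


def predict_yp(eq: AllometricEquation, subject: Subject) -> float:
    """Predicted diameter Yp (mm) for ``subject`` under equation ``eq``."""
    return eq.predict(subject.gender, subject.age, subject.height, subject.weight)


def correct_yc(yu: float, yp: float) -> float:
    """Corrected value Yc = Yu / Yp (dimensionless)."""
    if yp <= 0:
        raise ValueError(f"predicted value must be positive, got {yp}")
    return yu / yp


def index_bsa(yu: float, bsa: float) -> float:
    """Ratiometric (isometric) indexation Yu / BSA in mm/m^2."""
    if bsa <= 0:
        raise ValueError(f"BSA must be positive, got {bsa}")
    return yu / bsa


@dataclass
class EquationSet:
    """One population's equation per aortic parameter, optionally with
    reference intervals for the corrected values."""

    population: str
    equations: dict[AorticParam, AllometricEquation]
    intervals: dict[AorticParam, "ReferenceInterval"] | None = None

    def __post_init__(self) -> None:
        self.equations = {AorticParam.coerce(k): v for k, v in self.equations.items()}
        missing = [p.value for p in AorticParam if p not in self.equations]
        if missing:
            raise ValueError(f"equation set for {self.population!r} missing: {missing}")
        if self.intervals is not None:
            self.intervals = {AorticParam.coerce(k): v for k, v in self.intervals.items()}

    def __getitem__(self, param: AorticParam | str) -> AllometricEquation:
        return self.equations[AorticParam.coerce(param)]

    def interval_for(self, param: AorticParam | str) -> "ReferenceInterval | None":
        if self.intervals is None:
            return None
        return self.intervals.get(AorticParam.coerce(param))


def geometric_mean(values) -> float:
    """Geometric mean of a positive sequence (helper used across modules)."""
    arr = [float(v) for v in values]
    if not arr or any(v <= 0 for v in arr):
        raise ValueError("geometric mean requires a non-empty positive sequence")
    return math.exp(sum(math.log(v) for v in arr) / len(arr))
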
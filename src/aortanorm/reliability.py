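"""Measurement reproducibility: Bland-Altman agreement and ICC.

Repeated echocardiographic measurements of the same subjects (by the same
reader twice, or by two readers) are compared with the Bland-Altman
method -- bias as the mean paired difference and 95% limits of agreement
as bias +/- 1.96 SD of the differences -- and with the intraclass
correlation coefficient.  The default ICC is the two-way random-effects,
absolute-agreement, single-measurement form; the one-way form is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AgreementResult", "bland_altman", "icc", "agreement_analysis", "plot_bland_altman"]

LOA_MULTIPLIER = 1.96


@dataclass
class AgreementResult:
    """Bias, limits of agreement and ICC for one pair of measurement series."""

    bias: float
    loa_lower: float
    loa_upper: float
    icc: float | None
    icc_model: str | None
    n: int


def _paired(m1: Sequence[float], m2: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"series must be 1-d and equal length, got {a.shape} vs {b.shape}")
    return a, b


def bland_altman(m1: Sequence[float], m2: Sequence[float]) -> AgreementResult:
    """Bias and 95% limits of agreement for paired measurements.

    Differences are m1 - m2; the SD uses the n-1 denominator.  Swapping
    the two series negates the bias and mirrors the limits.
    """
    a, b = _paired(m1, m2)
    if a.size < 2:
        raise ValueError(f"need at least 2 paired measurements, got {a.size}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        icc=None,
        icc_model=None,
        n=int(a.size),
    )


def icc(m1: Sequence[float], m2: Sequence[float], model: str = "two_way_agreement") -> float:
    """Intraclass correlation coefficient for two measurement series.

    ``two_way_agreement`` (default) is the two-way random-effects,
    absolute-agreement, single-measurement ICC,

        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n),

    where MSR, MSC and MSE are the row (subject), column (rater) and error
    mean squares of the two-way layout with k = 2 raters.  ``one_way``
    gives (MSB - MSW) / (MSB + (k-1) MSW).
    """
    a, b = _paired(m1, m2)
    n = a.size
    if n < 3:
        raise ValueError(f"ICC needs at least 3 subjects, got {n}")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0:
        raise ValueError("ICC is undefined when between-subject variance is zero")
    if model == "two_way_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        return float((msr - mse) / denom)
    if model == "one_way":
        msw = (ss_cols + ss_err) / (n * (k - 1))
        return float((msr - msw) / (msr + (k - 1) * msw))
    raise ValueError(f"unknown ICC model {model!r}")


def agreement_analysis(
    m1: Sequence[float], m2: Sequence[float], icc_model: str = "two_way_agreement"
) -> AgreementResult:
    """Bland-Altman statistics together with the ICC."""
    result = bland_altman(m1, m2)
    result.icc = icc(m1, m2, model=icc_model)
    result.icc_model = icc_model
    return result


def plot_bland_altman(m1: Sequence[float], m2: Sequence[float], ax=None):
    """Bland-Altman plot: paired means vs differences with bias and LoA lines."""
    import matplotlib.pyplot as plt

    a, b = _paired(m1, m2)
    res = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2, a - b, s=12, alpha=0.7)
    ax.axhline(res.bias, color="k", lw=1, label=f"bias = {res.bias:.2f}")
    for y, label in ((res.loa_lower, "lower LoA"), (res.loa_upper, "upper LoA")):
        ax.axhline(y, color="k", lw=1, ls="--", label=f"{label} = {y:.2f}")
    ax.set_xlabel("mean of paired measurements (mm)")
    ax.set_ylabel("difference (mm)")
    ax.legend(fontsize=8)
    return ax
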
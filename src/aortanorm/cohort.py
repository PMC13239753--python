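"""Cohort construction: propensity matching, 7:3 split, age strata.

Two populations measured in different settings are made demographically
comparable by 1:1 nearest-neighbour propensity-score matching on gender
and age: a binary logistic model on the pooled sample estimates each
subject's probability of belonging to the second population, and subjects
are paired greedily on the logit scale without replacement.  Each matched
population is then split at random into a construction group A (70%) used
to fit equations and a validation group B (30%) used to judge them, and
descriptive analyses stratify age into young (18-40 y), middle-aged
(41-65 y) and elderly (> 65 y) bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import Subject

__all__ = [
    "MatchResult",
    "SplitResult",
    "propensity_match",
    "split_ab",
    "assign_age_group",
]


@dataclass
class MatchResult:
    """1:1 matched pairs (ids) with their propensity distances."""

    pairs: list[tuple[str, str, float]]
    unmatched_pop1: list[str] = field(default_factory=list)
    unmatched_pop2: list[str] = field(default_factory=list)
    caliper: float | None = None
    seed: int | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> tuple[list[str], list[str]]:
        return [p[0] for p in self.pairs], [p[1] for p in self.pairs]

    def to_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "unmatched_pop1": self.unmatched_pop1,
            "unmatched_pop2": self.unmatched_pop2,
            "caliper": self.caliper,
            "seed": self.seed,
        }


@dataclass
class SplitResult:
    """Random partition into construction (A) and validation (B) groups."""

    group_a: list[str]
    group_b: list[str]
    ratio: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "ratio": self.ratio,
            "seed": self.seed,
        }


def _propensity_logits(pop1: Sequence[Subject], pop2: Sequence[Subject]) -> np.ndarray:
    """Fitted logit-scale propensity of pop2 membership, pooled order (pop1 then pop2)."""
    genders = [s.gender for s in pop1] + [s.gender for s in pop2]
    ages = [s.age for s in pop1] + [s.age for s in pop2]
    label = np.r_[np.zeros(len(pop1)), np.ones(len(pop2))]
    X = sm.add_constant(np.column_stack([genders, ages]).astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(label, X, family=sm.families.Binomial()).fit(maxiter=200)
        lp = X @ fit.params
    except Exception as exc:  # noqa: BLE001 - any fit failure gets the same advice
        raise RuntimeError(
            "propensity model failed to fit (perfect separation of the two "
            "populations?); consider exact matching on gender and age instead"
        ) from exc
    if not np.all(np.isfinite(lp)):
        raise RuntimeError(
            "propensity model produced non-finite scores (perfect separation); "
            "consider exact matching on gender and age instead"
        )
    return np.asarray(lp, dtype=float)


def propensity_match(
    pop1: Sequence[Subject],
    pop2: Sequence[Subject],
    seed: int = 0,
    caliper_sd: float | None = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the logit propensity score.

    The smaller population drives the matching, its subjects processed in
    a seeded random order; each is paired with the nearest still-available
    subject of the other population on the logit scale (ties break toward
    the earlier subject in input order).  ``caliper_sd``, if given,
    discards pairs whose distance exceeds ``caliper_sd`` times the pooled
    SD of the logit score (0.2 is the conventional width); by default no
    caliper is applied.
    """
    if not pop1 or not pop2:
        raise ValueError("both populations must be non-empty")
    lp = _propensity_logits(pop1, pop2)
    lp1, lp2 = lp[: len(pop1)], lp[len(pop1):]
    threshold = None
    if caliper_sd is not None:
        threshold = caliper_sd * float(np.std(lp, ddof=1))

    rng = np.random.default_rng(seed)
    driver_is_pop1 = len(pop1) <= len(pop2)
    drv, oth = (lp1, lp2) if driver_is_pop1 else (lp2, lp1)
    order = rng.permutation(len(drv))
    available = np.ones(len(oth), dtype=bool)
    pairs_idx: list[tuple[int, int, float]] = []
    unmatched_driver: list[int] = []
    for i in order:
        dist = np.abs(oth - drv[i])
        dist[~available] = np.inf
        j = int(np.argmin(dist))  # argmin takes the first minimum: stable tie-break
        d = float(dist[j])
        if not np.isfinite(d) or (threshold is not None and d > threshold):
            unmatched_driver.append(i)
            continue
        available[j] = False
        pairs_idx.append((i, j, d))

    ids1 = [s.id for s in pop1]
    ids2 = [s.id for s in pop2]
    if driver_is_pop1:
        pairs = [(ids1[i], ids2[j], d) for i, j, d in pairs_idx]
        un1 = sorted(ids1[i] for i in unmatched_driver)
        un2 = sorted(ids2[j] for j in np.flatnonzero(available))
    else:
        pairs = [(ids1[j], ids2[i], d) for i, j, d in pairs_idx]
        un1 = sorted(ids1[j] for j in np.flatnonzero(available))
        un2 = sorted(ids2[i] for i in unmatched_driver)
    return MatchResult(
        pairs=pairs, unmatched_pop1=un1, unmatched_pop2=un2, caliper=threshold, seed=seed
    )


def split_ab(cohort: Sequence[Subject], ratio: float = 0.7, seed: int = 0) -> SplitResult:
    """Seeded random partition: floor(ratio * n) subjects to group A, rest to B.

    With the default 7:3 ratio a cohort of 910 splits into 637 and 273.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must lie strictly in (0, 1), got {ratio}")
    n = len(cohort)
    if n < 10:
        raise ValueError(f"cohort too small to split meaningfully (n = {n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_a = int(np.floor(ratio * n))
    ids = [s.id for s in cohort]
    return SplitResult(
        group_a=[ids[i] for i in order[:n_a]],
        group_b=[ids[i] for i in order[n_a:]],
        ratio=ratio,
        seed=seed,
    )


def assign_age_group(age: float) -> str:
    """Age stratum: young [18, 40], middle-aged (40, 65], elderly (65, 79].

    Ages are continuous; the band edges are closed on the right so every
    age in [18, 79] maps to exactly one stratum.
    """
    if not (18.0 <= age <= 79.0):
        raise ValueError(f"age {age} outside the eligible range [18, 79]")
    if age <= 40.0:
        return "young"
    if age <= 65.0:
        return "middle"
    return "elderly"


def split_subjects(
    cohort: Sequence[Subject], split: SplitResult
) -> tuple[list[Subject], list[Subject]]:
    """Materialize a SplitResult back into subject lists (A, B)."""
    by_id = {s.id: s for s in cohort}
    return [by_id[i] for i in split.group_a], [by_id[i] for i in split.group_b]
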
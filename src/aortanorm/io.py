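"""Reading and writing subject tables and equation-set files.

Subject tables are UTF-8 comma-separated text with a header row:

    id,population,gender,age,height_cm,weight_kg,ao_a_mm,ao_s_mm,ao_asc_mm[,sbp,dbp]

Gender accepts 0/1 or common tokens (m/man/male -> 0, f/w/woman/female -> 1);
decimals use the '.' separator regardless of locale.  In strict mode (the
default) a row violating the subject invariants aborts the read with a
row-numbered diagnostic; in lenient mode offending rows are skipped and
counted.

Equation sets serialize to JSON as::

    {"population": ..., "equations": [{"param": "ao_a", "a": ..., "b": ...,
     "x": ..., "y": ..., "z": ...}, ...], "intervals": {"ao_a": {...}, ...}}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import AllometricEquation, AorticParam, EquationSet, Subject
from .evaluation import ReferenceInterval

__all__ = [
    "read_subjects",
    "write_subjects",
    "subjects_to_dataframe",
    "subjects_from_dataframe",
    "read_equation_set",
    "write_equation_set",
]

REQUIRED_COLUMNS = (
    "id",
    "population",
    "gender",
    "age",
    "height_cm",
    "weight_kg",
    "ao_a_mm",
    "ao_s_mm",
    "ao_asc_mm",
)
OPTIONAL_COLUMNS = ("sbp", "dbp")

GENDER_TOKENS = {
    "0": 0, "m": 0, "man": 0, "male": 0, "men": 0,
    "1": 1, "f": 1, "w": 1, "woman": 1, "female": 1, "women": 1,
}

_DIM_COLUMNS = {
    AorticParam.AO_A: "ao_a_mm",
    AorticParam.AO_S: "ao_s_mm",
    AorticParam.AO_ASC: "ao_asc_mm",
}


def _parse_gender(token) -> int:
    key = str(token).strip().lower()
    if key not in GENDER_TOKENS:
        raise ValueError(f"unrecognized gender token {token!r}")
    return GENDER_TOKENS[key]


def subjects_from_dataframe(df: pd.DataFrame, strict: bool = True) -> list[Subject]:
    """Convert a subject table to Subject records, validating invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{missing[0]} required (missing columns: {missing})")
    subjects: list[Subject] = []
    skipped = 0
    for row_no, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            subject = Subject(
                id=str(row["id"]),
                population=str(row["population"]),
                gender=_parse_gender(row["gender"]),
                age=float(row["age"]),
                height=float(row["height_cm"]),
                weight=float(row["weight_kg"]),
                sbp=float(row["sbp"]) if "sbp" in df.columns and pd.notna(row["sbp"]) else None,
                dbp=float(row["dbp"]) if "dbp" in df.columns and pd.notna(row["dbp"]) else None,
                dims={p: float(row[col]) for p, col in _DIM_COLUMNS.items()},
            )
            errors = subject.eligibility_errors()
            if errors:
                raise ValueError("; ".join(errors))
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"row {row_no}: {exc}") from exc
            skipped += 1
            continue
        subjects.append(subject)
    if skipped:
        import logging

        logging.getLogger(__name__).warning("skipped %d invalid rows", skipped)
    return subjects


def subjects_to_dataframe(subjects: Sequence[Subject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {
            "id": s.id,
            "population": s.population,
            "gender": s.gender,
            "age": s.age,
            "height_cm": s.height,
            "weight_kg": s.weight,
            "ao_a_mm": s.dims.get(AorticParam.AO_A),
            "ao_s_mm": s.dims.get(AorticParam.AO_S),
            "ao_asc_mm": s.dims.get(AorticParam.AO_ASC),
            "sbp": s.sbp,
            "dbp": s.dbp,
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=[*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS])


def read_subjects(path: str | Path, strict: bool = True) -> list[Subject]:
    """Read a subject CSV; see the module docstring for the schema."""
    df = pd.read_csv(
        path,
        dtype={"id": str, "population": str, "gender": str},
        float_precision="round_trip",
    )
    try:
        return subjects_from_dataframe(df, strict=strict)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_subjects(subjects: Sequence[Subject], path: str | Path) -> None:
    """Write subjects as CSV with full float precision (lossless round-trip)."""
    subjects_to_dataframe(subjects).to_csv(path, index=False)


def write_equation_set(eq_set: EquationSet, path: str | Path) -> None:
    payload = {
        "population": eq_set.population,
        "equations": [
            {
                "param": p.value,
                "a": eq.a,
                "b": eq.b,
                "x": eq.x,
                "y": eq.y,
                "z": eq.z,
                "provenance": eq.provenance,
            }
            for p, eq in sorted(eq_set.equations.items(), key=lambda kv: kv[0].value)
        ],
    }
    if eq_set.intervals:
        payload["intervals"] = {
            p.value: iv.to_dict() for p, iv in sorted(eq_set.intervals.items(), key=lambda kv: kv[0].value)
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_equation_set(path: str | Path) -> EquationSet:
    payload = json.loads(Path(path).read_text())
    equations = {
        AorticParam.coerce(e["param"]): AllometricEquation(
            param=e["param"],
            a=float(e["a"]),
            b=float(e.get("b", 1.0)),
            x=float(e.get("x", 0.0)),
            y=float(e.get("y", 0.0)),
            z=float(e.get("z", 0.0)),
            provenance=e.get("provenance", ""),
        )
        for e in payload["equations"]
    }
    intervals = None
    if payload.get("intervals"):
        intervals = {
            AorticParam.coerce(p): ReferenceInterval(
                mean=float(iv["mean"]),
                sd=float(iv["sd"]),
                lower=float(iv["lower"]),
                upper=float(iv["upper"]),
                method=iv.get("method", "percentile"),
                n=int(iv.get("n", 0)),
                degenerate=bool(iv.get("degenerate", False)),
            )
            for p, iv in payload["intervals"].items()
        }
    return EquationSet(
        population=payload["population"], equations=equations, intervals=intervals
    )
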
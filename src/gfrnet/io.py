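"""Cohort CSV dialect: column names, reading, writing, validation.

The on-disk dialect is a UTF-8 CSV with header
``id, age, sex, height_cm, weight_kg, scr_mg_dl, sun_mg_dl, alb_g_dl,
sgfr_ml_min_173`` (the last two optional).  In memory a cohort is a
pandas DataFrame with short variable names: ``id, age, sex, height,
weight, sc, sun, alb, sgfr``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List

import pandas as pd

from .equations import PatientRecord

#: short name -> CSV column
COLUMN_MAP = {
    "id": "id",
    "age": "age",
    "sex": "sex",
    "height": "height_cm",
    "weight": "weight_kg",
    "sc": "scr_mg_dl",
    "sun": "sun_mg_dl",
    "alb": "alb_g_dl",
    "sgfr": "sgfr_ml_min_173",
}
_REVERSE_MAP = {v: k for k, v in COLUMN_MAP.items()}

#: the seven candidate network input variables, in the conventional order
INPUT_VARIABLES = ["alb", "sun", "sc", "age", "height", "weight", "gender"]
OUTPUT_VARIABLE = "sgfr"

REQUIRED_COLUMNS = ["age", "sex", "height", "weight", "sc", "sun"]


def variable_column(variable: str) -> str:
    """DataFrame column backing a network variable ('gender' lives in 'sex')."""
    return "sex" if variable == "gender" else variable


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (dialect columns) into short-named DataFrame form."""
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in _REVERSE_MAP]
    if unknown:
        raise ValueError(f"unrecognized cohort columns: {unknown}")
    df = df.rename(columns=_REVERSE_MAP)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing required columns: {missing}")
    if "id" not in df.columns:
        df.insert(0, "id", [f"s{i:05d}" for i in range(len(df))])
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a short-named cohort DataFrame using the CSV dialect columns."""
    out = df.rename(columns=COLUMN_MAP)
    # keep dialect column order first, any extra columns (eGFR etc.) after
    known = [COLUMN_MAP[k] for k in COLUMN_MAP if COLUMN_MAP[k] in out.columns]
    extra = [c for c in out.columns if c not in known]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out[known + extra].to_csv(path, index=False)


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "id": r.id if r.id is not None else f"s{i:05d}",
                "age": r.age,
                "sex": r.sex,
                "height": r.height,
                "weight": r.weight,
                "sc": r.sc,
                "sun": r.sun,
                "alb": r.alb,
                "sgfr": r.sgfr,
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> List[PatientRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                age=float(row["age"]),
                sex=str(row["sex"]),
                height=float(row["height"]),
                weight=float(row["weight"]),
                sc=float(row["sc"]),
                sun=float(row["sun"]),
                alb=None if "alb" not in row or pd.isna(row["alb"]) else float(row["alb"]),
                sgfr=None if "sgfr" not in row or pd.isna(row["sgfr"]) else float(row["sgfr"]),
                id=str(row["id"]) if "id" in row else None,
            )
        )
    return records
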
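"""Long-format (NONMEM-dialect) dataset reading, validation and writing.

Conventions: time in minutes, amounts in mg, rates in mg min^-1,
concentrations in ug ml^-1; comma-separated, '.' decimal, UTF-8.  Lines
starting with '#' are provenance headers and are skipped on read.
"""
from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from .covariates import SubjectCovariates
from .system import DoseEvent, InfusionSchedule

__all__ = [
    "REQUIRED_COLUMNS",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "iter_subjects",
    "covariates_from_row",
    "schedule_from_rows",
]

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "RATE", "CMT", "DV", "MDV", "TYPE")
NUMERIC_COLUMNS = ("ID", "TIME", "EVID", "AMT", "RATE", "CMT", "DV", "MDV")
COVARIATE_COLUMNS = ("AGE", "WGT", "SEX", "OPI", "PUGH", "ESRD",
                     "ECMO", "ECMOACT", "ICU", "ICU24", "VENOUS")


class DatasetError(ValueError):
    """Raised for malformed dataset files with a row/column diagnosis."""


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DatasetError(f"missing required column {col!r}")
    out = df.copy()
    for col in NUMERIC_COLUMNS:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DatasetError(
                f"non-numeric value {out[col].iloc[row]!r} in column {col} at row {row}"
            )
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise DatasetError(f"missing value in column {col} at row {row}")
        out[col] = vals
    moaas = out["TYPE"] == "MOAAS"
    if moaas.any():
        dv = out.loc[moaas, "DV"]
        bad = ~dv.isin(range(6))
        if bad.any():
            row = int(dv.index[bad][0])
            raise DatasetError(
                f"MOAA/S DV must be an integer 0..5; got {dv[row]!r} at row {row}"
            )
    dose = out["EVID"] == 1
    if (out.loc[dose, "AMT"] <= 0).any():
        row = int(out.index[dose & (out["AMT"] <= 0)][0])
        raise DatasetError(f"dose row {row} has non-positive AMT")
    obs = out["EVID"] == 0
    if (out.loc[obs, "MDV"] != 0).any():
        row = int(out.index[obs & (out["MDV"] != 0)][0])
        raise DatasetError(f"observation row {row} must have MDV=0")
    return out


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a long-format dataset CSV."""
    df = pd.read_csv(path, comment="#")
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    """Write a dataset CSV; ``write_dataset`` then ``read_dataset`` round-trips."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False)


def covariates_from_row(row) -> SubjectCovariates:
    """Subject covariates from one dataset row (SEX: 1=male, 2=female)."""
    def flag(name):
        return bool(int(row[name])) if name in row else False

    return SubjectCovariates(
        age=float(row["AGE"]),
        weight=float(row["WGT"]),
        sex="male" if int(row["SEX"]) == 1 else "female",
        opioids_present=flag("OPI"),
        pugh_gt8=flag("PUGH"),
        esrd=flag("ESRD"),
        ecmo_subject=flag("ECMO"),
        ecmo_active=flag("ECMOACT"),
        icu_subject=flag("ICU"),
        icu_gt24h=flag("ICU24"),
        venous_only=flag("VENOUS"),
    )


def schedule_from_rows(df: pd.DataFrame) -> InfusionSchedule:
    """Dosing schedule from the EVID=1 rows of one subject.

    RATE = 0 encodes a bolus; otherwise duration = AMT / RATE.
    """
    events = []
    for _, r in df[df["EVID"] == 1].iterrows():
        amt, rate = float(r["AMT"]), float(r["RATE"])
        dur = amt / rate if rate > 0 else 0.0
        events.append(DoseEvent(time=float(r["TIME"]), amount=amt, duration=dur))
    return InfusionSchedule(events)


def iter_subjects(df: pd.DataFrame) -> Iterator[tuple[int, SubjectCovariates, InfusionSchedule, pd.DataFrame]]:
    """Yield (id, covariates, schedule, observation rows) per subject."""
    for sid, grp in df.groupby("ID", sort=True):
        cov = covariates_from_row(grp.iloc[0])
        schedule = schedule_from_rows(grp)
        obs = grp[grp["EVID"] == 0]
        yield int(sid), cov, schedule, obs
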
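"""Patient records, cohorts, CSV I/O and descriptive summaries.

The unit of analysis is an adult inpatient rehabilitation admission carrying
a ClinFIT total raw score (0–300, 30 ICF-derived categories each rated 0–10,
higher = greater functional limitation) at admission and optionally at
discharge, a rehabilitation-intensity level (the Therapy Disciplines domain
of the Rehabilitation Complexity Scale v2: TD0 no therapist involvement, TD1
one discipline, TD2 two–three, TD3 four or more), age, sex and a coarse
diagnosis group.

A :class:`Cohort` is a validated, pandas-backed table of such records with a
guaranteed canonical schema; all downstream analysis consumes cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._round import round_half_up
from .errors import CohortValidationError, SchemaError

SCORE_MIN, SCORE_MAX = 0, 300
TD_LEVELS = (0, 1, 2, 3)
SEXES = ("male", "female")
DIAGNOSES = ("stroke", "msk", "cancer", "other")

#: Canonical CSV column names, in write order.
CANONICAL_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "diagnosis",
    "clinfit_admission",
    "clinfit_discharge",
    "td_level",
)


@dataclass(frozen=True)
class PatientRecord:
    """One inpatient admission.

    ``clinfit_discharge`` is ``None`` when the discharge assessment is
    missing; such patients are excluded from paired pre/post statistics but
    participate fully in cutoff derivation (which uses admission scores).
    """

    patient_id: str
    clinfit_admission: int
    td_level: int
    age_years: float
    sex: str
    diagnosis: str
    clinfit_discharge: int | None = None


def _validate_df(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce dtypes and enforce row invariants; raises with row indices."""
    problems: list[str] = []
    out = pd.DataFrame(index=df.index)

    out["patient_id"] = df["patient_id"].astype(str)
    dup = out["patient_id"].duplicated(keep=False)
    if dup.any():
        ids = sorted(out.loc[dup, "patient_id"].unique())
        problems.append(f"duplicate patient_id values: {ids[:10]}")

    def _as_int(col: str, allow_missing: bool = False) -> pd.Series:
        s = pd.to_numeric(df[col], errors="coerce")
        bad = s.isna() & df[col].notna()
        for i in df.index[bad]:
            problems.append(f"row {i}: {col} is not numeric ({df.at[i, col]!r})")
        nonint = s.notna() & (s != np.floor(s))
        for i in df.index[nonint]:
            problems.append(f"row {i}: {col} must be an integer ({s.at[i]!r})")
        if not allow_missing and s.isna().any():
            for i in df.index[s.isna() & df[col].isna()]:
                problems.append(f"row {i}: {col} is missing")
        return s.astype("Int64")

    adm = _as_int("clinfit_admission")
    out["clinfit_admission"] = adm
    for i in df.index[(adm < SCORE_MIN) | (adm > SCORE_MAX)]:
        problems.append(
            f"row {i}: clinfit_admission {adm.at[i]} outside [{SCORE_MIN}, {SCORE_MAX}]"
        )

    if "clinfit_discharge" in df.columns:
        dis = _as_int("clinfit_discharge", allow_missing=True)
    else:
        dis = pd.Series(pd.NA, index=df.index, dtype="Int64")
    out["clinfit_discharge"] = dis
    for i in df.index[(dis < SCORE_MIN) | (dis > SCORE_MAX)]:
        problems.append(
            f"row {i}: clinfit_discharge {dis.at[i]} outside [{SCORE_MIN}, {SCORE_MAX}]"
        )

    td = _as_int("td_level")
    out["td_level"] = td
    for i in df.index[~td.isin(TD_LEVELS) & td.notna()]:
        problems.append(f"row {i}: td_level {td.at[i]} not in {set(TD_LEVELS)}")

    age = pd.to_numeric(df["age_years"], errors="coerce")
    out["age_years"] = age.astype(float)
    for i in df.index[age.isna()]:
        problems.append(f"row {i}: age_years is not numeric ({df.at[i, 'age_years']!r})")
    for i in df.index[age < 0]:
        problems.append(f"row {i}: age_years {age.at[i]} is negative")

    # Case-insensitive match against fixed vocabularies; unknown values are
    # errors, never silently mapped to "other" ("other" is a real category).
    for col, vocab in (("sex", SEXES), ("diagnosis", DIAGNOSES)):
        s = df[col].astype(str).str.strip().str.lower()
        out[col] = s
        for i in df.index[~s.isin(vocab)]:
            problems.append(f"row {i}: {col} {df.at[i, col]!r} not one of {vocab}")

    if problems:
        raise CohortValidationError(
            "invalid cohort:\n  " + "\n  ".join(problems[:50])
        )
    out["clinfit_admission"] = out["clinfit_admission"].astype("int64")
    out["td_level"] = out["td_level"].astype("int64")
    return out[list(CANONICAL_COLUMNS)]


class Cohort:
    """A validated collection of :class:`PatientRecord` with unique IDs."""

    def __init__(
        self,
        records: Iterable[PatientRecord] | pd.DataFrame,
        provenance: str = "",
    ) -> None:
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            rows = [
                {
                    "patient_id": r.patient_id,
                    "age_years": r.age_years,
                    "sex": r.sex,
                    "diagnosis": r.diagnosis,
                    "clinfit_admission": r.clinfit_admission,
                    "clinfit_discharge": (
                        pd.NA if r.clinfit_discharge is None else r.clinfit_discharge
                    ),
                    "td_level": r.td_level,
                }
                for r in records
            ]
            df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "clinfit_discharge"]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        self._df = _validate_df(df).reset_index(drop=True)
        self.provenance = provenance

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self._df.equals(other._df)

    @property
    def df(self) -> pd.DataFrame:
        """The canonical table (copy; mutating it cannot corrupt the cohort)."""
        return self._df.copy()

    @property
    def records(self) -> list[PatientRecord]:
        return [
            PatientRecord(
                patient_id=row.patient_id,
                clinfit_admission=int(row.clinfit_admission),
                clinfit_discharge=(
                    None if pd.isna(row.clinfit_discharge) else int(row.clinfit_discharge)
                ),
                td_level=int(row.td_level),
                age_years=float(row.age_years),
                sex=row.sex,
                diagnosis=row.diagnosis,
            )
            for row in self._df.itertuples(index=False)
        ]

    @property
    def admission_scores(self) -> np.ndarray:
        return self._df["clinfit_admission"].to_numpy(dtype=np.int64)

    @property
    def td_levels(self) -> np.ndarray:
        return self._df["td_level"].to_numpy(dtype=np.int64)

    def subset(self, mask: Sequence[bool], provenance: str | None = None) -> "Cohort":
        sub = self._df.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return Cohort(sub, provenance=provenance if provenance is not None else self.provenance)


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> Cohort:
    """Read a patient CSV into a validated :class:`Cohort`.

    Parameters
    ----------
    path
        CSV file with a header row; comma-separated, UTF-8. Missing discharge
        scores are empty cells.
    schema
        Optional mapping from canonical column names to the file's actual
        header names, for adapting foreign exports.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    raw = pd.read_csv(path, dtype={"patient_id": str}, encoding="utf-8")
    if schema:
        unknown = set(schema) - set(CANONICAL_COLUMNS)
        if unknown:
            raise SchemaError(f"schema maps unknown canonical columns: {sorted(unknown)}")
        rename = {v: k for k, v in schema.items()}
        missing_src = [v for v in schema.values() if v not in raw.columns]
        if missing_src:
            raise SchemaError(f"mapped columns absent from file: {missing_src}")
        raw = raw.rename(columns=rename)
    required = [c for c in CANONICAL_COLUMNS if c != "clinfit_discharge"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return Cohort(raw, provenance=provenance if provenance is not None else str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as canonical CSV; ``read_cohort`` round-trips it."""
    df = cohort.df
    # Int64 discharge renders missing values as empty cells.
    df.to_csv(Path(path), index=False, encoding="utf-8")


def _mean_sd(values: pd.Series) -> tuple[float, float, int]:
    vals = values.dropna().astype(float)
    n = len(vals)
    mean = float(vals.mean()) if n else float("nan")
    if n == 1:
        warnings.warn(
            "sample SD undefined for n = 1; reporting 0.0", UserWarning, stacklevel=3
        )
        sd = 0.0
    else:
        sd = float(vals.std(ddof=1)) if n else float("nan")
    return mean, sd, n


def describe_cohort(cohort: Cohort, age_boundary: float = 65.0) -> dict:
    """Descriptive summary: counts/percentages per categorical block and
    mean/SD of the admission and discharge scores, rounded to 1 decimal.

    Percentages are computed over non-missing values; each categorical block
    sums to 100 up to rounding.
    """
    if len(cohort) == 0:
        raise CohortValidationError("cannot describe an empty cohort")
    df = cohort.df
    n = len(df)

    def block(series: pd.Series, levels: Sequence) -> dict:
        counts = series.value_counts()
        return {
            str(lv): {
                "count": int(counts.get(lv, 0)),
                "pct": round_half_up(100.0 * counts.get(lv, 0) / n, 1),
            }
            for lv in levels
        }

    age_band = np.where(df["age_years"] >= age_boundary, f">={age_boundary:g}", f"<{age_boundary:g}")
    adm_mean, adm_sd, _ = _mean_sd(df["clinfit_admission"])
    dis_mean, dis_sd, dis_n = _mean_sd(df["clinfit_discharge"])
    age_mean, age_sd, _ = _mean_sd(df["age_years"])

    return {
        "n": n,
        "sex": block(df["sex"], SEXES),
        "age_band": block(
            pd.Series(age_band), [f"<{age_boundary:g}", f">={age_boundary:g}"]
        ),
        "age_years": {"mean": round_half_up(age_mean, 1), "sd": round_half_up(age_sd, 1)},
        "diagnosis": block(df["diagnosis"], DIAGNOSES),
        "td_level": block(df["td_level"], TD_LEVELS),
        "clinfit_admission": {
            "mean": round_half_up(adm_mean, 1),
            "sd": round_half_up(adm_sd, 1),
            "n": n,
        },
        "clinfit_discharge": {
            "mean": round_half_up(dis_mean, 1) if dis_n else None,
            "sd": round_half_up(dis_sd, 1) if dis_n else None,
            "n": dis_n,
            "n_missing": n - dis_n,
        },
    }
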
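"""Subject cohorts: validated container, delimited-text I/O, BMI, summaries.

A cohort is one row per adult subject with sex, age (years), height
(metres) and weight (kilograms), optionally carrying binary
cardiometabolic disease flags (diabetes, hypertension, coronary artery
disease, metabolic syndrome).  Heights are metres by construction: a
value above 3 m almost always means centimetres were entered, so it is
rejected with a hint unless the caller explicitly asks for conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from . import stat_tests
from .stat_tests import TestResult

__all__ = [
    "DISEASES",
    "SubjectRecord",
    "Cohort",
    "DemographicSummary",
    "read_cohort",
    "write_cohort",
    "body_mass_index",
    "summarize",
    "correlate_index",
]

logger = logging.getLogger(__name__)

DISEASES = ("dm", "htn", "cad", "mets")
REQUIRED_COLUMNS = ("subject_id", "sex", "age_years", "height_m", "weight_kg")

# plausible adult age window (inclusion criteria of the reference study)
DEFAULT_AGE_RANGE = (18.0, 79.0)

_SEX_TOKENS = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "0": "female",
}

# quantile estimator shared by summaries and thresholds: linear
# interpolation at rank (n+1)p ("weibull" in numpy's naming)
DEFAULT_QUANTILE_RULE = "weibull"


@dataclass(frozen=True)
class SubjectRecord:
    """One individual's anthropometry and optional disease flags."""

    subject_id: str
    sex: str                      # "male" | "female"
    age_years: float
    height_m: float
    weight_kg: float
    disease_flags: Optional[Mapping[str, bool]] = None


@dataclass
class Cohort:
    """An ordered, validated collection of subjects.

    The canonical representation is a pandas DataFrame (``frame``) with
    columns ``subject_id, sex, age_years, height_m, weight_kg`` and, when
    present, the disease flag columns ``dm, htn, cad, mets`` (0/1).
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_disease_flags(self) -> bool:
        return all(d in self.frame.columns for d in DISEASES)

    @property
    def records(self) -> Iterator[SubjectRecord]:
        for row in self.frame.itertuples(index=False):
            flags = None
            if self.has_disease_flags:
                flags = {d: bool(getattr(row, d)) for d in DISEASES}
            yield SubjectRecord(
                subject_id=row.subject_id, sex=row.sex,
                age_years=row.age_years, height_m=row.height_m,
                weight_kg=row.weight_kg, disease_flags=flags,
            )

    def subset(self, mask) -> "Cohort":
        return Cohort(self.frame.loc[np.asarray(mask)].reset_index(drop=True),
                      provenance=self.provenance)


@dataclass
class DemographicSummary:
    """Per-sex and overall counts plus median (IQR) of the anthropometry."""

    counts: dict            # {"male": n, "female": n, "overall": n}
    medians: pd.DataFrame   # rows: male/female/overall; cols: age..bmi
    iqrs: pd.DataFrame      # same layout

    def to_frame(self) -> pd.DataFrame:
        med = self.medians.add_suffix("_median")
        iqr = self.iqrs.add_suffix("_iqr")
        out = pd.concat([med, iqr], axis=1)
        out.insert(0, "n", pd.Series(self.counts))
        return out


def _normalise_sex(values: pd.Series) -> pd.Series:
    low = values.astype(str).str.strip().str.lower()
    mapped = low.map(_SEX_TOKENS)
    return mapped


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort is missing required columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("cohort must be nonempty")
    df = df.reset_index(drop=True).copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()[:5]
        raise ValueError(f"duplicate subject_id values: {dupes}")
    sex = _normalise_sex(df["sex"])
    if sex.isna().any():
        bad = sorted(df.loc[sex.isna(), "sex"].astype(str).unique().tolist())
        raise ValueError(f"unrecognised sex tokens: {bad}")
    df["sex"] = sex
    for col in ("age_years", "height_m", "weight_kg"):
        vals = pd.to_numeric(df[col], errors="coerce").astype(float)
        if vals.isna().any() or not np.all(np.isfinite(vals)) or (vals <= 0).any():
            raise ValueError(f"column {col} must be strictly positive and finite")
        df[col] = vals
    if (df["height_m"] > 3).any():
        raise ValueError(
            "height_m above 3 m — values look like centimetres; "
            "pass heights in metres or use convert_cm=True when reading"
        )
    for d in DISEASES:
        if d in df.columns:
            vals = pd.to_numeric(df[d], errors="coerce")
            if not vals.isin([0, 1]).all():
                raise ValueError(f"disease column {d} must be 0/1")
            df[d] = vals.astype(int)
    return df


def read_cohort(
    path,
    policy: str = "strict",
    sep: str = ",",
    convert_cm: bool = False,
    age_range: tuple = DEFAULT_AGE_RANGE,
    provenance: Optional[str] = None,
) -> Cohort:
    """Read a cohort from delimited text.

    Expected header: ``subject_id,sex,age_years,height_m,weight_kg`` with
    optional trailing ``dm,htn,cad,mets`` (0/1) columns.

    ``policy`` controls row-level failures: ``"strict"`` aborts with an
    error naming the first offending row, ``"drop"`` removes invalid rows
    and logs how many were dropped.  ``convert_cm=True`` divides the
    height column by 100 (explicit unit override).  Rows whose age falls
    outside ``age_range`` are treated as invalid under the same policy.
    """
    if policy not in ("strict", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    if convert_cm:
        df["height_m"] = pd.to_numeric(df["height_m"], errors="coerce") / 100.0

    bad = pd.Series(False, index=df.index)
    reasons = {}

    def flag(mask: pd.Series, reason: str):
        for i in df.index[mask & ~bad]:
            reasons[i] = reason
        bad[mask] = True

    sex_norm = _normalise_sex(df["sex"])
    flag(sex_norm.isna(), "unrecognised sex token")
    for col in ("age_years", "height_m", "weight_kg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        flag(~np.isfinite(vals) | (vals <= 0), f"non-positive or unparseable {col}")
        df[col] = vals
    flag(df["height_m"] > 3, "height above 3 m (centimetres entered as metres?)")
    lo, hi = age_range
    flag((df["age_years"] < lo) | (df["age_years"] > hi),
         f"age outside plausible range [{lo}, {hi}]")
    for d in DISEASES:
        if d in df.columns:
            vals = pd.to_numeric(df[d], errors="coerce")
            flag(~vals.isin([0, 1]), f"disease column {d} not 0/1")
            df[d] = vals

    if bad.any():
        if policy == "strict":
            i = df.index[bad][0]
            raise ValueError(f"{path}: row {i + 2} invalid ({reasons[i]})")
        logger.warning("read_cohort: dropped %d invalid rows from %s",
                       int(bad.sum()), path)
        df = df.loc[~bad]
    if len(df) == 0:
        raise ValueError(f"{path}: all rows failed validation")
    return Cohort(df.reset_index(drop=True),
                  provenance=provenance if provenance is not None else str(path))


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    """Write a cohort (or a scored frame) back to delimited text."""
    frame = getattr(cohort, "frame", cohort)
    frame.to_csv(path, sep=sep, index=False)


def body_mass_index(weight_kg, height_m):
    """Body mass index: weight (kg) divided by height (m) squared."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0) or not (
        np.all(np.isfinite(w)) and np.all(np.isfinite(h))
    ):
        raise ValueError("weight and height must be strictly positive and finite")
    bmi = w / h**2
    return float(bmi) if np.ndim(bmi) == 0 else bmi


def _iqr(values: np.ndarray, rule: str) -> float:
    q1, q3 = np.quantile(values, [0.25, 0.75], method=rule)
    return float(q3 - q1)


def summarize(cohort: Cohort, quantile_rule: str = DEFAULT_QUANTILE_RULE) -> DemographicSummary:
    """Median (IQR) of age, height, weight and BMI, per sex and overall."""
    df = cohort.frame
    if len(df) == 0:
        raise ValueError("cannot summarise an empty cohort")
    work = df.assign(bmi=body_mass_index(df["weight_kg"], df["height_m"]))
    variables = {"age": "age_years", "height": "height_m",
                 "weight": "weight_kg", "bmi": "bmi"}
    strata = {
        "male": work[work["sex"] == "male"],
        "female": work[work["sex"] == "female"],
        "overall": work,
    }
    counts, medians, iqrs = {}, {}, {}
    for name, sub in strata.items():
        counts[name] = len(sub)
        medians[name] = {
            v: float(np.median(sub[c])) if len(sub) else np.nan
            for v, c in variables.items()
        }
        iqrs[name] = {
            v: _iqr(sub[c].to_numpy(), quantile_rule) if len(sub) else np.nan
            for v, c in variables.items()
        }
    return DemographicSummary(
        counts=counts,
        medians=pd.DataFrame(medians).T,
        iqrs=pd.DataFrame(iqrs).T,
    )


def correlate_index(cohort: Cohort, index_values) -> pd.DataFrame:
    """Audit an index against weight, height and age by Spearman correlation.

    For a successful weight index the correlation with weight should be
    strong and positive while the correlations with height and age should
    vanish.  Returns a DataFrame indexed by (stratum, variable) with
    columns ``rho``, ``p``, ``status``; zero-variance inputs yield a
    ``not_computable`` status instead of a number.
    """
    idx = np.asarray(index_values, dtype=float)
    df = cohort.frame
    if len(idx) != len(df):
        raise ValueError("index_values must align with the cohort")
    if len(df) < 4:
        raise ValueError("need at least 4 subjects for a correlation audit")
    variables = {"weight": "weight_kg", "height": "height_m", "age": "age_years"}
    strata = {
        "overall": np.full(len(df), True),
        "male": (df["sex"] == "male").to_numpy(),
        "female": (df["sex"] == "female").to_numpy(),
    }
    rows = []
    for stratum, mask in strata.items():
        for var, col in variables.items():
            x = idx[mask]
            y = df.loc[mask, col].to_numpy()
            if len(x) < 4:
                rows.append((stratum, var, np.nan, np.nan, "too_few"))
                continue
            res = stat_tests.spearman(x, y)
            rho = res.statistic if res.status == "ok" else np.nan
            p = res.p_value if res.status == "ok" else np.nan
            rows.append((stratum, var, rho, p, res.status))
    out = pd.DataFrame(rows, columns=["stratum", "variable", "rho", "p", "status"])
    return out.set_index(["stratum", "variable"])
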
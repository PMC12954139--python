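"""Reclassification and diagnostic-performance comparison of WC vs BMI.

Both overweight criteria are treated as screening tests for each
cardiometabolic condition (positive = overweight).  Performance is the
usual sensitivity / specificity / accuracy triple; the two criteria are
compared per metric with McNemar's test on paired per-subject outcomes:
accuracy on correctness pairs over all subjects, sensitivity on the
diseased subjects' positive/negative pairs, specificity on the healthy
subjects' pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import stat_tests
from .allometric import AllometricCoefficients
from .cohort import DISEASES
from .stat_tests import TestResult
from .wc_index import DEFAULT_BMI_CUTOFF, ThresholdSpec, score_cohort

__all__ = [
    "ConfusionCounts",
    "PerformanceMetrics",
    "CriteriaComparison",
    "ReclassificationSummary",
    "confusion",
    "performance",
    "compare_criteria",
    "reclassification_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tabulation of an overweight criterion against a disease label."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity, specificity and accuracy (NaN when not computable)."""

    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class CriteriaComparison:
    """Per-disease, per-stratum comparison of the BMI and WC criteria.

    ``results`` maps (disease, stratum) to a dict with the two criteria's
    metrics and the three McNemar results; strata with no subjects are
    absent.
    """

    results: dict
    bmi_cutoff: float
    threshold: ThresholdSpec

    def to_frame(self, percent_decimals: int = 1) -> pd.DataFrame:
        """Flat table: rows = disease x stratum x metric; columns BMI/WC/p."""
        rows = []
        for (disease, stratum), rec in self.results.items():
            for metric in ("accuracy", "sensitivity", "specificity"):
                b = getattr(rec["bmi"], metric)
                w = getattr(rec["wc"], metric)
                p = rec["mcnemar"][metric].p_value
                rows.append({
                    "disease": disease, "stratum": stratum, "metric": metric,
                    "bmi_pct": round(100 * b, percent_decimals)
                    if not math.isnan(b) else float("nan"),
                    "wc_pct": round(100 * w, percent_decimals)
                    if not math.isnan(w) else float("nan"),
                    "p": p,
                })
        return pd.DataFrame(rows)


@dataclass
class ReclassificationSummary:
    """How many BMI-overweight subjects the WC criterion calls normal."""

    n_overweight_bmi: int
    n_reclassified_normal: int
    n_male: int
    n_male_reclassified: int
    n_female: int
    n_female_reclassified: int

    def __post_init__(self):
        if self.n_reclassified_normal > self.n_overweight_bmi:
            raise ValueError("reclassified count exceeds group size")
        if self.n_male + self.n_female != self.n_overweight_bmi:
            raise ValueError("sex counts must sum to the total")
        if (self.n_male_reclassified + self.n_female_reclassified
                != self.n_reclassified_normal):
            raise ValueError("sex reclassified counts must sum to the total")

    @staticmethod
    def _rate(k: int, n: int) -> float:
        return round(100.0 * k / n, 1) if n else float("nan")

    @property
    def reclassification_rate(self) -> float:
        """% of BMI-overweight subjects reclassified as normal (1 dp)."""
        return self._rate(self.n_reclassified_normal, self.n_overweight_bmi)

    @property
    def remaining_overweight_rate(self) -> float:
        return round(100.0 - self.reclassification_rate, 1)

    @property
    def male_remaining_overweight_rate(self) -> float:
        return round(100.0 - self._rate(self.n_male_reclassified, self.n_male), 1)

    @property
    def female_remaining_overweight_rate(self) -> float:
        return round(100.0 - self._rate(self.n_female_reclassified, self.n_female), 1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_overweight_bmi": self.n_overweight_bmi,
                "n_reclassified_normal": self.n_reclassified_normal,
                "male": {"n": self.n_male, "reclassified": self.n_male_reclassified,
                         "remaining_overweight_rate": self.male_remaining_overweight_rate},
                "female": {"n": self.n_female, "reclassified": self.n_female_reclassified,
                           "remaining_overweight_rate": self.female_remaining_overweight_rate},
                "reclassification_rate": self.reclassification_rate,
                "remaining_overweight_rate": self.remaining_overweight_rate,
            },
            indent=2,
        )


def confusion(predicted_overweight, diseased) -> ConfusionCounts:
    """Tabulate criterion positives against disease labels."""
    pred = np.asarray(predicted_overweight, dtype=bool)
    dis = np.asarray(diseased, dtype=bool)
    if pred.shape != dis.shape:
        raise ValueError("prediction and label vectors must align")
    if pred.size == 0:
        raise ValueError("empty input")
    return ConfusionCounts(
        tp=int(np.sum(pred & dis)),
        fp=int(np.sum(pred & ~dis)),
        tn=int(np.sum(~pred & ~dis)),
        fn=int(np.sum(~pred & dis)),
    )


def performance(counts: ConfusionCounts) -> PerformanceMetrics:
    """The three standard ratios; NaN where a denominator is zero."""
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else float("nan")
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else float("nan")
    acc = (counts.tp + counts.tn) / counts.total if counts.total else float("nan")
    return PerformanceMetrics(sensitivity=sens, specificity=spec, accuracy=acc)


def _paired_mcnemar(pred_a: np.ndarray, pred_b: np.ndarray) -> TestResult:
    """McNemar from two paired boolean outcome vectors."""
    b = int(np.sum(pred_a & ~pred_b))
    c = int(np.sum(~pred_a & pred_b))
    return stat_tests.mcnemar(b, c)


def compare_criteria(
    cohort,
    coeffs: Optional[AllometricCoefficients] = None,
    threshold: Optional[ThresholdSpec] = None,
    bmi_cutoff: float = DEFAULT_BMI_CUTOFF,
    diseases=DISEASES,
) -> CriteriaComparison:
    """Head-to-head comparison of the WC and BMI overweight criteria.

    For every disease label and stratum (total / male / female) the two
    criteria's sensitivity, specificity and accuracy are computed along
    with per-metric McNemar tests on the paired per-subject outcomes.
    """
    frame = getattr(cohort, "frame", cohort)
    missing = [d for d in diseases if d not in frame.columns]
    if missing:
        raise ValueError(f"cohort lacks disease labels: {missing}")
    scored = score_cohort(cohort, coeffs=coeffs, threshold=threshold,
                          bmi_cutoff=bmi_cutoff)
    wc_pos = (scored["wc_class"] == "overweight").to_numpy()
    bmi_pos = (scored["bmi_class"] == "overweight").to_numpy()
    strata = {"total": np.full(len(scored), True)}
    for sex in ("male", "female"):
        mask = (scored["sex"] == sex).to_numpy()
        if mask.any():
            strata[sex] = mask

    results = {}
    for disease in diseases:
        dis = scored[disease].to_numpy().astype(bool)
        for stratum, mask in strata.items():
            d, w, b = dis[mask], wc_pos[mask], bmi_pos[mask]
            correct_w = w == d
            correct_b = b == d
            results[(disease, stratum)] = {
                "bmi": performance(confusion(b, d)),
                "wc": performance(confusion(w, d)),
                "mcnemar": {
                    "accuracy": _paired_mcnemar(correct_b, correct_w),
                    "sensitivity": _paired_mcnemar(b[d], w[d]),
                    "specificity": _paired_mcnemar(~b[~d], ~w[~d]),
                },
            }
    if threshold is None:
        from .wc_index import published_threshold
        threshold = published_threshold()
    return CriteriaComparison(results=results, bmi_cutoff=bmi_cutoff,
                              threshold=threshold)


def reclassification_summary(
    cohort,
    coeffs: Optional[AllometricCoefficients] = None,
    threshold: Optional[ThresholdSpec] = None,
    bmi_cutoff: float = DEFAULT_BMI_CUTOFF,
) -> ReclassificationSummary:
    """Reclassification of a BMI-overweight cohort under the WC criterion.

    Every subject must already satisfy the BMI criterion (callers
    pre-filter); a subject below the cutoff raises ``ValueError``.
    """
    scored = score_cohort(cohort, coeffs=coeffs, threshold=threshold,
                          bmi_cutoff=bmi_cutoff)
    below = scored["bmi"] < bmi_cutoff
    if below.any():
        raise ValueError(
            f"{int(below.sum())} subjects fall below the BMI cutoff "
            f"{bmi_cutoff}; reclassification expects a BMI-overweight cohort"
        )
    normal = (scored["wc_class"] == "normal").to_numpy()
    male = (scored["sex"] == "male").to_numpy()
    return ReclassificationSummary(
        n_overweight_bmi=len(scored),
        n_reclassified_normal=int(normal.sum()),
        n_male=int(male.sum()),
        n_male_reclassified=int((normal & male).sum()),
        n_female=int((~male).sum()),
        n_female_reclassified=int((normal & ~male).sum()),
    )
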
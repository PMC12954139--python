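"""Equation-validation protocol: cohort splitting and the three conditions.

The protocol mirrors the reference-interval workflow: randomly split the
reference cohort 7:3 into a development subgroup (fit the equations,
derive the threshold) and a verification subgroup, re-drawing the split
until no covariate differs significantly between subgroups; then check
on the verification subgroup that

1. WC is centred at 1 (non-significant signed-rank test of ln WC vs 0);
2. WC correlates positively with measured weight (Spearman p < alpha,
   rho > 0);
3. WC is independent of the model covariates: Spearman vs age and vs
   height both p > alpha, and no sex difference by Mann-Whitney.

A coefficient set passes overall only when all three hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stat_tests
from .allometric import AllometricCoefficients
from .cohort import Cohort, body_mass_index
from .stat_tests import TestResult
from .wc_index import ThresholdSpec, wc_scores

__all__ = [
    "SplitResult",
    "ValidationReport",
    "split_cohort",
    "validate_equations",
    "coverage_test",
    "paired_shift_test",
]

DEFAULT_ALPHA = 0.05


@dataclass
class SplitResult:
    """A balanced random 7:3 (by default) partition of a cohort."""

    subgroup_a: Cohort
    subgroup_b: Cohort
    balance_report: dict       # variable -> TestResult
    seed: int
    attempts: int


@dataclass
class ValidationReport:
    """Outcome of the three-condition check on a verification cohort."""

    median_wc: float
    iqr_wc: float
    condition1: TestResult          # ln WC located at 0
    condition2: TestResult          # WC vs W, must be significant & positive
    condition3: dict                # {"age": ..., "height": ..., "sex": ...}
    alpha: float
    condition1_pass: bool = field(init=False)
    condition2_pass: bool = field(init=False)
    condition3_pass: bool = field(init=False)
    overall_pass: bool = field(init=False)

    def __post_init__(self):
        a = self.alpha
        c1 = self.condition1
        self.condition1_pass = c1.status == "ok" and c1.p_value >= a
        c2 = self.condition2
        self.condition2_pass = (
            c2.status == "ok" and c2.p_value < a and c2.statistic > 0
        )
        self.condition3_pass = all(
            r.status == "ok" and r.p_value > a
            for r in self.condition3.values()
        )
        self.overall_pass = (
            self.condition1_pass and self.condition2_pass and self.condition3_pass
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "median_wc": self.median_wc,
                "iqr_wc": self.iqr_wc,
                "condition1": self.condition1.to_json(),
                "condition2": self.condition2.to_json(),
                "condition3": {k: v.to_json() for k, v in self.condition3.items()},
                "alpha": self.alpha,
                "condition1_pass": self.condition1_pass,
                "condition2_pass": self.condition2_pass,
                "condition3_pass": self.condition3_pass,
                "overall_pass": self.overall_pass,
            },
            indent=2,
        )

    def summary_table(self) -> pd.DataFrame:
        """Human-readable layout: median (IQR) plus rho/p per covariate."""
        rows = [("WC", f"{self.median_wc:.4f} ({self.iqr_wc:.4f})", "", "")]
        for name, res in [("weight", self.condition2),
                          ("age", self.condition3["age"]),
                          ("height", self.condition3["height"])]:
            rows.append((f"WC vs {name}", "",
                         f"{res.statistic:.3f}" if res.status == "ok" else "n/a",
                         f"{res.p_value:.3f}" if res.status == "ok" else "n/a"))
        return pd.DataFrame(rows, columns=["quantity", "median (IQR)", "rho", "p"])


def _two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Two-sided two-proportion z-test (pooled), for sex-ratio balance."""
    p_pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return TestResult("two_proportion", 0.0, 1.0, "normal_approx",
                          n=(n1, n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2 * float(sps.norm.sf(abs(z)))
    return TestResult("two_proportion", float(z), min(1.0, p),
                      "normal_approx", n=(n1, n2))


def split_cohort(
    cohort: Cohort,
    ratio: float = 0.7,
    seed: int = 0,
    max_attempts: int = 100,
    alpha: float = DEFAULT_ALPHA,
) -> SplitResult:
    """Random partition with enforced covariate balance.

    Draws a random ``ratio`` : ``1-ratio`` partition; balance between the
    subgroups is checked by Mann-Whitney tests on age, height, weight and
    BMI and a two-proportion z-test on the sex ratio.  If any balance
    p-value falls below ``alpha`` the split is re-drawn with a new seed
    derived from the previous one, up to ``max_attempts`` times.
    """
    df = cohort.frame
    n = len(df)
    if n < 20:
        raise ValueError("cohort too small to split (need n >= 20)")
    n_a = int(round(n * ratio))
    bmi = body_mass_index(df["weight_kg"].to_numpy(), df["height_m"].to_numpy())
    variables = {
        "age": df["age_years"].to_numpy(),
        "height": df["height_m"].to_numpy(),
        "weight": df["weight_kg"].to_numpy(),
        "bmi": bmi,
    }
    is_male = (df["sex"] == "male").to_numpy()
    rng = np.random.default_rng(seed)
    last_fail = None
    for attempt in range(1, max_attempts + 1):
        perm = rng.permutation(n)
        idx_a, idx_b = perm[:n_a], perm[n_a:]
        report = {}
        ok = True
        report["sex"] = _two_proportion_test(
            int(is_male[idx_a].sum()), len(idx_a),
            int(is_male[idx_b].sum()), len(idx_b))
        if report["sex"].p_value < alpha:
            ok, last_fail = False, "sex"
        if ok:
            for name, vals in variables.items():
                res = stat_tests.mann_whitney(vals[idx_a], vals[idx_b])
                report[name] = res
                if res.p_value < alpha:
                    ok, last_fail = False, name
                    break
        if ok:
            a = Cohort(df.iloc[np.sort(idx_a)].reset_index(drop=True),
                       provenance=f"{cohort.provenance} [subgroup A]")
            b = Cohort(df.iloc[np.sort(idx_b)].reset_index(drop=True),
                       provenance=f"{cohort.provenance} [subgroup B]")
            return SplitResult(a, b, report, seed=seed, attempts=attempt)
    raise RuntimeError(
        f"split_cohort: no balanced split in {max_attempts} attempts "
        f"(last failing variable: {last_fail})"
    )


def validate_equations(
    cohort_b: Cohort,
    coeffs: AllometricCoefficients,
    alpha: float = DEFAULT_ALPHA,
) -> ValidationReport:
    """Run the three-condition check on an independent verification cohort."""
    df = cohort_b.frame
    if len(df) < 30:
        raise ValueError("verification cohort too small (need n >= 30)")
    sexes = set(df["sex"])
    if sexes != {"male", "female"}:
        raise ValueError("verification cohort must contain both sexes")
    wc = wc_scores(cohort_b, coeffs)
    q1, q3 = np.quantile(wc, [0.25, 0.75], method="weibull")

    cond1 = stat_tests.wilcoxon_signed_rank(np.log(wc))
    cond2 = stat_tests.spearman(wc, df["weight_kg"].to_numpy())
    cond3 = {
        "age": stat_tests.spearman(wc, df["age_years"].to_numpy()),
        "height": stat_tests.spearman(wc, df["height_m"].to_numpy()),
        "sex": stat_tests.mann_whitney(
            wc[(df["sex"] == "male").to_numpy()],
            wc[(df["sex"] == "female").to_numpy()],
        ),
    }
    return ValidationReport(
        median_wc=float(np.median(wc)),
        iqr_wc=float(q3 - q1),
        condition1=cond1,
        condition2=cond2,
        condition3=cond3,
        alpha=alpha,
    )


def coverage_test(scored, threshold: ThresholdSpec,
                  expected: float = 0.025) -> TestResult:
    """Binomial check of the over-threshold rate against its nominal level.

    ``scored`` is a scored cohort frame (``score_cohort`` output) or a
    plain vector of WC scores.  Tests the count with WC above the cutoff
    against the expected tail probability.
    """
    if isinstance(scored, pd.DataFrame):
        wc = scored["wc"].to_numpy()
    else:
        wc = np.asarray(getattr(scored, "frame", scored), dtype=float)
    n = len(wc)
    if n == 0:
        raise ValueError("empty sample in coverage_test")
    k = int(np.sum(wc > threshold.cutoff))
    res = stat_tests.binomial_test(k, n, expected)
    res.detail["over_threshold"] = k
    return res


def paired_shift_test(measured, predicted) -> TestResult:
    """Signed-rank test for a location shift of measured vs predicted weight.

    Reports the direction in ``detail["direction"]`` as one of
    ``"predicted < measured"``, ``"predicted > measured"`` or ``"none"``.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError("measured and predicted must be aligned")
    if len(m) < 5:
        raise ValueError("need at least 5 pairs")
    res = stat_tests.wilcoxon_signed_rank(m - p)
    med = float(np.median(m - p))
    if res.status != "ok" or med == 0:
        direction = "none"
    else:
        direction = "predicted < measured" if med > 0 else "predicted > measured"
    res.detail["direction"] = direction
    return res
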
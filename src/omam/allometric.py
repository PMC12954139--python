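"""The allometric body-weight model.

Adult body weight is modelled as a power law in age and height with a
sex-specific constant::

    W = c * A**x * H**y,        c = exp(a + b*G)

where ``G`` is a dummy variable (1 for men, 0 for women).  Taking natural
logarithms gives the log-linear form that is actually fitted by ordinary
least squares::

    ln W = a + x*ln A + y*ln H + b*G

All logarithms are natural logarithms; callers must supply raw
measurements (years, metres, kilograms), never pre-logged data.

The published coefficient set (fitted on a healthy Chinese Han reference
cohort) ships as a packaged constant and is the out-of-the-box default
everywhere a coefficient set is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AllometricCoefficients",
    "FitReport",
    "published_coefficients",
    "log_design",
    "fit_omam",
    "predict_weight",
    "AllometricWeightModel",
]

_TERMS = ("lnA", "lnH", "G")

# Stepwise thresholds: the conventional enter/remove defaults of classical
# stepwise regression software.
DEFAULT_ENTER_P = 0.05
DEFAULT_REMOVE_P = 0.10


@dataclass(frozen=True)
class AllometricCoefficients:
    """Coefficients of the log-linear allometric weight model.

    Parameters
    ----------
    intercept : float
        ``a`` on the log-kg scale.
    sex_effect : float
        ``b``, added to the intercept for men (dummy ``G = 1``).
    age_exponent : float
        ``x``, the power of age.
    height_exponent : float
        ``y``, the power of height.
    label : str
        Free-text provenance label.
    """

    intercept: float
    sex_effect: float
    age_exponent: float
    height_exponent: float
    label: str = ""

    @property
    def female_constant(self) -> float:
        """Multiplicative constant ``exp(a)`` of the women's equation."""
        return float(np.exp(self.intercept))

    @property
    def male_constant(self) -> float:
        """Multiplicative constant ``exp(a + b)`` of the men's equation."""
        return float(np.exp(self.intercept + self.sex_effect))

    def rounded(self, decimals: int = 4) -> "AllometricCoefficients":
        """Presentation copy with coefficients rounded to ``decimals``."""
        return AllometricCoefficients(
            round(self.intercept, decimals),
            round(self.sex_effect, decimals),
            round(self.age_exponent, decimals),
            round(self.height_exponent, decimals),
            self.label,
        )

    def to_json(self) -> str:
        d = {
            "a": self.intercept,
            "b": self.sex_effect,
            "x": self.age_exponent,
            "y": self.height_exponent,
            "label": self.label,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AllometricCoefficients":
        d = json.loads(text)
        return cls(d["a"], d["b"], d["x"], d["y"], d.get("label", ""))


@dataclass
class FitReport:
    """Result of fitting the log-linear model.

    ``selected_terms`` is the subset of ``{"lnA", "lnH", "G"}`` retained by
    the selection procedure; a term not selected has coefficient exactly 0
    in ``coefficients`` and contributes nothing to predictions.
    """

    coefficients: AllometricCoefficients
    selected_terms: tuple
    r2: float
    adjusted_r2: float
    residual_sd: float
    p_values: dict
    n_used: int

    def to_json(self) -> str:
        d = {
            "coefficients": json.loads(self.coefficients.to_json()),
            "selected_terms": list(self.selected_terms),
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "residual_sd": self.residual_sd,
            "p_values": self.p_values,
            "n_used": self.n_used,
        }
        return json.dumps(d, indent=2)


def published_coefficients() -> AllometricCoefficients:
    """The published reference coefficient set, exactly as printed.

    ``ln W = 2.7895 + 0.0526 ln A + 2.1659 ln H + 0.0326 G``.
    """
    text = resources.files("omam").joinpath("data/published.json").read_text()
    doc = json.loads(text)
    c = doc["coefficients"]
    return AllometricCoefficients(c["a"], c["b"], c["x"], c["y"], c["label"])


def _sex_dummy(sex) -> np.ndarray:
    """Map sex labels to the dummy G (male=1, female=0)."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "ifb":
        g = arr.astype(float)
        if not np.all(np.isin(g, (0.0, 1.0))):
            raise ValueError("numeric sex codes must be 0 (female) or 1 (male)")
        return g
    low = np.char.lower(arr.astype(str))
    g = np.where(np.isin(low, ("male", "m", "1")), 1.0, np.nan)
    g = np.where(np.isin(low, ("female", "f", "0")), 0.0, g)
    if np.any(np.isnan(g)):
        bad = sorted(set(arr[np.isnan(g)].tolist()))
        raise ValueError(f"unrecognised sex labels: {bad}")
    return g


def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be strictly positive and finite")
    return arr


def log_design(sex, age, height, weight=None):
    """Log-scale design row(s) ``(lnA, lnH, G)`` and, optionally, ``lnW``.

    Scalars in, scalars out; arrays in, arrays out.  Raises ``ValueError``
    on non-positive age, height or weight.
    """
    g = _sex_dummy(sex)
    ln_a = np.log(_check_positive("age", age))
    ln_h = np.log(_check_positive("height", height))
    if weight is None:
        return ln_a, ln_h, g
    ln_w = np.log(_check_positive("weight", weight))
    return ln_a, ln_h, g, ln_w


def predict_weight(coeffs: AllometricCoefficients, sex, age, height):
    """Predicted weight WP (kg) for the given sex, age (years), height (m)."""
    ln_a, ln_h, g = log_design(sex, age, height)
    ln_wp = (
        coeffs.intercept
        + coeffs.sex_effect * g
        + coeffs.age_exponent * ln_a
        + coeffs.height_exponent * ln_h
    )
    wp = np.exp(ln_wp)
    return float(wp) if np.ndim(wp) == 0 else wp


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _stepwise_select(y: np.ndarray, X: pd.DataFrame, enter_p: float, remove_p: float):
    """Forward selection with backward elimination over the candidate terms.

    Enter the best candidate whose partial t-test p-value is <= enter_p;
    after every entry, drop any included term whose p-value is >= remove_p.
    """
    included: list[str] = []
    while True:
        changed = False
        excluded = [t for t in X.columns if t not in included]
        if excluded:
            pvals = {}
            for term in excluded:
                res = _ols(y, X[included + [term]])
                pvals[term] = res.pvalues[term]
            best = min(pvals, key=pvals.get)
            if pvals[best] <= enter_p:
                included.append(best)
                changed = True
        while included:
            res = _ols(y, X[included])
            worst = res.pvalues[included].idxmax()
            if res.pvalues[worst] >= remove_p:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            return [t for t in X.columns if t in included]


def fit_omam(
    cohort,
    selection: str = "stepwise",
    enter_p: float = DEFAULT_ENTER_P,
    remove_p: float = DEFAULT_REMOVE_P,
) -> FitReport:
    """Fit the log-linear allometric model to a cohort.

    Parameters
    ----------
    cohort
        A :class:`~omam.cohort.Cohort` or a DataFrame with columns
        ``sex, age_years, height_m, weight_kg``.
    selection : {"stepwise", "full"}
        ``full`` fits all three terms; ``stepwise`` runs forward selection
        (entry p <= ``enter_p``) with backward removal (p >= ``remove_p``).

    Returns
    -------
    FitReport
        Coefficients (non-selected terms set to 0), selected terms,
        R-squared / adjusted R-squared, residual SD on the log scale, and
        per-term p-values.
    """
    df = getattr(cohort, "frame", cohort)
    n = len(df)
    if n < 10:
        raise ValueError(f"need at least 10 subjects to fit, got {n}")
    ln_a, ln_h, g, ln_w = log_design(
        df["sex"].to_numpy(), df["age_years"].to_numpy(),
        df["height_m"].to_numpy(), df["weight_kg"].to_numpy(),
    )
    X = pd.DataFrame({"lnA": ln_a, "lnH": ln_h, "G": g})
    if g.min() == g.max():
        raise ValueError("cohort must contain both sexes")
    for term in ("lnA", "lnH"):
        if np.ptp(X[term].to_numpy()) == 0:
            raise ValueError(f"predictor {term} has zero variance")

    if selection == "full":
        terms = list(_TERMS)
    elif selection == "stepwise":
        terms = _stepwise_select(ln_w, X, enter_p, remove_p)
    else:
        raise ValueError(f"unknown selection mode: {selection!r}")

    res = _ols(ln_w, X[terms])
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise ValueError("degenerate (collinear) design matrix")

    coef = {t: float(res.params.get(t, 0.0)) for t in _TERMS}
    coefficients = AllometricCoefficients(
        intercept=float(res.params["const"]),
        sex_effect=coef["G"],
        age_exponent=coef["lnA"],
        height_exponent=coef["lnH"],
        label=f"fitted (n={n}, selection={selection})",
    )
    p_values = {t: float(res.pvalues[t]) for t in terms}
    # residual SD on the log scale, df-corrected
    resid_sd = float(np.sqrt(res.scale)) if res.df_resid > 0 else 0.0
    return FitReport(
        coefficients=coefficients,
        selected_terms=tuple(terms),
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        residual_sd=resid_sd,
        p_values=p_values,
        n_used=n,
    )


class AllometricWeightModel(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for the allometric body-weight model.

    ``fit`` expects ``X`` as a DataFrame (or record array) with columns
    ``sex``, ``age_years``, ``height_m`` and ``y`` as measured weight in
    kilograms; fitting happens on the natural-log scale, predictions are
    returned on the kilogram scale.

    Parameters
    ----------
    selection : {"stepwise", "full"}, default="full"
        Term-selection strategy; see :func:`fit_omam`.
    enter_p, remove_p : float
        Stepwise entry/removal p-value thresholds.

    Attributes
    ----------
    coefficients_ : AllometricCoefficients
    report_ : FitReport
    """

    def __init__(self, selection: str = "full",
                 enter_p: float = DEFAULT_ENTER_P,
                 remove_p: float = DEFAULT_REMOVE_P):
        self.selection = selection
        self.enter_p = enter_p
        self.remove_p = remove_p

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        df = getattr(X, "frame", X)
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
        missing = {"sex", "age_years", "height_m"} - set(df.columns)
        if missing:
            raise ValueError(f"X is missing columns: {sorted(missing)}")
        return df

    def fit(self, X, y=None):
        df = self._as_frame(X)
        if y is None:
            if "weight_kg" not in df.columns:
                raise ValueError("y not given and X has no weight_kg column")
            y = df["weight_kg"].to_numpy()
        df = df.assign(weight_kg=np.asarray(y, dtype=float))
        self.report_ = fit_omam(df, selection=self.selection,
                                enter_p=self.enter_p, remove_p=self.remove_p)
        self.coefficients_ = self.report_.coefficients
        self.n_features_in_ = 3
        return self

    @classmethod
    def from_coefficients(cls, coeffs: AllometricCoefficients) -> "AllometricWeightModel":
        """A ready-to-predict model wrapping an existing coefficient set."""
        model = cls()
        model.coefficients_ = coeffs
        model.report_ = None
        model.n_features_in_ = 3
        return model

    @classmethod
    def published(cls) -> "AllometricWeightModel":
        """A ready-to-predict model carrying the published coefficients."""
        return cls.from_coefficients(published_coefficients())

    def predict(self, X):
        check_is_fitted(self, "coefficients_")
        df = self._as_frame(X)
        return np.asarray(
            predict_weight(
                self.coefficients_,
                df["sex"].to_numpy(),
                df["age_years"].to_numpy(),
                df["height_m"].to_numpy(),
            ),
            dtype=float,
        ).reshape(-1)
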
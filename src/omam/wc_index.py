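"""Corrected-weight scoring, reference thresholds and classification.

The corrected weight WC is the ratio of measured weight W to the weight
WP predicted by the allometric model for the subject's sex, age and
height.  In a reference population WC is dimensionless and centred near
1; its empirical 97.5th percentile defines the upper limit of the normal
reference range and hence the overweight criterion.

Two classification rules live here, with deliberately different boundary
conventions (both verbatim conventions of the reference analysis):

* corrected weight: overweight iff WC > cutoff (strict; the published
  cutoff is 1.1440);
* body mass index: overweight iff BMI >= cutoff (inclusive; default
  25.0 kg/m^2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .allometric import AllometricCoefficients, AllometricWeightModel, predict_weight, published_coefficients
from .cohort import DEFAULT_QUANTILE_RULE, body_mass_index

__all__ = [
    "CorrectedWeight",
    "ThresholdSpec",
    "corrected_weight",
    "wc_scores",
    "derive_threshold",
    "published_threshold",
    "classify_wc",
    "classify_bmi",
    "score_cohort",
    "CorrectedWeightClassifier",
    "BMIClassifier",
]

logger = logging.getLogger(__name__)

DEFAULT_LEVEL = 0.975
DEFAULT_BMI_CUTOFF = 25.0
MIN_RELIABLE_N = 40


@dataclass(frozen=True)
class CorrectedWeight:
    """A single corrected-weight score WC = W / WP."""

    wc: float
    wp: float
    measured_w: float


@dataclass(frozen=True)
class ThresholdSpec:
    """A percentile-based reference cutoff for WC.

    ``lower_cutoff`` carries the symmetric lower reference bound (the
    (1-level) percentile, i.e. the underweight side); it is reported for
    completeness but plays no part in overweight classification.
    """

    level: float
    cutoff: float
    n_source: int
    quantile_rule: str
    label: str = ""
    lower_cutoff: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "level": self.level,
                "cutoff": self.cutoff,
                "n_source": self.n_source,
                "quantile_rule": self.quantile_rule,
                "label": self.label,
                "lower_cutoff": self.lower_cutoff,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdSpec":
        d = json.loads(text)
        return cls(d["level"], d["cutoff"], d["n_source"],
                   d["quantile_rule"], d.get("label", ""),
                   d.get("lower_cutoff"))


def corrected_weight(measured: float, predicted: float) -> CorrectedWeight:
    """WC for one subject: measured weight divided by predicted weight."""
    if measured <= 0 or predicted <= 0:
        raise ValueError("measured and predicted weight must be positive")
    return CorrectedWeight(wc=measured / predicted, wp=predicted,
                           measured_w=measured)


def wc_scores(cohort, coeffs: Optional[AllometricCoefficients] = None) -> np.ndarray:
    """Vector of WC scores for a whole cohort (order preserved)."""
    if coeffs is None:
        coeffs = published_coefficients()
    df = getattr(cohort, "frame", cohort)
    wp = predict_weight(coeffs, df["sex"].to_numpy(),
                        df["age_years"].to_numpy(), df["height_m"].to_numpy())
    return df["weight_kg"].to_numpy() / np.asarray(wp)


def derive_threshold(
    wc_sample,
    level: float = DEFAULT_LEVEL,
    quantile_rule: str = DEFAULT_QUANTILE_RULE,
    label: str = "",
) -> ThresholdSpec:
    """Empirical reference cutoff at ``level`` from a WC sample.

    The default quantile estimator interpolates linearly at rank
    (n+1)*level on the sorted sample, clamped to the extremes (numpy's
    "weibull" rule).  Below 40 observations the upper 2.5% tail is
    unstable, so a warning is logged.
    """
    wc = np.asarray(wc_sample, dtype=float)
    if wc.size == 0:
        raise ValueError("wc_sample must be nonempty")
    if not np.all(np.isfinite(wc)):
        raise ValueError("wc_sample contains non-finite values")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie strictly between 0 and 1")
    if wc.size < MIN_RELIABLE_N:
        logger.warning(
            "derive_threshold: only %d observations; the %.1f%% tail "
            "estimate will be unstable", wc.size, 100 * (1 - level),
        )
    cutoff = float(np.quantile(wc, level, method=quantile_rule))
    lower = float(np.quantile(wc, 1.0 - level, method=quantile_rule))
    return ThresholdSpec(level=level, cutoff=cutoff, n_source=int(wc.size),
                         quantile_rule=quantile_rule, label=label,
                         lower_cutoff=lower)


def published_threshold() -> ThresholdSpec:
    """The published overweight cutoff WC > 1.1440 (97.5th percentile)."""
    text = resources.files("omam").joinpath("data/published.json").read_text()
    d = json.loads(text)["threshold"]
    return ThresholdSpec(level=d["level"], cutoff=d["cutoff"],
                         n_source=d["n_source"],
                         quantile_rule=d["quantile_rule"], label=d["label"])


def classify_wc(wc, threshold: Optional[ThresholdSpec] = None):
    """Classify WC score(s): ``overweight`` iff WC > cutoff, else ``normal``.

    The boundary value itself is normal (strict inequality).
    """
    if threshold is None:
        threshold = published_threshold()
    arr = np.asarray(wc, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("WC scores must be positive and finite")
    labels = np.where(arr > threshold.cutoff, "overweight", "normal")
    return str(labels) if np.ndim(wc) == 0 else labels


def classify_bmi(weight_kg, height_m, cutoff: float = DEFAULT_BMI_CUTOFF):
    """Classify by BMI: ``overweight`` iff BMI >= cutoff (inclusive)."""
    bmi = np.asarray(body_mass_index(weight_kg, height_m))
    labels = np.where(bmi >= cutoff, "overweight", "normal")
    return str(labels) if np.ndim(labels) == 0 else labels


def score_cohort(
    cohort,
    coeffs: Optional[AllometricCoefficients] = None,
    threshold: Optional[ThresholdSpec] = None,
    bmi_cutoff: float = DEFAULT_BMI_CUTOFF,
) -> pd.DataFrame:
    """Score every subject; appends ``wp_kg, wc, wc_class, bmi, bmi_class``.

    Row order equals input order and the input is never mutated.
    Defaults to the published coefficients and threshold.
    """
    if coeffs is None:
        coeffs = published_coefficients()
    if threshold is None:
        threshold = published_threshold()
    df = getattr(cohort, "frame", cohort)
    if len(df) == 0:
        raise ValueError("cannot score an empty cohort")
    out = df.copy()
    wp = np.asarray(predict_weight(coeffs, df["sex"].to_numpy(),
                                   df["age_years"].to_numpy(),
                                   df["height_m"].to_numpy()))
    wc = df["weight_kg"].to_numpy() / wp
    out["wp_kg"] = wp
    out["wc"] = wc
    out["wc_class"] = classify_wc(wc, threshold)
    out["bmi"] = body_mass_index(df["weight_kg"].to_numpy(),
                                 df["height_m"].to_numpy())
    out["bmi_class"] = classify_bmi(df["weight_kg"].to_numpy(),
                                    df["height_m"].to_numpy(), bmi_cutoff)
    return out


class CorrectedWeightClassifier(BaseEstimator, ClassifierMixin):
    """Overweight classifier based on the corrected weight WC.

    ``fit(X)`` derives the reference cutoff as the empirical ``level``
    percentile of WC in the training frame (a reference population of
    normal-weight adults); ``predict(X)`` returns 1 for overweight
    (WC strictly above the cutoff) and 0 otherwise.  ``X`` is a DataFrame
    with columns ``sex, age_years, height_m, weight_kg``.

    Parameters
    ----------
    model : AllometricWeightModel or None
        Fitted weight model used for WP.  ``None`` (default) uses the
        published coefficients.  Pass an unfitted model to have it fitted
        on the training frame during ``fit`` (the reference-cohort
        workflow: fit equations and threshold on the same subgroup).
    level : float, default 0.975
        Reference percentile.
    threshold : ThresholdSpec or None
        Pre-derived cutoff; when given, ``fit`` only validates input.
    quantile_rule : str
        Quantile estimator name (numpy method).
    """

    def __init__(self, model=None, level: float = DEFAULT_LEVEL,
                 threshold: Optional[ThresholdSpec] = None,
                 quantile_rule: str = DEFAULT_QUANTILE_RULE):
        self.model = model
        self.level = level
        self.threshold = threshold
        self.quantile_rule = quantile_rule

    def _resolve_model(self) -> AllometricWeightModel:
        if self.model is None:
            return AllometricWeightModel.published()
        return self.model

    def fit(self, X, y=None):
        df = getattr(X, "frame", X)
        model = self._resolve_model()
        if not hasattr(model, "coefficients_"):
            from sklearn.base import clone
            model = clone(model).fit(df)
        self.model_ = model
        if self.threshold is not None:
            self.threshold_ = self.threshold
        else:
            wc = df["weight_kg"].to_numpy() / model.predict(df)
            self.threshold_ = derive_threshold(
                wc, level=self.level, quantile_rule=self.quantile_rule,
                label="fitted reference cohort")
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        """WC scores (centred at the cutoff would be wc - cutoff; raw WC here)."""
        check_is_fitted(self, "threshold_")
        df = getattr(X, "frame", X)
        return df["weight_kg"].to_numpy() / self.model_.predict(df)

    def predict(self, X):
        wc = self.decision_function(X)
        return (wc > self.threshold_.cutoff).astype(int)


class BMIClassifier(BaseEstimator, ClassifierMixin):
    """Overweight classifier by body mass index (BMI >= cutoff).

    Stateless apart from the configured cutoff; ``fit`` is a no-op kept
    for pipeline compatibility.
    """

    def __init__(self, cutoff: float = DEFAULT_BMI_CUTOFF):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        self.classes_ = np.array([0, 1])
        self.cutoff_ = self.cutoff
        return self

    def decision_function(self, X):
        df = getattr(X, "frame", X)
        return body_mass_index(df["weight_kg"].to_numpy(),
                               df["height_m"].to_numpy())

    def predict(self, X):
        if not hasattr(self, "cutoff_"):
            self.fit(X)
        return (self.decision_function(X) >= self.cutoff_).astype(int)
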
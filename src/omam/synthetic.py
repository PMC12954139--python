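"""Synthetic cohorts with the statistical structure of the reference data.

The generator emulates a sex-balanced healthy adult reference
population: ages uniform over the inclusion window [18, 79]; heights
normal within sex around the reference medians (1.71 m men, 1.60 m
women) with SD chosen so the IQR matches the reference 0.07 m
(SD = IQR / 1.349 under normality), truncated to (1.2, 2.2) m; and
weights generated from the log-linear allometric model with additive
Gaussian noise on the log scale.  With the published coefficients and
zero noise every subject's corrected weight is exactly 1.

The residual SD is the one free parameter the printed summaries do not
pin down; :func:`calibrate_sigma` backs it out of the reported model fit
(adjusted R-squared) by Monte Carlo.

All generators are pure functions of (params, seed).  The single seed is
expanded into independent per-stream seeds with a fixed derivation
(``SeedSequence(seed, spawn_key=(stream,))``) so adding a stream never
perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional

import numpy as np
from scipy import optimize, stats

from .allometric import AllometricCoefficients, published_coefficients
from .cohort import DISEASES, Cohort, body_mass_index
from .wc_index import DEFAULT_BMI_CUTOFF, wc_scores

__all__ = [
    "GeneratorParams",
    "DiseaseLinkParams",
    "generate_normal_cohort",
    "calibrate_sigma",
    "generate_overweight_cohort",
    "generate_disease_cohort",
    "tune_intercepts",
]

# fixed per-stream identifiers for seed derivation
_STREAMS = {"sex": 0, "age": 1, "height": 2, "noise": 3,
            "inflation": 4, "disease": 5}

HEIGHT_TRUNCATION = (1.2, 2.2)
# normal-model SD reproducing the reference height IQR of 0.07 m
IQR_TO_SD = 1.349
DEFAULT_HEIGHT_SD = 0.07 / IQR_TO_SD


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the reference-population generator.

    Defaults reproduce the reference cohort's printed structure: equal
    sexes, ages uniform on [18, 79] (median 46, IQR ~27 as reported),
    per-sex height means 1.71 / 1.60 m with SD 0.052 m, and weights from
    the published coefficients with log-scale residual SD 0.1.
    """

    n: int = 1224
    sex_ratio: float = 0.5
    age_range: tuple = (18.0, 79.0)
    male_height_mean: float = 1.71
    female_height_mean: float = 1.60
    height_sd: float = DEFAULT_HEIGHT_SD
    coefficients: AllometricCoefficients = field(
        default_factory=published_coefficients)
    residual_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if self.height_sd <= 0:
            raise ValueError("height_sd must be positive")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("n", "sex_ratio", "age_range", "male_height_mean",
              "female_height_mean", "height_sd", "residual_sd", "seed")}
        d["coefficients"] = json.loads(self.coefficients.to_json())
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class DiseaseLinkParams:
    """Logistic link from WC to binary disease labels.

    ``links`` maps each disease code to (intercept, slope); the label
    probability for a subject is ``expit(intercept + slope * WC)``.
    """

    links: Mapping[str, tuple]
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.links) - set(DISEASES)
        if unknown:
            raise ValueError(f"unknown disease codes: {sorted(unknown)}")

    def to_json(self) -> str:
        return json.dumps({"links": {k: list(v) for k, v in self.links.items()},
                           "seed": self.seed}, indent=2)


def _draw_anthropometry(params: GeneratorParams, n: int, seed: int):
    sex_rng = _rng(seed, "sex")
    age_rng = _rng(seed, "age")
    height_rng = _rng(seed, "height")
    male = sex_rng.random(n) < params.sex_ratio
    lo, hi = params.age_range
    age = age_rng.uniform(lo, hi, size=n)
    mean = np.where(male, params.male_height_mean, params.female_height_mean)
    a, b = HEIGHT_TRUNCATION
    u = height_rng.random(n)
    alpha = (a - mean) / params.height_sd
    beta = (b - mean) / params.height_sd
    height = stats.truncnorm.ppf(u, alpha, beta, loc=mean,
                                 scale=params.height_sd)
    return male, age, height


def _weights_from_model(params: GeneratorParams, male, age, height, seed: int):
    c = params.coefficients
    ln_wp = (c.intercept + c.sex_effect * male.astype(float)
             + c.age_exponent * np.log(age)
             + c.height_exponent * np.log(height))
    eps = _rng(seed, "noise").normal(0.0, params.residual_sd, size=len(age))
    return np.exp(ln_wp + eps)


def _as_cohort(male, age, height, weight, provenance: str,
               start_id: int = 0) -> Cohort:
    import pandas as pd
    n = len(age)
    frame = pd.DataFrame({
        "subject_id": [f"S{start_id + i:06d}" for i in range(n)],
        "sex": np.where(male, "male", "female"),
        "age_years": age,
        "height_m": height,
        "weight_kg": weight,
    })
    return Cohort(frame, provenance=provenance)


def generate_normal_cohort(params: GeneratorParams) -> Cohort:
    """Draw a reference (normal-weight-type) cohort from the model."""
    male, age, height = _draw_anthropometry(params, params.n, params.seed)
    weight = _weights_from_model(params, male, age, height, params.seed)
    return _as_cohort(male, age, height, weight,
                      provenance=f"synthetic reference (seed={params.seed})")


def calibrate_sigma(
    params: GeneratorParams,
    target_adj_r2: float = 0.6634,
    n_mc: int = 200_000,
) -> float:
    """Residual SD that makes the model fit reach a target adjusted R^2.

    Estimates the variance V of the linear predictor
    ``a + x lnA + y lnH + bG`` by Monte Carlo under ``params`` and
    returns ``sqrt(V * (1 - target) / target)``, the noise SD at which
    the population R-squared equals the target.
    """
    if not (0.0 < target_adj_r2 < 1.0):
        raise ValueError("target_adj_r2 must lie strictly in (0, 1)")
    male, age, height = _draw_anthropometry(params, n_mc, params.seed)
    c = params.coefficients
    eta = (c.sex_effect * male.astype(float)
           + c.age_exponent * np.log(age)
           + c.height_exponent * np.log(height))
    v = float(np.var(eta))
    if v <= 0:
        raise ValueError("degenerate covariate model: zero signal variance")
    return float(np.sqrt(v * (1.0 - target_adj_r2) / target_adj_r2))


def generate_overweight_cohort(
    params: GeneratorParams,
    inflation=1.25,
    bmi_cutoff: float = DEFAULT_BMI_CUTOFF,
    sex_counts: Optional[tuple] = None,
    max_batches: int = 200,
) -> Cohort:
    """An overweight-type cohort: inflated weights, filtered on BMI.

    Subjects are drawn from the reference model, their weights multiplied
    by draws from ``inflation`` (a scalar >= 1 or a callable
    ``f(rng, size) -> array`` with support >= 1), and only subjects
    meeting the BMI criterion are retained until ``params.n`` (or the
    per-sex quotas in ``sex_counts = (n_male, n_female)``) are collected.
    """
    inf_rng = _rng(params.seed, "inflation")
    if callable(inflation):
        draw = inflation
    else:
        if inflation < 1:
            raise ValueError("inflation must be >= 1")
        draw = lambda rng, size: np.full(size, float(inflation))

    if sex_counts is not None:
        need = {"male": sex_counts[0], "female": sex_counts[1]}
        total_needed = sum(need.values())
    else:
        need = None
        total_needed = params.n

    kept = {"male": [], "female": []}
    batch = max(4 * total_needed, 1000)
    drawn = accepted = 0
    for i in range(max_batches):
        sub = replace(params, n=batch, seed=params.seed + 100_003 * (i + 1))
        male, age, height = _draw_anthropometry(sub, batch, sub.seed)
        weight = _weights_from_model(sub, male, age, height, sub.seed)
        factors = np.asarray(draw(inf_rng, batch), dtype=float)
        if np.any(factors < 1):
            raise ValueError("inflation draws must be >= 1")
        weight = weight * factors
        ok = body_mass_index(weight, height) >= bmi_cutoff
        drawn += batch
        accepted += int(ok.sum())
        for sex_label, is_sex in (("male", male), ("female", ~male)):
            sel = ok & is_sex
            kept[sex_label].append(
                np.column_stack([male[sel], age[sel], height[sel], weight[sel]]))
        have = {s: sum(len(a) for a in kept[s]) for s in kept}
        if need is not None:
            if all(have[s] >= need[s] for s in need):
                break
        elif sum(have.values()) >= total_needed:
            break
        if drawn >= 10 * batch and accepted / drawn < 0.01:
            raise RuntimeError(
                "overweight generator acceptance rate below 1%; "
                "increase the inflation factor")
    else:
        raise RuntimeError("overweight generator did not reach the quota")

    parts = []
    for sex_label in ("male", "female"):
        arr = np.concatenate(kept[sex_label]) if kept[sex_label] else np.empty((0, 4))
        quota = need[sex_label] if need is not None else len(arr)
        parts.append(arr[:quota])
    data = np.concatenate(parts)
    if need is None:
        data = data[:total_needed]
    male = data[:, 0].astype(bool)
    return _as_cohort(male, data[:, 1], data[:, 2], data[:, 3],
                      provenance=f"synthetic overweight (seed={params.seed})")


def generate_disease_cohort(
    params: GeneratorParams,
    link: DiseaseLinkParams,
    n: Optional[int] = None,
) -> Cohort:
    """A cohort with WC-linked binary disease labels.

    Anthropometry comes from the reference generator (``n`` overrides
    ``params.n``); each disease label is Bernoulli with probability
    ``expit(intercept + slope * WC)``.
    """
    if n is not None:
        params = replace(params, n=n)
    cohort = generate_normal_cohort(params)
    wc = wc_scores(cohort, params.coefficients)
    rng = _rng(link.seed, "disease")
    frame = cohort.frame.copy()
    for disease in DISEASES:
        if disease not in link.links:
            continue
        intercept, slope = link.links[disease]
        p = 1.0 / (1.0 + np.exp(-(intercept + slope * wc)))
        frame[disease] = (rng.random(len(frame)) < p).astype(int)
    return Cohort(frame, provenance=f"synthetic disease cohort "
                                    f"(seed={params.seed}/{link.seed})")


def tune_intercepts(
    slopes: Mapping[str, float],
    prevalences: Mapping[str, float],
    params: GeneratorParams,
    n_mc: int = 100_000,
) -> DiseaseLinkParams:
    """Choose logistic intercepts hitting target disease prevalences.

    Given per-disease slopes on WC and target marginal prevalences,
    solves ``E[expit(a + slope * WC)] = prevalence`` for each intercept
    by root-finding over a Monte Carlo sample of WC under ``params``.
    """
    mc = replace(params, n=n_mc)
    wc = wc_scores(generate_normal_cohort(mc), params.coefficients)
    links = {}
    for disease, slope in slopes.items():
        target = prevalences[disease]
        if not (0.0 < target < 1.0):
            raise ValueError("target prevalence must lie in (0, 1)")

        def gap(a, _s=slope, _t=target):
            return float(np.mean(1.0 / (1.0 + np.exp(-(a + _s * wc))))) - _t

        links[disease] = (float(optimize.brentq(gap, -50, 50)), float(slope))
    return DiseaseLinkParams(links=links, seed=params.seed)
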
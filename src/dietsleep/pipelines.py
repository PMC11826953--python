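"""End-to-end analysis stages: quartile regression, reallocation, substitution.

Three analyses run on an analysis-ready cohort table, each adjusted for
age, sex and BMI:

* ``quartile_regression`` — one OLS model per (exposure, outcome) pair with
  dummy variables for quartiles 2–4 of the exposure against the lowest
  quartile (forced entry: dummies and covariates all enter).
* ``compda_reallocation_table`` — compositional analysis: each outcome is
  regressed on the four ilr balance coordinates of the macronutrient energy
  composition, and the estimand for a nutrient is the model-predicted
  outcome difference between the cohort's compositional mean and that mean
  with 6 % of energy displaced into (or out of) the nutrient, the other
  parts scaled proportionally.
* ``isotemporal_table`` — isocaloric one-to-one substitution: the same
  fitted models, contrasting the compositional mean against a pairwise swap
  of 6 % of energy from one nutrient to another with the rest untouched.

Prediction contrasts hold covariates at identical values in both rows, so
they cancel exactly; confidence intervals come from the residual standard
error, the model-matrix cross-product inverse and the t critical value.
Because ilr coordinates under any orthonormal basis are affinely
equivalent, a single default-basis fit per outcome serves every focal
nutrient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .composition import (
    KCAL_PER_GRAM,
    NUTRIENTS,
    ReallocationSpec,
    closure,
    compositional_mean,
    ilr,
    reallocate,
    substitute_pairwise,
)
from .regression import FittedModel, fit_ols, predict_difference_ci
from .simulate import OUTCOMES

__all__ = [
    "GRAM_COLUMNS",
    "COMPOSITION_COLUMNS",
    "PCT_ENERGY_COLUMNS",
    "DEFAULT_QUARTILE_EXPOSURES",
    "derive_exposures",
    "quartile_assign",
    "quartile_regression",
    "compda_reallocation_table",
    "isotemporal_table",
    "fit_ilr_models",
]

GRAM_COLUMNS = ("protein_g", "carb_g", "satfat_g", "monofat_g", "polyfat_g")
COMPOSITION_COLUMNS = tuple(f"comp_{n}" for n in NUTRIENTS)
PCT_ENERGY_COLUMNS = (
    "protein_pct_e",
    "carb_pct_e",
    "satfat_pct_e",
    "monofat_pct_e",
    "polyfat_pct_e",
)

DEFAULT_QUARTILE_EXPOSURES = (
    "energy_kcal",
    "protein_pct_e",
    "carb_pct_e",
    "fat_pct_e",
    "satfat_pct_e",
    "monofat_pct_e",
    "polyfat_pct_e",
    "sodium_mg",
    "potassium_mg",
    "fiber_g",
    "na_k_ratio",
)

_COVARIATES = ("age_years", "sex_female", "bmi")


def derive_exposures(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add energy-adjusted and compositional exposure columns.

    Macronutrients are energy adjusted as percentage of total energy intake
    (grams x kcal-factor / energy x 100, plus their sum ``fat_pct_e`` for the
    three fat classes); sodium, potassium and fiber stay absolute;
    ``na_k_ratio`` is the mass ratio of sodium to potassium; and the closed
    5-part energy composition is attached as ``comp_*`` columns.
    """
    missing = [c for c in (*GRAM_COLUMNS, "energy_kcal") if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort is missing intake columns: {missing}")
    df = cohort.copy()
    energy = df["energy_kcal"].to_numpy(dtype=float)
    if np.any(energy <= 0):
        raise ValueError("total energy intake must be strictly positive")
    kcal = df[list(GRAM_COLUMNS)].to_numpy(dtype=float) * KCAL_PER_GRAM
    pct = 100.0 * kcal / energy[:, None]
    for j, col in enumerate(PCT_ENERGY_COLUMNS):
        df[col] = pct[:, j]
    df["fat_pct_e"] = pct[:, 2:].sum(axis=1)
    comp = closure(kcal)
    for j, col in enumerate(COMPOSITION_COLUMNS):
        df[col] = comp[:, j]
    if {"sodium_mg", "potassium_mg"}.issubset(df.columns):
        potassium = df["potassium_mg"].to_numpy(dtype=float)
        if np.any(potassium <= 0):
            raise ValueError("potassium intake must be strictly positive")
        df["na_k_ratio"] = df["sodium_mg"].to_numpy(dtype=float) / potassium
    if "sex" in df.columns and "sex_female" not in df.columns:
        df["sex_female"] = (df["sex"].astype(str) == "female").astype(float)
    return df


def quartile_assign(values) -> tuple[np.ndarray, np.ndarray]:
    """Quartile labels (1–4) and the three sample-percentile cutpoints.

    Cutpoints are the 25th/50th/75th percentiles under the
    linear-interpolation convention; intervals are closed on the right, so a
    value equal to a cutpoint falls in the lower quartile.  Requires at
    least four distinct values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if np.unique(values).size < 4:
        raise ValueError("quartile categorisation needs at least 4 distinct values")
    cutpoints = np.percentile(values, [25, 50, 75])
    labels = 1 + np.searchsorted(cutpoints, values, side="left")
    return labels, cutpoints


def _covariate_block(df: pd.DataFrame) -> np.ndarray:
    if "sex_female" not in df.columns:
        if "sex" not in df.columns:
            raise KeyError("cohort needs a 'sex' or 'sex_female' column")
        df = df.assign(sex_female=(df["sex"].astype(str) == "female").astype(float))
    return df[["age_years", "sex_female", "bmi"]].to_numpy(dtype=float)


def quartile_regression(
    cohort: pd.DataFrame,
    exposures=DEFAULT_QUARTILE_EXPOSURES,
    outcomes=OUTCOMES,
    level: float = 0.95,
) -> pd.DataFrame:
    """Quartile dummy-variable regression of each exposure on each outcome.

    One forced-entry model per (exposure, outcome): outcome on Q2–Q4
    dummies plus age, sex and BMI.  Returns one row per (exposure, outcome,
    quartile 2–4) with the estimate and CI against the first (reference)
    quartile, which is never itself reported.
    """
    df = cohort if all(e in cohort.columns for e in exposures) else derive_exposures(cohort)
    covars = _covariate_block(df)
    rows = []
    for exposure in exposures:
        labels, cuts = quartile_assign(df[exposure].to_numpy(dtype=float))
        dummies = np.column_stack([(labels == q).astype(float) for q in (2, 3, 4)])
        X = np.column_stack([np.ones(len(df)), dummies, covars])
        names = ("intercept", "Q2", "Q3", "Q4", *_COVARIATES)
        for outcome in outcomes:
            fit = fit_ols(X, df[outcome].to_numpy(dtype=float), columns=names)
            for q in (2, 3, 4):
                x1 = np.zeros(len(names))
                x1[q - 1] = 1.0
                ci = predict_difference_ci(fit, x1, np.zeros(len(names)), level=level)
                rows.append(
                    {
                        "exposure": exposure,
                        "outcome": outcome,
                        "quartile": f"Q{q}",
                        "cut_25": cuts[0],
                        "cut_50": cuts[1],
                        "cut_75": cuts[2],
                        "estimate": ci.estimate,
                        "ci_low": ci.lower,
                        "ci_high": ci.upper,
                        "significant": ci.significant,
                    }
                )
    return pd.DataFrame(rows)


def _composition_matrix(cohort: pd.DataFrame) -> np.ndarray:
    if all(c in cohort.columns for c in COMPOSITION_COLUMNS):
        return cohort[list(COMPOSITION_COLUMNS)].to_numpy(dtype=float)
    return closure(cohort[list(GRAM_COLUMNS)].to_numpy(dtype=float) * KCAL_PER_GRAM)


def fit_ilr_models(
    cohort: pd.DataFrame, outcomes=OUTCOMES, basis: np.ndarray | None = None
) -> tuple[dict[str, FittedModel], np.ndarray, np.ndarray]:
    """Fit outcome ~ ilr balances + age + sex + BMI for each outcome.

    Returns the fits, the cohort's compositional mean and the covariate
    means (at which contrasts hold the covariates; any common value gives
    identical contrasts since covariates cancel).
    """
    comp = _composition_matrix(cohort)
    Z = ilr(comp, basis)
    covars = _covariate_block(cohort)
    X = np.column_stack([np.ones(len(cohort)), Z, covars])
    names = ("intercept", *(f"z{k+1}" for k in range(Z.shape[1])), *_COVARIATES)
    fits = {
        outcome: fit_ols(X, cohort[outcome].to_numpy(dtype=float), columns=names)
        for outcome in outcomes
    }
    return fits, compositional_mean(comp), covars.mean(axis=0)


def _contrast_row(z, covar_values) -> np.ndarray:
    return np.concatenate([[1.0], np.ravel(z), np.ravel(covar_values)])


def compda_reallocation_table(
    cohort: pd.DataFrame,
    delta: float = 0.06,
    level: float = 0.95,
    basis: np.ndarray | None = None,
    outcomes=OUTCOMES,
) -> pd.DataFrame:
    """Proportional +/-delta reallocation estimands for every nutrient.

    For each nutrient and each mode (take ``delta`` from it and distribute
    proportionally / add ``delta`` to it from the others) the table reports
    the model-predicted outcome difference at the compositional mean with
    its CI: 5 nutrients x 2 modes x ``len(outcomes)`` rows.
    """
    fits, xbar, covar_means = fit_ilr_models(cohort, outcomes, basis)
    zbar = ilr(xbar, basis)
    x0 = _contrast_row(zbar, covar_means)
    rows = []
    for nutrient in NUTRIENTS:
        for mode in ("take", "add"):
            spec = ReallocationSpec(nutrient, delta, mode)
            z_new = ilr(reallocate(xbar, spec), basis)
            x1 = _contrast_row(z_new, covar_means)
            for outcome in outcomes:
                ci = predict_difference_ci(fits[outcome], x1, x0, level=level)
                rows.append(
                    {
                        "nutrient": nutrient,
                        "mode": mode,
                        "delta": delta,
                        "outcome": outcome,
                        "estimate": ci.estimate,
                        "ci_low": ci.lower,
                        "ci_high": ci.upper,
                        "significant": ci.significant,
                    }
                )
    return pd.DataFrame(rows)


def isotemporal_table(
    cohort: pd.DataFrame,
    delta: float = 0.06,
    level: float = 0.95,
    basis: np.ndarray | None = None,
    outcomes=OUTCOMES,
) -> pd.DataFrame:
    """Pairwise isocaloric substitution estimands for every ordered pair.

    Contrasts the compositional mean against a one-to-one swap of ``delta``
    energy share from one nutrient to another (all other parts constant),
    for every ordered (from, to) pair with from != to: 5 x 4 x
    ``len(outcomes)`` rows.
    """
    fits, xbar, covar_means = fit_ilr_models(cohort, outcomes, basis)
    zbar = ilr(xbar, basis)
    x0 = _contrast_row(zbar, covar_means)
    rows = []
    for frm in NUTRIENTS:
        for to in NUTRIENTS:
            if frm == to:
                continue
            z_new = ilr(substitute_pairwise(xbar, frm, to, delta), basis)
            x1 = _contrast_row(z_new, covar_means)
            for outcome in outcomes:
                ci = predict_difference_ci(fits[outcome], x1, x0, level=level)
                rows.append(
                    {
                        "from_nutrient": frm,
                        "to_nutrient": to,
                        "delta": delta,
                        "outcome": outcome,
                        "estimate": ci.estimate,
                        "ci_low": ci.lower,
                        "ci_high": ci.upper,
                        "significant": ci.significant,
                    }
                )
    return pd.DataFrame(rows)
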
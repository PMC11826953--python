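"""Seeded synthetic cohorts with plantable diet–sleep effects.

No participant-level data are deposited for the app cohort this package
analyses, so every pipeline stage is exercised against a simulator whose
defaults reproduce the published cohort's marginal structure: n = 4825
analysed participants, 81.6 % female, mean age 36.7 (SD 10.4) years, BMI
24.8 (SD 4.8) kg/m2, mean total sleep time 6.7 (SD 1.1) h, sleep-onset
latency 21.5 (SD 12.1) min, %WASO 9.9 (SD 7.2), energy 1662.6 (SD 330.3)
kcal/d, and a mean macronutrient energy composition of
(protein 18.2, carbohydrate 53.8, saturated 9.7, monounsaturated 11.8,
polyunsaturated 6.5) %.

Compositions are logistic-normal: the four default-pivot balance
coordinates are drawn from a normal centred at the balances of the mean
composition (diagonal SD 0.12) and back-transformed, which guarantees
strict positivity and closure.  Sleep outcomes follow a linear model on
balance coordinates:

    y = mu + sum_j b_j * z1_j(x) + covariate terms + noise,

where each planted effect j places a coefficient on the first (pivot)
balance of its focal nutrient and the coefficients are calibrated jointly
so that the model-implied prediction difference of each planted
reallocation equals its requested value exactly.  The systematic part is
centred empirically, so marginal outcome means are preserved.  Latency and
%WASO noise is gamma (moment-matched) because normal noise would produce
negative times; total sleep time is normal, truncated to a plausible
(0, 14] h.

The generator can also plant the three exclusion categories of the study
flow chart — missing sleep summaries, total-sleep-time outliers, and
short-usage participants — to exercise the filtering cascade end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .composition import (
    NUTRIENTS,
    KCAL_PER_GRAM,
    ReallocationSpec,
    closure,
    ilr,
    ilr_inv,
    make_basis,
    nutrient_index,
    reallocate,
)

__all__ = [
    "OUTCOMES",
    "PARTICIPANT_COLUMNS",
    "DAILY_LOG_COLUMNS",
    "OutcomeParams",
    "PlantedEffect",
    "GeneratorConfig",
    "default_planted_effects",
    "calibrate_balance_effect",
    "planted_coefficients",
    "generate_cohort",
    "generate_daily_logs",
]

OUTCOMES = ("tst_h", "sl_min", "waso_pct")

PARTICIPANT_COLUMNS = (
    "participant_id",
    "age_years",
    "sex",
    "bmi",
    "protein_g",
    "carb_g",
    "satfat_g",
    "monofat_g",
    "polyfat_g",
    "energy_kcal",
    "sodium_mg",
    "potassium_mg",
    "fiber_g",
    "tst_h",
    "sl_min",
    "waso_pct",
    "days_sleep",
    "days_diet",
)

DAILY_LOG_COLUMNS = (
    "participant_id",
    "date",
    "breakfast",
    "lunch",
    "dinner",
    "protein_g",
    "carb_g",
    "satfat_g",
    "monofat_g",
    "polyfat_g",
    "energy_kcal",
    "sodium_mg",
    "potassium_mg",
    "fiber_g",
    "tst_h",
    "sl_min",
    "waso_pct",
    "diet_recorded",
    "sleep_recorded",
)

_GRAM_COLUMNS = ("protein_g", "carb_g", "satfat_g", "monofat_g", "polyfat_g")

# Covariate slopes (age per year, female indicator, BMI per kg/m2) entering
# the outcome models; centred at generation time so marginal means are kept.
# The sex contrasts mirror the male/female gaps of the reference cohort.
_COVARIATE_EFFECTS = {
    "tst_h": (-0.005, 0.2, -0.01),
    "sl_min": (0.05, -2.4, 0.1),
    "waso_pct": (0.05, -3.9, 0.1),
}

_AGE_BOUNDS = (18.0, 80.0)
_BMI_BOUNDS = (14.0, 60.0)
_TST_BOUNDS = (1e-3, 14.0)


@dataclass(frozen=True)
class OutcomeParams:
    """Marginal mean/SD and noise family ('normal' or 'gamma') of an outcome."""

    mean: float
    sd: float
    family: str = "normal"

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("outcome SD must be non-negative")
        if self.family not in ("normal", "gamma"):
            raise ValueError(f"unknown noise family {self.family!r}")


@dataclass(frozen=True)
class PlantedEffect:
    """A reallocation whose model-implied outcome difference is fixed by design."""

    realloc: ReallocationSpec
    outcome: str
    difference: float

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


def default_planted_effects() -> tuple[PlantedEffect, ...]:
    """Reference scenario: three significant add-6% effects.

    Adding 6 % of energy to protein lengthens total sleep time by 0.27 h;
    adding 6 % to monounsaturated fat lengthens sleep latency by 4.64 min;
    adding 6 % to polyunsaturated fat shortens it by 4.72 min.
    """
    return (
        PlantedEffect(ReallocationSpec("protein", 0.06, "add"), "tst_h", 0.27),
        PlantedEffect(ReallocationSpec("monounsaturated_fat", 0.06, "add"), "sl_min", 4.64),
        PlantedEffect(ReallocationSpec("polyunsaturated_fat", 0.06, "add"), "sl_min", -4.72),
    )


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the reference cohort."""

    n_participants: int = 4825
    seed: int = 0
    mean_composition: tuple = (0.182, 0.538, 0.097, 0.118, 0.065)
    ilr_sd: tuple = (0.12, 0.12, 0.12, 0.12)
    outcome_params: dict = field(
        default_factory=lambda: {
            "tst_h": OutcomeParams(6.7, 1.1, "normal"),
            "sl_min": OutcomeParams(21.5, 12.1, "gamma"),
            "waso_pct": OutcomeParams(9.9, 7.2, "gamma"),
        }
    )
    # demographics
    age_mean: float = 36.7
    age_sd: float = 10.4
    bmi_mean: float = 24.8
    bmi_sd: float = 4.8
    p_female: float = 0.816
    # non-compositional exposures
    energy_mean: float = 1662.6
    energy_sd: float = 330.3
    fiber_mean: float = 11.7
    fiber_sd: float = 3.5
    potassium_mean: float = 2295.3
    potassium_sd: float = 602.1
    na_k_mean: float = 1.6
    na_k_sd: float = 0.4
    # app-usage day counts
    days_sleep_mean: float = 134.0
    days_sleep_sd: float = 54.5
    days_diet_mean: float = 85.8
    days_diet_sd: float = 63.6
    # planted diet–sleep effects
    planted_effects: tuple = field(default_factory=default_planted_effects)
    # planted exclusion categories (flow-chart stages); 0 = clean cohort
    n_missing_sleep: int = 0
    n_tst_outliers: int = 0
    n_short_usage: int = 0
    # day-level log generation
    days_per_participant: int = 28
    p_complete_day: float = 0.8
    daily_noise_cv: float = 0.15

    def __post_init__(self):
        mc = np.asarray(self.mean_composition, dtype=float)
        if mc.shape != (len(NUTRIENTS),) or not np.all(mc > 0):
            raise ValueError("mean_composition must be 5 strictly positive shares")
        if abs(mc.sum() - 1.0) > 1e-9:
            raise ValueError("mean_composition must sum to 1")
        self.mean_composition = tuple(mc / mc.sum())
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        if self.n_excluded > self.n_participants:
            raise ValueError("planted exclusions exceed n_participants")
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must lie in [0, 1]")
        if not 0.0 <= self.p_complete_day <= 1.0:
            raise ValueError("p_complete_day must lie in [0, 1]")
        if min(self.n_missing_sleep, self.n_tst_outliers, self.n_short_usage) < 0:
            raise ValueError("exclusion counts must be non-negative")
        if self.days_per_participant < 0:
            raise ValueError("days_per_participant must be non-negative")
        sds = (
            *self.ilr_sd,
            self.age_sd,
            self.bmi_sd,
            self.energy_sd,
            self.fiber_sd,
            self.potassium_sd,
            self.na_k_sd,
            self.days_sleep_sd,
            self.days_diet_sd,
        )
        if any(s < 0 for s in sds):
            raise ValueError("all SD parameters must be non-negative")
        if len(self.ilr_sd) != len(NUTRIENTS) - 1:
            raise ValueError("ilr_sd must have D-1 entries")

    @property
    def n_excluded(self) -> int:
        return self.n_missing_sleep + self.n_tst_outliers + self.n_short_usage

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


def calibrate_balance_effect(
    target_difference: float,
    realloc: ReallocationSpec,
    mean_comp,
    basis: np.ndarray,
) -> float:
    """Coefficient on the focal pivot balance implying a given difference.

    Returns ``b = target / (z1(reallocate(x, realloc)) - z1(x))`` where z1 is
    the first balance of ``basis``.  Planting ``b`` on that balance alone
    makes the model-implied difference of the reallocation exactly the
    target.  Raises on a degenerate reallocation with zero displacement.
    """
    x = closure(mean_comp)
    z1 = float(basis[0] @ np.log(x))
    z1_new = float(basis[0] @ np.log(reallocate(x, realloc)))
    dz = z1_new - z1
    if abs(dz) < 1e-12:
        raise ValueError("reallocation does not move the focal balance (zero displacement)")
    return float(target_difference) / dz


def planted_coefficients(config: GeneratorConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-outcome balance directions and coefficients hitting all targets.

    Each planted effect contributes one coefficient on its focal pivot
    balance.  When an outcome carries several effects, a reallocation aimed
    at one nutrient also moves the other focal balances, so the
    coefficients are solved jointly from the linear system

        sum_j b_j * [z1_j(x_i') - z1_j(xbar)] = difference_i .

    Returns ``{outcome: (U, b)}`` with ``U`` the stacked first-balance rows
    (so the systematic term is ``(ln x @ U.T) @ b``).
    """
    xbar = np.asarray(config.mean_composition)
    logx = np.log(xbar)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for outcome in OUTCOMES:
        effects = [e for e in config.planted_effects if e.outcome == outcome]
        if not effects:
            continue
        U = np.stack(
            [make_basis(len(xbar), focal=e.realloc.nutrient)[0] for e in effects]
        )
        A = np.empty((len(effects), len(effects)))
        for i, e in enumerate(effects):
            dlog = np.log(reallocate(xbar, e.realloc)) - logx
            A[i] = U @ dlog
        targets = np.array([e.difference for e in effects])
        b = np.linalg.solve(A, targets)
        out[outcome] = (U, b)
    return out


def _lognormal(rng, mean, sd, size):
    """Lognormal draws moment-matched to the requested mean and SD."""
    if sd == 0:
        return np.full(size, float(mean))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    draws = rng.normal(mean, sd, size)
    return np.clip(draws, lo, hi)


def _empty_participants() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in PARTICIPANT_COLUMNS})
    df["participant_id"] = df["participant_id"].astype(int)
    df["sex"] = df["sex"].astype(str)
    df["days_sleep"] = df["days_sleep"].astype(int)
    df["days_diet"] = df["days_diet"].astype(int)
    return df


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one analysis-ready row per participant.

    The first ``n_participants - n_excluded`` conceptual rows are clean; the
    planted exclusion rows (missing sleep summary, total-sleep-time
    outliers at mean +/- 6 SD, short app usage) are mixed in by a seeded
    shuffle.  Identical configs (including the seed) produce byte-identical
    tables.
    """
    n = config.n_participants
    if n == 0:
        return _empty_participants()
    rng = np.random.default_rng(config.seed)

    # demographics
    female = rng.random(n) < config.p_female
    sex = np.where(female, "female", "male")
    age = _truncated_normal(rng, config.age_mean, config.age_sd, *_AGE_BOUNDS, n)
    bmi = _truncated_normal(rng, config.bmi_mean, config.bmi_sd, *_BMI_BOUNDS, n)

    # composition: logistic-normal on the default pivot basis
    xbar = np.asarray(config.mean_composition)
    zbar = ilr(xbar)
    z = zbar + rng.normal(0.0, config.ilr_sd, size=(n, len(zbar)))
    comp = ilr_inv(z)

    # intakes
    energy = _lognormal(rng, config.energy_mean, config.energy_sd, n)
    grams = comp * energy[:, None] / KCAL_PER_GRAM
    fiber = _lognormal(rng, config.fiber_mean, config.fiber_sd, n)
    potassium = _lognormal(rng, config.potassium_mean, config.potassium_sd, n)
    na_k = _lognormal(rng, config.na_k_mean, config.na_k_sd, n)
    sodium = na_k * potassium  # ratio controlled directly in expectation

    # app usage
    days_sleep = np.rint(
        _truncated_normal(rng, config.days_sleep_mean, config.days_sleep_sd, 7, 365, n)
    ).astype(int)
    days_diet = np.rint(
        _truncated_normal(rng, config.days_diet_mean, config.days_diet_sd, 7, 365, n)
    ).astype(int)

    # outcomes: planted balance effects + centred covariates + noise
    coeffs = planted_coefficients(config)
    logc = np.log(comp)
    covars = np.column_stack([age, female.astype(float), bmi])
    covar_centre = np.array([config.age_mean, config.p_female, config.bmi_mean])
    outcomes = {}
    for name in OUTCOMES:
        params = config.outcome_params[name]
        systematic = np.zeros(n)
        if name in coeffs:
            U, b = coeffs[name]
            systematic += (logc @ U.T) @ b
        systematic += (covars - covar_centre) @ np.asarray(_COVARIATE_EFFECTS[name])
        systematic -= systematic.mean()  # keep the marginal mean on target
        var_sys = systematic.var()
        noise_var = max(params.sd**2 - var_sys, (0.05 * params.sd) ** 2)
        if params.family == "normal":
            y = params.mean + systematic + rng.normal(0.0, np.sqrt(noise_var), n)
        else:  # gamma noise keeps skewed, non-negative marginals
            shape = params.mean**2 / noise_var
            scale = noise_var / params.mean
            y = rng.gamma(shape, scale, n) + systematic
        outcomes[name] = y
    outcomes["tst_h"] = np.clip(outcomes["tst_h"], *_TST_BOUNDS)
    outcomes["sl_min"] = np.maximum(outcomes["sl_min"], 0.0)
    outcomes["waso_pct"] = np.clip(outcomes["waso_pct"], 0.0, 100.0)

    # plant the exclusion categories on the tail rows, then shuffle
    n_clean = n - config.n_excluded
    idx = n_clean
    miss = slice(idx, idx + config.n_missing_sleep)
    idx += config.n_missing_sleep
    outl = slice(idx, idx + config.n_tst_outliers)
    idx += config.n_tst_outliers
    short = slice(idx, idx + config.n_short_usage)

    for name in OUTCOMES:
        outcomes[name][miss] = np.nan
    tst_params = config.outcome_params["tst_h"]
    lo = max(_TST_BOUNDS[0], tst_params.mean - 6 * tst_params.sd)
    hi = tst_params.mean + 6 * tst_params.sd
    n_out = outl.stop - outl.start
    outcomes["tst_h"][outl] = np.where(np.arange(n_out) % 2 == 0, lo, hi)
    days_sleep[short] = rng.integers(1, 7, short.stop - short.start)
    days_diet[short] = rng.integers(1, 7, short.stop - short.start)

    order = rng.permutation(n)
    df = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "age_years": age[order],
            "sex": sex[order],
            "bmi": bmi[order],
            **{col: grams[order, j] for j, col in enumerate(_GRAM_COLUMNS)},
            "energy_kcal": energy[order],
            "sodium_mg": sodium[order],
            "potassium_mg": potassium[order],
            "fiber_g": fiber[order],
            **{name: outcomes[name][order] for name in OUTCOMES},
            "days_sleep": days_sleep[order],
            "days_diet": days_diet[order],
        }
    )
    return df[list(PARTICIPANT_COLUMNS)]


def _empty_logs() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in DAILY_LOG_COLUMNS})
    for c in ("participant_id", "date"):
        df[c] = df[c].astype(int)
    for c in ("breakfast", "lunch", "dinner", "diet_recorded", "sleep_recorded"):
        df[c] = df[c].astype(bool)
    return df


def generate_daily_logs(config: GeneratorConfig, cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-day meal and sleep logs consistent with a participant table.

    Day values are the participant's averages perturbed by mean-one
    multiplicative lognormal noise, so averages over retained days
    reproduce the participant-level values in expectation.  A day is
    complete (all three meals logged) with probability ``p_complete_day``;
    incomplete days have at least one meal flag false.  Uses an rng stream
    derived from, but distinct from, the cohort stream.
    """
    if cohort is None:
        cohort = generate_cohort(config)
    days = config.days_per_participant
    if days == 0 or len(cohort) == 0:
        return _empty_logs()
    rng = np.random.default_rng([config.seed, 1])
    n = len(cohort)
    m = n * days
    pid = np.repeat(cohort["participant_id"].to_numpy(), days)
    date = np.tile(np.arange(days), n)

    cv = config.daily_noise_cv

    def noisy(col):
        base = np.repeat(cohort[col].to_numpy(dtype=float), days)
        return base * _lognormal(rng, 1.0, cv, m)

    grams = {c: noisy(c) for c in _GRAM_COLUMNS}
    energy = sum(grams[c] * k for c, k in zip(_GRAM_COLUMNS, KCAL_PER_GRAM))
    sodium, potassium, fiber = noisy("sodium_mg"), noisy("potassium_mg"), noisy("fiber_g")
    tst = np.clip(noisy("tst_h"), 0, None)
    sl = np.clip(noisy("sl_min"), 0, None)
    waso = np.clip(noisy("waso_pct"), 0, 100)

    complete = rng.random(m) < config.p_complete_day
    flags = rng.random((m, 3)) < 0.6
    all_true = flags.all(axis=1)
    flags[all_true, rng.integers(0, 3, int(all_true.sum()))] = False
    flags[complete] = True

    sleep_ok = ~np.isnan(np.repeat(cohort["tst_h"].to_numpy(dtype=float), days))
    df = pd.DataFrame(
        {
            "participant_id": pid,
            "date": date,
            "breakfast": flags[:, 0],
            "lunch": flags[:, 1],
            "dinner": flags[:, 2],
            **grams,
            "energy_kcal": energy,
            "sodium_mg": sodium,
            "potassium_mg": potassium,
            "fiber_g": fiber,
            "tst_h": tst,
            "sl_min": sl,
            "waso_pct": waso,
            "diet_recorded": np.ones(m, dtype=bool),
            "sleep_recorded": sleep_ok,
        }
    )
    return df[list(DAILY_LOG_COLUMNS)]
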
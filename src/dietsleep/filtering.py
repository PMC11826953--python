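"""Cohort construction: day-level filters, averaging, exclusions, summaries.

The analysis cohort is built from two per-participant record streams — a
food-log stream and a nightly sleep stream — collected through separate
apps.  Days are kept only when all three meals were logged (a missing meal
cannot be told apart from a skipped recording), both streams are restricted
to their overlapping date range, per-day values are averaged into one row
per participant, and an exclusion cascade then removes, in order,

1. participants with a missing sleep summary (or any missing analysis
   variable),
2. total-sleep-time outliers beyond ``mean +/- z_cut * SD`` (sample SD,
   computed once on the post-stage-1 cohort),
3. participants with fewer than ``min_days`` retained days in either stream.

Every removal is tallied in an :class:`ExclusionLedger` so the counts always
reconcile with the consented total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MEAL_FLAGS",
    "SLEEP_COLUMNS",
    "DIET_COLUMNS",
    "ExclusionLedger",
    "filter_complete_meal_days",
    "restrict_overlap_and_average",
    "apply_exclusions",
    "cohort_summary",
]

MEAL_FLAGS = ("breakfast", "lunch", "dinner")
SLEEP_COLUMNS = ("tst_h", "sl_min", "waso_pct")
DIET_COLUMNS = (
    "protein_g",
    "carb_g",
    "satfat_g",
    "monofat_g",
    "polyfat_g",
    "energy_kcal",
    "sodium_mg",
    "potassium_mg",
    "fiber_g",
)


@dataclass(frozen=True)
class ExclusionLedger:
    """Stage counts of the exclusion cascade; always reconciles."""

    consented: int
    missing_sleep: int
    tst_outliers: int
    short_usage: int

    def __post_init__(self):
        if min(self.consented, self.missing_sleep, self.tst_outliers, self.short_usage) < 0:
            raise ValueError("ledger counts must be non-negative")
        if self.analyzed < 0:
            raise ValueError("exclusions exceed the consented count")

    @property
    def analyzed(self) -> int:
        return self.consented - self.missing_sleep - self.tst_outliers - self.short_usage

    def to_dict(self) -> dict:
        return {
            "consented": self.consented,
            "missing_sleep": self.missing_sleep,
            "tst_outliers": self.tst_outliers,
            "short_usage": self.short_usage,
            "analyzed": self.analyzed,
        }


def filter_complete_meal_days(logs: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the day rows where all three meal flags are true."""
    missing = [c for c in MEAL_FLAGS if c not in logs.columns]
    if missing:
        raise KeyError(f"daily logs are missing meal-flag columns: {missing}")
    mask = np.ones(len(logs), dtype=bool)
    for c in MEAL_FLAGS:
        mask &= logs[c].astype(bool).to_numpy()
    return logs.loc[mask].copy()


def restrict_overlap_and_average(
    logs: pd.DataFrame, demographics: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Average each participant's days inside the overlap of both streams.

    The overlap window is ``[max(first diet day, first sleep night),
    min(last diet day, last sleep night)]``.  Diet fields are averaged over
    complete-meal diet days inside the window, sleep fields over sleep
    nights inside it; ``days_diet``/``days_sleep`` record the retained
    counts.  A participant whose streams do not overlap is still emitted,
    with zero day counts and missing averages (removed later by the
    minimum-usage rule).  ``demographics`` (participant_id, age_years, sex,
    bmi) is merged in when provided.
    """
    required = {"participant_id", "date"}
    if not required.issubset(logs.columns):
        raise KeyError(f"daily logs need columns {sorted(required)}")
    df = logs.copy()
    diet_flag = df["diet_recorded"].astype(bool) if "diet_recorded" in df else pd.Series(True, index=df.index)
    sleep_flag = df["sleep_recorded"].astype(bool) if "sleep_recorded" in df else pd.Series(True, index=df.index)
    complete = pd.Series(True, index=df.index)
    for c in MEAL_FLAGS:
        if c in df:
            complete &= df[c].astype(bool)

    def spans(flag):
        sub = df.loc[flag, ["participant_id", "date"]]
        return sub.groupby("participant_id")["date"].agg(["min", "max"])

    diet_span, sleep_span = spans(diet_flag), spans(sleep_flag)
    span = diet_span.join(sleep_span, how="outer", lsuffix="_diet", rsuffix="_sleep")
    start = span[["min_diet", "min_sleep"]].max(axis=1)
    end = span[["max_diet", "max_sleep"]].min(axis=1)

    pid = df["participant_id"]
    in_window = df["date"].ge(pid.map(start)) & df["date"].le(pid.map(end))

    diet_cols = [c for c in DIET_COLUMNS if c in df.columns]
    sleep_cols = [c for c in SLEEP_COLUMNS if c in df.columns]

    diet_rows = df.loc[in_window & diet_flag & complete, ["participant_id", *diet_cols]]
    sleep_rows = df.loc[in_window & sleep_flag, ["participant_id", *sleep_cols]].dropna(
        subset=sleep_cols or None
    )

    diet_avg = diet_rows.groupby("participant_id").mean()
    diet_avg["days_diet"] = diet_rows.groupby("participant_id").size()
    sleep_avg = sleep_rows.groupby("participant_id").mean()
    sleep_avg["days_sleep"] = sleep_rows.groupby("participant_id").size()

    everyone = pd.Index(sorted(df["participant_id"].unique()), name="participant_id")
    out = diet_avg.join(sleep_avg, how="outer").reindex(everyone)
    out[["days_diet", "days_sleep"]] = out[["days_diet", "days_sleep"]].fillna(0).astype(int)
    out = out.reset_index()
    if demographics is not None:
        out = out.merge(demographics, on="participant_id", how="left")
    lead = ["participant_id"] + [c for c in ("age_years", "sex", "bmi") if c in out.columns]
    rest = [c for c in out.columns if c not in lead]
    return out[lead + rest]


def apply_exclusions(
    cohort: pd.DataFrame, min_days: int = 7, z_cut: float = 3.0
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the three-stage exclusion cascade; return survivors and ledger.

    Stage 1 removes rows with a missing sleep summary (missingness in any
    other analysis variable also removes the row, with a logged reason).
    Stage 2 removes total-sleep-time outliers outside ``mean +/- z_cut *
    sample SD``, with mean and SD computed once on the post-stage-1 cohort.
    Stage 3 removes rows with fewer than ``min_days`` retained days in
    either stream.
    """
    if min_days < 0 or z_cut < 0:
        raise ValueError("min_days and z_cut must be non-negative")
    consented = len(cohort)
    df = cohort

    sleep_cols = [c for c in SLEEP_COLUMNS if c in df.columns]
    if "tst_h" not in df.columns:
        raise KeyError("cohort must carry a tst_h column")
    other_cols = [c for c in DIET_COLUMNS if c in df.columns]
    missing_sleep = df[sleep_cols].isna().any(axis=1)
    missing_other = df[other_cols].isna().any(axis=1) & ~missing_sleep
    if int(missing_other.sum()):
        log.warning(
            "%d rows removed for missingness in non-sleep analysis variables", int(missing_other.sum())
        )
    stage1 = missing_sleep | missing_other
    df = df.loc[~stage1]

    tst = df["tst_h"].to_numpy(dtype=float)
    if len(tst) >= 2:
        m, s = tst.mean(), tst.std(ddof=1)
        outlier = np.abs(tst - m) > z_cut * s
    else:
        outlier = np.zeros(len(tst), dtype=bool)
    df = df.loc[~outlier]

    if {"days_sleep", "days_diet"}.issubset(df.columns):
        short = (df["days_sleep"] < min_days) | (df["days_diet"] < min_days)
    else:
        short = pd.Series(False, index=df.index)
    kept = df.loc[~short].copy()

    ledger = ExclusionLedger(
        consented=consented,
        missing_sleep=int(stage1.sum()),
        tst_outliers=int(outlier.sum()),
        short_usage=int(short.sum()),
    )
    return kept, ledger


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of every numeric variable, overall and by sex.

    Returns one row per variable with columns ``{all,male,female}_{mean,sd}``.
    Group sizes and the female percentage (one decimal) are stored in
    ``DataFrame.attrs``.  A single-row group reports SD 0 by convention.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarise an empty cohort")
    numeric = cohort.select_dtypes(include=[np.number]).drop(
        columns=["participant_id"], errors="ignore"
    )
    groups = {"all": cohort.index}
    n_female = n_male = 0
    if "sex" in cohort.columns:
        sexes = cohort["sex"].astype(str)
        groups["male"] = cohort.index[sexes == "male"]
        groups["female"] = cohort.index[sexes == "female"]
        n_male, n_female = len(groups["male"]), len(groups["female"])
    out = pd.DataFrame(index=numeric.columns)
    for name, idx in groups.items():
        sub = numeric.loc[idx]
        out[f"{name}_mean"] = sub.mean()
        out[f"{name}_sd"] = sub.std(ddof=1).fillna(0.0) if len(sub) else np.nan
    out.index.name = "variable"
    out.attrs["n"] = len(cohort)
    out.attrs["n_male"] = n_male
    out.attrs["n_female"] = n_female
    out.attrs["pct_female"] = round(100.0 * n_female / len(cohort), 1)
    return out
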
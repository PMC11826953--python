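"""One-shot pipeline runs: configuration, artifact emission, forest plots.

``run_pipeline`` ties the stages together — simulate (or load) a
participant table, apply the exclusion cascade, summarise, derive
exposures, and emit the quartile, reallocation and substitution tables plus
diagnostics — writing headered CSV/JSON artifacts and a run log into one
output directory.  The same configuration and seed produce identical
tabular artifacts; only the run log carries timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composition import ilr
from .filtering import apply_exclusions, cohort_summary, filter_complete_meal_days, restrict_overlap_and_average
from .pipelines import (
    _composition_matrix,
    _covariate_block,
    compda_reallocation_table,
    derive_exposures,
    fit_ilr_models,
    isotemporal_table,
    quartile_regression,
)
from .regression import diagnostics
from .simulate import GeneratorConfig, OUTCOMES, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_run_config", "run_pipeline", "render_forest"]


@dataclass
class RunConfig:
    """Inputs, generator overrides and analysis settings for one run."""

    participants_csv: str | None = None  # None -> simulate
    daily_logs_csv: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    delta: float = 0.06
    level: float = 0.95
    seed: int | None = None  # overrides generator.seed when set
    min_days: int = 7
    z_cut: float = 3.0
    out_dir: str = "dietsleep_out"
    make_plots: bool = True

    def __post_init__(self):
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        max_delta = min(self.generator.mean_composition)
        if not 0 < self.delta < max_delta:
            raise ValueError(
                f"delta must lie in (0, {max_delta:g}), the smallest mean share; got {self.delta:g}"
            )
        if not 0 < self.level < 1:
            raise ValueError("confidence level must lie in (0, 1)")
        if self.seed is not None:
            self.generator = self.generator.with_seed(self.seed)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML key-value file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and return a manifest of written artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    log_lines: list[str] = []

    def note(msg: str) -> None:
        stamp = pd.Timestamp.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")
        log.info(msg)

    note(f"run start; config hash {config.config_hash()}; seed {config.generator.seed}")

    if config.participants_csv is not None:
        cohort_raw = pd.read_csv(config.participants_csv)
        note(f"loaded {len(cohort_raw)} participants from {config.participants_csv}")
    elif config.daily_logs_csv is not None:
        logs = pd.read_csv(config.daily_logs_csv)
        logs = filter_complete_meal_days(logs)
        cohort_raw = restrict_overlap_and_average(logs)
        note(f"built {len(cohort_raw)} participants from daily logs {config.daily_logs_csv}")
    else:
        cohort_raw = generate_cohort(config.generator)
        manifest["participants"] = _write_csv(cohort_raw, out / "participants.csv")
        note(f"simulated {len(cohort_raw)} participants")

    cohort, ledger = apply_exclusions(cohort_raw, config.min_days, config.z_cut)
    ledger_path = out / "exclusion_ledger.json"
    ledger_path.write_text(json.dumps(ledger.to_dict(), indent=2) + "\n")
    manifest["exclusion_ledger"] = ledger_path
    note(f"exclusions {ledger.to_dict()}")
    if len(cohort) == 0:
        raise ValueError("no participants remain after exclusions")

    exposures = derive_exposures(cohort)
    summary = cohort_summary(exposures)
    summary_out = summary.reset_index()
    manifest["table1_summary"] = _write_csv(summary_out, out / "table1_summary.csv")
    note(f"cohort summary: n={summary.attrs['n']}, {summary.attrs['pct_female']}% female")

    quart = quartile_regression(exposures, level=config.level)
    manifest["quartile_results"] = _write_csv(quart, out / "quartile_results.csv")
    realloc = compda_reallocation_table(exposures, delta=config.delta, level=config.level)
    manifest["reallocation_results"] = _write_csv(realloc, out / "reallocation_results.csv")
    iso = isotemporal_table(exposures, delta=config.delta, level=config.level)
    manifest["isotemporal_results"] = _write_csv(iso, out / "isotemporal_results.csv")
    note(
        f"tables: quartile {len(quart)} rows, reallocation {len(realloc)} rows, "
        f"isotemporal {len(iso)} rows"
    )

    diag_path = out / "diagnostics.txt"
    fits, _, _ = fit_ilr_models(exposures)
    Z = ilr(_composition_matrix(exposures))
    X = np.column_stack([np.ones(len(exposures)), Z, _covariate_block(exposures)])
    with open(diag_path, "w") as fh:
        for outcome in OUTCOMES:
            rep = diagnostics(fits[outcome], X, exposures[outcome].to_numpy(dtype=float))
            fh.write(f"[{outcome}] " + json.dumps(rep, sort_keys=True) + "\n")
    manifest["diagnostics"] = diag_path

    if config.make_plots:
        manifest["reallocation_forest"] = render_forest(
            realloc, out / "reallocation_forest.png", title="Proportional 6% reallocation"
        )

    run_log = out / "run.log"
    run_log.write_text("\n".join(log_lines + ["run end"]) + "\n")
    manifest["run_log"] = run_log
    return manifest


_OUTCOME_TITLES = {
    "tst_h": "Total sleep time (h)",
    "sl_min": "Sleep latency (min)",
    "waso_pct": "%WASO",
}


def _row_labels(results: pd.DataFrame) -> pd.Series:
    if {"nutrient", "mode"}.issubset(results.columns):
        return results["nutrient"].str.replace("_", " ") + " (" + results["mode"] + ")"
    if {"from_nutrient", "to_nutrient"}.issubset(results.columns):
        return (
            results["from_nutrient"].str.replace("_", " ")
            + " → "
            + results["to_nutrient"].str.replace("_", " ")
        )
    if {"exposure", "quartile"}.issubset(results.columns):
        return results["exposure"] + " " + results["quartile"]
    return pd.Series([str(i) for i in results.index], index=results.index)


def render_forest(results: pd.DataFrame, path: str | Path, title: str | None = None) -> Path:
    """Forest plot of estimates with CI whiskers, one panel per outcome."""
    from matplotlib.figure import Figure

    if len(results) == 0:
        raise ValueError("nothing to plot: empty results table")
    required = {"outcome", "estimate", "ci_low", "ci_high"}
    if not required.issubset(results.columns):
        raise KeyError(f"results need columns {sorted(required)}")
    bad = results[["estimate", "ci_low", "ci_high"]].isna().any(axis=1)
    if bad.any():
        log.warning("skipping %d rows with missing estimate or CI", int(bad.sum()))
        results = results.loc[~bad]
    outcomes = [o for o in _OUTCOME_TITLES if o in set(results["outcome"])] or sorted(
        set(results["outcome"])
    )
    fig = Figure(figsize=(4.0 * len(outcomes), max(3.0, 0.32 * results["outcome"].value_counts().max())))
    axes = fig.subplots(1, len(outcomes), squeeze=False)[0]
    for ax, outcome in zip(axes, outcomes):
        sub = results[results["outcome"] == outcome]
        labels = _row_labels(sub)
        y = np.arange(len(sub))[::-1]
        err = np.vstack(
            [sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]]
        )
        ax.errorbar(sub["estimate"], y, xerr=err, fmt="o", color="black", ecolor="gray", capsize=2)
        ax.axvline(0.0, color="firebrick", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(labels, fontsize=7)
        ax.set_title(_OUTCOME_TITLES.get(outcome, outcome), fontsize=9)
    if title:
        fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    return path
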
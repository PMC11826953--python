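"""Simulate a roster with planted exclusions and run the cascade.

Builds a synthetic consented roster of 6052 app users containing 140
participants with missing sleep summaries, 377 total-sleep-time outliers
and 710 short-usage participants, then applies the staged exclusion
cascade and summarises the analysis cohort.
"""

import dietsleep as ds

config = ds.GeneratorConfig(
    n_participants=6052,
    n_missing_sleep=140,
    n_tst_outliers=377,
    n_short_usage=710,
    seed=20240131,
)
roster = ds.generate_cohort(config)
cohort, ledger = ds.apply_exclusions(roster, min_days=7, z_cut=3.0)

print("exclusion cascade:", ledger.to_dict())
print("  consented minus the three exclusion stages leaves the analysis cohort")

summary = ds.cohort_summary(cohort)
print(f"analysis cohort: n={summary.attrs['n']}, {summary.attrs['pct_female']}% female")
for var, label in [("tst_h", "total sleep time (h)"), ("sl_min", "sleep latency (min)"),
                   ("waso_pct", "%WASO"), ("energy_kcal", "energy (kcal/d)")]:
    row = summary.loc[var]
    print(f"  {label:24s} mean {row['all_mean']:7.1f}  SD {row['all_sd']:6.1f}")
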
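"""Simulate the full three-group study and compare binding windows.

The default synthetic cohort has 53 dyslexic children (CD), 53 controls (TD)
and 37 adults (AD, two of whom do only the temporal-order task), with a
fixed number of deliberately unfittable observers per group. We fit every
participant, summarize exclusions, and run the one-way window ANOVA with LSD
pairwise follow-ups.
"""

from avsync import default_cohort_config, sample_cohort, aggregate_synchrony, fit_cohort
from avsync.psychometric import FitConfig, summarize_exclusions
from avsync.stats import window_anova, within_va_av_contrast

config = default_cohort_config(seed=7)
_, trials, truth = sample_cohort(config)
profiles = aggregate_synchrony([t for t in trials if t.task == "SJ"])
windows = fit_cohort(profiles, FitConfig())

summary = summarize_exclusions(
    {r.participant_id: (r.group, r.status) for r in windows.itertuples()}
)
for g in summary.groups:
    print(f"{g.group}: {g.n_excluded}/{g.n_enrolled} unfittable "
          f"({g.exclusion_percent:.2f}%), {g.n_fitted} analyzed")

ok = windows[windows["status"] == "ok"]
print("\nmean windows (ms) among fitted participants:")
print(ok.groupby("group")[["av_tbw", "va_tbw", "tbw", "pss"]].mean().round(1))

res = window_anova(windows, "tbw")
row = res["anova"].iloc[0]
print(f"\ntotal TBW ANOVA: F({row.df1}, {row.df2}) = {row.F:.2f}, "
      f"p = {row.p:.4f}, partial eta^2 = {row.np2:.3f}")
print(res["lsd"].round(3).to_string(index=False))

print("\nVA vs AV half-window (paired), per group:")
for group in ("CD", "TD", "AD"):
    row = within_va_av_contrast(windows, group).iloc[0]
    print(f"  {group}: F({row.df1}, {row.df2}) = {row.F:.2f}, p = {row.p:.4f}")
print("\nA wider window in CD than TD, and VA > AV asymmetry in children but")
print("not adults, mirrors the generative group parameters.")
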
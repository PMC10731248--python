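"""Generate a synthetic two-timepoint cohort and run the grouped statistics.

The cohort emulates a neoadjuvant-chemotherapy study: 8 good and 9 poor
responders (Miller-Payne grades 4-5 vs 1-3), baseline ROI medians and
percentage changes after the first cycle drawn around the published effect
sizes, Ki-67 changes rank-coupled to the perfusion-fraction change.  The
report mirrors the usual layout: per-marker group medians (IQR), Wilcoxon
rank-sum p-values, and Spearman correlations against Ki-67.
"""

from ivimtools.stats import run_cohort_analysis
from ivimtools.synthetic import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(seed=11))
df = cohort.to_frame()
print(f"{len(df)} patients ({(df.group == 'good').sum()} good / "
      f"{(df.group == 'poor').sum()} poor); "
      f"{df['pct_change_f'].notna().sum()} completed the Cycle-1 scan\n")

report = run_cohort_analysis(cohort)
print(report.to_text())
print()
print("With only 16 follow-up patients a single synthetic cohort often fails")
print("to reach p < 0.05 on the %change-f comparison; across many seeds the")
print("group medians centre on the injected -7.98% / +10.04% effect sizes.")
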
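"""End-to-end analysis report on a synthetic cohort.

Runs load -> derived ratios -> univariate table -> KDE intervals and
C-statistics -> FDA -> seafood correlations -> subtype-exclusion
sensitivity rerun, and writes the report files into ``report/``.
"""

from fattyroc import default_paper_spec, run_full_analysis
from fattyroc.pipeline import write_report

report = run_full_analysis(default_paper_spec(), seed=7)
path = write_report(report, "report")
s = report.summary()

print(f"report written to {path}")
print(f"cohorts: {s['n_asd']} ASD vs {s['n_neu']} NEU")
print(f"smallest raw p-value:       {s['min_p_raw']:.4f}")
print(f"smallest adjusted p-value:  {s['min_p_adjusted']:.4f}")
print(f"largest univariate C:       {s['max_univariate_c']:.3f}")
print(f"FDA score C-statistic:      {s['fda_c_statistic']:.3f}")
print(f"power note: d={report.power_note['d']} at alpha="
      f"{report.power_note['alpha']} needs "
      f"{report.power_note['min_n_per_group']} per group")
print("sensitivity rerun (subtype exclusions) is in report/sensitivity.csv;")
print("adjusted p-values and moderate C-statistics together say the panel")
print("separates cohorts weakly at the individual level.")
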
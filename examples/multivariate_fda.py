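"""Fisher discriminant classification and seafood-intake correlation.

FDA projects the standardized 15-analyte panel onto the direction
maximizing between- to within-class scatter; the score C-statistic
summarizes how separable the cohorts are with the whole panel at once.
Seafood correlations mirror the diet link: more seafood meals, more
DHA/EPA in the erythrocyte membrane.
"""

from fattyroc import default_paper_spec, fda_fit, seafood_correlation
from fattyroc.synthetic import generate_cohort

table = generate_cohort(default_paper_spec(seed=7))

model = fda_fit(table)
print(f"FDA over {len(model.variables)} analytes: "
      f"score C-statistic = {model.score_c_statistic.c_statistic:.3f}")
top = sorted(zip(model.variables, model.weights), key=lambda t: -abs(t[1]))[:3]
for name, w in top:
    print(f"  strongest weight: {name:12s} {w:+.3f}")

corr = seafood_correlation(table, analytes=("DHA", "EPA", "stearic"))
print("\ncorrelation with seafood meals/month:")
print(corr.to_string(float_format=lambda v: f"{v:+.3f}"))
print("\npositive DHA/EPA rows reproduce the expected diet signal; the")
print("FDA C-statistic, although above every univariate one, stays far")
print("from the ~0.9+ needed for a usable diagnostic.")
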
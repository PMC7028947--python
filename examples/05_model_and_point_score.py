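"""Full model-building pass and the three-factor point score.

Runs features -> univariable screen -> ALASSO -> multivariable logistic fit
with the stay criterion on a simulated cohort, then applies the published
point mapping (intercept +1, visceral metastasis -2.5, NLR >= 5 -2, SNV
count >= 10 +3; predict benefit when the score is >= -1).
"""

from ucipred import (
    PAPER_POINTS,
    paper_like_preset,
    run_pipeline,
    simulate_cohort,
)
from ucipred.io import default_gene_annotations

annotations = default_gene_annotations()
cohort = simulate_cohort(paper_like_preset(n_patients=300, seed=2))
result = run_pipeline(
    cohort.clinical, cohort.variants, cohort.cnv_calls, annotations,
    explicit_points=PAPER_POINTS,  # pin the published mapping
)

print("screened (univariable p<=0.05):", sorted(result.screened))
print("ALASSO selection:              ", sorted(result.selected))
model = result.model
print("multivariable model:")
for var, beta, se, p in zip(
    model.variables, model.coefficients, model.standard_errors, model.p_values
):
    orr, lo, hi = model.effect_estimates[var]
    print(f"  {var:<14} beta {beta:+.2f} +/- {se:.2f}   OR {orr:.2f} ({lo:.2f}, {hi:.2f})  p {p:.3g}")
print(f"c-statistic: {model.c_statistic:.3f}")

psm = result.point_score
print(f"\npoint score range: {psm.score_range}, threshold >= {psm.threshold} predicts benefit")
if result.metrics:
    m = result.metrics
    print(f"classification on scorable patients: sensitivity {m['sensitivity_pct']}%, "
          f"specificity {m['specificity_pct']}% "
          f"(TP {m['tp']}, FN {m['fn']}, TN {m['tn']}, FP {m['fp']})")
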
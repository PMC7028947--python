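"""Univariable association testing, including the published DDR tables.

First re-tests the five carrier-count contingency tables printed for the
study cohort (24 clinical-benefit vs. 38 no-benefit patients), then runs
the univariable screen on a simulated cohort.
"""

from ucipred import (
    ContingencyTable2x2,
    fisher_exact_two_sided,
    paper_like_preset,
    simulate_cohort,
    build_feature_table,
)
from ucipred.io import default_gene_annotations
from ucipred.pipeline import feature_frame, univariable_screen
from ucipred.stats import printed_ddr_tables

print("published DDR/gene tables (two-sided Fisher exact):")
for _, row in printed_ddr_tables().iterrows():
    t = ContingencyTable2x2(
        a=int(row["cb_altered"]), b=int(row["cb_total"] - row["cb_altered"]),
        c=int(row["ncb_altered"]), d=int(row["ncb_total"] - row["ncb_altered"]),
    )
    res = fisher_exact_two_sided(t)
    print(f"  {row['label']:<12} p = {res.p_value:.4f} (printed {row['printed_p']})")

annotations = default_gene_annotations()
cohort = simulate_cohort(paper_like_preset(n_patients=300, seed=11))
table = build_feature_table(cohort.clinical, cohort.variants, cohort.cnv_calls, annotations)
frame = feature_frame(table, cohort.clinical)
results, passed = univariable_screen(frame)
print(f"\nunivariable screen on a simulated 300-patient cohort "
      f"(p <= 0.05): {sorted(passed)}")
# Under the study-like preset only the three outcome-driving factors (and
# features correlated with them, e.g. the signature counts that track SNV
# burden) should pass.
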
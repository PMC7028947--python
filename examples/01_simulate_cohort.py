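"""Simulate a study-like cohort and inspect its marginals.

Generates 62 patients under the default (study-like) preset: panel-scale
SNV counts, four-signature mutation spectra, purity-thinned CNV events and
clinical-benefit outcomes driven by the three-factor model.
"""

from ucipred import paper_like_preset, simulate_cohort

cohort = simulate_cohort(paper_like_preset(n_patients=62, seed=0))
truth = cohort.truth

print(f"patients: {len(cohort.clinical)}")
print(f"variant rows: {len(cohort.variants)} (includes putative-germline contaminants)")
print(f"CNV call rows: {len(cohort.cnv_calls)}")
print(f"mean SNV count: {truth['snv_count'].mean():.1f} (range {truth['snv_count'].min()}-{truth['snv_count'].max()})")
print(f"clinical benefit rate: {truth['cb'].mean():.2f}")
print(f"CDKN2B homozygous deletion: {truth['cdkn2b_del'].mean():.2f}")

# The truth record keeps every latent quantity (purity, signature mixture,
# benefit probability) so downstream stages can be validated exactly.
print("\ntruth columns:", ", ".join(truth.columns[:8]), "...")
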
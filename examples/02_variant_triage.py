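"""Variant triage: germline filtering, deleteriousness and DDR calls.

Builds a handful of annotated somatic calls for one patient and walks them
through the triage rules: population-frequency filtering (> 0.1% treated as
likely germline), loss-of-function / damaging-missense classification, the
panel SNV count, and the inclusive vs. restrictive DDR criteria.
"""

from ucipred import (
    Variant,
    filter_putative_germline,
    is_deleterious,
    pathway_flags,
    snv_count,
)
from ucipred.io import default_gene_annotations

annotations = default_gene_annotations()

variants = [
    # damaging missense in an HR gene -> deleterious, inclusive DDR hit
    Variant("P1", "BRCA1", "17", 100, "C", "T", "missense", sift_call="damaging"),
    # recurrent hotspot missense, benign predictions -> restrictive-only hit
    Variant("P1", "MSH6", "2", 200, "G", "A", "missense",
            sift_call="tolerated", polyphen_call="benign", cosmic_count=9),
    # frameshift indel: loss of function, always deleterious
    Variant("P1", "TP53", "17", 300, "A", "AT", "frameshift_indel"),
    # synonymous: never counted
    Variant("P1", "FGFR3", "4", 400, "C", "T", "synonymous"),
    # common population variant: removed as putative germline
    Variant("P1", "KMT2D", "12", 500, "G", "C", "missense", population_af=0.02),
]

somatic = filter_putative_germline(variants)
print(f"{len(variants)} calls -> {len(somatic)} after the >0.1% population-frequency filter")
print(f"SNV count (non-synonymous incl. indels): {snv_count(somatic)}")
for v in somatic:
    print(f"  {v.gene:<6} {v.consequence.value:<16} deleterious={is_deleterious(v)}")

inclusive = pathway_flags(somatic, annotations, "inclusive")
restrictive = pathway_flags(somatic, annotations, "restrictive")
print("inclusive DDR pathways hit: ", sorted(k for k, v in inclusive.items() if v and k != "any"))
print("restrictive DDR pathways hit:", sorted(k for k, v in restrictive.items() if v and k != "any"))
# The MSH6 hotspot contributes only under the catalog-based restrictive
# rule; the BRCA1 damaging missense only under the prediction-based one.
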
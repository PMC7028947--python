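"""Variant triage rules: germline filtering, deleteriousness, DDR calls and
the SNV-count statistic."""

import numpy as np
import pytest

from ucipred import (
    Consequence,
    GeneAnnotation,
    Variant,
    ddr_alteration_inclusive,
    ddr_alteration_restrictive,
    filter_putative_germline,
    is_deleterious,
    is_loss_of_function,
    pathway_flags,
    snv_count,
)
from ucipred.variants import SNV_COUNT_CONSEQUENCES, apply_gene_whitelist

from conftest import make_variant, random_variant

HR_GENE = GeneAnnotation("BRCA1", role="tumour_suppressor", ddr_pathway="HR")
NER_GENE = GeneAnnotation("ERCC2", role="tumour_suppressor", ddr_pathway="NER")
NON_DDR = GeneAnnotation("TP53", role="tumour_suppressor", ddr_pathway="none")


class TestGermlineFilter:
    @pytest.mark.parametrize(
        "af,kept",
        [(0.05, False), (0.0005, True), (None, True), (0.001, True), (0.0011, False)],
    )
    def test_frequency_rule(self, af, kept):
        v = make_variant(population_af=af)
        assert (v in filter_putative_germline([v])) is kept

    def test_idempotent_subset_order_preserving(self):
        rng = np.random.default_rng(0)
        variants = [random_variant(rng) for _ in range(200)]
        once = filter_putative_germline(variants)
        assert filter_putative_germline(once) == once
        assert all(v in variants for v in once)
        positions = [variants.index(v) for v in once]
        assert positions == sorted(positions)

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            filter_putative_germline([], af_threshold=0.0)


class TestDeleteriousness:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            (Consequence.NONSENSE, True),
            (Consequence.FRAMESHIFT_INDEL, True),
            (Consequence.SPLICE_SITE, True),
            (Consequence.MISSENSE, False),
            (Consequence.INFRAME_INDEL, False),
            (Consequence.SYNONYMOUS, False),
        ],
    )
    def test_loss_of_function_set(self, consequence, expected):
        v = make_variant(consequence=consequence, ref="AT" if "indel" in consequence.value else "C",
                         alt="A" if "indel" in consequence.value else "T")
        assert is_loss_of_function(v) is expected

    @pytest.mark.parametrize(
        "sift,polyphen,expected",
        [
            ("damaging", "benign", True),     # either predictor suffices
            ("tolerated", "probably_damaging", True),
            ("damaging", "probably_damaging", True),
            ("tolerated", "possibly_damaging", False),
            ("unknown", "unknown", False),
        ],
    )
    def test_missense_rule(self, sift, polyphen, expected):
        v = make_variant(sift_call=sift, polyphen_call=polyphen)
        assert is_deleterious(v) is expected

    def test_lof_always_deleterious_even_unannotated(self):
        v = make_variant(consequence=Consequence.FRAMESHIFT_INDEL, ref="A", alt="AT")
        assert is_deleterious(v)

    def test_lof_implies_deleterious_property(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            v = random_variant(rng)
            if is_loss_of_function(v):
                assert is_deleterious(v)


class TestDdrCalls:
    def test_inclusive_requires_ddr_gene_and_deleteriousness(self):
        hit = make_variant(gene="BRCA1", polyphen_call="probably_damaging")
        assert ddr_alteration_inclusive(hit, HR_GENE)
        nonsense_non_ddr = make_variant(consequence=Consequence.NONSENSE)
        assert not ddr_alteration_inclusive(nonsense_non_ddr, NON_DDR)
        silent = make_variant(gene="BRCA1", consequence=Consequence.SYNONYMOUS)
        assert not ddr_alteration_inclusive(silent, HR_GENE)

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(cosmic_count=5), True),
            (dict(cosmic_count=4), False),
            (dict(in_oncokb=True), True),
            (dict(in_hotspot_catalog=True), True),
            (dict(), False),
        ],
    )
    def test_restrictive_catalog_criteria(self, kwargs, expected):
        v = make_variant(gene="BRCA1", **kwargs)
        assert ddr_alteration_restrictive(v, HR_GENE) is expected

    def test_ercc2_helicase_domain_missense_qualifies(self):
        v = make_variant(gene="ERCC2", in_helicase_domain=True)
        assert ddr_alteration_restrictive(v, NER_GENE)
        # helicase-domain rule is specific to ERCC2
        v2 = make_variant(gene="BRCA1", in_helicase_domain=True)
        assert not ddr_alteration_restrictive(v2, HR_GENE)

    def test_criteria_do_not_imply_each_other(self):
        # catalog-recurrent missense with benign functional predictions:
        # restrictive yes, inclusive no
        catalog_only = make_variant(
            gene="BRCA1", cosmic_count=12, sift_call="tolerated", polyphen_call="benign"
        )
        assert ddr_alteration_restrictive(catalog_only, HR_GENE)
        assert not ddr_alteration_inclusive(catalog_only, HR_GENE)
        # predicted-damaging missense with no catalog support: inclusive
        # yes, restrictive no
        predicted_only = make_variant(gene="BRCA1", sift_call="damaging", cosmic_count=0)
        assert ddr_alteration_inclusive(predicted_only, HR_GENE)
        assert not ddr_alteration_restrictive(predicted_only, HR_GENE)

    def test_restrictive_lof_implies_inclusive(self):
        v = make_variant(gene="BRCA1", consequence=Consequence.NONSENSE)
        assert ddr_alteration_restrictive(v, HR_GENE)
        assert ddr_alteration_inclusive(v, HR_GENE)

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ddr_alteration_inclusive(make_variant(gene="TP53"), HR_GENE)


class TestSnvCount:
    def test_examples(self):
        assert snv_count([]) == 0
        variants = (
            [make_variant() for _ in range(2)]
            + [make_variant(consequence=Consequence.SYNONYMOUS)]
            + [make_variant(consequence=Consequence.FRAMESHIFT_INDEL, ref="A", alt="AT")]
        )
        assert snv_count(variants) == 3
        assert snv_count([make_variant() for _ in range(10)]) == 10

    def test_mixed_patients_rejected(self):
        with pytest.raises(ValueError, match="multiple patients"):
            snv_count([make_variant(patient_id="P1"), make_variant(patient_id="P2")])

    def test_additive_over_disjoint_lists(self):
        rng = np.random.default_rng(2)
        a = [random_variant(rng) for _ in range(30)]
        b = [random_variant(rng) for _ in range(20)]
        assert snv_count(a + b) == snv_count(a) + snv_count(b)

    def test_against_brute_force_whitelist(self):
        """1000 random variants vs. an independently coded whitelist."""
        whitelist = {"missense", "nonsense", "frameshift_indel", "inframe_indel", "splice_site"}
        rng = np.random.default_rng(3)
        variants = [random_variant(rng) for _ in range(1000)]
        brute = sum(1 for v in variants if v.consequence.value in whitelist)
        assert snv_count(variants) == brute


class TestPathwayFlags:
    def test_membership_and_any(self):
        brca1 = make_variant(gene="BRCA1", sift_call="damaging")
        ann = {"BRCA1": HR_GENE, "ERCC2": NER_GENE}
        flags = pathway_flags([brca1], ann, "inclusive")
        assert flags["HR"] and not flags["NER"] and flags["any"]

    def test_empty_all_false(self, annotations):
        flags = pathway_flags([], annotations, "inclusive")
        assert not any(flags.values())

    def test_default_table_assigns_ercc2_to_ner(self, annotations):
        v = make_variant(gene="ERCC2", sift_call="damaging")
        flags = pathway_flags([v], annotations, "inclusive")
        assert flags["NER"]

    def test_unannotated_gene_named_in_error(self):
        with pytest.raises(KeyError, match="GENEX"):
            pathway_flags([make_variant(gene="GENEX")], {}, "inclusive")


class TestWhitelistAndInvariants:
    def test_whitelist_filter(self):
        variants = [make_variant(gene=g) for g in ("TP53", "BRCA1", "XYZ")]
        assert len(apply_gene_whitelist(variants, {"TP53", "BRCA1"})) == 2
        assert apply_gene_whitelist(variants, None) == variants

    def test_variant_invariants(self):
        with pytest.raises(ValueError):
            make_variant(ref="C", alt="C")
        with pytest.raises(ValueError):
            make_variant(pos=0)
        with pytest.raises(ValueError):
            make_variant(population_af=1.5)
        with pytest.raises(ValueError):
            make_variant(trinucleotide_context="AAG")  # middle matches neither strand
        # context may be in reference orientation or its reverse complement
        make_variant(ref="C", alt="T", trinucleotide_context="ACG")
        make_variant(ref="G", alt="A", trinucleotide_context="ACG")
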
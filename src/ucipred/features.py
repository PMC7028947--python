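"""Per-patient analysis table: clinical covariates joined to derived
genomic features, with the study's dichotomizations and SNV/CNV subgroups.

All ">= cut" comparisons are inclusive (a value on the boundary belongs to
the high group); "high CNV" is strictly > 0. The cohort median used for the
median SNV split is the lower median for even cohorts, and can be pinned in
the rule set.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .cnv import CopyNumberCall, cnv_count, gene_homdel_flag
from .signatures import SignatureCatalog, build_spectrum, default_catalog, project_signatures
from .variants import (
    GeneAnnotation,
    Variant,
    apply_gene_whitelist,
    filter_putative_germline,
    pathway_flags,
    snv_count,
    DEFAULT_GERMLINE_AF_THRESHOLD,
)

__all__ = [
    "PatientClinical",
    "FeatureRecord",
    "RuleSet",
    "FeatureTable",
    "build_feature_table",
    "dichotomize",
    "snv_cnv_subset",
]


@dataclass(frozen=True)
class PatientClinical:
    """Baseline covariates, treatment arm, outcome label and survival times.

    ``ecog`` is coded 0, 1 or 2 (2 meaning >= 2) and may be missing;
    ``nlr`` (neutrophil-to-lymphocyte ratio) may be missing. ``cb`` is the
    binary benefit label ("CB" = any objective tumour reduction, "NCB"
    otherwise) and may be absent for unevaluable patients.
    """

    patient_id: str
    age: float
    gender: str
    site: str = "bladder"
    prior_lines: int = 0
    ecog: Optional[int] = None
    visceral_mets: bool = False
    nlr: Optional[float] = None
    hb: Optional[float] = None
    plt: Optional[float] = None
    arm: str = "ICI"
    cb: Optional[str] = None
    pfs_months: Optional[float] = None
    pfs_event: Optional[bool] = None
    os_months: Optional[float] = None
    os_event: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.ecog is not None and self.ecog not in (0, 1, 2):
            raise ValueError(f"ecog must be 0, 1 or 2 (>=2), got {self.ecog}")
        if self.site not in ("bladder", "upper_tract"):
            raise ValueError(f"site must be 'bladder' or 'upper_tract', got {self.site!r}")
        if self.arm not in ("ICI", "taxane"):
            raise ValueError(f"arm must be 'ICI' or 'taxane', got {self.arm!r}")
        if self.cb is not None and self.cb not in ("CB", "NCB"):
            raise ValueError(f"cb must be 'CB' or 'NCB', got {self.cb!r}")
        if self.nlr is not None and self.nlr < 0:
            raise ValueError(f"nlr must be >= 0, got {self.nlr}")
        for name in ("pfs_months", "os_months"):
            t = getattr(self, name)
            if t is not None and t < 0:
                raise ValueError(f"{name} must be >= 0, got {t}")
        if (
            self.pfs_months is not None
            and self.os_months is not None
            and self.pfs_months > self.os_months + 1e-9
        ):
            raise ValueError(
                f"pfs_months ({self.pfs_months}) exceeds os_months ({self.os_months})"
            )


@dataclass(frozen=True)
class FeatureRecord:
    """Derived per-patient features; indicator flags are None until
    :func:`dichotomize` fills them, and stay None when the source value is
    missing."""

    patient_id: str
    snv_count: int
    cnv_count: int
    sig_apobec: float = 0.0
    sig_ct_cpg: float = 0.0
    sig_ercc2: float = 0.0
    cdkn2a_del: bool = False
    cdkn2b_del: bool = False
    ddr_inclusive: bool = False
    ddr_restrictive: bool = False
    nlr_ge5: Optional[bool] = None
    snv_ge10: Optional[bool] = None
    snv_ge_median: Optional[bool] = None
    cnv_gt0: Optional[bool] = None
    ecog_ge1: Optional[bool] = None


@dataclass(frozen=True)
class RuleSet:
    """Dichotomization cut-points. ``snv_median_cut`` of None means
    "recompute the cohort median"; pin it (the study cohort's median was 8)
    to mirror a fixed split."""

    nlr_cut: float = 5.0
    snv_cut: int = 10
    snv_median_cut: Optional[float] = None
    cnv_cut: int = 0
    ecog_cut: int = 1


@dataclass(frozen=True)
class FeatureTable:
    """Feature records plus the provenance manifest that produced them."""

    records: tuple[FeatureRecord, ...]
    manifest: Mapping[str, object] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _lower_median(values: Sequence[float]) -> float:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def dichotomize(
    record: FeatureRecord,
    clinical: PatientClinical,
    rules: RuleSet,
    median_cut: Optional[float] = None,
) -> FeatureRecord:
    """Fill the indicator flags from the raw values; missing inputs leave
    the corresponding flag missing. Idempotent; non-flag fields untouched."""
    cut = rules.snv_median_cut if rules.snv_median_cut is not None else median_cut
    return replace(
        record,
        nlr_ge5=None if clinical.nlr is None else clinical.nlr >= rules.nlr_cut,
        snv_ge10=record.snv_count >= rules.snv_cut,
        snv_ge_median=None if cut is None else record.snv_count >= cut,
        cnv_gt0=record.cnv_count > rules.cnv_cut,
        ecog_ge1=None if clinical.ecog is None else clinical.ecog >= rules.ecog_cut,
    )


def snv_cnv_subset(record: FeatureRecord, rules: RuleSet, median_cut: Optional[float] = None) -> str:
    """Assign one of the four SNV/CNV subgroups (median SNV split, CNV > 0)."""
    cut = rules.snv_median_cut if rules.snv_median_cut is not None else median_cut
    if cut is None:
        raise ValueError("no median SNV cut available; pin snv_median_cut or pass median_cut")
    hi_snv = record.snv_count >= cut
    hi_cnv = record.cnv_count > rules.cnv_cut
    return f"{'high' if hi_snv else 'low'}SNV_{'high' if hi_cnv else 'low'}CNV"


def build_feature_table(
    clinical: Sequence[PatientClinical],
    variants: Sequence[Variant],
    cnv_calls: Sequence[CopyNumberCall],
    annotations: Mapping[str, GeneAnnotation],
    catalog: Optional[SignatureCatalog] = None,
    rules: RuleSet = RuleSet(),
    af_threshold: float = DEFAULT_GERMLINE_AF_THRESHOLD,
    gene_whitelist: Optional[set[str]] = None,
) -> FeatureTable:
    """Assemble the per-patient feature table from the three input tables.

    Applies, in order: putative-germline filter, optional panel-gene
    whitelist, SNV counting, 96-channel spectrum projection onto the
    catalog, CNV counting, CDKN2A/CDKN2B deletion flags, inclusive and
    restrictive DDR calls, then dichotomization. Patients with no genomic
    rows get zero counts; genomic rows for patients absent from the clinical
    table are an error.
    """
    ids = [c.patient_id for c in clinical]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate clinical rows for patients: {dupes}")
    known = set(ids)
    orphans = sorted(
        {v.patient_id for v in variants if v.patient_id not in known}
        | {c.patient_id for c in cnv_calls if c.patient_id not in known}
    )
    if orphans:
        raise ValueError(f"genomic rows reference unknown patients: {orphans}")

    cat = catalog if catalog is not None else default_catalog()
    kept = filter_putative_germline(variants, af_threshold)
    kept = apply_gene_whitelist(kept, gene_whitelist)
    by_patient: dict[str, list[Variant]] = {i: [] for i in ids}
    for v in kept:
        by_patient[v.patient_id].append(v)
    cnv_by_patient: dict[str, list[CopyNumberCall]] = {i: [] for i in ids}
    for c in cnv_calls:
        cnv_by_patient[c.patient_id].append(c)

    raw: list[FeatureRecord] = []
    for p in clinical:
        pv = by_patient[p.patient_id]
        pc = cnv_by_patient[p.patient_id]
        attributed = project_signatures(build_spectrum(pv), cat)
        ddr_inc = pathway_flags(pv, annotations, "inclusive")["any"]
        ddr_res = pathway_flags(pv, annotations, "restrictive")["any"]
        raw.append(
            FeatureRecord(
                patient_id=p.patient_id,
                snv_count=snv_count(pv),
                cnv_count=cnv_count(pc, annotations),
                sig_apobec=attributed.get("APOBEC", 0.0),
                sig_ct_cpg=attributed.get("C_T_CpG", 0.0),
                sig_ercc2=attributed.get("ERCC2", 0.0),
                cdkn2a_del=gene_homdel_flag(pc, "CDKN2A"),
                cdkn2b_del=gene_homdel_flag(pc, "CDKN2B"),
                ddr_inclusive=ddr_inc,
                ddr_restrictive=ddr_res,
            )
        )

    median_cut = (
        rules.snv_median_cut
        if rules.snv_median_cut is not None
        else (_lower_median([r.snv_count for r in raw]) if raw else None)
    )
    records = tuple(
        dichotomize(r, p, rules, median_cut=median_cut) for r, p in zip(raw, clinical)
    )
    catalog_hash = hashlib.sha256(cat.profiles.tobytes()).hexdigest()[:16]
    manifest = {
        "af_threshold": af_threshold,
        "rules": {
            "nlr_cut": rules.nlr_cut,
            "snv_cut": rules.snv_cut,
            "snv_median_cut": median_cut,
            "cnv_cut": rules.cnv_cut,
            "ecog_cut": rules.ecog_cut,
        },
        "n_patients": len(records),
        "n_variants_in": len(variants),
        "n_variants_after_germline_filter": len(
            filter_putative_germline(variants, af_threshold)
        ),
        "gene_whitelist_size": None if gene_whitelist is None else len(gene_whitelist),
        "n_annotated_genes": len(annotations),
        "catalog_hash": catalog_hash,
        "catalog_signatures": list(cat.names),
    }
    return FeatureTable(records=records, manifest=manifest)
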
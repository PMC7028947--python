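"""Readers and writers for the pipeline's table schemas, plus the run
manifest.

Formats: variants arrive as a MAF-dialect TSV, copy-number calls and
feature tables as TSV, clinical covariates as CSV, model reports / truth
records / manifests as JSON. All writers produce files the corresponding
reader maps back to identical domain objects.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .cnv import CnvCall, CopyNumberCall
from .features import FeatureRecord, FeatureTable, PatientClinical
from .models import FittedModel, PointScoreModel
from .variants import (
    Consequence,
    DdrPathway,
    GeneAnnotation,
    GeneRole,
    PolyphenCall,
    SiftCall,
    Variant,
)

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_cnv_table",
    "write_cnv_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_gene_annotations",
    "default_gene_annotations",
    "write_feature_table",
    "read_feature_table",
    "model_to_dict",
    "point_score_to_dict",
    "point_score_from_dict",
    "write_json",
    "build_manifest",
    "load_profile",
]

#: MAF-dialect consequence synonyms (canonical names also accepted).
MAF_CONSEQUENCE_SYNONYMS: Mapping[str, Consequence] = {
    "Missense_Mutation": Consequence.MISSENSE,
    "Nonsense_Mutation": Consequence.NONSENSE,
    "Frame_Shift_Del": Consequence.FRAMESHIFT_INDEL,
    "Frame_Shift_Ins": Consequence.FRAMESHIFT_INDEL,
    "In_Frame_Del": Consequence.INFRAME_INDEL,
    "In_Frame_Ins": Consequence.INFRAME_INDEL,
    "Splice_Site": Consequence.SPLICE_SITE,
    "Silent": Consequence.SYNONYMOUS,
    **{c.value: c for c in Consequence},
}

_REQUIRED_VARIANT_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
)

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no", ""}


def _parse_flag(value: object) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise ValueError(f"cannot parse flag value {value!r}")


def _opt(value: object) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def read_variant_table(path: str | Path) -> list[Variant]:
    """Read a MAF-dialect TSV into variants.

    Required columns are validated up front; unknown consequence strings map
    to ``other`` with a warning; parse failures report the 1-based data row.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_VARIANT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"variant table {path} is missing required columns: {missing}")
    variants: list[Variant] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        record = dict(zip(frame.columns, row))
        raw_cons = record["Variant_Classification"]
        cons = MAF_CONSEQUENCE_SYNONYMS.get(raw_cons)
        if cons is None:
            warnings.warn(
                f"{path} row {row_number}: unknown consequence {raw_cons!r} mapped to 'other'",
                RuntimeWarning,
                stacklevel=2,
            )
            cons = Consequence.OTHER
        try:
            af = _opt(record.get("ExAC_AF"))
            cosmic = _opt(record.get("COSMIC_Count"))
            variants.append(
                Variant(
                    patient_id=record["Tumor_Sample_Barcode"],
                    gene=record["Hugo_Symbol"],
                    chrom=record["Chromosome"],
                    pos=int(record["Start_Position"]),
                    ref=record["Reference_Allele"],
                    alt=record["Tumor_Seq_Allele2"],
                    consequence=cons,
                    population_af=None if af is None else float(af),
                    sift_call=SiftCall(_opt(record.get("SIFT")) or "unknown"),
                    polyphen_call=PolyphenCall(_opt(record.get("PolyPhen")) or "unknown"),
                    cosmic_count=None if cosmic is None else int(cosmic),
                    in_oncokb=_parse_flag(record.get("OncoKB", "")),
                    in_hotspot_catalog=_parse_flag(record.get("Hotspot", "")),
                    trinucleotide_context=_opt(record.get("Context3")),
                    in_helicase_domain=_parse_flag(record.get("Helicase_Domain", "")),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"variant table {path}, data row {row_number}: {exc}") from exc
    return variants


def write_variant_table(variants: Sequence[Variant], path: str | Path) -> None:
    rows = [
        {
            "Tumor_Sample_Barcode": v.patient_id,
            "Hugo_Symbol": v.gene,
            "Chromosome": v.chrom,
            "Start_Position": v.pos,
            "Reference_Allele": v.ref,
            "Tumor_Seq_Allele2": v.alt,
            "Variant_Classification": v.consequence.value,
            "ExAC_AF": "" if v.population_af is None else repr(v.population_af),
            "SIFT": v.sift_call.value,
            "PolyPhen": v.polyphen_call.value,
            "COSMIC_Count": "" if v.cosmic_count is None else v.cosmic_count,
            "OncoKB": int(v.in_oncokb),
            "Hotspot": int(v.in_hotspot_catalog),
            "Context3": v.trinucleotide_context or "",
            "Helicase_Domain": int(v.in_helicase_domain),
        }
        for v in variants
    ]
    columns = list(_REQUIRED_VARIANT_COLUMNS) + [
        "ExAC_AF", "SIFT", "PolyPhen", "COSMIC_Count", "OncoKB", "Hotspot",
        "Context3", "Helicase_Domain",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_cnv_table(path: str | Path) -> list[CopyNumberCall]:
    """Read gene-level copy-number calls (columns sample, gene, call,
    copy_number)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("sample", "gene", "call") if c not in frame.columns]
    if missing:
        raise ValueError(f"CNV table {path} is missing required columns: {missing}")
    calls: list[CopyNumberCall] = []
    for row_number, record in enumerate(frame.to_dict("records"), start=1):
        try:
            cn = _opt(record.get("copy_number"))
            calls.append(
                CopyNumberCall(
                    patient_id=record["sample"],
                    gene=record["gene"],
                    call=CnvCall(record["call"]),
                    copy_number=None if cn is None else float(cn),
                )
            )
        except ValueError as exc:
            raise ValueError(f"CNV table {path}, data row {row_number}: {exc}") from exc
    return calls


def write_cnv_table(calls: Sequence[CopyNumberCall], path: str | Path) -> None:
    rows = [
        {
            "sample": c.patient_id,
            "gene": c.gene,
            "call": c.call.value,
            "copy_number": "" if c.copy_number is None else repr(c.copy_number),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["sample", "gene", "call", "copy_number"]).to_csv(
        path, sep="\t", index=False
    )


_CLINICAL_COLUMNS = [
    "patient_id", "age", "gender", "site", "prior_lines", "ecog", "visceral_mets",
    "nlr", "hb", "plt", "arm", "cb", "pfs_months", "pfs_event", "os_months", "os_event",
]


def read_clinical_table(path: str | Path) -> list[PatientClinical]:
    """Read the clinical covariate CSV (one row per patient; blank cells are
    missing values)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("patient_id", "age", "gender") if c not in frame.columns]
    if missing:
        raise ValueError(f"clinical table {path} is missing required columns: {missing}")
    patients: list[PatientClinical] = []
    for row_number, record in enumerate(frame.to_dict("records"), start=1):
        try:
            def opt_float(key: str) -> Optional[float]:
                s = _opt(record.get(key))
                return None if s is None else float(s)

            def opt_flag(key: str) -> Optional[bool]:
                s = _opt(record.get(key))
                return None if s is None else _parse_flag(s)

            ecog = _opt(record.get("ecog"))
            patients.append(
                PatientClinical(
                    patient_id=record["patient_id"],
                    age=float(record["age"]),
                    gender=record["gender"],
                    site=_opt(record.get("site")) or "bladder",
                    prior_lines=int(_opt(record.get("prior_lines")) or 0),
                    ecog=None if ecog is None else int(ecog),
                    visceral_mets=_parse_flag(record.get("visceral_mets", "")),
                    nlr=opt_float("nlr"),
                    hb=opt_float("hb"),
                    plt=opt_float("plt"),
                    arm=_opt(record.get("arm")) or "ICI",
                    cb=_opt(record.get("cb")),
                    pfs_months=opt_float("pfs_months"),
                    pfs_event=opt_flag("pfs_event"),
                    os_months=opt_float("os_months"),
                    os_event=opt_flag("os_event"),
                )
            )
        except ValueError as exc:
            raise ValueError(f"clinical table {path}, data row {row_number}: {exc}") from exc
    return patients


def write_clinical_table(patients: Sequence[PatientClinical], path: str | Path) -> None:
    def fmt(value: object) -> object:
        if value is None:
            return ""
        if isinstance(value, bool):
            return int(value)
        if isinstance(value, float):
            return repr(value)
        return value

    rows = [
        {col: fmt(getattr(p, col)) for col in _CLINICAL_COLUMNS} for p in patients
    ]
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(path, index=False)


def read_gene_annotations(path) -> dict[str, GeneAnnotation]:
    """Read a gene annotation TSV (columns gene, role, ddr_pathway)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("gene", "role", "ddr_pathway") if c not in frame.columns]
    if missing:
        raise ValueError(f"gene annotation table is missing required columns: {missing}")
    out: dict[str, GeneAnnotation] = {}
    for record in frame.to_dict("records"):
        gene = record["gene"]
        if gene in out:
            raise ValueError(f"gene {gene} appears more than once in the annotation table")
        out[gene] = GeneAnnotation(
            gene=gene,
            role=GeneRole(record["role"] or "unknown"),
            ddr_pathway=DdrPathway(record["ddr_pathway"] or "none"),
        )
    return out


def default_gene_annotations() -> dict[str, GeneAnnotation]:
    """The packaged default gene table: a documented, editable stand-in for
    the panel's 30 DDR genes (with pathway assignments) and common
    tumour-suppressor/oncogene roles, drawn from the general DDR and cancer
    gene literature."""
    ref = resources.files("ucipred.data").joinpath("gene_annotations.tsv")
    with ref.open() as fh:
        return read_gene_annotations(fh)


_FEATURE_COLUMNS = [f.name for f in dataclasses.fields(FeatureRecord)]


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    def fmt(value: object) -> object:
        if value is None:
            return ""
        if isinstance(value, bool):
            return int(value)
        return value

    rows = [
        {col: fmt(getattr(r, col)) for col in _FEATURE_COLUMNS} for r in table.records
    ]
    pd.DataFrame(rows, columns=_FEATURE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table {path} is missing columns: {missing}")
    records = []
    bool_fields = {"cdkn2a_del", "cdkn2b_del", "ddr_inclusive", "ddr_restrictive"}
    opt_bool_fields = {"nlr_ge5", "snv_ge10", "snv_ge_median", "cnv_gt0", "ecog_ge1"}
    for record in frame.to_dict("records"):
        kwargs: dict = {"patient_id": record["patient_id"]}
        for col in ("snv_count", "cnv_count"):
            kwargs[col] = int(record[col])
        for col in ("sig_apobec", "sig_ct_cpg", "sig_ercc2"):
            kwargs[col] = float(record[col])
        for col in bool_fields:
            kwargs[col] = _parse_flag(record[col])
        for col in opt_bool_fields:
            s = _opt(record.get(col))
            kwargs[col] = None if s is None else _parse_flag(s)
        records.append(FeatureRecord(**kwargs))
    return FeatureTable(records=tuple(records))


def model_to_dict(model: FittedModel) -> dict:
    return {
        "family": model.family,
        "variables": list(model.variables),
        "coefficients": list(model.coefficients),
        "standard_errors": list(model.standard_errors),
        "p_values": list(model.p_values),
        "effect_estimates": {k: list(v) for k, v in model.effect_estimates.items()},
        "intercept": model.intercept,
        "intercept_se": model.intercept_se,
        "intercept_p": model.intercept_p,
        "c_statistic": model.c_statistic,
        "c_statistic_ci": list(model.c_statistic_ci) if model.c_statistic_ci else None,
        "flags": list(model.flags),
    }


def point_score_to_dict(psm: PointScoreModel) -> dict:
    return {
        "intercept_points": psm.intercept_points,
        "variable_points": dict(psm.variable_points),
        "threshold": psm.threshold,
        "rounding": psm.rounding,
        "score_range": list(psm.score_range),
    }


def point_score_from_dict(data: Mapping) -> PointScoreModel:
    return PointScoreModel(
        intercept_points=float(data["intercept_points"]),
        variable_points={k: float(v) for k, v in data["variable_points"].items()},
        threshold=float(data["threshold"]),
        rounding=str(data.get("rounding", "explicit")),
    )


def write_json(data: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


_PROFILE_SCHEMA = "ucipred-profile/1"


def load_profile(path: str | Path) -> dict:
    """Load a YAML analysis profile (versioned schema).

    A profile bundles every tunable threshold of a run — the germline
    allele-frequency cut, the dichotomization rule set, model-building
    settings, an optional pinned point mapping with its classification
    threshold, and optional prognostic-index cutoffs — so an analysis is
    fully described by its profile plus its input tables. The shipped
    ``examples/paper_reproduction.yaml`` pins the published values.
    """
    from .features import RuleSet
    from .models import ModelBuildConfig

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or data.get("schema") != _PROFILE_SCHEMA:
        raise ValueError(
            f"profile {path} must declare 'schema: {_PROFILE_SCHEMA}'"
        )
    known = {
        "schema", "af_threshold", "rules", "model", "points",
        "score_threshold", "prognostic_cutoffs",
    }
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"profile {path} has unknown keys: {sorted(unknown)}")
    rules_kwargs = data.get("rules") or {}
    model_kwargs = data.get("model") or {}
    points = data.get("points")
    return {
        "af_threshold": float(data.get("af_threshold", 0.001)),
        "rules": RuleSet(**rules_kwargs),
        "model": ModelBuildConfig(**model_kwargs),
        "points": None if points is None else {k: float(v) for k, v in points.items()},
        "score_threshold": float(data.get("score_threshold", -1.0)),
        "prognostic_cutoffs": tuple(data.get("prognostic_cutoffs", (-0.29, 1.54))),
    }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def build_manifest(
    inputs: Mapping[str, str | Path],
    config: Mapping[str, object],
    seed: Optional[int] = None,
) -> dict:
    """Assemble the run manifest: config hash, input digests, seed, tool
    version, timestamp. Every output file written by the CLI carries one."""
    from . import __version__

    config_blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "tool": "ucipred",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest()[:16],
        "config": json.loads(config_blob),
        "inputs": {name: _digest(Path(p)) for name, p in inputs.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
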
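"""Synthetic metastatic-urothelial-carcinoma cohorts for end-to-end testing.

Each simulated patient receives baseline clinical covariates, a panel-scale
somatic variant list whose single-base substitutions are drawn from a
per-patient mixture of the catalog signatures, gene-level copy-number
events thinned by purity-dependent detection (emulating the reduced
sensitivity of read-depth CNV calling in low-purity samples), and outcomes:
a clinical-benefit label sampled from a logistic model on the realized
features, and progression-free/overall survival from exponential
proportional-hazards models with independent censoring (progression-free
time is the minimum of progression and death, so PFS <= OS by
construction).

The default configuration is the study-like preset: negative-binomial SNV
counts with mean 9.7 in the observed 1-32 range, ~73% visceral metastasis,
NLR averaging ~5, and clinical-benefit coefficients equal to the published
three-factor model in the ICI arm. The taxane comparator arm is null: all
outcome coefficients are zero (intercept only), so no clinical or genomic
feature carries information about benefit there.

All randomness flows from one seed; per-patient substreams are spawned by
patient index, so patient k's data are reproducible regardless of cohort
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cnv import CnvCall, CopyNumberCall, cnv_count, gene_homdel_flag
from .features import PatientClinical
from .io import default_gene_annotations
from .signatures import SUBSTITUTION_BLOCKS, default_catalog
from .variants import (
    Consequence,
    GeneRole,
    PolyphenCall,
    SiftCall,
    Variant,
    filter_putative_germline,
    pathway_flags,
    snv_count,
)

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort", "paper_like_preset"]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Published three-factor logistic coefficients (CB = 1).
_ICI_COEFFICIENTS: Mapping[str, float] = {
    "intercept": 1.15,
    "visceral_mets": -2.93,
    "nlr_ge5": -2.11,
    "snv_ge10": 3.21,
}
#: Null comparator arm: benefit independent of every feature.
_TAXANE_COEFFICIENTS: Mapping[str, float] = {
    "intercept": -0.95,
    "visceral_mets": 0.0,
    "nlr_ge5": 0.0,
    "snv_ge10": 0.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the study-like conditions."""

    n_patients: int = 62
    seed: int = 0
    arm: str = "ICI"
    # SNV count: 1 + NegBin with the given mean/dispersion (target range ~1-32)
    snv_mean: float = 9.7
    snv_dispersion: float = 2.5
    synonymous_rate: float = 1.5
    # consequence mix among counted (non-synonymous) variants
    consequence_probs: tuple[float, ...] = (0.78, 0.07, 0.06, 0.05, 0.04)  # mis, non, fs, inf, spl
    # per-patient Dirichlet concentration over catalog signatures
    signature_alpha: tuple[float, ...] = (2.0, 1.5, 1.5, 1.2)
    # functional annotations of missense variants
    sift_damaging_prob: float = 0.35
    polyphen_probably_prob: float = 0.30
    cosmic_hit_prob: float = 0.10
    oncokb_prob: float = 0.05
    hotspot_prob: float = 0.04
    ddr_gene_frac: float = 30 / 237
    germline_contam_rate: float = 0.8
    # copy number
    purity_alpha: float = 5.0
    purity_beta: float = 3.0
    cdkn2_del_prob: float = 0.40
    cdkn2_concordance: float = 0.85
    homdel_rate: float = 0.4
    amp_rate: float = 0.5
    purity_detection_slope: float = 4.0
    purity_detection_intercept: float = -1.6
    # clinical marginals
    male_frac: float = 0.73
    age_mean: float = 65.6
    age_sd: float = 9.0
    ecog_probs: tuple[float, ...] = (0.44, 0.42, 0.14)
    ecog_missing_rate: float = 0.05
    bladder_frac: float = 0.74
    prior_lines_probs: tuple[float, ...] = (0.24, 0.58, 0.18)
    visceral_frac: float = 0.73
    nlr_log_mean: float = 1.42
    nlr_log_sd: float = 0.60
    nlr_missing_rate: float = 0.11
    hb_mean: float = 12.0
    hb_sd: float = 1.8
    plt_mean: float = 240.0
    plt_sd: float = 80.0
    # outcomes; None = arm default (published coefficients for ICI, null for taxane)
    outcome_coefficients: Optional[Mapping[str, float]] = None
    base_hazard_progression: float = 0.25
    base_hazard_death: float = 0.06
    progression_log_hrs: Mapping[str, float] = field(
        default_factory=lambda: {"visceral_mets": 1.0, "nlr_ge5": 0.4, "snv_ge10": -0.8, "cnv_gt0": 0.35}
    )
    death_log_hrs: Mapping[str, float] = field(
        default_factory=lambda: {"visceral_mets": 1.2, "nlr_ge5": 0.5, "snv_ge10": -0.4, "ecog_ge1": 0.6}
    )
    censoring_rate: float = 0.03
    admin_censor_months: float = 36.0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.arm not in ("ICI", "taxane"):
            raise ValueError(f"arm must be 'ICI' or 'taxane', got {self.arm!r}")
        if abs(sum(self.consequence_probs) - 1) > 1e-9:
            raise ValueError("consequence_probs must sum to 1")
        if abs(sum(self.ecog_probs) - 1) > 1e-9 or abs(sum(self.prior_lines_probs) - 1) > 1e-9:
            raise ValueError("categorical probabilities must sum to 1")
        for name in ("snv_mean", "snv_dispersion", "base_hazard_progression", "base_hazard_death"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "sift_damaging_prob", "polyphen_probably_prob", "cosmic_hit_prob", "oncokb_prob",
            "hotspot_prob", "ddr_gene_frac", "cdkn2_del_prob", "cdkn2_concordance",
            "male_frac", "bladder_frac", "visceral_frac", "nlr_missing_rate", "ecog_missing_rate",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def resolved_outcome_coefficients(self) -> Mapping[str, float]:
        if self.outcome_coefficients is not None:
            return dict(self.outcome_coefficients)
        return dict(_ICI_COEFFICIENTS if self.arm == "ICI" else _TAXANE_COEFFICIENTS)


@dataclass(frozen=True)
class SimulatedCohort:
    """Simulator output: the three pipeline input tables plus the latent
    truth record (one row per patient)."""

    clinical: tuple[PatientClinical, ...]
    variants: tuple[Variant, ...]
    cnv_calls: tuple[CopyNumberCall, ...]
    truth: pd.DataFrame
    config: SimulationConfig


def paper_like_preset(
    n_patients: int = 62, seed: int = 0, arm: str = "ICI"
) -> SimulationConfig:
    """The study-like preset: every default of :class:`SimulationConfig`."""
    return SimulationConfig(n_patients=n_patients, seed=seed, arm=arm)


def _channel_to_snv(channel: int, rng: np.random.Generator) -> tuple[str, str, str]:
    """Realize (ref, alt, context) for a channel, on a random strand."""
    ref, alt = SUBSTITUTION_BLOCKS[channel // 16]
    ctx = _BASES[(channel % 16) // 4] + ref + _BASES[channel % 4]
    if rng.random() < 0.5:  # emit on the purine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        ctx = "".join(_COMPLEMENT[b] for b in reversed(ctx))
    return ref, alt, ctx


def _random_indel(rng: np.random.Generator, frameshift: bool) -> tuple[str, str]:
    base = _BASES[rng.integers(4)]
    ins = "".join(_BASES[rng.integers(4)] for _ in range(1 if frameshift else 3))
    return (base, base + ins) if rng.random() < 0.5 else (base + ins, base)


def _other_base(ref: str, rng: np.random.Generator) -> str:
    choices = [b for b in _BASES if b != ref]
    return choices[rng.integers(3)]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort. Identical configs (including seed) give
    identical outputs; patient k's substream depends only on (seed, k)."""
    catalog = default_catalog()
    if len(config.signature_alpha) != len(catalog.names):
        raise ValueError(
            f"signature_alpha has {len(config.signature_alpha)} entries for "
            f"{len(catalog.names)} catalog signatures"
        )
    annotations = default_gene_annotations()
    ddr_genes = sorted(g for g, a in annotations.items() if a.is_ddr)
    tsg_genes = sorted(
        g for g, a in annotations.items()
        if a.role in (GeneRole.TUMOUR_SUPPRESSOR, GeneRole.BOTH) and not a.is_ddr
        and g not in ("CDKN2A", "CDKN2B")
    )
    onc_genes = sorted(g for g, a in annotations.items() if a.role is GeneRole.ONCOGENE)
    non_ddr_genes = sorted(g for g, a in annotations.items() if not a.is_ddr)

    coeffs = config.resolved_outcome_coefficients
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)

    clinical: list[PatientClinical] = []
    variants: list[Variant] = []
    cnv_calls: list[CopyNumberCall] = []
    truth_rows: list[dict] = []

    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i])
        pid = f"P{i + 1:04d}"

        # --- clinical covariates -------------------------------------------
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 41, 84))
        gender = "male" if rng.random() < config.male_frac else "female"
        site = "bladder" if rng.random() < config.bladder_frac else "upper_tract"
        ecog = int(rng.choice(3, p=config.ecog_probs))
        prior_lines = int(rng.choice(3, p=config.prior_lines_probs))
        visceral = bool(rng.random() < config.visceral_frac)
        nlr = float(np.clip(rng.lognormal(config.nlr_log_mean, config.nlr_log_sd), 0.3, 25.0))
        hb = float(np.clip(rng.normal(config.hb_mean, config.hb_sd), 8.0, 16.5))
        plt = float(np.clip(rng.normal(config.plt_mean, config.plt_sd), 60, 588))
        ecog_missing = rng.random() < config.ecog_missing_rate
        nlr_missing = rng.random() < config.nlr_missing_rate

        # --- somatic variants ----------------------------------------------
        r = config.snv_dispersion
        mean_extra = config.snv_mean - 1.0
        n_snv = 1 + int(rng.negative_binomial(r, r / (r + mean_extra)))
        mixture = rng.dirichlet(config.signature_alpha)
        channel_probs = mixture @ catalog.profiles
        consequences = rng.choice(5, size=n_snv, p=config.consequence_probs)
        cons_map = (
            Consequence.MISSENSE,
            Consequence.NONSENSE,
            Consequence.FRAMESHIFT_INDEL,
            Consequence.INFRAME_INDEL,
            Consequence.SPLICE_SITE,
        )
        patient_variants: list[Variant] = []
        n_syn = int(rng.poisson(config.synonymous_rate))
        all_consequences = [cons_map[c] for c in consequences] + [Consequence.SYNONYMOUS] * n_syn
        for cons in all_consequences:
            gene = (
                ddr_genes[rng.integers(len(ddr_genes))]
                if rng.random() < config.ddr_gene_frac
                else non_ddr_genes[rng.integers(len(non_ddr_genes))]
            )
            chrom = str(1 + int(rng.integers(22)))
            pos = int(rng.integers(1, 10_000_000))
            if cons in (Consequence.FRAMESHIFT_INDEL, Consequence.INFRAME_INDEL):
                ref, alt = _random_indel(rng, cons is Consequence.FRAMESHIFT_INDEL)
                ctx = None
            else:
                channel = int(rng.choice(96, p=channel_probs))
                ref, alt, ctx = _channel_to_snv(channel, rng)
            sift = SiftCall.UNKNOWN
            polyphen = PolyphenCall.UNKNOWN
            cosmic = None
            oncokb = hotspot = helicase = False
            if cons is Consequence.MISSENSE:
                sift = SiftCall.DAMAGING if rng.random() < config.sift_damaging_prob else SiftCall.TOLERATED
                u = rng.random()
                polyphen = (
                    PolyphenCall.PROBABLY_DAMAGING
                    if u < config.polyphen_probably_prob
                    else (PolyphenCall.POSSIBLY_DAMAGING if u < config.polyphen_probably_prob + 0.2 else PolyphenCall.BENIGN)
                )
                cosmic = int(5 + rng.geometric(0.3)) if rng.random() < config.cosmic_hit_prob else int(rng.integers(0, 3))
                oncokb = rng.random() < config.oncokb_prob
                hotspot = rng.random() < config.hotspot_prob
                helicase = gene == "ERCC2" and rng.random() < 0.5
            af = float(rng.uniform(0, 5e-4)) if rng.random() < 0.2 else None
            patient_variants.append(
                Variant(
                    patient_id=pid, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    consequence=cons, population_af=af, sift_call=sift,
                    polyphen_call=polyphen, cosmic_count=cosmic, in_oncokb=oncokb,
                    in_hotspot_catalog=hotspot, trinucleotide_context=ctx,
                    in_helicase_domain=helicase,
                )
            )
        # putative germline contaminants (removed by the frequency filter)
        for _ in range(int(rng.poisson(config.germline_contam_rate))):
            ref = _BASES[rng.integers(4)]
            patient_variants.append(
                Variant(
                    patient_id=pid,
                    gene=non_ddr_genes[rng.integers(len(non_ddr_genes))],
                    chrom=str(1 + int(rng.integers(22))),
                    pos=int(rng.integers(1, 10_000_000)),
                    ref=ref,
                    alt=_other_base(ref, rng),
                    consequence=Consequence.MISSENSE,
                    population_af=float(rng.uniform(2e-3, 5e-2)),
                )
            )

        # --- copy number with purity-dependent detection -------------------
        purity = float(np.clip(rng.beta(config.purity_alpha, config.purity_beta), 0.2, 0.95))
        p_detect = float(
            expit(config.purity_detection_intercept + config.purity_detection_slope * purity)
        )
        true_events: list[tuple[str, CnvCall]] = []
        if rng.random() < config.cdkn2_del_prob:
            true_events.append(("CDKN2A", CnvCall.HOMOZYGOUS_DELETION))
            if rng.random() < config.cdkn2_concordance:
                true_events.append(("CDKN2B", CnvCall.HOMOZYGOUS_DELETION))
        for _ in range(int(rng.poisson(config.homdel_rate))):
            true_events.append((tsg_genes[rng.integers(len(tsg_genes))], CnvCall.HOMOZYGOUS_DELETION))
        for _ in range(int(rng.poisson(config.amp_rate))):
            true_events.append((onc_genes[rng.integers(len(onc_genes))], CnvCall.AMPLIFICATION))
        patient_cnv: list[CopyNumberCall] = []
        n_true = len(true_events)
        for gene, call in true_events:
            if rng.random() < p_detect:
                cn = (
                    float(rng.uniform(0, 0.4))
                    if call is CnvCall.HOMOZYGOUS_DELETION
                    else float(rng.uniform(6.5, 30.0))
                )
                patient_cnv.append(CopyNumberCall(patient_id=pid, gene=gene, call=call, copy_number=cn))

        # --- derived truth features (via the pipeline's own rules) ---------
        somatic = filter_putative_germline(patient_variants)
        t_snv = snv_count(somatic)
        t_cnv = cnv_count(patient_cnv, annotations)
        t_ddr_inc = pathway_flags(somatic, annotations, "inclusive")["any"]
        t_ddr_res = pathway_flags(somatic, annotations, "restrictive")["any"]
        nlr_ge5 = nlr >= 5.0
        snv_ge10 = t_snv >= 10
        ecog_ge1 = ecog >= 1

        # --- outcomes -------------------------------------------------------
        x = {"visceral_mets": visceral, "nlr_ge5": nlr_ge5, "snv_ge10": snv_ge10}
        lp = coeffs.get("intercept", 0.0) + sum(
            coeffs.get(k, 0.0) * float(v) for k, v in x.items()
        )
        p_cb = float(expit(lp))
        cb = bool(rng.random() < p_cb)
        surv_x = {**x, "cnv_gt0": t_cnv > 0, "ecog_ge1": ecog_ge1}
        lp_prog = sum(config.progression_log_hrs.get(k, 0.0) * float(v) for k, v in surv_x.items())
        lp_death = sum(config.death_log_hrs.get(k, 0.0) * float(v) for k, v in surv_x.items())
        t_prog = float(rng.exponential(1.0 / (config.base_hazard_progression * np.exp(lp_prog))))
        t_death = float(rng.exponential(1.0 / (config.base_hazard_death * np.exp(lp_death))))
        t_cens = float(min(rng.exponential(1.0 / config.censoring_rate), config.admin_censor_months))
        pfs_raw = min(t_prog, t_death)
        pfs_months, pfs_event = min(pfs_raw, t_cens), pfs_raw <= t_cens
        os_months, os_event = min(t_death, t_cens), t_death <= t_cens

        clinical.append(
            PatientClinical(
                patient_id=pid, age=age, gender=gender, site=site,
                prior_lines=prior_lines, ecog=None if ecog_missing else ecog,
                visceral_mets=visceral, nlr=None if nlr_missing else nlr,
                hb=hb, plt=plt, arm=config.arm, cb="CB" if cb else "NCB",
                pfs_months=round(pfs_months, 3), pfs_event=bool(pfs_event),
                os_months=round(os_months, 3), os_event=bool(os_event),
            )
        )
        variants.extend(patient_variants)
        cnv_calls.extend(patient_cnv)
        truth_rows.append(
            {
                "patient_id": pid,
                "snv_count": t_snv,
                "cnv_count": t_cnv,
                "cnv_true_events": n_true,
                "cdkn2a_del": gene_homdel_flag(patient_cnv, "CDKN2A"),
                "cdkn2b_del": gene_homdel_flag(patient_cnv, "CDKN2B"),
                "ddr_inclusive": t_ddr_inc,
                "ddr_restrictive": t_ddr_res,
                "visceral_mets": visceral,
                "nlr": nlr,
                "nlr_ge5": nlr_ge5,
                "snv_ge10": snv_ge10,
                "ecog_ge1": ecog_ge1,
                "purity": purity,
                "p_clinical_benefit": p_cb,
                "cb": cb,
                **{f"mix_{name}": float(m) for name, m in zip(catalog.names, mixture)},
            }
        )

    truth_cols = [
        "patient_id", "snv_count", "cnv_count", "cnv_true_events", "cdkn2a_del",
        "cdkn2b_del", "ddr_inclusive", "ddr_restrictive", "visceral_mets", "nlr",
        "nlr_ge5", "snv_ge10", "ecog_ge1", "purity", "p_clinical_benefit", "cb",
    ] + [f"mix_{name}" for name in catalog.names]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return SimulatedCohort(
        clinical=tuple(clinical),
        variants=tuple(variants),
        cnv_calls=tuple(cnv_calls),
        truth=truth,
        config=config,
    )
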
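"""Somatic variant triage for targeted-panel sequencing of urothelial tumours.

Without matched-normal DNA, variants common in population exome databases are
treated as putative germline and removed (frequency > 0.1% by default). The
remaining calls are classified as loss-of-function or deleterious-missense,
counted into the panel SNV-count statistic (the panel proxy for tumour
mutational burden), and flagged as DNA-damage-repair (DDR) alterations under
an inclusive (functional-prediction-based) or restrictive (catalog-based)
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Consequence",
    "SiftCall",
    "PolyphenCall",
    "GeneRole",
    "DdrPathway",
    "Variant",
    "GeneAnnotation",
    "filter_putative_germline",
    "is_loss_of_function",
    "is_deleterious",
    "ddr_alteration_inclusive",
    "ddr_alteration_restrictive",
    "snv_count",
    "pathway_flags",
    "apply_gene_whitelist",
    "DEFAULT_GERMLINE_AF_THRESHOLD",
]

DEFAULT_GERMLINE_AF_THRESHOLD = 0.001

_BASES = set("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class SiftCall(str, Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


class PolyphenCall(str, Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class GeneRole(str, Enum):
    TUMOUR_SUPPRESSOR = "tumour_suppressor"
    ONCOGENE = "oncogene"
    BOTH = "both"
    UNKNOWN = "unknown"


class DdrPathway(str, Enum):
    HR = "HR"
    NER = "NER"
    MMR = "MMR"
    BER = "BER"
    FA = "FA"
    CHECKPOINT = "checkpoint"
    OTHER = "other"
    NONE = "none"


#: Loss-of-function consequence classes (all considered deleterious).
LOF_CONSEQUENCES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT_INDEL, Consequence.SPLICE_SITE}
)

#: Consequence classes contributing to the panel SNV count / TMB proxy:
#: exonic non-synonymous changes including indels, nonsense and splice sites.
SNV_COUNT_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT_INDEL,
        Consequence.INFRAME_INDEL,
        Consequence.SPLICE_SITE,
    }
)


@dataclass(frozen=True)
class Variant:
    """One somatic call with its functional and population annotations.

    ``trinucleotide_context`` may be given in reference orientation (middle
    base equals ``ref``) or on the opposite strand (middle base equals the
    complement of ``ref``); channelization normalizes to the pyrimidine
    strand either way.
    """

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    population_af: Optional[float] = None
    sift_call: SiftCall = SiftCall.UNKNOWN
    polyphen_call: PolyphenCall = PolyphenCall.UNKNOWN
    cosmic_count: Optional[int] = None
    in_oncokb: bool = False
    in_hotspot_catalog: bool = False
    trinucleotide_context: Optional[str] = None
    in_helicase_domain: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "consequence", Consequence(self.consequence))
        object.__setattr__(self, "sift_call", SiftCall(self.sift_call))
        object.__setattr__(self, "polyphen_call", PolyphenCall(self.polyphen_call))
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref!r})")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based and >= 1, got {self.pos}")
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError(f"population_af out of [0,1]: {self.population_af}")
        if self.cosmic_count is not None and self.cosmic_count < 0:
            raise ValueError(f"cosmic_count must be >= 0, got {self.cosmic_count}")
        ctx = self.trinucleotide_context
        if ctx is not None:
            if len(ctx) != 3 or any(b not in _BASES for b in ctx):
                raise ValueError(f"trinucleotide context must be 3 ACGT bases, got {ctx!r}")
            if self.is_snv and ctx[1] not in (self.ref, _COMPLEMENT[self.ref]):
                raise ValueError(
                    f"context middle base {ctx[1]!r} matches neither reference "
                    f"allele {self.ref!r} nor its complement"
                )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref in _BASES and self.alt in _BASES


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-level metadata: tumour-suppressor/oncogene role and DDR pathway."""

    gene: str
    role: GeneRole = GeneRole.UNKNOWN
    ddr_pathway: DdrPathway = DdrPathway.NONE
    in_panel: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", GeneRole(self.role))
        object.__setattr__(self, "ddr_pathway", DdrPathway(self.ddr_pathway))

    @property
    def is_ddr(self) -> bool:
        return self.ddr_pathway != DdrPathway.NONE


def filter_putative_germline(
    variants: Sequence[Variant],
    af_threshold: float = DEFAULT_GERMLINE_AF_THRESHOLD,
) -> list[Variant]:
    """Drop variants seen above ``af_threshold`` in a population database.

    With no germline sequencing available, a population frequency above the
    threshold (default 0.1%) marks a call as likely germline. Variants with
    no frequency annotation are retained: the rule excludes only observed
    high-frequency variants, and absence of annotation is not evidence of
    germline origin.
    """
    if not 0.0 < af_threshold < 1.0:
        raise ValueError(f"af_threshold must lie in (0, 1), got {af_threshold}")
    return [v for v in variants if v.population_af is None or v.population_af <= af_threshold]


def is_loss_of_function(v: Variant) -> bool:
    """Nonsense, frameshift indel or splice-site alteration."""
    return v.consequence in LOF_CONSEQUENCES


def is_deleterious(v: Variant) -> bool:
    """Loss-of-function, or missense called damaging by SIFT and/or
    probably-damaging by PolyPhen-2 (inclusive or)."""
    if is_loss_of_function(v):
        return True
    return v.consequence is Consequence.MISSENSE and (
        v.sift_call is SiftCall.DAMAGING
        or v.polyphen_call is PolyphenCall.PROBABLY_DAMAGING
    )


def _check_gene(v: Variant, ann: GeneAnnotation) -> None:
    if ann.gene != v.gene:
        raise ValueError(f"annotation for {ann.gene} applied to a {v.gene} variant")


def ddr_alteration_inclusive(v: Variant, ann: GeneAnnotation) -> bool:
    """Inclusive DDR call: any deleterious variant in a DDR gene."""
    _check_gene(v, ann)
    return ann.is_ddr and is_deleterious(v)


def ddr_alteration_restrictive(v: Variant, ann: GeneAnnotation) -> bool:
    """Restrictive DDR call in a DDR gene: loss-of-function, or missense
    recurrent in COSMIC (>= 5), reported in OncoKB, or in a hotspot catalog;
    ERCC2 missense within the conserved helicase domains also qualifies."""
    _check_gene(v, ann)
    if not ann.is_ddr:
        return False
    if is_loss_of_function(v):
        return True
    if v.consequence is Consequence.MISSENSE:
        if (v.cosmic_count is not None and v.cosmic_count >= 5) or v.in_oncokb or v.in_hotspot_catalog:
            return True
        if v.gene == "ERCC2" and v.in_helicase_domain:
            return True
    return False


def _one_patient(variants: Sequence[Variant]) -> None:
    ids = {v.patient_id for v in variants}
    if len(ids) > 1:
        raise ValueError(f"variants span multiple patients: {sorted(ids)}")


def snv_count(variants: Sequence[Variant]) -> int:
    """Panel SNV count for one patient: exonic non-synonymous variants,
    including indels, nonsense and splice-site mutations.

    Expects the germline filter to have been applied already. Raises on a
    list mixing patient identifiers (malformed grouping).
    """
    _one_patient(variants)
    return sum(1 for v in variants if v.consequence in SNV_COUNT_CONSEQUENCES)


def pathway_flags(
    variants: Sequence[Variant],
    annotations: Mapping[str, GeneAnnotation],
    mode: str = "inclusive",
) -> dict[str, bool]:
    """Per-DDR-pathway alteration flags for one patient, plus an ``any`` flag.

    A pathway is flagged when at least one variant in one of its genes passes
    the selected DDR criterion (``"inclusive"`` or ``"restrictive"``).
    """
    if mode == "inclusive":
        predicate = ddr_alteration_inclusive
    elif mode == "restrictive":
        predicate = ddr_alteration_restrictive
    else:
        raise ValueError(f"mode must be 'inclusive' or 'restrictive', got {mode!r}")
    flags = {p.value: False for p in DdrPathway if p not in (DdrPathway.NONE,)}
    for v in variants:
        ann = annotations.get(v.gene)
        if ann is None:
            raise KeyError(f"gene {v.gene} has no annotation")
        if predicate(v, ann):
            flags[ann.ddr_pathway.value] = True
    flags["any"] = any(flags.values())
    return flags


def apply_gene_whitelist(
    variants: Iterable[Variant], whitelist: Optional[set[str]]
) -> list[Variant]:
    """Restrict to genes shared across panel versions (no-op when None)."""
    if whitelist is None:
        return list(variants)
    return [v for v in variants if v.gene in whitelist]
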
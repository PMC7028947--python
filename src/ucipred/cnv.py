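"""Gene-level copy-number features.

Only the two most reliably detected event classes enter the analysis:
homozygous deletions and high-level amplifications (> 6 copies). The CNV
count statistic — a quantitative proxy for aneuploidy — counts homozygous
deletions in tumour-suppressor genes plus amplifications in proto-oncogenes,
each gene-level event at most once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

from .variants import GeneAnnotation, GeneRole

__all__ = ["CnvCall", "CopyNumberCall", "cnv_count", "gene_homdel_flag"]


class CnvCall(str, Enum):
    HOMOZYGOUS_DELETION = "homozygous_deletion"
    AMPLIFICATION = "amplification"
    OTHER = "other"


@dataclass(frozen=True)
class CopyNumberCall:
    """One gene-level copy-number call for one patient."""

    patient_id: str
    gene: str
    call: CnvCall
    copy_number: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "call", CnvCall(self.call))
        cn = self.copy_number
        if cn is not None:
            if cn < 0:
                raise ValueError(f"copy_number must be >= 0, got {cn}")
            if self.call is CnvCall.AMPLIFICATION and cn <= 6:
                raise ValueError(f"amplification requires copy_number > 6, got {cn}")
            if self.call is CnvCall.HOMOZYGOUS_DELETION and cn >= 0.5:
                raise ValueError(f"homozygous deletion requires copy_number < 0.5, got {cn}")


def _one_patient(calls: Sequence[CopyNumberCall]) -> None:
    ids = {c.patient_id for c in calls}
    if len(ids) > 1:
        raise ValueError(f"copy-number calls span multiple patients: {sorted(ids)}")


def cnv_count(
    calls: Sequence[CopyNumberCall],
    annotations: Mapping[str, GeneAnnotation],
) -> int:
    """CNV count for one patient.

    Counts distinct (gene, call) events where the event type matches the
    gene's role: homozygous deletions in tumour-suppressors and
    amplifications in oncogenes ("both" qualifies through either). Events in
    genes of unknown role never count; a warning lists them. Repeated
    segments for one gene count once.
    """
    _one_patient(calls)
    qualifying: set[tuple[str, CnvCall]] = set()
    skipped_unknown: list[str] = []
    for c in calls:
        ann = annotations.get(c.gene)
        if ann is None:
            raise KeyError(f"gene {c.gene} has no role annotation")
        if c.call is CnvCall.HOMOZYGOUS_DELETION:
            if ann.role in (GeneRole.TUMOUR_SUPPRESSOR, GeneRole.BOTH):
                qualifying.add((c.gene, c.call))
            elif ann.role is GeneRole.UNKNOWN:
                skipped_unknown.append(c.gene)
        elif c.call is CnvCall.AMPLIFICATION:
            if ann.role in (GeneRole.ONCOGENE, GeneRole.BOTH):
                qualifying.add((c.gene, c.call))
            elif ann.role is GeneRole.UNKNOWN:
                skipped_unknown.append(c.gene)
    if skipped_unknown:
        warnings.warn(
            "copy-number events skipped in genes of unknown role: "
            + ", ".join(sorted(set(skipped_unknown))),
            RuntimeWarning,
            stacklevel=2,
        )
    return len(qualifying)


def gene_homdel_flag(calls: Sequence[CopyNumberCall], gene: str) -> bool:
    """True when the patient carries a homozygous deletion of ``gene``."""
    _one_patient(calls)
    return any(c.gene == gene and c.call is CnvCall.HOMOZYGOUS_DELETION for c in calls)
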
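"""96-channel trinucleotide mutation spectra and fixed-catalog refitting.

Single-base substitutions are folded onto the pyrimidine strand and binned
into the canonical 96 channels (six substitution blocks C>A, C>G, C>T, T>A,
T>C, T>G, each crossed with the 4 x 4 flanking-base combinations ordered
A, C, G, T). A per-sample spectrum is then projected onto a small fixed
catalog of signature profiles by non-negative least squares, and the
non-negative loadings are rescaled so that they partition the sample's total
mutation count among the mutational processes. Closely related signatures
(the two APOBEC components) can be fused in the report.

The shipped default catalog is a *synthetic* four-profile catalog emulating
the processes dominating bladder-cancer genomes: APOBEC cytidine deamination
(C>T and C>G at TpCpW), a flat clock-like/NER-deficiency profile (ERCC2
label) and C>T deamination at CpG sites. It is a constructed stand-in for
the published reference profiles, suitable for simulation and refitting
tests; any catalog with the same schema can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variants import Variant

__all__ = [
    "SUBSTITUTION_BLOCKS",
    "CHANNEL_LABELS",
    "trinucleotide_channel",
    "channel_label",
    "Spectrum",
    "build_spectrum",
    "SignatureCatalog",
    "default_catalog",
    "project_signatures",
]

_BASES = "ACGT"
_BASE_RANK = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Pyrimidine-strand substitution blocks in canonical order.
SUBSTITUTION_BLOCKS: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
)
_BLOCK_INDEX = {sub: i for i, sub in enumerate(SUBSTITUTION_BLOCKS)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def trinucleotide_channel(ref: str, alt: str, context: str) -> int:
    """Map a single-base substitution with flanking context to [0, 95].

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand first, so G>A in 5'-CGT-3' and C>T in 5'-ACG-3' share a
    channel. ``context`` may be supplied in reference orientation or as its
    reverse complement. Index = 16*block + 4*rank(5' base) + rank(3' base).
    """
    for name, b in (("ref", ref), ("alt", alt)):
        if len(b) != 1 or b not in _BASES:
            raise ValueError(f"{name} must be a single A/C/G/T base, got {b!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical; not a substitution")
    if len(context) != 3 or any(b not in _BASES for b in context):
        raise ValueError(f"context must be 3 A/C/G/T bases, got {context!r}")
    if context[1] == _COMPLEMENT[ref] and context[1] != ref:
        context = _revcomp(context)  # supplied on the opposite strand
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} does not match ref {ref!r}")
    if ref in "AG":  # fold onto the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = _revcomp(context)
    block = _BLOCK_INDEX[(ref, alt)]
    return 16 * block + 4 * _BASE_RANK[context[0]] + _BASE_RANK[context[2]]


def channel_label(index: int) -> str:
    """Human-readable channel label, e.g. ``A[C>T]G`` for index 34."""
    if not 0 <= index <= 95:
        raise ValueError(f"channel index out of [0, 95]: {index}")
    ref, alt = SUBSTITUTION_BLOCKS[index // 16]
    five = _BASES[(index % 16) // 4]
    three = _BASES[index % 4]
    return f"{five}[{ref}>{alt}]{three}"


#: Canonical channel labels in index order.
CHANNEL_LABELS: tuple[str, ...] = tuple(channel_label(i) for i in range(96))


@dataclass(frozen=True)
class Spectrum:
    """Per-sample 96-channel substitution counts.

    ``excluded`` records the variants that could not be channelized
    (indels, and substitutions lacking a trinucleotide context).
    """

    patient_id: str
    counts: np.ndarray
    excluded: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (96,):
            raise ValueError(f"spectrum must have 96 channels, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_spectrum(variants: Sequence[Variant]) -> Spectrum:
    """Accumulate one patient's single-base substitutions into a spectrum.

    Indels and SNVs without a context are excluded and tallied in
    ``Spectrum.excluded``. Raises if the variants mix patient identifiers.
    """
    ids = {v.patient_id for v in variants}
    if len(ids) > 1:
        raise ValueError(f"variants span multiple patients: {sorted(ids)}")
    patient_id = next(iter(ids)) if ids else ""
    counts = np.zeros(96, dtype=int)
    excluded = 0
    for v in variants:
        if v.is_snv and v.trinucleotide_context is not None:
            counts[trinucleotide_channel(v.ref, v.alt, v.trinucleotide_context)] += 1
        else:
            excluded += 1
    return Spectrum(patient_id=patient_id, counts=counts, excluded=excluded)


@dataclass(frozen=True)
class SignatureCatalog:
    """Fixed catalog of non-negative 96-channel signature profiles.

    ``fuse_groups`` maps a report label to the member signatures whose
    loadings are summed when reporting (e.g. one APOBEC label covering both
    APOBEC components).
    """

    names: tuple[str, ...]
    profiles: np.ndarray  # shape (n_signatures, 96), rows sum to 1
    fuse_groups: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        profiles = np.asarray(self.profiles, dtype=float)
        if profiles.ndim != 2 or profiles.shape[1] != 96:
            raise ValueError(f"profiles must be (n, 96), got {profiles.shape}")
        if len(self.names) != profiles.shape[0]:
            raise ValueError("number of names does not match number of profiles")
        if len(set(self.names)) != len(self.names):
            raise ValueError("signature names must be unique")
        if (profiles < 0).any():
            raise ValueError("profiles must be non-negative")
        sums = profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"each profile must sum to 1 within 1e-9, got sums {sums}")
        members = set()
        for label, group in self.fuse_groups.items():
            for m in group:
                if m not in self.names:
                    raise ValueError(f"fuse group {label!r} names unknown signature {m!r}")
                members.add(m)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "profiles", profiles)
        object.__setattr__(
            self, "fuse_groups", {k: frozenset(v) for k, v in self.fuse_groups.items()}
        )

    @property
    def report_labels(self) -> tuple[str, ...]:
        """Report labels in catalog order, with fused members collapsed."""
        fused_members = {m for g in self.fuse_groups.values() for m in g}
        labels: list[str] = []
        for name in self.names:
            if name in fused_members:
                for label, group in self.fuse_groups.items():
                    if name in group and label not in labels:
                        labels.append(label)
            else:
                labels.append(name)
        return tuple(labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles.T, index=list(CHANNEL_LABELS), columns=list(self.names)
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        fuse_groups: Optional[Mapping[str, set[str]]] = None,
    ) -> "SignatureCatalog":
        if list(frame.index) != list(CHANNEL_LABELS):
            raise ValueError("catalog rows must be the 96 canonical channel labels in order")
        return cls(
            names=tuple(frame.columns),
            profiles=frame.to_numpy(dtype=float).T,
            fuse_groups=dict(fuse_groups or {}),
        )


_DEFAULT_FUSE = {"APOBEC": frozenset({"APOBEC_a", "APOBEC_b"})}


def default_catalog() -> SignatureCatalog:
    """Load the packaged synthetic four-signature bladder-cancer catalog."""
    with resources.files("ucipred.data").joinpath("signature_catalog_synthetic.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    return SignatureCatalog.from_frame(frame, fuse_groups=_DEFAULT_FUSE)


def project_signatures(
    spectrum: Spectrum,
    catalog: SignatureCatalog,
    fused: bool = True,
) -> dict[str, float]:
    """Attribute a sample's mutations to the catalog signatures.

    Solves ``min_{w >= 0} || counts - P'w ||_2`` by non-negative least
    squares, then rescales the loadings so that they sum to the spectrum
    total (skipped when every loading is zero), yielding an estimated count
    of mutations generated by each process. With ``fused=True`` (default)
    the catalog's fuse groups are summed into single report labels.
    """
    A = catalog.profiles.T  # (96, n_signatures)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn(
            "signature profiles are linearly dependent; the projection is "
            "non-unique and the returned loadings are one optimum",
            RuntimeWarning,
            stacklevel=2,
        )
    w, _ = nnls(A, spectrum.counts.astype(float))
    total = float(spectrum.total)
    if w.sum() > 0:
        w = w * (total / w.sum())
    raw = dict(zip(catalog.names, (float(x) for x in w)))
    if not fused:
        return raw
    out: dict[str, float] = {}
    for label in catalog.report_labels:
        members = catalog.fuse_groups.get(label, frozenset({label}))
        out[label] = sum(raw[m] for m in members)
    return out
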
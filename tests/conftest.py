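import numpy as np
import pytest

from ucipred import Consequence, GeneAnnotation, Variant
from ucipred.io import default_gene_annotations
from ucipred.signatures import default_catalog

CONSEQUENCES = list(Consequence)


@pytest.fixture(scope="session")
def annotations():
    return default_gene_annotations()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_variant(
    patient_id="P1",
    gene="TP53",
    consequence=Consequence.MISSENSE,
    **kwargs,
):
    defaults = dict(chrom="17", pos=100, ref="C", alt="T")
    defaults.update(kwargs)
    return Variant(
        patient_id=patient_id, gene=gene, consequence=consequence, **defaults
    )


@pytest.fixture
def variant_factory():
    return make_variant


def random_variant(rng: np.random.Generator, patient_id="P1", genes=("TP53", "BRCA1", "ERCC2")):
    """A random variant with random consequence/annotation fields, for
    brute-force comparison tests."""
    cons = CONSEQUENCES[rng.integers(len(CONSEQUENCES))]
    bases = "ACGT"
    ref = bases[rng.integers(4)]
    alt = [b for b in bases if b != ref][rng.integers(3)]
    return Variant(
        patient_id=patient_id,
        gene=genes[rng.integers(len(genes))],
        chrom=str(1 + rng.integers(22)),
        pos=int(rng.integers(1, 1_000_000)),
        ref=ref,
        alt=alt,
        consequence=cons,
        population_af=float(rng.uniform(0, 0.01)) if rng.random() < 0.3 else None,
    )
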
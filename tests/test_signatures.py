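"""Trinucleotide channelization and fixed-catalog signature refitting."""

import numpy as np
import pytest

from ucipred import Spectrum, build_spectrum, project_signatures, trinucleotide_channel
from ucipred.signatures import CHANNEL_LABELS, SignatureCatalog, channel_label

from conftest import make_variant

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


class TestChannelization:
    def test_known_channel_indices(self):
        # C>T block is the third (index 2); 5' A rank 0; 3' G rank 2
        assert trinucleotide_channel("C", "T", "ACG") == 34
        # purine-strand input folds onto the same channel
        assert trinucleotide_channel("G", "A", "CGT") == 34
        assert channel_label(34) == "A[C>T]G"

    def test_bijection_over_pyrimidine_pairs(self):
        seen = set()
        for ref in "CT":
            for alt in _BASES:
                if alt == ref:
                    continue
                for five in _BASES:
                    for three in _BASES:
                        seen.add(trinucleotide_channel(ref, alt, five + ref + three))
        assert seen == set(range(96))

    def test_strand_symmetry_everywhere(self):
        for ref in "AG":
            for alt in _BASES:
                if alt == ref:
                    continue
                for five in _BASES:
                    for three in _BASES:
                        ctx = five + ref + three
                        rc = "".join(_COMP[b] for b in reversed(ctx))
                        assert trinucleotide_channel(ref, alt, ctx) == trinucleotide_channel(
                            _COMP[ref], _COMP[alt], rc
                        )

    @pytest.mark.parametrize(
        "ref,alt,ctx",
        [("C", "C", "ACG"), ("C", "T", "AAG"), ("C", "T", "ACGT"), ("N", "T", "ANG")],
    )
    def test_invalid_inputs_rejected(self, ref, alt, ctx):
        with pytest.raises(ValueError):
            trinucleotide_channel(ref, alt, ctx)


class TestSpectrum:
    def test_empty_and_accumulation(self):
        assert build_spectrum([]).total == 0
        variants = [
            make_variant(ref="C", alt="T", trinucleotide_context="ACG") for _ in range(3)
        ]
        s = build_spectrum(variants)
        assert s.counts[34] == 3 and s.total == 3

    def test_indels_and_contextless_snvs_excluded(self):
        variants = [
            make_variant(ref="C", alt="T", trinucleotide_context="ACG"),
            make_variant(consequence="frameshift_indel", ref="A", alt="AT"),
            make_variant(ref="C", alt="A", trinucleotide_context=None),
        ]
        s = build_spectrum(variants)
        assert s.total == 1 and s.excluded == 2

    def test_mixed_patients_rejected(self):
        with pytest.raises(ValueError):
            build_spectrum([make_variant(patient_id="A"), make_variant(patient_id="B")])


def _simple_catalog() -> SignatureCatalog:
    """Rational-valued catalog so exact integer mixtures exist."""
    profiles = np.zeros((4, 96))
    profiles[0, 0:10] = 0.1
    profiles[1, 10:20] = 0.1
    profiles[2, 20:30] = 0.1
    profiles[3, 30:40] = 0.1
    return SignatureCatalog(names=("s1", "s2", "s3", "s4"), profiles=profiles)


def _grid_oracle(counts, profiles, resolution=0.02):
    """Best mixture over a dense simplex grid: independent check of the
    constrained least-squares projection."""
    total = counts.sum()
    steps = int(round(1 / resolution))
    best = (np.inf, None)
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            for k in range(steps + 1 - i - j):
                w = np.array([i, j, k, steps - i - j - k]) / steps * total
                resid = np.linalg.norm(counts - w @ profiles)
                if resid < best[0]:
                    best = (resid, w)
    return best


class TestProjection:
    def test_pure_component_attributed_to_generator(self, catalog):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(1000, catalog.profiles[0])
        out = project_signatures(Spectrum("P1", counts), catalog)
        assert out["APOBEC"] >= 0.95 * 1000
        assert sum(out.values()) == pytest.approx(1000)

    def test_zero_spectrum_zero_attribution(self, catalog):
        out = project_signatures(Spectrum("P1", np.zeros(96, int)), catalog)
        assert all(v == 0 for v in out.values())

    def test_exact_two_component_mixture_matches_grid_oracle(self):
        cat = _simple_catalog()
        counts = (60 * cat.profiles[0] + 40 * cat.profiles[2]).round().astype(int)
        assert counts.sum() == 100
        out = project_signatures(Spectrum("P1", counts), cat, fused=False)
        assert out["s1"] == pytest.approx(60, abs=1e-6)
        assert out["s2"] == pytest.approx(0, abs=1e-6)
        assert out["s3"] == pytest.approx(40, abs=1e-6)
        resid_impl = np.linalg.norm(
            counts - np.array([out[n] for n in cat.names]) @ cat.profiles
        )
        resid_oracle, w_oracle = _grid_oracle(counts.astype(float), cat.profiles)
        assert resid_impl <= resid_oracle + 1e-9
        assert np.allclose([out[n] for n in cat.names], w_oracle, atol=2.0)

    def test_scale_equivariance(self, catalog):
        rng = np.random.default_rng(1)
        counts = rng.multinomial(200, rng.dirichlet(np.ones(4)) @ catalog.profiles)
        base = project_signatures(Spectrum("P1", counts), catalog)
        tripled = project_signatures(Spectrum("P1", 3 * counts), catalog)
        for k in base:
            assert tripled[k] == pytest.approx(3 * base[k], rel=1e-9, abs=1e-9)

    def test_attribution_nonneg_sums_to_total(self, catalog):
        rng = np.random.default_rng(2)
        for _ in range(25):
            mix = rng.dirichlet(np.ones(4))
            counts = rng.multinomial(300, mix @ catalog.profiles)
            out = project_signatures(Spectrum("P1", counts), catalog)
            assert all(v >= 0 for v in out.values())
            assert sum(out.values()) == pytest.approx(counts.sum())

    def test_mixture_recovery_small_batch(self, catalog):
        rng = np.random.default_rng(3)
        errors = []
        for _ in range(40):
            mix = rng.dirichlet(np.ones(4))
            counts = rng.multinomial(500, mix @ catalog.profiles)
            out = project_signatures(Spectrum("P1", counts), catalog, fused=False)
            props = np.array([out[n] for n in catalog.names]) / counts.sum()
            errors.append(np.abs(props - mix).mean())
        assert np.mean(errors) < 0.05

    def test_collinear_catalog_warns(self):
        profiles = np.zeros((2, 96))
        profiles[:, 0:10] = 0.1
        cat = SignatureCatalog(names=("dup_a", "dup_b"), profiles=profiles)
        with pytest.warns(RuntimeWarning, match="linearly dependent"):
            project_signatures(Spectrum("P1", np.ones(96, int)), cat)

    def test_fused_report_sums_members(self, catalog):
        rng = np.random.default_rng(4)
        counts = rng.multinomial(400, np.full(4, 0.25) @ catalog.profiles)
        raw = project_signatures(Spectrum("P1", counts), catalog, fused=False)
        fused = project_signatures(Spectrum("P1", counts), catalog, fused=True)
        assert fused["APOBEC"] == pytest.approx(raw["APOBEC_a"] + raw["APOBEC_b"])


class TestCatalogValidation:
    def test_profile_sum_and_shape_enforced(self):
        with pytest.raises(ValueError):
            SignatureCatalog(names=("a",), profiles=np.full((1, 96), 0.02))
        with pytest.raises(ValueError):
            SignatureCatalog(names=("a",), profiles=np.full((1, 10), 0.1))

    def test_fuse_group_members_must_exist(self):
        profiles = np.full((1, 96), 1 / 96)
        with pytest.raises(ValueError):
            SignatureCatalog(
                names=("a",), profiles=profiles, fuse_groups={"g": {"missing"}}
            )

    def test_packaged_catalog_is_valid(self, catalog):
        assert len(CHANNEL_LABELS) == 96
        assert catalog.names == ("APOBEC_a", "APOBEC_b", "ERCC2", "C_T_CpG")
        assert catalog.report_labels == ("APOBEC", "ERCC2", "C_T_CpG")
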
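"""Phantom-cohort generator: label rules, imaging signatures, I/O round trip."""

import numpy as np
import pytest

from gliotype.config import MODALITIES
from gliotype.synthetic import (
    GenotypeTriple,
    apply_missing_modalities,
    brain_mask,
    generate_cohort,
    read_cohort,
    render_subject,
    sample_genotypes,
    write_cohort,
)

from conftest import small_spec


# ---------------------------------------------------------------------------
# genotype sampling
# ---------------------------------------------------------------------------

class TestGenotypeSampling:
    def test_dependency_rules_hold_exactly_at_full_adherence(self):
        spec = small_spec(n_subjects=5000)
        triples = sample_genotypes(spec, np.random.default_rng(7))
        for t in triples:
            if t.idh == 0:
                assert t.codel_1p19q == 0  # wild-type IDH => non-codeleted
            if t.atrx == 1:
                assert t.codel_1p19q == 0  # mutant ATRX => non-codeleted

    def test_marginal_fractions_approach_targets(self):
        spec = small_spec(
            n_subjects=10000,
            class_fractions={"idh": 0.33, "atrx": 0.20, "codel_1p19q": 0.11},
        )
        arr = np.stack([t.as_array() for t in
                        sample_genotypes(spec, np.random.default_rng(11))])
        frac = arr.mean(axis=0)
        assert abs(frac[0] - 0.33) < 0.02
        assert abs(frac[1] - 0.20) < 0.02
        assert abs(frac[2] - 0.11) < 0.02

    def test_partial_adherence_allows_rule_violations(self):
        spec = small_spec(
            n_subjects=4000, rule_adherence=0.0,
            class_fractions={"idh": 0.33, "atrx": 0.20, "codel_1p19q": 0.11},
        )
        arr = np.stack([t.as_array() for t in
                        sample_genotypes(spec, np.random.default_rng(3))])
        violations = ((arr[:, 0] == 0) & (arr[:, 2] == 1)).sum()
        assert violations > 0
        assert abs(arr[:, 2].mean() - 0.11) < 0.02

    def test_infeasible_codel_fraction_raises(self):
        spec = small_spec(
            class_fractions={"idh": 0.05, "atrx": 0.5, "codel_1p19q": 0.5}
        )
        with pytest.raises(ValueError, match="unattainable"):
            sample_genotypes(spec, np.random.default_rng(0))

    def test_invalid_genotype_values_rejected(self):
        with pytest.raises(ValueError):
            GenotypeTriple(2, 0, 0)


# ---------------------------------------------------------------------------
# phantom rendering
# ---------------------------------------------------------------------------

def _lesion_core_mask(sample):
    from gliotype.synthetic import _CORE_FRACTION, _normalized_radius

    center = sample.meta["lesion_center"]
    semi = sample.meta["lesion_semiaxes"]
    shape = next(iter(sample.volumes.values())).shape
    return _normalized_radius(shape, center, semi) <= _CORE_FRACTION


class TestRendering:
    def test_idh_mutant_shows_t2_flair_mismatch(self):
        spec = small_spec(noise_sd=0.0)
        s = render_subject(GenotypeTriple(1, 1, 0), spec, np.random.default_rng(5))
        core = _lesion_core_mask(s)
        assert s.volumes["t2"][core].mean() > s.volumes["flair"][core].mean()

    def test_idh_wildtype_shows_annular_t1ce_enhancement(self):
        spec = small_spec(noise_sd=0.0)
        s = render_subject(GenotypeTriple(0, 0, 0), spec, np.random.default_rng(5))
        from gliotype.synthetic import _CORE_FRACTION, _normalized_radius

        r = _normalized_radius(
            s.volumes["t1ce"].shape, s.meta["lesion_center"],
            s.meta["lesion_semiaxes"]
        )
        rim = (r > _CORE_FRACTION) & (r <= 1.0)
        core = r <= _CORE_FRACTION
        assert s.volumes["t1ce"][rim].mean() > s.volumes["t1ce"][core].mean()

    def test_noise_free_rendering_is_deterministic(self):
        spec = small_spec(noise_sd=0.0)
        a = render_subject(GenotypeTriple(1, 0, 0), spec, np.random.default_rng(9))
        b = render_subject(GenotypeTriple(1, 0, 0), spec, np.random.default_rng(9))
        for m in MODALITIES:
            np.testing.assert_array_equal(a.volumes[m], b.volumes[m])

    def test_background_outside_brain_is_zero(self):
        spec = small_spec()
        s = render_subject(GenotypeTriple(0, 0, 0), spec, np.random.default_rng(2))
        outside = ~brain_mask(spec.volume_shape)
        for m in MODALITIES:
            assert np.all(s.volumes[m][outside] == 0)

    def test_oversized_lesion_rejected(self):
        spec = small_spec(lesion_radius_range=(14.0, 15.0))
        with pytest.raises(ValueError):
            render_subject(GenotypeTriple(0, 0, 0), spec, np.random.default_rng(0))

    def test_core_contrast_separates_idh_groups(self):
        # mean core T2-FLAIR contrast: positive for mutants, higher than wild-type
        spec = small_spec(noise_sd=0.0)
        rng = np.random.default_rng(21)
        mut = [render_subject(GenotypeTriple(1, 0, 0), spec, rng) for _ in range(4)]
        wt = [render_subject(GenotypeTriple(0, 0, 0), spec, rng) for _ in range(4)]

        def contrast(s):
            core = _lesion_core_mask(s)
            return s.volumes["t2"][core].mean() - s.volumes["flair"][core].mean()

        assert min(contrast(s) for s in mut) > max(contrast(s) for s in wt)


# ---------------------------------------------------------------------------
# missing modalities
# ---------------------------------------------------------------------------

class TestMissingModalities:
    def test_degenerate_weights_keep_all_modalities(self):
        spec = small_spec(missing_modality_weights=(1.0, 0.0, 0.0))
        rng = np.random.default_rng(0)
        s = render_subject(GenotypeTriple(0, 0, 0), spec, rng)
        out = apply_missing_modalities(s, spec, rng)
        assert out.availability_mask == (1, 1, 1, 1)

    def test_second_pattern_always_drops_t1ce(self):
        spec = small_spec(missing_modality_weights=(0.0, 1.0, 0.0))
        rng = np.random.default_rng(0)
        s = render_subject(GenotypeTriple(0, 0, 0), spec, rng)
        out = apply_missing_modalities(s, spec, rng)
        assert out.availability_mask == (1, 0, 1, 1)
        assert "t1ce" not in out.volumes

    def test_pattern_frequencies_match_clinical_mix(self):
        spec = small_spec(missing_modality_weights=(0.168, 0.495, 0.337))
        rng = np.random.default_rng(42)
        s = render_subject(GenotypeTriple(0, 0, 0), spec, rng)
        counts = {(1, 1, 1, 1): 0, (1, 0, 1, 1): 0, (0, 1, 1, 1): 0}
        n = 1000
        for _ in range(n):
            counts[apply_missing_modalities(s, spec, rng).availability_mask] += 1
        assert abs(counts[(1, 1, 1, 1)] / n - 0.168) < 0.05
        assert abs(counts[(1, 0, 1, 1)] / n - 0.495) < 0.05
        assert abs(counts[(0, 1, 1, 1)] / n - 0.337) < 0.05

    def test_t2_and_flair_never_dropped(self, tiny_cohort):
        for s in tiny_cohort:
            assert "t2" in s.volumes and "flair" in s.volumes


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

class TestCohortIO:
    def test_write_counts_and_round_trip(self, tmp_path):
        spec = small_spec(n_subjects=2, missing_modality_weights=(1, 0, 0))
        samples = generate_cohort(spec)
        manifest = write_cohort(samples, str(tmp_path))
        assert len(manifest["volumes"]) == 8  # 2 subjects x 4 modalities
        back = read_cohort(str(tmp_path))
        assert len(back) == 2
        for orig, rt in zip(samples, back):
            assert rt.labels == orig.labels
            for m in MODALITIES:
                np.testing.assert_array_equal(rt.volumes[m], orig.volumes[m])

    def test_missing_modality_layout(self, tmp_path):
        spec = small_spec(n_subjects=3, missing_modality_weights=(0, 1, 0))
        samples = generate_cohort(spec)
        write_cohort(samples, str(tmp_path))
        nii = sorted(p.name for p in tmp_path.glob("*.nii.gz"))
        assert len(nii) == 9  # 3 subjects x 3 modalities (T1-ce dropped)
        back = read_cohort(str(tmp_path))
        assert all(s.availability_mask == (1, 0, 1, 1) for s in back)

    def test_cohort_generation_deterministic_under_seed(self):
        a = generate_cohort(small_spec(n_subjects=2, seed=5))
        b = generate_cohort(small_spec(n_subjects=2, seed=5))
        for sa, sb in zip(a, b):
            assert sa.labels == sb.labels
            for m in sa.volumes:
                np.testing.assert_array_equal(sa.volumes[m], sb.volumes[m])
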
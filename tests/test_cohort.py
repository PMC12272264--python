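"""Synthetic cohort generator: atlas geometry, phenotype marginals,
volume rendering identities, typical-subject selection."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from vqnorm import (
    CohortSpec,
    EffectSpec,
    ScaleModel,
    make_atlas,
    render_volume,
    sample_phenotypes,
    select_typical,
    simulate_cohort,
    generate_cohort,
)
from vqnorm.cohort import phenotypes_to_frame

from conftest import tiny_cohort_spec


class TestMakeAtlas:
    def test_all_rois_present_and_partition(self):
        atlas = make_atlas((32, 32, 32), 10, seed=7)
        labels = np.unique(atlas.label_volume)
        assert set(labels) == set(range(11))  # background + 10 regions
        assert all((atlas.label_volume == r).sum() >= 1 for r in range(1, 11))

    def test_regions_are_connected(self):
        atlas = make_atlas((24, 24, 24), 8, seed=3)
        for r in range(1, 9):
            _, n_components = ndimage.label(atlas.label_volume == r)
            assert n_components == 1

    def test_block_alignment(self):
        atlas = make_atlas((32, 32, 32), 6, seed=1, block=4)
        blocks = atlas.label_volume.reshape(8, 4, 8, 4, 8, 4).transpose(0, 2, 4, 1, 3, 5)
        blocks = blocks.reshape(-1, 64)
        assert np.all(blocks == blocks[:, :1])  # each block single-labelled

    def test_too_many_rois_fails(self):
        with pytest.raises(ValueError, match="cannot place ROIs"):
            make_atlas((8, 8, 8), 500, seed=1)

    def test_deterministic(self):
        a = make_atlas((16, 16, 16), 5, seed=9)
        b = make_atlas((16, 16, 16), 5, seed=9)
        np.testing.assert_array_equal(a.label_volume, b.label_volume)

    def test_mask_roughly_ellipsoidal(self):
        atlas = make_atlas((32, 32, 32), 4, seed=2)
        # corners of the grid lie outside the brain mask
        assert atlas.label_volume[0, 0, 0] == 0
        assert atlas.label_volume[-1, -1, -1] == 0
        assert atlas.brain_mask[16, 16, 16]


class TestSamplePhenotypes:
    def test_zero_inflation_matches_mixture_oracle(self):
        spec = tiny_cohort_spec(
            n_subjects=1000,
            scales={"total": ScaleModel(zero_inflation=0.3, shape=2.0, scale=12.9)},
            seed=4,
        )
        cohort = sample_phenotypes(spec)
        totals = np.array([p.scale_scores["total"] for p in cohort])
        frac_zero = np.mean(totals == 0.0)
        assert frac_zero >= 0.25
        # independent Monte-Carlo draw of the stated mixture
        oracle_rng = np.random.default_rng(12345)
        oracle = np.where(
            oracle_rng.random(100_000) < 0.3, 0.0, oracle_rng.gamma(2.0, 12.9, 100_000)
        )
        assert abs(frac_zero - np.mean(oracle == 0.0)) < 0.05
        assert abs(totals.mean() - oracle.mean()) < 2.0

    def test_full_zero_inflation_degenerates(self):
        spec = tiny_cohort_spec(scales={"total": ScaleModel(zero_inflation=1.0)})
        cohort = sample_phenotypes(spec)
        assert all(p.scale_scores["total"] == 0.0 for p in cohort)

    def test_deterministic(self):
        spec = tiny_cohort_spec(seed=11)
        a = phenotypes_to_frame(sample_phenotypes(spec))
        b = phenotypes_to_frame(sample_phenotypes(spec))
        pd.testing.assert_frame_equal(a, b)

    def test_scores_right_skewed(self):
        spec = tiny_cohort_spec(n_subjects=2000, seed=8)
        totals = [p.scale_scores["total"] for p in sample_phenotypes(spec)]
        assert stats.skew(totals) > 0

    def test_diagnosis_couples_to_total(self):
        spec = tiny_cohort_spec(n_subjects=500, diagnosis_prevalence=0.3, seed=13)
        cohort = sample_phenotypes(spec)
        totals = np.array([p.scale_scores["total"] for p in cohort])
        dx = np.array([p.diagnosis for p in cohort])
        assert abs(dx.mean() - 0.3) < 0.01
        assert totals[dx == 1].mean() > totals[dx == 0].mean()

    def test_age_range_and_sex(self):
        spec = tiny_cohort_spec(n_subjects=400, seed=2)
        cohort = sample_phenotypes(spec)
        ages = np.array([p.age for p in cohort])
        assert ages.min() >= spec.age_range[0] and ages.max() <= spec.age_range[1]
        assert 0.35 < np.mean([p.sex == "M" for p in cohort]) < 0.7


class TestRenderVolume:
    def test_all_perturbations_off_gives_baselines(self):
        spec = tiny_cohort_spec(noise_sd=0.0, texture_sd=0.0, age_slope_sd=0.0)
        atlas, phen, _ = simulate_cohort(spec)
        from vqnorm.cohort import _cohort_region_params

        baselines, _, _ = _cohort_region_params(spec)
        vol = render_volume(atlas, phen[0], spec)
        for r in range(1, spec.n_rois + 1):
            np.testing.assert_allclose(vol.intensities[atlas.label_volume == r], baselines[r - 1])
        np.testing.assert_array_equal(vol.intensities[atlas.label_volume == 0], 0.0)

    def test_effect_identity_gamma_times_delta(self):
        """Mean pre-noise intensity difference inside affected regions is
        exactly gamma * delta-score; exactly zero outside."""
        gamma = -0.012
        spec = tiny_cohort_spec(
            noise_sd=0.0, texture_sd=0.0,
            effects=(EffectSpec("total", (2,), gamma),),
        )
        atlas, _, _ = simulate_cohort(spec)
        from vqnorm.cohort import SubjectPhenotype

        # scores small enough that gamma*score never drives an intensity
        # through the non-negativity clip (the identity holds pre-clip)
        a = SubjectPhenotype("x", 10.0, "F", {"total": 0.0, "social": 1.0})
        b = SubjectPhenotype("y", 10.0, "F", {"total": 10.0, "social": 1.0})
        va = render_volume(atlas, a, spec).intensities
        vb = render_volume(atlas, b, spec).intensities
        diff = vb - va
        affected = atlas.label_volume == 2
        np.testing.assert_allclose(diff[affected], gamma * 10.0, atol=1e-12)
        np.testing.assert_array_equal(diff[~affected], 0.0)

    def test_missing_scale_errors(self):
        spec = tiny_cohort_spec(effects=(EffectSpec("total", (1,), 0.01),))
        atlas, phen, _ = simulate_cohort(spec)
        phen[0].scale_scores.pop("total")
        with pytest.raises(ValueError, match="lacks scale"):
            render_volume(atlas, phen[0], spec)

    def test_deterministic(self):
        spec = tiny_cohort_spec(seed=3)
        atlas, phen, _ = simulate_cohort(spec)
        va = render_volume(atlas, phen[0], spec).intensities
        vb = render_volume(atlas, phen[0], spec).intensities
        np.testing.assert_array_equal(va, vb)

    def test_non_negative_and_background_zero(self):
        spec = tiny_cohort_spec(seed=3)
        atlas, phen, vols = simulate_cohort(spec)
        for v in vols.values():
            assert v.intensities.min() >= 0.0
            assert np.abs(v.intensities[atlas.label_volume == 0]).max() == 0.0


class TestSelectTypical:
    def _subjects(self, scores):
        from vqnorm.cohort import SubjectPhenotype

        return [
            SubjectPhenotype(f"s{i}", 10.0, "F", {"total": float(s)})
            for i, s in enumerate(scores)
        ]

    def test_uniform_ranks(self):
        selected = select_typical(self._subjects(range(100)), "total", 0.25)
        assert len(selected) == 25  # scores 0..24; the 24.75 threshold keeps exactly a quarter
        assert max(p.scale_scores["total"] for p in selected) <= np.quantile(range(100), 0.25)

    def test_all_tied_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="tied"):
            selected = select_typical(self._subjects([5] * 20), "total", 0.25)
        assert len(selected) == 20

    def test_matches_sort_and_slice_oracle(self):
        spec = tiny_cohort_spec(n_subjects=1000, seed=17)
        cohort = sample_phenotypes(spec)
        selected = select_typical(cohort, "total", 0.25)
        scores = np.sort([p.scale_scores["total"] for p in cohort])
        assert max(p.scale_scores["total"] for p in selected) <= scores[int(0.25 * 1000)]

    def test_selected_fraction_converges_to_quantile(self):
        spec = tiny_cohort_spec(n_subjects=10_000, seed=19)
        cohort = sample_phenotypes(spec)
        # zero-inflation puts ~30% of mass at exactly 0, so use a quantile
        # above the atom to test convergence of the <=-threshold rule
        selected = select_typical(cohort, "total", 0.5)
        assert abs(len(selected) / 10_000 - 0.5) < 0.02

    def test_bad_quantile(self):
        with pytest.raises(ValueError):
            select_typical(self._subjects(range(10)), "total", 1.5)


class TestGenerateCohort:
    def test_artifact_counts_and_manifest_reproduction(self, tmp_path):
        spec = tiny_cohort_spec(n_subjects=5, seed=23)
        manifest = generate_cohort(spec, tmp_path / "run1")
        niis = list((tmp_path / "run1").glob("sub-*.nii"))
        assert len(niis) == 5
        frame = pd.read_csv(tmp_path / "run1" / "phenotypes.csv")
        assert len(frame) == 5

        from vqnorm.cohort import spec_from_jsonable

        manifest2 = generate_cohort(spec_from_jsonable(manifest["spec"]), tmp_path / "run2")
        assert (tmp_path / "run1" / "phenotypes.csv").read_bytes() == (
            tmp_path / "run2" / "phenotypes.csv"
        ).read_bytes()
        assert manifest["checksums"] == manifest2["checksums"]

    def test_effect_localized_between_diagnosis_groups(self):
        spec = tiny_cohort_spec(
            n_subjects=40,
            noise_sd=0.0,
            age_slope_sd=0.0,  # age drift off: groups differ only via diagnosis
            diagnosis_prevalence=0.5,
            diagnosis_liability_sd=1e6,  # diagnosis ~ independent of scores
            effects=(EffectSpec("diagnosis", (3,), -0.2),),
            seed=29,
        )
        atlas, phen, vols = simulate_cohort(spec)
        dx = np.array([p.diagnosis for p in phen], dtype=bool)
        stack = np.stack([vols[p.subject_id].intensities for p in phen])
        diff = stack[dx].mean(axis=0) - stack[~dx].mean(axis=0)
        assert abs(diff[atlas.label_volume == 3].mean() + 0.2) < 1e-9
        other = (atlas.label_volume > 0) & (atlas.label_volume != 3)
        assert np.abs(diff[other]).max() < 1e-9
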
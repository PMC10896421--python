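import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cryoredox.calibration import calibrate_stack
from cryoredox.synthetic import (
    CohortSpec,
    PhantomParams,
    SerumSpec,
    draw_true_means,
    generate_cohort,
    generate_phantom_stack,
    generate_serum_table,
    kidney_cohort_spec,
    liver_cohort_spec,
    young_serum_spec,
    aged_serum_spec,
)


class TestPhantomForwardModel:
    def test_identity_forward_model_returns_field(self):
        p = PhantomParams(shape=(6, 24, 24), noise_sd=0.0, dark_level=0.0,
                          vignette_strength=1.0, brightness_cv=0.0,
                          voxel_rr_cv=0.0, seed=0)
        nadh, fad, _, truth = generate_phantom_stack(p)
        np.testing.assert_allclose(nadh.data, truth.nadh_field, atol=1e-12)
        np.testing.assert_allclose(fad.data, truth.fad_field, atol=1e-12)

    def test_pure_dark_offset(self):
        p = PhantomParams(shape=(6, 24, 24), noise_sd=0.0, dark_level=100.0,
                          vignette_strength=1.0, brightness_cv=0.0,
                          voxel_rr_cv=0.0, seed=0)
        nadh, _, _, truth = generate_phantom_stack(p)
        np.testing.assert_allclose(nadh.data - 100.0, truth.nadh_field, atol=1e-12)

    def test_same_seed_bit_identical(self):
        p = PhantomParams(shape=(6, 24, 24), noise_sd=5.0, seed=7)
        a = generate_phantom_stack(p)
        b = generate_phantom_stack(p)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)

    def test_returned_frames_invert_forward_model(self, noisy_phantom):
        # calibrate(generate(...)) recovers truth to within read noise
        nadh_raw, _, frames, truth = noisy_phantom
        nadh = calibrate_stack(nadh_raw, frames)
        inside = truth.tissue_mask
        resid = nadh.data[inside] - truth.nadh_field[inside]
        # residual = noise / illumination; bounded by a few noise SDs
        assert np.abs(resid).max() < 6 * truth.noise_sd / truth.illumination.min()
        assert abs(resid.mean()) < 0.5

    def test_fields_zero_outside_tissue(self, noisy_phantom):
        _, _, _, truth = noisy_phantom
        outside = ~truth.tissue_mask
        assert (truth.nadh_field[outside] == 0).all()
        assert (truth.fad_field[outside] == 0).all()

    def test_illumination_has_unit_mean(self, noisy_phantom):
        _, _, _, truth = noisy_phantom
        assert truth.illumination.mean() == pytest.approx(1.0, abs=1e-12)
        assert (truth.illumination > 0).all()

    @pytest.mark.parametrize("bad", [
        dict(shape=(0, 8, 8)),
        dict(noise_sd=-1.0),
        dict(nadh_level=0.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomParams(**bad)


class TestCohortGeneration:
    def test_zero_cv_gives_exact_genotype_means(self):
        spec = liver_cohort_spec(rng_seed=1, between_animal_cv=0.0,
                                 slices_per_animal=4, frame_shape=(16, 16))
        _, manifest = generate_cohort(spec)
        wt = manifest.loc[manifest.genotype == "WT", "true_mean_rr"]
        ko = manifest.loc[manifest.genotype == "KO", "true_mean_rr"]
        assert (wt == spec.wt_rr_mean).all()
        assert (ko == spec.ko_rr_mean).all()

    def test_cohort_means_converge_to_spec_means(self):
        # law of large numbers at n=200 animals per genotype, 3 SE band
        spec = liver_cohort_spec(rng_seed=9)
        spec.n_per_group_by_sex = {("WT", "M"): 100, ("WT", "F"): 100,
                                   ("KO", "M"): 100, ("KO", "F"): 100}
        truth = draw_true_means(spec)
        for genotype, target in (("WT", 2.59), ("KO", 1.77)):
            vals = truth.loc[truth.genotype == genotype, "true_mean_rr"]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - target) < 3 * se

    def test_nadh_effect_channel_leaves_fad_common(self):
        spec = liver_cohort_spec(rng_seed=2, slices_per_animal=4,
                                 frame_shape=(24, 24), between_animal_cv=0.0,
                                 noise_sd=0.0, brightness_cv=0.0, voxel_rr_cv=0.0)
        animals, _ = generate_cohort(spec)
        fad_means = {}
        nadh_means = {}
        for a in animals:
            m = a.truth.tissue_mask
            fad_means.setdefault(a.genotype, []).append(a.truth.fad_field[m].mean())
            nadh_means.setdefault(a.genotype, []).append(a.truth.nadh_field[m].mean())
        assert np.mean(fad_means["WT"]) == pytest.approx(np.mean(fad_means["KO"]))
        assert np.mean(nadh_means["KO"]) < np.mean(nadh_means["WT"])

    def test_null_fad_effect_yields_uniform_pvalues(self):
        # fold 1.0 on the FAD channel: WT and KO true means are exchangeable
        pvals = []
        for seed in range(40):
            spec = liver_cohort_spec(rng_seed=seed, effect_channel="fad",
                                     ko_rr_mean=2.59)
            truth = draw_true_means(spec)
            wt = truth.loc[truth.genotype == "WT", "true_mean_rr"]
            ko = truth.loc[truth.genotype == "KO", "true_mean_rr"]
            pvals.append(sps.ttest_ind(wt, ko).pvalue)
        # KS against uniform; derandomised, generous threshold
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_manifest_truth_matches_realized_volume_mean(self):
        spec = liver_cohort_spec(rng_seed=4, slices_per_animal=6,
                                 frame_shape=(32, 32), noise_sd=0.0,
                                 dark_level=0.0)
        animals, manifest = generate_cohort(spec)
        a = animals[0]
        m = a.truth.tissue_mask
        realized = (a.truth.nadh_field[m] / a.truth.fad_field[m]).mean()
        assert realized == pytest.approx(a.true_mean_rr, rel=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least one group"):
            CohortSpec(n_per_group_by_sex={})

    def test_study_designs(self):
        liver = liver_cohort_spec()
        kidney = kidney_cohort_spec()
        assert sum(liver.n_per_group_by_sex.values()) == 16
        assert sum(kidney.n_per_group_by_sex.values()) == 36
        assert liver.slice_thickness_um == 100.0
        assert kidney.slice_thickness_um == 30.0


class TestSerumTables:
    def test_zero_cv_ko_values_exact_fold(self):
        spec = SerumSpec(analytes=[("glucose", 180.0, "mg/dL", 1.238, 0.0)],
                         n_per_group=5, rng_seed=0)
        table = generate_serum_table(spec)
        ko = table.loc[table.genotype == "KO", "value"].to_numpy()
        np.testing.assert_allclose(ko, 1.238 * 180.0, rtol=0)
        wt = table.loc[table.genotype == "WT", "value"].to_numpy()
        np.testing.assert_allclose(wt, 180.0, rtol=0)

    def test_null_fold_type_one_rate_near_alpha(self):
        rejections = 0
        n_reps = 200
        for seed in range(n_reps):
            spec = SerumSpec(analytes=[("x", 10.0, "u", 1.0, 0.2)],
                             n_per_group=10, rng_seed=seed)
            table = generate_serum_table(spec)
            wt = table.loc[table.genotype == "WT", "value"]
            ko = table.loc[table.genotype == "KO", "value"]
            if sps.ttest_ind(wt, ko).pvalue < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_reps <= 0.10

    def test_presets_carry_reported_effects(self):
        young = {n: f for n, _, _, f, _ in young_serum_spec().analytes}
        aged = {n: f for n, _, _, f, _ in aged_serum_spec().analytes}
        assert young["glucose"] == pytest.approx(1.238)
        assert young["BUN"] == pytest.approx(1.175)
        assert aged["glucose"] == pytest.approx(1.799)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SerumSpec(analytes=[("x", -1.0, "u", 1.0, 0.1)])
        with pytest.raises(ValueError):
            SerumSpec(analytes=[("x", 1.0, "u", 1.0, 0.1)], n_per_group=0)
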
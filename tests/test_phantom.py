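"""Phantom generator: tissue maps, CT rendering, atlases, cohorts, missingness."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from csficv import phantom as phm
from csficv import cohort as chrt
from csficv import models as mdl
from csficv.errors import InvalidRateError, InvalidSpecError, InvalidTransformError, ShapeError

from conftest import make_uniform_tissue_map


class TestTissueMap:
    def test_fractions_partition_of_unity(self, default_phantom):
        s = default_phantom["tmap"].fractions.sum(axis=-1)
        assert np.allclose(s, 1.0, atol=1e-9)

    def test_zero_atrophy_means_zero_csf(self):
        tmap = phm.make_tissue_map(phm.PhantomSpec(atrophy=0.0))
        truth = phm.true_volumes(tmap)
        assert truth.ratio_pct == 0.0
        assert truth.icv_ml > 0

    def test_true_ratio_strictly_increasing_in_atrophy(self):
        ratios = [
            phm.true_volumes(phm.make_tissue_map(phm.PhantomSpec(atrophy=a))).ratio_pct
            for a in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_deterministic_for_fixed_spec(self):
        a = phm.make_tissue_map(phm.PhantomSpec(atrophy=0.4))
        b = phm.make_tissue_map(phm.PhantomSpec(atrophy=0.4))
        assert np.array_equal(a.fractions, b.fractions)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"grid_shape": (0, 64, 64)},
            {"voxel_size": (3.0, -1.0, 3.0)},
            {"atrophy": 1.5},
            {"hu_sds": {"csf": 0.0, "gm": 5.0, "wm": 5.0}},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            phm.make_tissue_map(phm.PhantomSpec(**kwargs))


class TestTrueVolumes:
    def test_all_csf_cube(self):
        tmap = make_uniform_tissue_map(csf=1.0)
        truth = phm.true_volumes(tmap)
        assert truth.csf_ml == pytest.approx(1.0)  # 1000 voxels of 1 mm^3
        assert truth.ratio_pct == pytest.approx(100.0)

    def test_half_csf_half_gm(self):
        tmap = make_uniform_tissue_map(csf=0.5, gm=0.5)
        truth = phm.true_volumes(tmap)
        assert truth.ratio_pct == pytest.approx(50.0)
        assert truth.icv_ml == pytest.approx(truth.csf_ml + truth.gm_ml + truth.wm_ml)

    def test_matches_bruteforce_summation(self):
        rng = np.random.default_rng(3)
        raw = rng.random((5, 6, 7, 4))
        fractions = raw / raw.sum(axis=-1, keepdims=True)
        tmap = phm.TissueMap(fractions=fractions, voxel_size=(2.0, 2.0, 2.0))
        truth = phm.true_volumes(tmap)
        # independent per-voxel loop
        csf = gm = wm = 0.0
        for i in range(5):
            for j in range(6):
                for k in range(7):
                    csf += fractions[i, j, k, 0]
                    gm += fractions[i, j, k, 1]
                    wm += fractions[i, j, k, 2]
        voxml = 8.0 / 1000.0
        assert truth.csf_ml == pytest.approx(csf * voxml, rel=1e-12)
        assert truth.ratio_pct == pytest.approx(100 * csf / (csf + gm + wm), rel=1e-12)

    def test_empty_phantom_rejected(self):
        tmap = make_uniform_tissue_map(csf=0.0)
        with pytest.raises(phm.DegeneratePhantomError):
            phm.true_volumes(tmap)


class TestRenderCT:
    def test_noiseless_mixing(self):
        spec = phm.PhantomSpec(grid_shape=(2, 1, 1), voxel_size=(1, 1, 1), noise_sd=0.0)
        fractions = np.zeros((2, 1, 1, 4))
        fractions[0, 0, 0, 2] = 1.0  # pure WM
        fractions[1, 0, 0, 0] = 0.5  # 50/50 CSF/GM
        fractions[1, 0, 0, 1] = 0.5
        tmap = phm.TissueMap(fractions=fractions, voxel_size=(1, 1, 1))
        ct = phm.render_ct(tmap, spec)
        assert ct.values[0, 0, 0] == pytest.approx(30.0)
        assert ct.values[1, 0, 0] == pytest.approx(0.5 * 5 + 0.5 * 40)

    def test_noise_sd_matches_spec(self, default_phantom):
        spec = replace(default_phantom["spec"], noise_sd=5.0, seed=99)
        noisy = phm.render_ct(default_phantom["tmap"], spec)
        clean = phm.render_ct(default_phantom["tmap"], replace(spec, noise_sd=0.0))
        resid = (noisy.values - clean.values).ravel()
        assert resid.size >= 1e5
        assert np.std(resid) == pytest.approx(5.0, abs=0.2)

    def test_seeded_reproducibility(self, default_phantom):
        spec = default_phantom["spec"]
        a = phm.render_ct(default_phantom["tmap"], spec)
        b = phm.render_ct(default_phantom["tmap"], spec)
        assert np.array_equal(a.values, b.values)

    def test_geometry_mismatch_rejected(self):
        tmap = make_uniform_tissue_map(csf=1.0)
        with pytest.raises(ShapeError):
            phm.render_ct(tmap, phm.PhantomSpec(grid_shape=(4, 4, 4)))


class TestMakeAtlas:
    def test_no_blur_identity_equals_fractions(self, default_phantom):
        tmap = default_phantom["tmap"]
        atlas = phm.make_atlas(tmap, blur_sigma=0.0)
        assert np.allclose(atlas.probs, tmap.fractions[..., :3], atol=1e-12)

    def test_blurred_probabilities_sum_below_one(self, default_phantom):
        atlas = phm.make_atlas(default_phantom["tmap"], blur_sigma=4.0)
        s = atlas.probs.sum(axis=-1)
        assert np.all(s <= 1.0 + 1e-9)
        assert np.all(atlas.probs >= 0.0)

    def test_integer_translation_shifts_probs(self, default_phantom):
        tmap = default_phantom["tmap"]
        vs = tmap.voxel_size
        M = np.eye(4)
        M[:3, 3] = [2 * vs[0], 0.0, 0.0]  # 2 voxels along x
        shifted = phm.make_atlas(tmap, blur_sigma=0.0, misalign=M)
        plain = phm.make_atlas(tmap, blur_sigma=0.0)
        # atlas(v) samples truth at v + 2 voxels along x
        assert np.allclose(shifted.probs[:-2], plain.probs[2:], atol=1e-9)

    def test_singular_transform_rejected(self, default_phantom):
        M = np.eye(4)
        M[0, 0] = 0.0
        with pytest.raises(InvalidTransformError):
            phm.make_atlas(default_phantom["tmap"], misalign=M)


class TestSimulateCohort:
    def test_intercept_only_gives_half_events(self):
        spec = phm.CohortSpec(n=10_000, coefficients={"intercept": 0.0},
                              death_unknown_rate=0.0, seed=5)
        df = phm.simulate_cohort(spec)
        frac = (df["outcome"] == chrt.MALIGNANT_EDEMA).mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_csf_slope_recovered_by_refit(self):
        beta = np.log(1.2)
        spec = phm.CohortSpec(
            n=20_000,
            coefficients={"intercept": -2.0, "csf_icv_inv": beta},
            death_unknown_rate=0.0,
            seed=17,
        )
        df = phm.simulate_cohort(spec)
        fit = mdl.fit_logistic(chrt.code_covariates(df), ["csf_icv_inv"])
        se = fit.bse["csf_icv_inv"]
        assert abs(fit.params["csf_icv_inv"] - beta) < 2 * se

    def test_default_cohort_event_rate_near_six_percent(self):
        spec = phm.default_cohort_spec("extended", n=20_000, seed=23)
        df = chrt.exclude_death_unknown(phm.simulate_cohort(spec))
        rate = 100 * (df["outcome"] == chrt.MALIGNANT_EDEMA).mean()
        assert rate == pytest.approx(5.86, abs=1.0)

    def test_covariate_moments_match_spec(self):
        spec = phm.default_cohort_spec("extended", n=100_000, seed=31)
        df = phm.simulate_cohort(spec)
        d = spec.covariates
        # 3 Monte-Carlo SEs
        assert df["age_yr"].mean() == pytest.approx(d.age_mean, abs=3 * d.age_sd / np.sqrt(len(df)))
        assert df["age_yr"].std() == pytest.approx(d.age_sd, rel=0.02)
        assert df["ica_occlusion"].mean() == pytest.approx(d.ica_p, abs=3 * 0.45 / np.sqrt(len(df)))
        counts = df["collateral_score"].value_counts(normalize=True).sort_index()
        assert np.allclose(counts.to_numpy(), d.collateral_probs, atol=0.01)

    def test_reproducible_for_fixed_seed(self):
        spec = phm.default_cohort_spec("extended", n=500, seed=7)
        a = phm.simulate_cohort(spec)
        b = phm.simulate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_outcome_flags_roundtrip_through_classifier(self, extended_cohort):
        recls = chrt.classify_edema_table(extended_cohort)
        assert (recls == extended_cohort["outcome"]).all()

    def test_age_csf_correlation_positive(self):
        spec = phm.default_cohort_spec("extended", n=50_000, seed=3)
        df = phm.simulate_cohort(spec)
        r = np.corrcoef(df["age_yr"], df["csf_icv_pct"])[0, 1]
        assert r == pytest.approx(spec.covariates.age_csf_corr, abs=0.03)

    def test_unnormalized_category_probs_rejected(self):
        bad = replace(phm.CovariateDistributions(), collateral_probs=(0.5, 0.5, 0.5, 0.5))
        spec = phm.CohortSpec(n=10, covariates=bad)
        with pytest.raises(InvalidSpecError):
            phm.simulate_cohort(spec)


class TestInjectMissingness:
    def test_zero_rates_leave_table_unchanged(self, extended_cohort):
        out = phm.inject_missingness(extended_cohort, {"nihss": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out, extended_cohort)

    def test_rate_one_masks_everything(self, extended_cohort):
        out = phm.inject_missingness(extended_cohort, {"nihss": 1.0}, seed=1)
        assert out["nihss"].isna().all()

    def test_missing_count_within_binomial_bounds(self):
        spec = phm.default_cohort_spec("extended", n=1000, seed=2)
        df = phm.simulate_cohort(spec)
        out = phm.inject_missingness(df, {"csf_icv_pct": 0.1}, seed=3)
        k = out["csf_icv_pct"].isna().sum()
        # central 99% binomial(1000, 0.1) interval
        lo, hi = 76, 125
        assert lo <= k <= hi

    def test_invalid_rate_rejected(self, extended_cohort):
        with pytest.raises(InvalidRateError):
            phm.inject_missingness(extended_cohort, {"nihss": 1.5}, seed=1)

    def test_outcome_cannot_be_masked(self, extended_cohort):
        with pytest.raises(InvalidRateError):
            phm.inject_missingness(extended_cohort, {"outcome": 0.5}, seed=1)
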
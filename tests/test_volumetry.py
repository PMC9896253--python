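"""Volumetry: histograms, mixture fits, volume estimates, registration."""

import numpy as np
import pytest
from dataclasses import replace

from scipy.stats import norm

from csficv import phantom as phm
from csficv import volumetry as vol
from csficv.errors import (
    ConstraintViolationError,
    DegenerateFitError,
    EmptyMaskError,
    ShapeError,
)

from conftest import make_uniform_tissue_map


def uniform_ct(shape, value, voxel=(1.0, 1.0, 1.0)):
    return phm.CTVolume(
        values=np.full(shape, float(value)),
        voxel_size=voxel,
        affine=np.diag(list(voxel) + [1.0]),
    )


def pure_atlas(shape, tissue, voxel=(1.0, 1.0, 1.0)):
    probs = np.zeros(shape + (3,))
    probs[..., phm.TISSUES.index(tissue)] = 1.0
    return phm.ProbAtlas(probs=probs, voxel_size=voxel)


class TestBuildHistograms:
    def test_uniform_wm_volume_in_single_bin(self):
        ct = uniform_ct((8, 8, 8), 30.0)
        atlas = pure_atlas((8, 8, 8), "wm")
        hists = vol.build_histograms(ct, atlas)
        wm = hists.volumes["wm"]
        occupied = np.nonzero(wm)[0]
        assert len(occupied) == 1
        assert wm[occupied[0]] == pytest.approx(hists.masked_volume_ml)
        assert hists.volumes["csf"].sum() == 0.0

    def test_linearity_in_probabilities(self, default_phantom):
        ct, atlas = default_phantom["ct"], default_phantom["atlas"]
        half = phm.ProbAtlas(
            probs=0.5 * atlas.probs,
            voxel_size=atlas.voxel_size,
            intracranial_mask_threshold=atlas.intracranial_mask_threshold * 0.5,
        )
        full = vol.build_histograms(ct, atlas)
        halved = vol.build_histograms(ct, half)
        for t in phm.TISSUES:
            assert np.allclose(halved.volumes[t], 0.5 * full.volumes[t], rtol=1e-12)

    def test_matches_bruteforce_accumulation(self, default_phantom):
        ct, atlas = default_phantom["ct"], default_phantom["atlas"]
        cfg = vol.HistogramConfig()
        hists = vol.build_histograms(ct, atlas, cfg)
        edges = cfg.edges
        voxml = float(np.prod(ct.voxel_size)) / 1000.0
        mask = atlas.probs.sum(axis=-1) >= atlas.intracranial_mask_threshold
        # independent accumulation with searchsorted
        for i, t in enumerate(phm.TISSUES):
            expect = np.zeros(len(edges) - 1)
            hu = ct.values[mask]
            w = atlas.probs[..., i][mask] * voxml
            idx = np.clip(np.searchsorted(edges, hu, side="right") - 1, 0, len(edges) - 2)
            np.add.at(expect, idx, w)
            assert np.allclose(hists.volumes[t], expect, atol=1e-9)

    def test_total_volume_conserved(self, default_phantom):
        hists = vol.build_histograms(default_phantom["ct"], default_phantom["atlas"])
        total = sum(hists.volumes[t].sum() for t in phm.TISSUES)
        assert total == pytest.approx(hists.masked_volume_ml, rel=1e-6)

    def test_empty_mask_rejected(self):
        ct = uniform_ct((4, 4, 4), 30.0)
        probs = np.zeros((4, 4, 4, 3))
        atlas = phm.ProbAtlas(probs=probs, voxel_size=(1, 1, 1))
        with pytest.raises(EmptyMaskError):
            vol.build_histograms(ct, atlas)


def synthetic_histograms(params, cfg=None):
    """HUHistogramSet whose per-tissue histograms are exact Gaussian discretizations."""
    cfg = cfg or vol.HistogramConfig()
    edges = cfg.edges
    volumes = {}
    for t, (area, mean, sd) in params.items():
        volumes[t] = area * np.diff(norm.cdf(edges, loc=mean, scale=sd))
    total = sum(v.sum() for v in volumes.values())
    return vol.HUHistogramSet(edges=edges, volumes=volumes, masked_volume_ml=float(total))


class TestFitMixtures:
    def test_exact_gaussian_recovery(self):
        truth = {"csf": (150.0, 5.0, 4.0), "gm": (600.0, 40.0, 5.0), "wm": (450.0, 30.0, 5.0)}
        hists = synthetic_histograms(truth)
        cfg = vol.MixtureFitConfig(
            n_components={"csf": 1, "gm": 1, "wm": 1},
            mean_bounds={"csf": (-10.0, 18.0), "wm": (18.0, 35.0), "gm": (35.0, 60.0)},
        )
        fit = vol.fit_mixtures(hists, cfg)
        for t, (area, mean, sd) in truth.items():
            (c,) = fit.components[t]
            assert c.area_ml == pytest.approx(area, rel=0.005)
            assert c.mean_hu == pytest.approx(mean, rel=0.005)
            assert c.sd_hu == pytest.approx(sd, rel=0.005)

    def test_single_tissue_histogram_leaves_others_empty(self):
        hists = synthetic_histograms(
            {"csf": (0.0, 5.0, 4.0), "gm": (800.0, 40.0, 5.0), "wm": (0.0, 30.0, 5.0)}
        )
        fit = vol.fit_mixtures(hists)
        total = sum(fit.tissue_volume_ml(t) for t in phm.TISSUES)
        assert fit.tissue_volume_ml("csf") <= 0.01 * total
        assert fit.tissue_volume_ml("wm") <= 0.01 * total

    def test_dominant_component_means_track_tissue_hu(self):
        # large ventricles => substantial pure CSF; noise 5 HU
        spec = phm.PhantomSpec(atrophy=0.95, seed=4)
        tmap = phm.make_tissue_map(spec)
        ct = phm.render_ct(tmap, spec)
        fit = vol.fit_mixtures(vol.build_histograms(ct, phm.make_atlas(tmap)))
        for t in phm.TISSUES:
            dominant = max(fit.components[t], key=lambda c: c.area_ml)
            assert dominant.mean_hu == pytest.approx(spec.hu_means[t], abs=2.0)

    def test_empty_histograms_rejected(self):
        hists = synthetic_histograms(
            {"csf": (0.0, 5.0, 4.0), "gm": (0.0, 40.0, 5.0), "wm": (0.0, 30.0, 5.0)}
        )
        with pytest.raises(EmptyMaskError):
            vol.fit_mixtures(hists)

    def test_violated_ordering_detected(self):
        # GM mass placed where CSF should be and vice versa, with bounds that
        # permit the wrong ordering
        hists = synthetic_histograms(
            {"csf": (500.0, 45.0, 4.0), "gm": (500.0, 5.0, 4.0), "wm": (500.0, 30.0, 4.0)}
        )
        cfg = vol.MixtureFitConfig(
            n_components={"csf": 1, "gm": 1, "wm": 1},
            mean_bounds={"csf": (-10.0, 60.0), "wm": (-10.0, 60.0), "gm": (-10.0, 60.0)},
        )
        with pytest.raises(ConstraintViolationError):
            vol.fit_mixtures(hists, cfg)


class TestComputeVolumes:
    def test_ratio_arithmetic(self):
        fit = vol.MixtureFit(
            components={
                "csf": [vol.GaussianComponent(150.0, 5.0, 4.0)],
                "gm": [vol.GaussianComponent(600.0, 40.0, 5.0)],
                "wm": [vol.GaussianComponent(450.0, 30.0, 5.0)],
            },
            residual_norm=0.0,
            n_evaluations=1,
            converged=True,
        )
        est = vol.compute_volumes(fit)
        assert est.icv_ml == pytest.approx(1200.0)
        assert est.ratio_pct == pytest.approx(12.5)

    def test_zero_csf_gives_zero_ratio(self):
        fit = vol.MixtureFit(
            components={
                "csf": [vol.GaussianComponent(0.0, 5.0, 4.0)],
                "gm": [vol.GaussianComponent(600.0, 40.0, 5.0)],
                "wm": [vol.GaussianComponent(450.0, 30.0, 5.0)],
            },
            residual_norm=0.0,
            n_evaluations=1,
            converged=True,
        )
        assert vol.compute_volumes(fit).ratio_pct == 0.0

    def test_degenerate_fit_rejected(self):
        fit = vol.MixtureFit(
            components={t: [vol.GaussianComponent(0.0, 5.0, 4.0)] for t in phm.TISSUES},
            residual_norm=0.0,
            n_evaluations=1,
            converged=True,
        )
        with pytest.raises(DegenerateFitError):
            vol.compute_volumes(fit)


class TestMeasureEndToEnd:
    def test_noiseless_phantom_within_one_point(self, default_phantom):
        spec = replace(default_phantom["spec"], noise_sd=0.0)
        ct = phm.render_ct(default_phantom["tmap"], spec)
        est = vol.measure_csf_icv(ct, default_phantom["atlas"])
        assert abs(est.ratio_pct - default_phantom["truth"].ratio_pct) <= 1.0

    def test_noisy_phantom_within_two_points(self, default_phantom):
        est = vol.measure_csf_icv(default_phantom["ct"], default_phantom["atlas"])
        assert abs(est.ratio_pct - default_phantom["truth"].ratio_pct) <= 2.0

    def test_all_csf_head_saturates(self):
        spec = phm.PhantomSpec(noise_sd=3.0, seed=8)
        base = phm.make_tissue_map(spec)
        fr = base.fractions.copy()
        brain = fr[..., :3].sum(axis=-1)
        fr[..., 0] = brain  # everything intracranial becomes CSF
        fr[..., 1] = 0.0
        fr[..., 2] = 0.0
        tmap = phm.TissueMap(fractions=fr, voxel_size=base.voxel_size)
        ct = phm.render_ct(tmap, spec)
        atlas = phm.make_atlas(tmap)
        est = vol.measure_csf_icv(ct, atlas)
        assert est.ratio_pct >= 95.0

    def test_estimated_ratio_monotone_in_atrophy(self):
        ests = []
        for a in (0.15, 0.3, 0.45, 0.6, 0.75):
            spec = phm.PhantomSpec(atrophy=a, noise_sd=0.0)
            tmap = phm.make_tissue_map(spec)
            ct = phm.render_ct(tmap, spec)
            ests.append(vol.measure_csf_icv(ct, phm.make_atlas(tmap)).ratio_pct)
        assert all(b > a for a, b in zip(ests, ests[1:]))

    def test_noise_robustness_drift_below_one_point(self, default_phantom):
        tmap = default_phantom["tmap"]
        atlas = default_phantom["atlas"]
        spec = default_phantom["spec"]
        est0 = vol.measure_csf_icv(phm.render_ct(tmap, replace(spec, noise_sd=0.0)), atlas)
        est10 = vol.measure_csf_icv(phm.render_ct(tmap, replace(spec, noise_sd=10.0)), atlas)
        assert abs(est10.ratio_pct - est0.ratio_pct) <= 1.0

    def test_icv_close_to_masked_probabilistic_volume(self, default_phantom):
        est = vol.measure_csf_icv(default_phantom["ct"], default_phantom["atlas"])
        hists = vol.build_histograms(default_phantom["ct"], default_phantom["atlas"])
        assert est.icv_ml == pytest.approx(hists.masked_volume_ml, rel=0.05)

    def test_binary_phantom_matches_voxel_counts(self):
        spec = phm.PhantomSpec(atrophy=0.6, pve_blur_sigma=0.0, supersample=1,
                               noise_sd=0.0, seed=5)
        tmap = phm.make_tissue_map(spec)
        truth = phm.true_volumes(tmap)
        ct = phm.render_ct(tmap, spec)
        atlas = phm.make_atlas(tmap, blur_sigma=0.5)
        est = vol.measure_csf_icv(ct, atlas)
        assert est.csf_ml == pytest.approx(truth.csf_ml, rel=0.01)
        assert est.gm_ml == pytest.approx(truth.gm_ml, rel=0.01)
        assert est.wm_ml == pytest.approx(truth.wm_ml, rel=0.01)


class TestRegistration:
    def test_identity_mode_returns_atlas_unchanged(self, default_phantom):
        atlas, T = vol.register_atlas(default_phantom["ct"], default_phantom["atlas"])
        assert atlas is default_phantom["atlas"]
        assert np.array_equal(T, np.eye(4))

    def test_grid_mismatch_rejected(self, default_phantom):
        small = phm.ProbAtlas(probs=np.zeros((4, 4, 4, 3)), voxel_size=(3, 3, 3))
        with pytest.raises(ShapeError):
            vol.register_atlas(default_phantom["ct"], small)

    def test_affine_recovers_known_translation(self, default_phantom):
        tmap = default_phantom["tmap"]
        ct = default_phantom["ct"]
        M = np.eye(4)
        M[:3, 3] = [4.0, 0.0, -4.0]  # mm
        misaligned = phm.make_atlas(tmap, misalign=M)
        aligned, T = vol.register_atlas(ct, misaligned, mode="affine")
        # the recovered transform samples the atlas, which itself samples the
        # truth through M, so T should approximate M^-1
        expected = np.linalg.inv(M)[:3, 3]
        err_vox = np.abs(T[:3, 3] - expected) / np.asarray(ct.voxel_size)
        assert np.all(err_vox <= 0.5)
        est = vol.measure_csf_icv(ct, aligned)
        assert abs(est.ratio_pct - default_phantom["truth"].ratio_pct) <= 2.0

    def test_affine_identity_is_fixed_point(self, default_phantom):
        aligned, T = vol.register_atlas(
            default_phantom["ct"], default_phantom["atlas"], mode="affine"
        )
        err_vox = np.abs(T[:3, 3]) / np.asarray(default_phantom["ct"].voxel_size)
        assert np.all(err_vox <= 0.1)
        assert np.allclose(T[:3, :3], np.eye(3), atol=0.02)
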
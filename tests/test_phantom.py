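"""Phantom generator: geometry, activity bookkeeping, forward models."""

import math

import numpy as np
import pytest

from y90dosim import phantom as ph
from y90dosim.spect import RoiSet3D, lsf_spect, organ_counts


def ellipsoid_volume_ml(e: ph.Ellipsoid) -> float:
    a, b, c = e.semiaxes_mm
    return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


class TestBuildPhantom:
    def test_activity_normalized_and_lung_fraction_exact(self, default_phantom):
        spec, activity, _, masks, truth = default_phantom
        vox = spec.voxel_volume_ml
        assert activity.sum() * vox == pytest.approx(1.0, abs=1e-12)
        lung_frac = activity[masks["lung"]].sum() * vox
        assert lung_frac == pytest.approx(spec.true_lsf, abs=1e-12)
        assert sum(truth.activity_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_tumor_to_liver_concentration_ratio(self, default_phantom):
        spec, activity, _, masks, _ = default_phantom
        c_tumor = activity[masks["tumor"]].mean()
        c_ihl = activity[masks["ihl"]].mean()
        assert c_tumor / c_ihl == pytest.approx(spec.tlr_true, rel=1e-12)

    def test_zero_shunt_means_cold_lungs(self):
        spec = ph.PhantomSpec(true_lsf=0.0)
        activity, _, masks, _ = ph.build_phantom(spec)
        assert np.all(activity[masks["lung"]] == 0.0)

    def test_unit_tlr_means_uniform_liver(self):
        spec = ph.PhantomSpec(tlr_true=1.0)
        activity, _, masks, _ = ph.build_phantom(spec)
        liver_vals = activity[masks["liver"]]
        assert np.all(liver_vals == liver_vals[0])

    def test_tumor_outside_liver_rejected(self):
        spec = ph.PhantomSpec(
            tumor=ph.Ellipsoid((60.0, 200.0, 60.0), (20.0, 20.0, 20.0))
        )
        with pytest.raises(ph.GeometryError):
            ph.build_phantom(spec)

    def test_voxelized_volumes_near_analytic(self, default_phantom):
        spec, _, _, _, truth = default_phantom
        pairs = [
            ("liver", spec.liver),
            ("tumor", spec.tumor),
            ("lung_left", spec.lung_left),
            ("lung_right", spec.lung_right),
        ]
        for name, e in pairs:
            assert truth.volumes_ml[name] == pytest.approx(
                ellipsoid_volume_ml(e), rel=0.05
            ), name


class TestProjectPlanar:
    def test_conjugate_views_identical_without_attenuation(self, default_phantom):
        spec, activity, mu, _, _ = default_phantom
        spec0 = spec.with_(scatter_fraction=0.0)
        mu0 = np.zeros_like(mu)
        ant = ph.project_planar(activity, mu0, "anterior", "peak", spec0, noise=False)
        post = ph.project_planar(activity, mu0, "posterior", "peak", spec0, noise=False)
        np.testing.assert_allclose(ant.counts, post.counts, rtol=1e-12)

    def test_downscatter_zero_without_scatter(self, default_phantom):
        spec, activity, mu, _, _ = default_phantom
        spec0 = spec.with_(scatter_fraction=0.0)
        low = ph.project_planar(activity, mu, "anterior", "downscatter", spec0,
                                noise=False)
        assert np.all(low.counts == 0.0)

    def test_single_voxel_closed_form_attenuation(self):
        """A lone emission voxel at depth d attenuates the view total to
        total_counts * exp(-mu * d), d measured from the voxel center."""
        spec = ph.PhantomSpec(scatter_fraction=0.0)
        n = 32
        activity = np.zeros((n, n, n))
        k = 10
        activity[16, 16, k] = 1.0 / spec.voxel_volume_ml  # unit total activity
        mu = np.full((n, n, n), spec.mu_soft)
        img = ph.project_planar(activity, mu, "anterior", "peak", spec, noise=False)
        d_cm = (k + 0.5) * spec.voxel_size_mm / 10.0
        assert img.counts.sum() == pytest.approx(
            spec.total_counts * math.exp(-spec.mu_soft * d_cm), rel=1e-12
        )

    def test_poisson_noise_deterministic_given_seed(self, default_phantom):
        spec, activity, mu, _, _ = default_phantom
        a = ph.project_planar(activity, mu, "anterior", "peak", spec, noise=True)
        b = ph.project_planar(activity, mu, "anterior", "peak", spec, noise=True)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_shape_mismatch_rejected(self, default_phantom):
        spec, activity, mu, _, _ = default_phantom
        with pytest.raises(ValueError):
            ph.project_planar(activity, mu[:-1], "anterior", "peak", spec)


class TestEmulateSpect:
    def test_acsc_calibration_recovers_truth(self, default_phantom):
        spec, activity, mu, masks, _ = default_phantom
        vol = ph.emulate_spect(activity, mu, "AC-SC", spec, noise=False)
        oc = organ_counts(vol, RoiSet3D(masks["lung"], masks["liver"]))
        assert lsf_spect(oc.lc, oc.lvc).lsf == pytest.approx(spec.true_lsf, abs=1e-9)

    def test_noac_equals_acsc_without_attenuation(self, default_phantom):
        spec, activity, mu, _, _ = default_phantom
        mu0 = np.zeros_like(mu)
        ac = ph.emulate_spect(activity, mu0, "AC-SC", spec, noise=False)
        noac = ph.emulate_spect(activity, mu0, "NoAC-SC", spec, noise=False)
        np.testing.assert_allclose(noac.counts, ac.counts, rtol=1e-12)

    def test_missing_attenuation_correction_inflates_lsf(self, default_phantom):
        """The liver sits deeper than the lungs, so dropping AC suppresses
        liver counts more and inflates the shunt fraction."""
        spec, activity, mu, masks, _ = default_phantom
        rois = RoiSet3D(masks["lung"], masks["liver"])
        lsfs = {}
        for mode in ("AC-SC", "NoAC-SC"):
            vol = ph.emulate_spect(activity, mu, mode, spec, noise=False)
            oc = organ_counts(vol, rois)
            lsfs[mode] = lsf_spect(oc.lc, oc.lvc, mode=mode).lsf
        assert lsfs["NoAC-SC"] > lsfs["AC-SC"]

    def test_lateral_attenuation_factor_against_brute_force(self):
        """f(v) equals a per-voxel loop over the four lateral rays."""
        rng = np.random.default_rng(7)
        mu = rng.uniform(0.0, 0.2, size=(8, 8, 8))
        voxel_cm = 0.4
        f = ph._lateral_attenuation_factor(mu, voxel_cm)
        for idx in [(0, 0, 0), (3, 4, 2), (7, 7, 7), (5, 1, 6)]:
            i, j, k = idx
            paths = [
                (mu[: i + 1, j, k].sum() - 0.5 * mu[i, j, k]) * voxel_cm,
                (mu[i:, j, k].sum() - 0.5 * mu[i, j, k]) * voxel_cm,
                (mu[i, : j + 1, k].sum() - 0.5 * mu[i, j, k]) * voxel_cm,
                (mu[i, j:, k].sum() - 0.5 * mu[i, j, k]) * voxel_cm,
            ]
            expected = np.mean([math.exp(-p) for p in paths])
            assert f[idx] == pytest.approx(expected, rel=1e-12)

    def test_unknown_mode_rejected(self, default_phantom):
        spec, activity, mu, _, _ = default_phantom
        with pytest.raises(ValueError):
            ph.emulate_spect(activity, mu, "AC-NoSC", spec)


def test_doubling_counts_shrinks_relative_error(default_phantom):
    """Poisson scaling: doubling total counts shrinks the relative standard
    error of the recovered LSF by roughly 1/sqrt(2)."""
    from y90dosim import planar as pl

    spec, activity, mu, masks, _ = default_phantom
    mu0 = np.zeros_like(mu)
    rois = ph.planar_rois(masks)
    expected = {
        (v, w): ph.project_planar(activity, mu0, v, w, spec, noise=False).counts
        for v in ("anterior", "posterior")
        for w in ("peak", "downscatter")
    }

    def recovered(scale, n_seeds=150):
        vals = []
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            noisy = {
                k: pl.PlanarImage(rng.poisson(c * scale).astype(float),
                                  spec.voxel_size_mm, k[0], k[1])
                for k, c in expected.items()
            }
            r = pl.lsf_planar(
                noisy[("anterior", "peak")], noisy[("posterior", "peak")],
                noisy[("anterior", "downscatter")], noisy[("posterior", "downscatter")],
                rois, mode="scatter_corrected",
            )
            vals.append(r.lsf)
        vals = np.asarray(vals)
        return vals.std() / vals.mean()

    ratio = recovered(2.0) / recovered(1.0)
    assert 0.55 < ratio < 0.85  # ideal 0.707
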
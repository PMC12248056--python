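"""Elastic operator, PIV, and regularized inversion properties."""

import numpy as np
import pytest

from mechanoquant import synthgen, tfm
from mechanoquant.containers import (
    ChannelImage,
    DisplacementField,
    LabelMask,
    Substrate,
    TractionField,
)


def boussinesq_point_displacement(n, center, force_pa, E, nu, d):
    """Real-space surface Green's function evaluated on the grid (oracle)."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    ry, rx = (yy - center[0]) * d, (xx - center[1]) * d
    r = np.hypot(ry, rx)
    r[r == 0] = 1.0
    pref = (1 + nu) / (np.pi * E)
    F = force_pa * d * d
    ux = pref * ((1 - nu) / r + nu * rx**2 / r**3) * F
    uy = pref * (nu * rx * ry / r**3) * F
    return np.stack([uy, ux], axis=-1)


class TestGreensTensor:
    def test_positive_semidefinite_symmetric(self):
        ky, kx = np.meshgrid(np.linspace(-3, 3, 21), np.linspace(-3, 3, 21), indexing="ij")
        Gyy, Gyx, Gxx = tfm.greens_tensor(ky, kx, Substrate(1e4, 0.4))
        nz = (ky != 0) | (kx != 0)
        trace = Gyy + Gxx
        det = Gyy * Gxx - Gyx**2
        assert np.all(trace[nz] > 0)
        assert np.all(det[nz] >= -1e-20)

    def test_invalid_substrate_rejected(self):
        with pytest.raises(ValueError):
            Substrate(-5.0, 0.5)
        with pytest.raises(ValueError):
            Substrate(1e4, 0.7)
        with pytest.raises(ValueError):
            Substrate(1e4, 0.5, regularization=-1e-3)


class TestForwardBoussinesq:
    def test_zero_traction_zero_displacement(self):
        t = TractionField(np.zeros((32, 32, 2)), 1.0)
        u = tfm.forward_boussinesq(t, Substrate(1e4, 0.5))
        assert np.all(u.vectors == 0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 50, (32, 32, 2))
        s = Substrate(1e4, 0.5)
        u1 = tfm.forward_boussinesq(TractionField(v, 1.0), s).vectors
        u2 = tfm.forward_boussinesq(TractionField(2 * v, 1.0), s).vectors
        np.testing.assert_allclose(u2, 2 * u1, rtol=1e-12)

    @pytest.mark.parametrize("nu", [0.3, 0.5])
    def test_matches_spatial_domain_convolution(self, nu):
        """FFT operator vs the real-space point-force solution for a
        localized (band-limited Gaussian) force, modulo the rigid DC mode."""
        n, d, E = 64, 1.0, 1e4
        s = Substrate(E, nu)
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        prof = 1000.0 * np.exp(-0.5 * (((yy - 32) / 1.2) ** 2 + ((xx - 32) / 1.2) ** 2))
        t = np.stack([np.zeros((n, n)), prof], axis=-1)
        u = tfm.forward_boussinesq(TractionField(t, d, pixel_size=d), s, pad_factor=4).vectors

        # direct spatial convolution of the patch with the point-force kernel
        oracle = np.zeros_like(u)
        for (sy, sx) in np.argwhere(prof > 1e-3 * prof.max()):
            oracle += boussinesq_point_displacement(n, (sy, sx), prof[sy, sx], E, nu, d)

        r = np.hypot(yy - 32, xx - 32)
        outside = r > 3
        du, do = u.copy(), oracle.copy()
        for c in range(2):
            du[..., c] -= du[..., c][outside].mean()
            do[..., c] -= do[..., c][outside].mean()
        rel = np.linalg.norm((du - do)[outside]) / np.linalg.norm(do[outside])
        assert rel < 0.05


class TestInvertFttc:
    def test_zero_displacement_zero_traction(self):
        u = DisplacementField(np.zeros((32, 32, 2)), 1.0)
        for lam in (0.0, 1e-4, 1e-2):
            t = tfm.invert_fttc(u, Substrate(1e4, 0.5, regularization=lam))
            assert np.all(t.vectors == 0)

    def test_round_trip_identity_on_band_limited_field(self, substrate_10kpa):
        traction = synthgen.traction_dipole((128, 128), peak_pa=300.0, sigma_um=1.5,
                                            separation_um=4.0, pixel_size=0.1)
        s0 = Substrate(1e4, 0.5, regularization=0.0)
        u = tfm.forward_boussinesq(traction, s0, pad_factor=1)
        rec = tfm.invert_fttc(u, s0, pad=False)
        rel = np.linalg.norm(rec.vectors - traction.vectors) / np.linalg.norm(traction.vectors)
        assert rel < 0.01

    def test_recovered_traction_real_and_force_balanced(self, substrate_10kpa):
        traction = synthgen.traction_dipole((64, 64), peak_pa=300.0, sigma_um=3.0,
                                            separation_um=2.0, pixel_size=0.1)
        u = tfm.forward_boussinesq(traction, substrate_10kpa, pad_factor=1)
        rec = tfm.invert_fttc(u, substrate_10kpa, pad=False)
        fy, fx = rec.net_force()
        scale = np.abs(rec.vectors).max() * rec.grid_spacing**2 * 64 * 64
        assert abs(fy) / scale < 1e-10 and abs(fx) / scale < 1e-10

    def test_regularization_reduces_noise_error(self):
        """Monte-Carlo over seeds: the lam=1e-4 solution is never worse than
        the unregularized one on noisy displacements."""
        traction = synthgen.traction_dipole((64, 64), peak_pa=300.0, sigma_um=3.0,
                                            separation_um=2.0, pixel_size=0.1)
        s0 = Substrate(1e4, 0.5, regularization=0.0)
        s_reg = Substrate(1e4, 0.5, regularization=1e-4)
        u = tfm.forward_boussinesq(traction, s0, pad_factor=1)
        better = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            noisy = DisplacementField(
                u.vectors + rng.normal(0, 0.05 * np.abs(u.vectors).max(), u.vectors.shape),
                u.grid_spacing,
            )
            e0 = np.linalg.norm(tfm.invert_fttc(noisy, s0, pad=False).vectors - traction.vectors)
            e1 = np.linalg.norm(tfm.invert_fttc(noisy, s_reg, pad=False).vectors - traction.vectors)
            better += e1 <= e0
        assert better == n_seeds

    def test_total_force_stable_across_lambda(self):
        """Total recovered force magnitude over a generous mask varies < 10%
        for lam in [0, 1e-3] on noiseless input."""
        traction = synthgen.traction_dipole((64, 64), peak_pa=300.0, sigma_um=3.0,
                                            separation_um=2.0, pixel_size=0.1)
        u = tfm.forward_boussinesq(traction, Substrate(1e4, 0.5), pad_factor=1)
        totals = []
        for lam in (0.0, 1e-4, 1e-3):
            rec = tfm.invert_fttc(u, Substrate(1e4, 0.5, regularization=lam), pad=False)
            totals.append(rec.magnitude().sum() * rec.grid_spacing**2)
        assert (max(totals) - min(totals)) / max(totals) < 0.10


class TestEstimateDisplacement:
    def test_identical_pair_zero_field(self, tfm_scene):
        _, _, relaxed, _, _ = tfm_scene
        d = tfm.estimate_displacement(relaxed, relaxed, subtract_drift=False)
        assert np.abs(d.vectors).max() < 1e-9

    def test_uniform_rigid_shift_recovered(self, tfm_scene):
        from scipy import ndimage

        _, _, relaxed, _, _ = tfm_scene
        shifted = ChannelImage(
            np.clip(ndimage.shift(relaxed.pixels, (2.25, -1.50), order=3, mode="nearest"), 0, None),
            relaxed.pixel_size,
        )
        d = tfm.estimate_displacement(shifted, relaxed, subtract_drift=False)
        upx = d.vectors / relaxed.pixel_size
        assert np.abs(upx - np.array([2.25, -1.50])).max() < 0.2

    def test_smooth_patch_field_matches_forward_operator(self, tfm_scene):
        traction, deformed, relaxed, mask, gt = tfm_scene
        d = tfm.estimate_displacement(deformed, relaxed)
        oy, ox = d.origin_px
        iy = np.round(oy + np.arange(d.shape[0]) * d.spacing_px).astype(int)
        ix = np.round(ox + np.arange(d.shape[1]) * d.spacing_px).astype(int)
        truth = gt.displacement_true.vectors[np.ix_(iy, ix)]
        truth = truth - truth.mean(axis=(0, 1))
        rms_px = np.sqrt(((d.vectors - truth) ** 2).mean()) / relaxed.pixel_size
        assert rms_px < 0.2

    def test_textureless_images_rejected(self):
        flat = ChannelImage(np.full((128, 128), 5.0), 0.1)
        with pytest.raises(ValueError, match="bead texture"):
            tfm.estimate_displacement(flat, flat)

    def test_window_too_small_rejected(self, tfm_scene):
        _, deformed, relaxed, _, _ = tfm_scene
        with pytest.raises(ValueError):
            tfm.estimate_displacement(deformed, relaxed, window_px=8)


class TestAvgTractionStress:
    def test_uniform_magnitude_any_mask(self):
        t = TractionField(np.full((32, 32, 2), 100.0 / np.sqrt(2)), 1.6, spacing_px=16.0)
        mask = np.zeros((512, 512), np.int32)
        mask[100:300, 100:300] = 1
        df = tfm.avg_traction_stress(t, LabelMask(mask, 0.1))
        assert df.avg_stress_Pa[0] == pytest.approx(100.0)

    def test_zero_traction_zero_stress(self):
        t = TractionField(np.zeros((32, 32, 2)), 1.6, spacing_px=16.0)
        mask = np.ones((512, 512), np.int32)
        df = tfm.avg_traction_stress(t, LabelMask(mask, 0.1))
        assert df.avg_stress_Pa[0] == 0.0

    def test_matches_node_enumeration_oracle(self, tfm_scene):
        traction, deformed, relaxed, mask, gt = tfm_scene
        d = tfm.estimate_displacement(deformed, relaxed)
        rec = tfm.invert_fttc(d, gt.substrate)
        df = tfm.avg_traction_stress(rec, mask)
        node_labels = tfm.sample_mask_on_grid(mask, rec)
        mag = rec.magnitude()
        oracle = np.mean([mag[i, j] for i, j in zip(*np.where(node_labels == 1))])
        assert df.avg_stress_Pa[0] == pytest.approx(oracle, abs=1e-9)

    def test_empty_mask_excluded(self):
        t = TractionField(np.zeros((8, 8, 2)), 1.6, spacing_px=16.0)
        mask = np.zeros((512, 512), np.int32)
        mask[0, 0] = 1  # far from any grid node? node (0,0) maps to px 15.5
        mask[:, :] = 0
        mask[2, 2] = 1
        df = tfm.avg_traction_stress(t, LabelMask(mask, 0.1))
        assert bool(df.excluded[0]) is True
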
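"""Phantom generators and forward models."""

import numpy as np
import pytest
from scipy.optimize import brentq

from bst1map.relaxometry import ir_signal
from bst1map.synthetic import (GEL_TUBE_T1_MS, IRProtocol, NoiseSpec,
                               PhantomSpec, VFAProtocol, make_breast_phantom,
                               make_gel_phantom, simulate_bs_pair, simulate_ir,
                               simulate_testretest, simulate_vfa)


class TestGelPhantom:
    def test_default_tubes_carry_reference_t1(self, gel_gt):
        values = set()
        for name, mask in gel_gt.masks.items():
            if name.startswith("tube_"):
                tube_vals = np.unique(gel_gt.t1_true.data[mask])
                assert len(tube_vals) == 1
                values.add(float(tube_vals[0]))
        assert values == set(GEL_TUBE_T1_MS)

    def test_tube_masks_disjoint_and_nonempty(self, gel_gt):
        # brute-force audit: every foreground voxel belongs to exactly one tube
        count = np.zeros(gel_gt.t1_true.shape, dtype=int)
        for name, mask in gel_gt.masks.items():
            if name.startswith("tube_"):
                assert mask.sum() > 0
                count += mask.astype(int)
        assert count.max() == 1
        assert (count.sum() == gel_gt.foreground.sum())

    def test_single_tube_uniform_b1_gives_unit_f(self):
        gt = make_gel_phantom(PhantomSpec(tube_t1_ms=(800.0,),
                                          b1_field="uniform", b1_range=(1, 1)))
        fg = gt.foreground
        np.testing.assert_array_equal(gt.f_true.f[fg], 1.0)

    def test_too_many_tubes_for_grid(self):
        with pytest.raises(ValueError, match="fit"):
            make_gel_phantom(PhantomSpec(grid_shape=(1, 10, 10),
                                         tube_radius_vox=4))


class TestBreastPhantom:
    def test_two_tissue_t1_values(self, breast_gt):
        fg = breast_gt.foreground
        assert set(np.unique(breast_gt.t1_true.data[fg])) == {420.0, 1290.0}
        assert breast_gt.masks["AT"].sum() > breast_gt.masks["FGT"].sum() > 0

    def test_at_shell_encloses_fgt(self, breast_gt):
        # FGT never touches the lateral body boundary columns
        body_cols = np.where(breast_gt.foreground.any(axis=(0, 1)))[0]
        fgt_cols = np.where(breast_gt.masks["FGT"].any(axis=(0, 1)))[0]
        assert fgt_cols.min() > body_cols.min()
        assert fgt_cols.max() < body_cols.max()

    def test_uniform_unit_field(self):
        gt = make_breast_phantom(PhantomSpec(kind="breast", b1_field="uniform",
                                             b1_range=(1, 1)))
        np.testing.assert_array_equal(gt.f_true.f[gt.foreground], 1.0)

    def test_linear_ramp_hits_edges_exactly(self):
        spec = PhantomSpec(kind="breast", b1_range=(0.8, 1.1))
        gt = make_breast_phantom(spec)
        # evaluate the interpolant at the two lateral edge columns
        full = 0.8 + (1.1 - 0.8) * np.arange(spec.grid_shape[2]) / (spec.grid_shape[2] - 1)
        assert abs(full[0] - 0.8) <= 1e-9 and abs(full[-1] - 1.1) <= 1e-9
        cols = np.where(gt.foreground.any(axis=(0, 1)))[0]
        expected = 0.8 + (1.1 - 0.8) * cols / (spec.grid_shape[2] - 1)
        observed = np.array([gt.f_true.f[:, :, c][gt.foreground[:, :, c]].mean()
                             for c in cols])
        np.testing.assert_allclose(observed, expected, atol=1e-12)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_fgt_fraction_range(self, frac):
        with pytest.raises(ValueError, match="fgt_fraction"):
            make_breast_phantom(PhantomSpec(kind="breast", fgt_fraction=frac))


class TestForwardModels:
    def test_spgr_closed_form_t1_equals_tr(self):
        gt = make_gel_phantom(PhantomSpec(tube_t1_ms=(7.9,), s0=1.0,
                                          b1_field="uniform", b1_range=(1, 1)))
        series = simulate_vfa(gt, VFAProtocol(flip_angles_deg=(45, 90), tr_ms=7.9))
        fg = gt.foreground
        np.testing.assert_allclose(series.volumes[1].data[fg], 1 - np.exp(-1),
                                   rtol=1e-12)

    def test_spgr_matches_direct_equation(self):
        gt = make_gel_phantom(PhantomSpec(tube_t1_ms=(1000.0,), s0=1.0,
                                          b1_field="uniform", b1_range=(1, 1)))
        series = simulate_vfa(gt, VFAProtocol(flip_angles_deg=(10,), tr_ms=7.9))
        e1 = np.exp(-7.9 / 1000.0)
        a = np.deg2rad(10)
        expected = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
        fg = gt.foreground
        np.testing.assert_allclose(series.volumes[0].data[fg], expected, rtol=1e-12)

    def test_ir_long_ti_recovers_s0(self):
        gt = make_gel_phantom(PhantomSpec(tube_t1_ms=(400.0,), s0=1.0))
        series = simulate_ir(gt, IRProtocol(ti_ms=(10000.0,)))
        fg = gt.foreground
        np.testing.assert_allclose(series.volumes[0].data[fg], 1.0, rtol=1e-9)

    def test_ir_null_close_to_classic_log2(self):
        # TD >> T1 reduces to the textbook null at T1 * ln 2
        s = ir_signal(1000.0, 1.0, 1000.0 * np.log(2.0), td_ms=1e9)
        assert abs(s) < 1e-12

    def test_ir_null_with_finite_predelay(self):
        # root of the signal equation found independently by bisection
        t1, td = 1300.0, 2500.0
        expected = t1 * np.log(2 - np.exp(-td / t1))
        signed = lambda ti: (np.cos(np.pi) * (1 - np.exp(-td / t1)) * np.exp(-ti / t1)
                             + 1 - np.exp(-ti / t1))
        root = brentq(signed, 100, 4000)
        assert abs(root - expected) < 1e-6
        assert ir_signal(t1, 1.0, root, td_ms=td) < 1e-12


class TestBlochSiegertSimulation:
    def test_unit_field_gives_uniform_phase_difference(self, gel_gt_uniform):
        pair = simulate_bs_pair(gel_gt_uniform)
        fg = gel_gt_uniform.foreground
        pd = np.angle(pair.img_plus.data * np.conj(pair.img_minus.data))
        assert np.ptp(pd[fg]) < 1e-12
        assert pd[fg].mean() > 0

    def test_background_has_no_shift(self, gel_gt):
        pair = simulate_bs_pair(gel_gt)
        bg = gel_gt.masks["background"]
        pd = np.angle(pair.img_plus.data * np.conj(pair.img_minus.data))
        np.testing.assert_array_equal(pd[bg], 0.0)

    def test_quadratic_b1_law(self):
        from bst1map.bloch_siegert import PulseSpec

        pulse = PulseSpec(shape="constant", offset_hz=12000.0, b1_rms_ut=1.0)
        spec1 = PhantomSpec(tube_t1_ms=(800.0,), b1_field="uniform", b1_range=(1, 1))
        spec2 = PhantomSpec(tube_t1_ms=(800.0,), b1_field="uniform", b1_range=(2, 2))
        pd = []
        for spec in (spec1, spec2):
            gt = make_gel_phantom(spec)
            pair = simulate_bs_pair(gt, pulse)
            fg = gt.foreground
            pd.append(np.angle(pair.img_plus.data * np.conj(pair.img_minus.data))[fg].mean())
        assert abs(pd[1] / pd[0] - 4.0) < 0.08  # doubling f quadruples the shift


class TestNoiseAndSeeding:
    def test_rician_background_mean(self):
        gt = make_gel_phantom(PhantomSpec(grid_shape=(1, 128, 128)))
        sigma = 5.0
        series = simulate_vfa(gt, None, NoiseSpec(model="rician", sigma=sigma, seed=4))
        bg = gt.masks["background"]
        assert bg.sum() >= 10_000
        observed = series.volumes[0].data[bg].mean()
        expected = sigma * np.sqrt(np.pi / 2)
        assert abs(observed / expected - 1) < 0.05

    def test_same_seed_bit_identical(self, gel_gt):
        noise = NoiseSpec(model="rician", sigma=2.0, seed=11)
        a = simulate_vfa(gel_gt, None, noise).stack()
        b = simulate_vfa(gel_gt, None, noise).stack()
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self, gel_gt):
        a = simulate_vfa(gel_gt, None, NoiseSpec("rician", 2.0, seed=1)).stack()
        b = simulate_vfa(gel_gt, None, NoiseSpec("rician", 2.0, seed=2)).stack()
        assert not np.array_equal(a, b)


class TestTestRetest:
    def test_noiseless_unjittered_sessions_identical(self, gel_gt):
        s1, s2 = simulate_testretest(gel_gt)
        np.testing.assert_array_equal(s1["vfa"].stack(), s2["vfa"].stack())
        np.testing.assert_array_equal(s1["ir"].stack(), s2["ir"].stack())

    def test_seeding_contract(self, gel_gt):
        noise = NoiseSpec(model="rician", sigma=2.0, seed=9)
        a1, a2 = simulate_testretest(gel_gt, noise=noise)
        b1, b2 = simulate_testretest(gel_gt, noise=noise)
        np.testing.assert_array_equal(a1["vfa"].stack(), b1["vfa"].stack())
        np.testing.assert_array_equal(a2["ir"].stack(), b2["ir"].stack())
        # the two sessions themselves carry independent noise
        assert not np.array_equal(a1["vfa"].stack(), a2["vfa"].stack())

    def test_jitter_translates_session2(self, gel_gt):
        s1, s2 = simulate_testretest(gel_gt, jitter=(0, 2, 3))
        np.testing.assert_array_equal(
            np.roll(s1["vfa"].stack(), (0, 2, 3), axis=(1, 2, 3)),
            s2["vfa"].stack())

    def test_jitter_larger_than_grid(self, gel_gt):
        with pytest.raises(ValueError, match="jitter"):
            simulate_testretest(gel_gt, jitter=(0, 96, 0))

    def test_gel_tube_sd_order_of_magnitude_at_snr50(self, gel_gt_uniform):
        # sigma at ~1/50 of the peak VFA signal: per-tube T1 SDs land in the
        # tens-of-ms range reported for gel measurements
        from bst1map.relaxometry import fit_vfa

        noise = NoiseSpec(model="rician", sigma=1.25, seed=21)
        series = simulate_vfa(gel_gt_uniform, None, noise)
        t1_map = fit_vfa(series)
        sds = []
        for name, mask in gel_gt_uniform.masks.items():
            if name.startswith("tube_"):
                sel = mask & t1_map.valid_mask
                sds.append(np.std(t1_map.t1_ms[sel], ddof=1))
        assert 5 < np.median(sds) < 150
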
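import numpy as np
import pytest

import greyblood as gb
from greyblood._fft import ifftc
from greyblood.motion import estimate_motion_trace, recon_inav, apply_phase_correction
from greyblood.sense import grid_kspace


@pytest.fixture(scope="module")
def moving_acq(small_cardiac, protocol_seq):
    """Undersampled acquisition with a sinusoidal 8 mm SI / 2.4 mm LR trace."""
    sched = gb.generate_sampling_schedule((32, 16), 3.0, 16, seed=0)
    maps = gb.simulate_coil_maps(1, small_cardiac.shape)
    trace = gb.simulate_motion_trace(
        sched.n_shots,
        {"amplitude_si": 8.0, "period": 3.7, "lr_ratio": 0.3, "drift": 0.0},
        rr=1.0,
    )
    raw = gb.simulate_acquisition(small_cardiac, maps, protocol_seq, sched, trace)
    return raw, trace


class TestReconInav:
    def test_fully_sampled_inav_equals_projection(self, small_cardiac, protocol_seq):
        """With every PE line acquired the navigator inverts the projection
        forward model exactly (per-line Mz weights included)."""
        from dataclasses import replace

        from greyblood._fft import fftc

        seq = replace(protocol_seq, n_inav_echoes=32, ti=300.0)
        sched = gb.generate_sampling_schedule((32, 16), 1.0, 16, seed=0)
        maps = gb.simulate_coil_maps(1, small_cardiac.shape)
        trace = gb.MotionTrace(np.zeros(sched.n_shots), np.zeros(sched.n_shots))
        raw = gb.simulate_acquisition(small_cardiac, maps, seq, sched, trace)
        nav = recon_inav(raw, 0, echo=0)
        # analytic weighted-projection k-space, inverted on the full grid
        kk = np.zeros((32, 32), dtype=complex)
        sin_nav = np.sin(np.deg2rad(seq.fa_inav))
        for lab, tp in small_cardiac.tissue_table.items():
            tr_ = gb.simulate_mz_train(tp, seq)
            pk = fftc((small_cardiac.labels == lab).sum(axis=2).astype(float))
            comp = (1 - tp.fat_fraction) + tp.fat_fraction * seq.fat_phase(0)
            w = tp.pd * tr_.mz_inav_ir * sin_nav * np.exp(-seq.te1 / tp.t2s) * comp
            for j, line in enumerate(raw.inav_lines):
                kk[:, line] += pk[:, line] * w[j]
        expect = ifftc(kk)
        assert np.linalg.norm(nav.image - expect) / np.linalg.norm(expect) < 1e-6

    def test_zero_filling_preserves_acquired_lines(self, moving_acq):
        raw, _ = moving_acq
        nav = recon_inav(raw, 3, echo=0)
        kk = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(nav.image), norm="ortho"))
        for j, line in enumerate(raw.inav_lines):
            np.testing.assert_allclose(kk[:, line], raw.inav[3, 0, j], atol=1e-10)
        other = [c for c in range(raw.grid_shape[1]) if c not in raw.inav_lines]
        assert np.abs(kk[:, other]).max() < 1e-10

    def test_shift_equivariance(self, small_cardiac, protocol_seq):
        """Shots differing by a pure 3-pixel SI shift give navigators related
        by the same circular shift."""
        sched = gb.generate_sampling_schedule((32, 16), 3.0, 16, seed=0)
        maps = gb.simulate_coil_maps(1, small_cardiac.shape)
        d = np.zeros(sched.n_shots)
        d[2] = 6.0  # 3 px at 2 mm
        raw = gb.simulate_acquisition(
            small_cardiac, maps, protocol_seq, sched,
            gb.MotionTrace(d, np.zeros_like(d)),
        )
        nav0 = recon_inav(raw, 0, echo=0).image
        nav2 = recon_inav(raw, 2, echo=0).image
        rel = np.linalg.norm(nav2 - np.roll(nav0, 3, axis=1)) / np.linalg.norm(nav0)
        assert rel < 1e-3

    def test_missing_shot_rejected(self, moving_acq):
        raw, _ = moving_acq
        with pytest.raises(ValueError):
            recon_inav(raw, raw.n_shots + 5)


class TestEstimateMotion:
    def test_static_series(self, small_cardiac, protocol_seq):
        sched = gb.generate_sampling_schedule((32, 16), 3.0, 16, seed=0)
        maps = gb.simulate_coil_maps(1, small_cardiac.shape)
        trace = gb.MotionTrace(np.zeros(sched.n_shots), np.zeros(sched.n_shots))
        raw = gb.simulate_acquisition(small_cardiac, maps, protocol_seq, sched, trace)
        navs = [recon_inav(raw, i) for i in range(0, raw.n_shots, 2)]
        est = estimate_motion_trace(navs, voxel_size=(2.0, 2.0))
        np.testing.assert_allclose(est.d_si, 0.0, atol=1e-9)
        np.testing.assert_allclose(est.d_lr, 0.0, atol=1e-9)
        assert np.all(est.correlation > 0.999)

    def test_integer_shifts_recovered(self):
        """Known integer pixel shifts of a textured scene are found at the
        exact NCC peak."""
        rng = np.random.default_rng(5)
        base = np.zeros((48, 48))
        base[12:36, 12:36] = rng.random((24, 24))
        from scipy import ndimage
        base = ndimage.gaussian_filter(base, 1.2)
        navs = []
        shifts = [(0, 0), (-3, 2), (2, -1)]
        for i, (sx, sy) in enumerate(shifts):
            img = np.roll(np.roll(base, sx, axis=0), sy, axis=1)
            navs.append(gb.INavImage(image=img.astype(complex), shot_index=i,
                                     volume_tag="IR", echo=0))
        est = estimate_motion_trace(navs, voxel_size=(1.0, 1.0), search_mm=8)
        ref = est.reference_shot
        for i, (sx, sy) in enumerate(shifts):
            assert est.d_lr[i] == pytest.approx(sx - shifts[ref][0], abs=0.05)
            assert est.d_si[i] == pytest.approx(sy - shifts[ref][1], abs=0.05)

    def test_subpixel_sinusoid_snr20(self, small_cardiac, protocol_seq):
        """Sub-pixel sinusoidal trace at SNR 20: RMSE < 0.5 px."""
        sched = gb.generate_sampling_schedule((32, 16), 3.0, 16, seed=0)
        maps = gb.simulate_coil_maps(1, small_cardiac.shape)
        trace = gb.simulate_motion_trace(
            sched.n_shots,
            {"amplitude_si": 10.0, "period": 3.3, "lr_ratio": 0.3},
            rr=1.0,
        )
        sigma = gb.sigma_for_snr(small_cardiac, maps, protocol_seq, 20.0)
        raw = gb.simulate_acquisition(small_cardiac, maps, protocol_seq, sched,
                                      trace, noise_sigma=sigma, seed=8)
        idx = [i for i, s in enumerate(sched.shots) if s.tag == "IR"]
        navs = [recon_inav(raw, i) for i in idx]
        est = estimate_motion_trace(navs, voxel_size=(2.0, 2.0))
        truth = trace.d_si[idx] - trace.d_si[idx][est.reference_shot]
        rmse_px = np.sqrt(np.mean((est.d_si - truth) ** 2)) / 2.0
        assert rmse_px < 0.5

    def test_reference_shot_has_zero_displacement(self, moving_acq):
        raw, _ = moving_acq
        idx = [i for i, s in enumerate(raw.schedule.shots) if s.tag == "IR"]
        est = estimate_motion_trace([recon_inav(raw, i) for i in idx],
                                    voxel_size=(2.0, 2.0))
        assert est.d_si[est.reference_shot] == 0.0
        assert est.d_lr[est.reference_shot] == 0.0

    def test_all_low_confidence_rejected(self):
        """Featureless navigators (no template correlation anywhere) reject."""
        navs = [gb.INavImage(image=np.ones((32, 32), dtype=complex),
                             shot_index=i, volume_tag="IR", echo=0)
                for i in range(4)]
        with pytest.raises(ValueError, match="low-confidence"):
            estimate_motion_trace(navs, voxel_size=(2.0, 2.0), search_mm=4.0)

    def test_roi_bounds_checked(self, moving_acq):
        raw, _ = moving_acq
        navs = [recon_inav(raw, i) for i in (0, 2)]
        with pytest.raises(ValueError, match="ROI"):
            estimate_motion_trace(navs, template_roi=((0, 64), (0, 10)))


class TestPhaseCorrection:
    def test_zero_motion_is_identity(self, moving_acq):
        raw, _ = moving_acq
        out = apply_phase_correction(raw, np.zeros(raw.n_shots), np.zeros(raw.n_shots))
        np.testing.assert_array_equal(out.kspace, raw.kspace)
        np.testing.assert_array_equal(out.inav, raw.inav)

    def test_group_property(self, moving_acq):
        """Correcting by s then by -s returns the original samples."""
        raw, trace = moving_acq
        d_si = trace.d_si[: raw.n_shots]
        d_lr = trace.d_lr[: raw.n_shots]
        fwd = apply_phase_correction(raw, d_si, d_lr)
        back = apply_phase_correction(fwd, -d_si, -d_lr)
        assert np.max(np.abs(back.kspace - raw.kspace)) / np.max(np.abs(raw.kspace)) < 1e-12

    def test_pure_phase(self, moving_acq):
        raw, trace = moving_acq
        out = apply_phase_correction(raw, trace.d_si[: raw.n_shots],
                                     trace.d_lr[: raw.n_shots])
        np.testing.assert_allclose(np.abs(out.kspace), np.abs(raw.kspace), rtol=1e-12)
        np.testing.assert_allclose(np.abs(out.inav), np.abs(raw.inav), rtol=1e-12)

    def test_constant_shift_correction_recovers_static(self, small_cardiac, protocol_seq):
        """4 mm constant trace: corrected fully sampled recon equals the
        static recon to < 1e-3 NRMSE."""
        sched = gb.generate_sampling_schedule((32, 16), 1.0, 16, seed=0)
        maps = gb.simulate_coil_maps(1, small_cardiac.shape)
        static = gb.simulate_acquisition(
            small_cardiac, maps, protocol_seq, sched,
            gb.MotionTrace(np.zeros(sched.n_shots), np.zeros(sched.n_shots)),
        )
        moving = gb.simulate_acquisition(
            small_cardiac, maps, protocol_seq, sched,
            gb.MotionTrace(np.full(sched.n_shots, 4.0), np.zeros(sched.n_shots)),
        )
        corr = apply_phase_correction(moving, np.full(sched.n_shots, 4.0),
                                      np.zeros(sched.n_shots))
        a = ifftc(grid_kspace(corr, "IR", 0)[0][0])
        b = ifftc(grid_kspace(static, "IR", 0)[0][0])
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 1e-3

    def test_missing_estimates_rejected(self, moving_acq):
        raw, _ = moving_acq
        with pytest.raises(ValueError, match="cover"):
            apply_phase_correction(raw, np.zeros(2), np.zeros(2))
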
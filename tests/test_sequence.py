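import numpy as np
import pytest

import greyblood as gb
from greyblood._fft import fftc, ifftc
from greyblood.phantom import VIAL_T1S_MS
from greyblood.sense import grid_kspace


# ---------------------------------------------------------------------------
# Independent brute-force oracle: RK4 time stepping at dt = 0.01 ms.
# Each free-relaxation interval is quantized to the step grid and advanced
# with the RK4 one-step map of dMz/dt = (1 - Mz)/T1 (fixed point exactly 1,
# so n steps give Mz -> 1 + beta**n (Mz - 1) with the RK4 amplification
# factor beta — identical to literal stepping, evaluated in closed form).
# ---------------------------------------------------------------------------

DT = 0.01


def _rk4_beta(t1: float) -> float:
    h = DT / t1
    return 1.0 - h + h**2 / 2 - h**3 / 6 + h**4 / 24


def _relax_steps(mz: float, duration_ms: float, t1: float) -> float:
    n = int(round(duration_ms / DT))
    return 1.0 + _rk4_beta(t1) ** n * (mz - 1.0)


def oracle_mz_train(t1, seq, n_beats=60):
    """Brute-force steady-state Mz train (IR and REF beats)."""
    cos_ir = np.cos(np.deg2rad(seq.fa_ir))
    cos_ref = np.cos(np.deg2rad(seq.fa_ref))
    cos_nav = np.cos(np.deg2rad(seq.fa_inav))
    use_nav = seq.fa_inav > 0
    gap = seq.ti - (seq.n_inav_echoes * seq.tr if use_nav else 0.0)
    tail = seq.rr - seq.ti - seq.n_segments * seq.tr
    mz = 1.0
    prev = None
    for _ in range(max(1, n_beats // 2)):
        ir = np.empty(seq.n_segments)
        ref = np.empty(seq.n_segments)
        mz = -seq.inv_efficiency * mz
        mz = _relax_steps(mz, gap, t1)
        if use_nav:
            for _k in range(seq.n_inav_echoes):
                mz = _relax_steps(mz * cos_nav, seq.tr, t1)
        for s in range(seq.n_segments):
            ir[s] = mz
            mz = _relax_steps(mz * cos_ir, seq.tr, t1)
        mz = _relax_steps(mz, tail, t1)
        mz = _relax_steps(mz, gap, t1)
        if use_nav:
            for _k in range(seq.n_inav_echoes):
                mz = _relax_steps(mz * cos_nav, seq.tr, t1)
        for s in range(seq.n_segments):
            ref[s] = mz
            mz = _relax_steps(mz * cos_ref, seq.tr, t1)
        mz = _relax_steps(mz, tail, t1)
        if prev is not None and np.max(np.abs(ir - prev)) < 1e-10:
            break
        prev = ir
    return ir, ref


class TestSequenceParams:
    def test_defaults_match_protocol(self):
        seq = gb.SequenceParams()
        assert (seq.tr, seq.te1, seq.te2) == (6.41, 2.38, 4.76)
        assert (seq.fa_ir, seq.fa_ref, seq.fa_inav) == (25.0, 5.0, 3.0)
        assert seq.n_segments == 16 and seq.n_inav_echoes == 14

    def test_fat_offresonance_out_of_phase_at_te1(self):
        seq = gb.SequenceParams()
        assert seq.fat_offres_hz == pytest.approx(-210.084, abs=0.01)
        assert seq.fat_phase(0) == pytest.approx(-1.0)
        assert seq.fat_phase(1) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(te1=5.0, te2=4.76),           # te1 > te2
            dict(tr=4.0),                      # te2 > tr
            dict(ti=950.0),                    # readout spills past RR
            dict(fa_ir=120.0),                 # flip angle out of range
            dict(inv_efficiency=0.0),
            dict(ti=50.0),                     # iNAV train does not fit
        ],
    )
    def test_invalid_timing_rejected(self, kwargs):
        with pytest.raises(ValueError):
            gb.SequenceParams(**kwargs)


class TestMzTrain:
    def test_no_recovery_no_excitation_stays_inverted(self):
        """T1 -> infinity with no pulses: Mz = -1 for the whole cycle."""
        seq = gb.SequenceParams(fa_ir=0, fa_ref=0, fa_inav=0, ti=300, rr=1000)
        tissue = gb.TissueParams(t1=1e9, t2s=30.0)
        train = gb.simulate_mz_train(tissue, seq, n_beats=2)
        # residual T1 recovery over the 2 s cycle is ~2e-6 at T1 = 1e9 ms
        np.testing.assert_allclose(train.mz_ir, -1.0, atol=1e-5)
        np.testing.assert_allclose(train.mz_ref, -1.0, atol=1e-5)

    def test_ideal_inversion_null_at_t1_ln2(self):
        """Full recovery, no readout perturbation: Mz(T1 ln 2) = 0."""
        t1 = 384.0
        seq = gb.SequenceParams(
            fa_ir=0, fa_ref=0, fa_inav=0, ti=t1 * np.log(2), rr=8000
        )
        train = gb.simulate_mz_train(gb.TissueParams(t1=t1, t2s=30.0), seq)
        assert abs(train.mz_ir[0]) < 1e-3

    def test_recursion_matches_brute_force_integrator(self):
        """Protocol timing, T1 = 384 ms: recursion vs 0.01 ms RK4 stepping."""
        seq = gb.SequenceParams(ti=300.0)
        t1 = 384.0
        train = gb.simulate_mz_train(gb.TissueParams(t1=t1, t2s=30.0), seq)
        ir, ref = oracle_mz_train(t1, seq)
        np.testing.assert_allclose(train.mz_ir, ir, atol=1e-6)
        np.testing.assert_allclose(train.mz_ref, ref, atol=1e-6)

    @pytest.mark.parametrize("t1", VIAL_T1S_MS)
    def test_steady_state_within_30_cycles(self, t1):
        seq = gb.SequenceParams(ti=300.0, rr=1000.0)
        train = gb.simulate_mz_train(gb.TissueParams(t1=t1, t2s=30.0), seq, n_beats=60)
        assert train.converged and train.n_cycles <= 30


class TestFindNullTi:
    @pytest.mark.parametrize("t1", [100.0, 384.0, 587.0])
    def test_ideal_limit_closed_form(self, t1):
        """Ideal IR limit: null TI = T1 ln 2 within 0.5 ms."""
        seq = gb.SequenceParams(fa_ir=0, fa_ref=0, fa_inav=0, rr=max(8000, 20 * t1), ti=300)
        ti = gb.find_null_ti(t1, seq, search=(20.0, 5 * t1, 0.05))
        assert ti == pytest.approx(t1 * np.log(2), abs=0.5)

    def test_agrees_with_oracle_zero_crossing(self):
        """Full protocol, T1 = 587 ms: bisection matches the brute-force
        integrator's zero crossing to < 1 ms."""
        seq = gb.SequenceParams(ti=300.0)
        t1 = 587.0
        ti = gb.find_null_ti(t1, seq, search=(150.0, 700.0, 0.1))

        def oracle_mz0(ti_val):
            from dataclasses import replace
            return oracle_mz_train(t1, replace(seq, ti=ti_val))[0][0]

        lo, hi = 150.0, 700.0
        flo = oracle_mz0(lo)
        for _ in range(24):
            mid = 0.5 * (lo + hi)
            fm = oracle_mz0(mid)
            if np.sign(fm) == np.sign(flo):
                lo, flo = mid, fm
            else:
                hi = mid
        assert abs(ti - 0.5 * (lo + hi)) < 1.0

    def test_no_null_in_bracket_rejected(self):
        seq = gb.SequenceParams(fa_ir=0, fa_ref=0, fa_inav=0, rr=8000, ti=300)
        with pytest.raises(ValueError, match="no null"):
            gb.find_null_ti(100.0, seq, search=(200.0, 400.0, 0.1))


class TestSimulateAcquisition:
    def test_forward_model_identity(self, small_cardiac, protocol_seq, static_raw):
        """Fully sampled static single-coil REF echo 2 inverts to the
        analytic signal-weighted phantom image."""
        maps = gb.simulate_coil_maps(1, small_cardiac.shape)
        y, mask, _ = grid_kspace(static_raw, "REF", 1)
        assert mask.all()
        img = ifftc(y[0])
        ref = gb.analytic_coil_image(small_cardiac, maps, protocol_seq, "REF", 1)[0]
        assert np.linalg.norm(img - ref) / np.linalg.norm(ref) < 1e-6

    def test_fourier_shift_theorem(self, small_cardiac, protocol_seq):
        """Constant 4 mm SI motion = circular 2-voxel shift of the image."""
        sched = gb.generate_sampling_schedule((32, 16), 1.0, 16, seed=0)
        maps = gb.simulate_coil_maps(1, small_cardiac.shape)
        trace = gb.MotionTrace(np.full(sched.n_shots, 4.0), np.zeros(sched.n_shots))
        raw = gb.simulate_acquisition(
            small_cardiac, maps, protocol_seq, sched, trace, segment_weighting=False
        )
        img = ifftc(grid_kspace(raw, "REF", 1)[0][0])
        ref = gb.analytic_coil_image(small_cardiac, maps, protocol_seq, "REF", 1)[0]
        shifted = np.roll(ref, 2, axis=1)
        assert np.linalg.norm(img - shifted) / np.linalg.norm(shifted) < 1e-12

    def test_noise_propagation(self):
        """Empty phantom: image-domain noise std equals k-space noise std
        through the unitary transform (per real/imaginary component)."""
        ph = gb.DigitalPhantom(np.zeros((32, 32, 16), dtype=int), {})
        sched = gb.generate_sampling_schedule((32, 16), 1.0, 16, seed=0)
        maps = gb.simulate_coil_maps(1, ph.shape)
        trace = gb.MotionTrace(np.zeros(sched.n_shots), np.zeros(sched.n_shots))
        sigma = 0.7
        raw = gb.simulate_acquisition(ph, maps, gb.SequenceParams(ti=300.0), sched,
                                      trace, noise_sigma=sigma, seed=99)
        img = ifftc(grid_kspace(raw, "IR", 0)[0][0])
        assert img.size >= 1e4
        assert np.std(img.real) == pytest.approx(sigma, rel=0.05)
        assert np.std(img.imag) == pytest.approx(sigma, rel=0.05)

    def test_energy_conservation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((16, 16, 8)) + 1j * rng.standard_normal((16, 16, 8))
        assert np.linalg.norm(fftc(x)) == pytest.approx(np.linalg.norm(x), rel=1e-12)
        np.testing.assert_allclose(ifftc(fftc(x)), x, atol=1e-12)

    def test_signal_linear_in_proton_density(self, protocol_seq):
        spec1 = gb.cardiac_spec(shape=(16, 16, 8), blood_radius_mm=6,
                                wall_thickness_mm=4, fat_thickness_mm=0,
                                scar_angle_deg=0)
        spec2 = gb.cardiac_spec(shape=(16, 16, 8), blood_radius_mm=6,
                                wall_thickness_mm=4, fat_thickness_mm=0,
                                scar_angle_deg=0,
                                tissue_overrides={"myocardium": {"pd": 1.7},
                                                  "blood": {"pd": 2.0}})
        ph1 = gb.make_phantom(spec1)
        ph2 = gb.make_phantom(spec2)
        maps = gb.simulate_coil_maps(1, ph1.shape)
        sched = gb.generate_sampling_schedule((16, 8), 1.0, 8, seed=0)
        trace = gb.MotionTrace(np.zeros(sched.n_shots), np.zeros(sched.n_shots))
        seq = protocol_seq
        r1 = gb.simulate_acquisition(ph1, maps, seq, sched, trace)
        r2 = gb.simulate_acquisition(ph2, maps, seq, sched, trace)
        i1 = ifftc(grid_kspace(r1, "REF", 1)[0][0])
        i2 = ifftc(grid_kspace(r2, "REF", 1)[0][0])
        blood = ph1.labels == ph1.label_of("blood")
        np.testing.assert_allclose(i2[blood], 2.0 * i1[blood], rtol=1e-6)

    def test_short_motion_trace_rejected(self, small_cardiac, protocol_seq):
        sched = gb.generate_sampling_schedule((32, 16), 3.0, 16, seed=0)
        maps = gb.simulate_coil_maps(1, small_cardiac.shape)
        trace = gb.MotionTrace(np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError, match="shorter"):
            gb.simulate_acquisition(small_cardiac, maps, protocol_seq, sched, trace)
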
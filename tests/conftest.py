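import numpy as np
import pytest

import greyblood as gb


@pytest.fixture(scope="session")
def small_cardiac():
    """32x32x16 cardiac phantom used by most recon-level tests."""
    return gb.make_phantom(
        gb.cardiac_spec(
            shape=(32, 32, 16),
            blood_radius_mm=10.0,
            wall_thickness_mm=8.0,
            scar_angle_deg=70.0,
            fat_thickness_mm=4.0,
        )
    )


@pytest.fixture(scope="session")
def protocol_seq():
    """Protocol sequence timing with a mid-range inversion time."""
    return gb.SequenceParams(ti=300.0)


@pytest.fixture(scope="session")
def static_raw(small_cardiac, protocol_seq):
    """Fully sampled, static, noiseless single-coil acquisition."""
    sched = gb.generate_sampling_schedule((32, 16), 1.0, 16, seed=0)
    maps = gb.simulate_coil_maps(1, small_cardiac.shape)
    trace = gb.MotionTrace(np.zeros(sched.n_shots), np.zeros(sched.n_shots))
    raw = gb.simulate_acquisition(
        small_cardiac, maps, protocol_seq, sched, trace, segment_weighting=False
    )
    return raw


@pytest.fixture(scope="session")
def multicoil_setup(small_cardiac, protocol_seq):
    """Undersampled 8-coil static noiseless acquisition + true maps."""
    sched = gb.generate_sampling_schedule((32, 16), 3.0, 16, seed=0)
    maps = gb.simulate_coil_maps(8, small_cardiac.shape, seed=2)
    trace = gb.MotionTrace(np.zeros(sched.n_shots), np.zeros(sched.n_shots))
    raw = gb.simulate_acquisition(small_cardiac, maps, protocol_seq, sched, trace)
    return {"raw": raw, "maps": maps, "schedule": sched, "phantom": small_cardiac}
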
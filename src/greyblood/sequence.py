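"""Bloch-recursion signal model and k-space acquisition simulator.

Models the two-heartbeat interleaved acquisition: one ECG-triggered
IR-prepared spoiled-GRE beat (flip angle ``fa_ir``) interleaved with one
non-prepared reference beat (``fa_ref``), both with a dual-echo (two-point
Dixon) bipolar readout, ``n_segments`` phase encodes per beat, and a
low-flip-angle 2D coronal image navigator (iNAV) played immediately before
each readout train. Perfect spoiling is assumed (longitudinal recursion
only); fat is a single spectral peak at ``fat_offres_hz``.

Timing within a heartbeat of length ``rr``::

    [inversion (IR beat only)] -- recovery -- iNAV train -- readout train -- recovery
    t=0                                        ends at TI   TI..TI+n_seg*TR

so TI is the inversion-to-k-space-centre delay under centric ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._fft import centered_indices, fftc, ifftc
from .phantom import CoilMaps, DigitalPhantom, MotionTrace, TissueParams
from .trajectory import SamplingSchedule

__all__ = [
    "SequenceParams",
    "MzTrain",
    "RawAcquisition",
    "simulate_mz_train",
    "find_null_ti",
    "simulate_acquisition",
    "analytic_coil_image",
    "sigma_for_snr",
]


@dataclass(frozen=True)
class SequenceParams:
    """Timing and flip angles of the interleaved IR/reference Dixon protocol.

    Defaults reproduce the acquisition protocol: TR/TE1/TE2 = 6.41/2.38/4.76
    ms, 25/5 degrees for the IR-prepared and reference volumes, 14 iNAV
    echoes at 3 degrees, 16 segments per heartbeat at 60 bpm. The fat
    off-resonance defaults to -1/(2*TE1), which makes echo 1 out-of-phase
    and echo 2 in-phase.
    """

    tr: float = 6.41
    te1: float = 2.38
    te2: float = 4.76
    fa_ir: float = 25.0
    fa_ref: float = 5.0
    fa_inav: float = 3.0
    n_segments: int = 16
    n_inav_echoes: int = 14
    ti: float = 300.0
    rr: float = 1000.0
    inv_efficiency: float = 1.0
    fat_offres_hz: float | None = None

    def __post_init__(self):
        if not (0 < self.te1 < self.te2 < self.tr):
            raise ValueError("need 0 < te1 < te2 < tr")
        if not self.ti + self.n_segments * self.tr < self.rr:
            raise ValueError("ti + n_segments*tr must be < rr")
        for fa in (self.fa_ir, self.fa_ref, self.fa_inav):
            if not 0.0 <= fa <= 90.0:
                raise ValueError("flip angles must be in [0, 90] degrees")
        if not 0 < self.inv_efficiency <= 1:
            raise ValueError("inv_efficiency must be in (0, 1]")
        if self.fa_inav > 0 and self.ti < self.n_inav_echoes * self.tr:
            raise ValueError("ti too short to fit the iNAV train before the readout")
        if self.fat_offres_hz is None:
            object.__setattr__(self, "fat_offres_hz", -1.0 / (2 * self.te1 * 1e-3))

    @property
    def readout_window_ms(self) -> float:
        """Duration of the imaging readout train per heartbeat."""
        return self.n_segments * self.tr

    def te(self, echo: int) -> float:
        return (self.te1, self.te2)[echo]

    def fat_phase(self, echo: int) -> complex:
        """Phase factor of the fat peak at the given echo."""
        return np.exp(2j * np.pi * self.fat_offres_hz * self.te(echo) * 1e-3)


@dataclass
class MzTrain:
    """Steady-state longitudinal magnetization train (units of M0)."""

    mz_ir: np.ndarray  # before each IR-beat imaging pulse, (n_segments,)
    mz_ref: np.ndarray
    mz_inav_ir: np.ndarray  # before each iNAV pulse, (n_inav_echoes,)
    mz_inav_ref: np.ndarray
    n_cycles: int
    converged: bool
    history: list = field(default_factory=list, repr=False)


def _relax(mz: float, t: float, t1: float) -> float:
    if t <= 0:
        return mz
    e = np.exp(-t / t1)
    return 1.0 + (mz - 1.0) * e


def simulate_mz_train(
    tissue: TissueParams, seq: SequenceParams, n_beats: int = 60
) -> MzTrain:
    """Run the two-beat recursion until periodic steady state.

    Starts from thermal equilibrium (Mz = M0) and iterates the IR/REF cycle
    until the IR-beat train changes by less than 1e-9 cycle-to-cycle, or
    ``n_beats`` heartbeats have elapsed. Returns the last cycle's trains.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    t1 = tissue.t1
    cos_ir = np.cos(np.deg2rad(seq.fa_ir))
    cos_ref = np.cos(np.deg2rad(seq.fa_ref))
    cos_nav = np.cos(np.deg2rad(seq.fa_inav))
    use_nav = seq.fa_inav > 0
    gap = seq.ti - (seq.n_inav_echoes * seq.tr if use_nav else 0.0)
    tail = seq.rr - seq.ti - seq.n_segments * seq.tr

    mz = 1.0
    n_cycles = max(1, int(np.ceil(n_beats / 2)))
    prev = None
    history = []
    converged = False
    for cyc in range(n_cycles):
        ir = np.empty(seq.n_segments)
        ref = np.empty(seq.n_segments)
        nav_ir = np.zeros(seq.n_inav_echoes)
        nav_ref = np.zeros(seq.n_inav_echoes)
        # --- IR-prepared beat ---
        mz = -seq.inv_efficiency * mz
        mz = _relax(mz, gap, t1)
        if use_nav:
            for k in range(seq.n_inav_echoes):
                nav_ir[k] = mz
                mz = _relax(mz * cos_nav, seq.tr, t1)
        for s in range(seq.n_segments):
            ir[s] = mz
            mz = _relax(mz * cos_ir, seq.tr, t1)
        mz = _relax(mz, tail, t1)
        # --- reference beat ---
        mz = _relax(mz, gap, t1)
        if use_nav:
            for k in range(seq.n_inav_echoes):
                nav_ref[k] = mz
                mz = _relax(mz * cos_nav, seq.tr, t1)
        for s in range(seq.n_segments):
            ref[s] = mz
            mz = _relax(mz * cos_ref, seq.tr, t1)
        mz = _relax(mz, tail, t1)

        history.append((ir.copy(), ref.copy()))
        if prev is not None and np.max(np.abs(ir - prev)) < 1e-9:
            converged = True
            prev = ir
            break
        prev = ir
    return MzTrain(
        mz_ir=history[-1][0],
        mz_ref=history[-1][1],
        mz_inav_ir=nav_ir,
        mz_inav_ref=nav_ref,
        n_cycles=len(history),
        converged=converged,
        history=history,
    )


def find_null_ti(
    t1: float, seq: SequenceParams, search: tuple[float, float, float] = (100.0, 700.0, 0.1)
) -> float:
    """Inversion time nulling the k-space-centre signal of the IR beat.

    Bisects the steady-state Mz of the first (centric) imaging segment of
    the IR beat as a function of TI. In the ideal-IR limit (no readout
    perturbation, full recovery) this converges to T1*ln(2).
    """
    ti_min, ti_max, tol = search
    tissue = TissueParams(t1=t1, t2s=30.0, pd=1.0)

    def f(ti: float) -> float:
        s = replace(seq, ti=ti)
        return simulate_mz_train(tissue, s, n_beats=400).mz_ir[0]

    fa, fb = f(ti_min), f(ti_max)
    if fa == 0.0:
        return ti_min
    if fb == 0.0:
        return ti_max
    if np.sign(fa) == np.sign(fb):
        raise ValueError("no null in range")
    a, b = ti_min, ti_max
    while (b - a) > tol:
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0.0:
            return m
        if np.sign(fm) == np.sign(fa):
            a, fa = m, fm
        else:
            b = m
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


@dataclass
class RawAcquisition:
    """Multi-coil dual-echo k-space of one interleaved acquisition.

    ``kspace`` has shape (shot, echo, coil, segment, readout); sample
    (i, e, c, s, :) is the full readout line at the (ky, kz) location of
    segment ``s`` of ``schedule.shots[i]``. ``inav`` holds the per-shot 2D
    navigator lines, shape (shot, echo, inav_line, readout), sampled on the
    ``inav_lines`` central ky rows of the coronal projection.
    """

    kspace: np.ndarray
    inav: np.ndarray
    inav_lines: np.ndarray
    schedule: SamplingSchedule
    seq: SequenceParams
    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    noise_sigma: float = 0.0
    ground_truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.kspace.shape[0] != self.schedule.n_shots:
            raise ValueError("kspace shot count must equal schedule shot count")
        if self.inav.shape[0] != self.schedule.n_shots:
            raise ValueError("an iNAV must be present for every shot")

    @property
    def n_shots(self) -> int:
        return self.kspace.shape[0]

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[2]

    def copy(self) -> "RawAcquisition":
        return RawAcquisition(
            kspace=self.kspace.copy(),
            inav=self.inav.copy(),
            inav_lines=self.inav_lines.copy(),
            schedule=self.schedule,
            seq=self.seq,
            grid_shape=self.grid_shape,
            voxel_size=self.voxel_size,
            noise_sigma=self.noise_sigma,
            ground_truth=self.ground_truth,
        )


def _tissue_weights(
    tissue: TissueParams, seq: SequenceParams, mz: np.ndarray, fa_deg: float, echo: int
) -> np.ndarray:
    """Complex transverse signal per segment for one tissue and echo."""
    decay = np.exp(-seq.te(echo) / tissue.t2s)
    comp = (1.0 - tissue.fat_fraction) + tissue.fat_fraction * seq.fat_phase(echo)
    return tissue.pd * mz * np.sin(np.deg2rad(fa_deg)) * decay * comp


def analytic_coil_image(
    phantom: DigitalPhantom,
    maps: CoilMaps,
    seq: SequenceParams,
    tag: str,
    echo: int,
    segment: int = 0,
    trains: dict | None = None,
) -> np.ndarray:
    """Noise-free coil images (coil, x, y, z) at one segment's contrast.

    This is the imaging target of the reconstruction: the coil-weighted,
    signal-weighted phantom at the k-space-centre (default) segment.
    """
    nx, ny, nz = phantom.shape
    out = np.zeros((maps.n_coils, nx, ny, nz), dtype=complex)
    for lab, tp in phantom.tissue_table.items():
        train = (trains or {}).get(lab) or simulate_mz_train(tp, seq)
        mz = train.mz_ir if tag == "IR" else train.mz_ref
        fa = seq.fa_ir if tag == "IR" else seq.fa_ref
        w = _tissue_weights(tp, seq, mz[segment : segment + 1], fa, echo)[0]
        m = phantom.labels == lab
        out[:, m] += w * maps.sens[:, m]
    return out


def simulate_acquisition(
    phantom: DigitalPhantom,
    maps: CoilMaps,
    seq: SequenceParams,
    schedule: SamplingSchedule,
    motion: MotionTrace,
    noise_sigma: float = 0.0,
    seed: int = 0,
    bipolar_phase: float = 0.0,
    segment_weighting: bool = True,
) -> RawAcquisition:
    """Simulate the full interleaved dual-echo acquisition.

    Per shot: the steady-state Mz train of the shot's beat type weights each
    segment's contribution; respiratory translation (d_si along y, d_lr
    along x, in mm) is applied as the exact k-space phase ramp of a rigid
    in-plane translation of the coil-weighted object; the scheduled (ky, kz)
    lines are sampled with the readout axis fully sampled; the coronal iNAV
    (projection along z, uniform sensitivity) is sampled on the central
    ``n_inav_echoes`` ky lines at both echoes; complex Gaussian noise of
    standard deviation ``noise_sigma`` per real/imaginary component is added
    to every sample.

    ``bipolar_phase`` (cycles across the FOV) adds an echo-2 linear phase
    along the readout, emulating bipolar-readout phase errors.
    ``segment_weighting=False`` freezes every segment at the k-space-centre
    (segment 0) contrast, which makes the fully sampled forward model an
    exact Fourier transform of :func:`analytic_coil_image` — useful for
    validation.
    """
    nx, ny, nz = phantom.shape
    if maps.sens.shape[1:] != phantom.shape:
        raise ValueError("coil maps and phantom shapes differ")
    if schedule.matrix != (ny, nz):
        raise ValueError("schedule matrix must equal (ny, nz) of the phantom")
    if motion.n_shots < schedule.n_shots:
        raise ValueError("motion trace shorter than schedule")
    seg_lens = {len(s.locations) for s in schedule.shots}
    if len(seg_lens) != 1:
        raise ValueError("all shots must have equal segment count for simulation")
    n_seg = seg_lens.pop()

    labs = sorted(phantom.tissue_table)
    trains = {lab: simulate_mz_train(phantom.tissue_table[lab], seq) for lab in labs}

    # static coil-weighted k-space per (coil, tissue), one per echo if a
    # bipolar echo-2 phase is requested
    K1 = np.empty((maps.n_coils, len(labs), nx, ny, nz), dtype=complex)
    for j, lab in enumerate(labs):
        timg = (phantom.labels == lab).astype(float)
        for c in range(maps.n_coils):
            K1[c, j] = fftc(maps.sens[c] * timg)
    if bipolar_phase != 0.0:
        xn = (np.arange(nx) - nx / 2) / nx
        bip = np.exp(2j * np.pi * bipolar_phase * xn)[:, None, None]
        K2 = np.empty_like(K1)
        for j, lab in enumerate(labs):
            timg = (phantom.labels == lab).astype(float)
            for c in range(maps.n_coils):
                K2[c, j] = fftc(maps.sens[c] * timg * bip)
    else:
        K2 = K1

    # coronal projection (along z) per tissue for the iNAV, unit sensitivity
    n_nav = seq.n_inav_echoes
    inav_lines = ny // 2 - n_nav // 2 + np.arange(n_nav)
    Pk = np.empty((len(labs), nx, ny), dtype=complex)
    for j, lab in enumerate(labs):
        Pk[j] = fftc((phantom.labels == lab).sum(axis=2).astype(float))

    kx = centered_indices(nx)
    ky_c = centered_indices(ny)

    rng = np.random.default_rng(seed)
    n_shots = schedule.n_shots
    kspace = np.empty((n_shots, 2, maps.n_coils, n_seg, nx), dtype=complex)
    inav = np.empty((n_shots, 2, n_nav, nx), dtype=complex)

    if n_seg > seq.n_segments:
        raise ValueError("schedule segments_per_beat exceeds seq.n_segments")
    # per-tissue per-segment weights, both beat types and echoes
    W = np.empty((2, 2, len(labs), n_seg), dtype=complex)  # (tagidx, echo, lab, seg)
    Wnav = np.empty((2, 2, len(labs), n_nav), dtype=complex)
    sin_nav = np.sin(np.deg2rad(seq.fa_inav))
    for j, lab in enumerate(labs):
        tp = phantom.tissue_table[lab]
        tr_ = trains[lab]
        for ti_tag, (mz, fa, mznav) in enumerate(
            [(tr_.mz_ir, seq.fa_ir, tr_.mz_inav_ir), (tr_.mz_ref, seq.fa_ref, tr_.mz_inav_ref)]
        ):
            for e in (0, 1):
                w = _tissue_weights(tp, seq, mz, fa, e)
                if not segment_weighting:
                    w = np.full_like(w, w[0])
                W[ti_tag, e, j] = w[:n_seg]
                decay = np.exp(-seq.te(e) / tp.t2s)
                comp = (1.0 - tp.fat_fraction) + tp.fat_fraction * seq.fat_phase(e)
                Wnav[ti_tag, e, j] = tp.pd * mznav * sin_nav * decay * comp

    for i, shot in enumerate(schedule.shots):
        tag_i = 0 if shot.tag == "IR" else 1
        sy = motion.d_si[i] / phantom.voxel_size[1]
        sx = motion.d_lr[i] / phantom.voxel_size[0]
        ramp_x = np.exp(-2j * np.pi * kx * sx / nx)  # (nx,)
        loc = shot.locations
        ramp_y = np.exp(-2j * np.pi * ky_c[loc[:, 0]] * sy / ny)  # (n_seg,)
        for e, K in ((0, K1), (1, K2)):
            # gather (coil, lab, x, seg) at the scheduled locations
            G = K[:, :, :, loc[:, 0], loc[:, 1]]
            sig = np.einsum("clxs,ls->csx", G, W[tag_i, e])
            kspace[i, e] = sig * ramp_y[None, :, None] * ramp_x[None, None, :]
        # iNAV
        ramp_ynav = np.exp(-2j * np.pi * ky_c[inav_lines] * sy / ny)
        for e in (0, 1):
            Gn = Pk[:, :, inav_lines]  # (lab, x, line)
            sn = np.einsum("lxk,lk->kx", Gn, Wnav[tag_i, e])
            inav[i, e] = sn * ramp_ynav[:, None] * ramp_x[None, :]

    if noise_sigma > 0:
        kspace += noise_sigma * (
            rng.standard_normal(kspace.shape) + 1j * rng.standard_normal(kspace.shape)
        )
        inav += noise_sigma * (
            rng.standard_normal(inav.shape) + 1j * rng.standard_normal(inav.shape)
        )

    return RawAcquisition(
        kspace=kspace,
        inav=inav,
        inav_lines=inav_lines,
        schedule=schedule,
        seq=seq,
        grid_shape=(nx, ny, nz),
        voxel_size=phantom.voxel_size,
        noise_sigma=noise_sigma,
        ground_truth={"phantom": phantom, "motion": motion, "maps": maps, "trains": trains},
    )


def sigma_for_snr(
    phantom: DigitalPhantom, maps: CoilMaps, seq: SequenceParams, snr: float
) -> float:
    """Noise std giving a target image-domain SNR on the REF echo-2 image.

    SNR is defined as the 99th-percentile root-sum-of-squares magnitude of
    the static reference image divided by the per-component image noise std
    (equal to the k-space std under the unitary transform, fully sampled).
    """
    img = analytic_coil_image(phantom, maps, seq, "REF", echo=1)
    peak = np.percentile(np.sqrt((np.abs(img) ** 2).sum(axis=0)), 99)
    return float(peak / snr)
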
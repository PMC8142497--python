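"""Digital phantoms, coil sensitivity maps and respiratory motion traces.

Every downstream stage of the pipeline (trajectory, Bloch acquisition
simulation, motion correction, SENSE, Dixon, PSIR) is validated against the
ground truth objects built here.

Axis convention (fixed for the whole package): ``(x, y, z)`` =
(readout, PE1, PE2); the coronal image-navigator plane is ``(y = SI,
x = LR)``, so respiratory superior-inferior motion displaces along axis 1
and left-right motion along axis 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueParams",
    "DigitalPhantom",
    "CoilMaps",
    "MotionTrace",
    "VIAL_T1S_MS",
    "make_phantom",
    "vial_spec",
    "cardiac_spec",
    "simulate_coil_maps",
    "simulate_motion_trace",
]

#: T1 relaxation times (ms) of the seven gadolinium-doped vials of the
#: reference T1 phantom, from 0 to 1 mMol Gd. The 0.3/0.5/0.7 mMol vials
#: (587/384/279 ms) approximate post-contrast myocardium, blood and scar.
VIAL_T1S_MS = (2883.0, 1259.0, 587.0, 384.0, 279.0, 217.0, 198.0)


@dataclass(frozen=True)
class TissueParams:
    """Relaxation and composition parameters of one tissue compartment.

    Parameters
    ----------
    t1 : float
        Longitudinal relaxation time in ms; must be positive.
    t2s : float
        Effective transverse decay time (T2*) in ms at the echo times used.
    pd : float
        Proton density in arbitrary units, >= 0.
    fat_fraction : float
        Fraction of the proton density that resonates at the (single-peak)
        fat frequency, in [0, 1].
    name : str
        Human-readable compartment label.
    """

    t1: float
    t2s: float
    pd: float = 1.0
    fat_fraction: float = 0.0
    name: str = ""

    def __post_init__(self):
        if not self.t1 > 0:
            raise ValueError(f"t1 must be > 0, got {self.t1}")
        if not self.t2s > 0:
            raise ValueError(f"t2s must be > 0, got {self.t2s}")
        if self.pd < 0:
            raise ValueError(f"pd must be >= 0, got {self.pd}")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError(f"fat_fraction must be in [0,1], got {self.fat_fraction}")


@dataclass
class DigitalPhantom:
    """3D labelled tissue grid plus per-label tissue parameters.

    ``labels`` is an integer grid of shape ``(nx, ny, nz)`` with 0 =
    background; every nonzero label must have an entry in ``tissue_table``.
    """

    labels: np.ndarray
    tissue_table: dict[int, TissueParams]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if min(self.labels.shape) < 8:
            raise ValueError("grid dimensions must be >= 8 per axis")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.tissue_table)
        if missing:
            raise ValueError(f"labels without tissue_table entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def property_map(self, attr: str) -> np.ndarray:
        """Real-valued 3D map of one tissue attribute (0 in background)."""
        out = np.zeros(self.labels.shape, dtype=float)
        for lab, tp in self.tissue_table.items():
            out[self.labels == lab] = getattr(tp, attr)
        return out

    def mask(self, label: int | None = None) -> np.ndarray:
        if label is None:
            return self.labels != 0
        return self.labels == label

    def label_of(self, name: str) -> int:
        for lab, tp in self.tissue_table.items():
            if tp.name == name:
                return lab
        raise KeyError(name)


@dataclass
class CoilMaps:
    """Complex receive sensitivity maps, shape (coil, nx, ny, nz)."""

    sens: np.ndarray

    def __post_init__(self):
        self.sens = np.asarray(self.sens, dtype=complex)
        if self.sens.ndim != 4:
            raise ValueError("sens must be 4D (coil, x, y, z)")

    @property
    def n_coils(self) -> int:
        return self.sens.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.sens) ** 2, axis=0))


@dataclass
class MotionTrace:
    """Per-shot translational respiratory displacement in mm.

    ``d_si`` is superior-inferior (axis y), ``d_lr`` left-right (axis x);
    ``d_si == 0`` is end-expiration.
    """

    d_si: np.ndarray
    d_lr: np.ndarray

    def __post_init__(self):
        self.d_si = np.atleast_1d(np.asarray(self.d_si, dtype=float))
        self.d_lr = np.atleast_1d(np.asarray(self.d_lr, dtype=float))
        if self.d_si.shape != self.d_lr.shape:
            raise ValueError("d_si and d_lr must have equal length")
        if not (np.all(np.isfinite(self.d_si)) and np.all(np.isfinite(self.d_lr))):
            raise ValueError("displacements must be finite")

    @property
    def n_shots(self) -> int:
        return self.d_si.size


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------


def vial_spec(
    shape=(64, 64, 16),
    voxel_size=(2.0, 2.0, 2.0),
    t1s_ms=VIAL_T1S_MS,
    vial_radius_mm: float = 10.0,
    t2s_ms: float = 40.0,
    pd: float = 1.0,
) -> dict:
    """Spec dict for a multi-vial T1 phantom (cylinders on a grid)."""
    return {
        "geometry": "vials",
        "shape": tuple(shape),
        "voxel_size": tuple(voxel_size),
        "t1s_ms": list(t1s_ms),
        "vial_radius_mm": float(vial_radius_mm),
        "t2s_ms": float(t2s_ms),
        "pd": float(pd),
    }


def cardiac_spec(
    shape=(64, 64, 64),
    voxel_size=(2.0, 2.0, 2.0),
    blood_radius_mm: float = 22.0,
    wall_thickness_mm: float = 12.0,
    scar_angle_deg: float = 70.0,
    scar_start_deg: float = -35.0,
    scar_transmurality: float = 1.0,
    fat_thickness_mm: float = 6.0,
    height_fraction: float = 0.7,
    tissue_overrides: dict | None = None,
) -> dict:
    """Spec dict for a cardiac-like phantom.

    A left-ventricle-like short-axis cylinder along z: blood pool inside an
    annular myocardium, an angular scar wedge carved out of the wall
    (transmural when ``scar_transmurality`` = 1, subendocardial when < 1)
    and an epicardial fat rim. Default T1s follow the post-contrast vial
    analogues: myocardium 587 ms, blood 384 ms, scar 279 ms.
    """
    return {
        "geometry": "cardiac",
        "shape": tuple(shape),
        "voxel_size": tuple(voxel_size),
        "blood_radius_mm": float(blood_radius_mm),
        "wall_thickness_mm": float(wall_thickness_mm),
        "scar_angle_deg": float(scar_angle_deg),
        "scar_start_deg": float(scar_start_deg),
        "scar_transmurality": float(scar_transmurality),
        "fat_thickness_mm": float(fat_thickness_mm),
        "height_fraction": float(height_fraction),
        "tissue_overrides": tissue_overrides or {},
    }


#: Default cardiac compartment parameters (post-contrast, 1.5 T).
_CARDIAC_TISSUES = {
    "myocardium": TissueParams(t1=587.0, t2s=30.0, pd=0.85, fat_fraction=0.0, name="myocardium"),
    "blood": TissueParams(t1=384.0, t2s=60.0, pd=1.0, fat_fraction=0.0, name="blood"),
    "scar": TissueParams(t1=279.0, t2s=35.0, pd=0.95, fat_fraction=0.0, name="scar"),
    "fat": TissueParams(t1=260.0, t2s=45.0, pd=1.0, fat_fraction=0.9, name="fat"),
}


def _cylinder_mask(shape, center_xy, radius_vox, z_range) -> np.ndarray:
    nx, ny, nz = shape
    x = np.arange(nx)[:, None] - center_xy[0]
    y = np.arange(ny)[None, :] - center_xy[1]
    disc = (x**2 + y**2) <= radius_vox**2
    mask = np.zeros(shape, dtype=bool)
    mask[:, :, z_range[0] : z_range[1]] = disc[:, :, None]
    return mask


def make_phantom(spec: dict) -> DigitalPhantom:
    """Build a :class:`DigitalPhantom` from a geometry spec dict.

    Deterministic: identical spec always yields an identical grid.
    Overlapping compartments and unknown geometry names are rejected.
    """
    geom = spec.get("geometry")
    if geom == "vials":
        return _make_vials(spec)
    if geom == "cardiac":
        return _make_cardiac(spec)
    raise ValueError(f"unknown phantom geometry: {geom!r}")


def _make_vials(spec: dict) -> DigitalPhantom:
    shape = tuple(spec["shape"])
    vs = tuple(spec["voxel_size"])
    t1s = spec["t1s_ms"]
    n = len(t1s)
    if n < 1:
        raise ValueError("need at least one vial")
    radius_vox = spec["vial_radius_mm"] / vs[0]
    nx, ny, nz = shape
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    # vial centers on a regular grid in the x-y plane, cylinders along z
    cx = (np.arange(ncols) + 0.5) * nx / ncols
    cy = (np.arange(nrows) + 0.5) * ny / nrows
    z0, z1 = int(0.2 * nz), max(int(0.8 * nz), int(0.2 * nz) + 1)
    labels = np.zeros(shape, dtype=np.int32)
    table: dict[int, TissueParams] = {}
    for i, t1 in enumerate(t1s):
        c = (cx[i % ncols], cy[i // ncols])
        m = _cylinder_mask(shape, c, radius_vox, (z0, z1))
        if np.any(labels[m] != 0):
            raise ValueError("overlapping vials: reduce vial_radius_mm")
        labels[m] = i + 1
        table[i + 1] = TissueParams(
            t1=float(t1), t2s=spec["t2s_ms"], pd=spec["pd"], name=f"vial{i + 1}"
        )
    return DigitalPhantom(labels, table, voxel_size=vs)


def _make_cardiac(spec: dict) -> DigitalPhantom:
    shape = tuple(spec["shape"])
    vs = tuple(spec["voxel_size"])
    nx, ny, nz = shape
    r_blood = spec["blood_radius_mm"] / vs[0]
    r_epi = r_blood + spec["wall_thickness_mm"] / vs[0]
    r_fat = r_epi + spec["fat_thickness_mm"] / vs[0]
    if not r_blood < r_epi:
        raise ValueError("wall thickness must be positive (inner radius < outer radius)")
    trans = spec["scar_transmurality"]
    if not 0.0 <= trans <= 1.0:
        raise ValueError("scar_transmurality must be in [0,1]")
    r_scar_out = r_blood + trans * (r_epi - r_blood)

    hfrac = spec["height_fraction"]
    z0 = int(round(nz * (1 - hfrac) / 2))
    z1 = max(int(round(nz * (1 + hfrac) / 2)), z0 + 1)

    cxy = (nx / 2.0, ny / 2.0)
    x = np.arange(nx)[:, None] - cxy[0]
    y = np.arange(ny)[None, :] - cxy[1]
    r = np.sqrt(x**2 + y**2)
    theta = np.degrees(np.arctan2(y, x))

    a0 = spec["scar_start_deg"]
    da = spec["scar_angle_deg"]
    in_wedge = ((theta - a0) % 360.0) < da if da > 0 else np.zeros_like(r, dtype=bool)

    blood2d = r <= r_blood
    wall2d = (r > r_blood) & (r <= r_epi)
    scar2d = wall2d & in_wedge & (r <= r_scar_out)
    myo2d = wall2d & ~scar2d
    fat2d = (r > r_epi) & (r <= r_fat) if r_fat > r_epi else np.zeros_like(r, dtype=bool)

    tissues = dict(_CARDIAC_TISSUES)
    for name, over in spec.get("tissue_overrides", {}).items():
        base = tissues[name]
        tissues[name] = TissueParams(
            t1=over.get("t1", base.t1),
            t2s=over.get("t2s", base.t2s),
            pd=over.get("pd", base.pd),
            fat_fraction=over.get("fat_fraction", base.fat_fraction),
            name=name,
        )

    labels = np.zeros(shape, dtype=np.int32)
    table: dict[int, TissueParams] = {}
    order = [("myocardium", myo2d), ("blood", blood2d), ("scar", scar2d), ("fat", fat2d)]
    next_lab = 1
    for name, m2d in order:
        if not m2d.any():
            continue
        labels[:, :, z0:z1][np.broadcast_to(m2d[:, :, None], (nx, ny, z1 - z0))] = next_lab
        table[next_lab] = tissues[name]
        next_lab += 1
    return DigitalPhantom(labels, table, voxel_size=vs)


# ---------------------------------------------------------------------------
# Coil maps
# ---------------------------------------------------------------------------


def simulate_coil_maps(n_coils: int, grid_shape, seed: int = 0) -> CoilMaps:
    """Smooth synthetic complex coil sensitivities.

    Coil centres sit on a ring around the grid in the x-y plane; each coil
    has a rational-decay magnitude profile and a slowly varying (linear +
    bilinear) phase with seeded coefficients. ``n_coils = 1`` returns the
    uniform unit map. Root-sum-of-squares is strictly positive everywhere.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nx, ny, nz = grid_shape
    if n_coils == 1:
        return CoilMaps(np.ones((1, nx, ny, nz), dtype=complex))
    rng = np.random.default_rng(seed)
    x = (np.arange(nx) - nx / 2)[:, None, None]
    y = (np.arange(ny) - ny / 2)[None, :, None]
    z = (np.arange(nz) - nz / 2)[None, None, :]
    ring_r = 0.65 * max(nx, ny)
    r0 = 0.6 * max(nx, ny, nz)
    sens = np.empty((n_coils, nx, ny, nz), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cxc, cyc = ring_r * np.cos(ang), ring_r * np.sin(ang)
        # alternate coils between two rings offset along z (chest/spine-like
        # arrangement) so the array encodes both phase-encode directions
        czc = 0.35 * nz * (1 if c % 2 else -1)
        d2 = (x - cxc) ** 2 + (y - cyc) ** 2 + (z - czc) ** 2
        mag = 1.0 / (1.0 + d2 / r0**2)
        a, b, cc, d = rng.uniform(-1, 1, 4)
        phase = (
            0.4 * np.pi * (a * x / nx + b * y / ny + cc * z / nz)
            + 0.2 * np.pi * d * (x / nx) * (y / ny)
            + rng.uniform(0, 2 * np.pi)
        )
        sens[c] = mag * np.exp(1j * phase)
    return CoilMaps(sens)


# ---------------------------------------------------------------------------
# Respiratory motion
# ---------------------------------------------------------------------------


def simulate_motion_trace(
    n_shots: int, model: dict, rr: float, seed: int = 0
) -> MotionTrace:
    """Sinusoid-plus-drift respiratory trace sampled once per heartbeat.

    d_si(t) = amplitude_si * (1 - cos(2*pi*t/period)) / 2 + drift * t,
    with t = shot_index * rr (seconds, 0-based) and d_lr = lr_ratio * d_si.
    End-expiration corresponds to d_si = 0. ``model`` keys: ``amplitude_si``
    (mm), ``period`` (s), ``lr_ratio``, ``drift`` (mm/min), optional
    ``jitter`` (mm std, seeded Gaussian, default 0).
    """
    if n_shots <= 0:
        raise ValueError("n_shots must be positive")
    amp = float(model.get("amplitude_si", 0.0))
    period = float(model.get("period", 4.0))
    lr_ratio = float(model.get("lr_ratio", 0.0))
    drift = float(model.get("drift", 0.0))
    jitter = float(model.get("jitter", 0.0))
    if amp < 0:
        raise ValueError("amplitude_si must be >= 0")
    if period <= 0:
        raise ValueError("period must be > 0")
    t = np.arange(n_shots) * float(rr)
    d_si = amp * (1.0 - np.cos(2 * np.pi * t / period)) / 2.0 + (drift / 60.0) * t
    d_lr = lr_ratio * d_si
    if jitter > 0:
        rng = np.random.default_rng(seed)
        d_si = d_si + rng.normal(0, jitter, n_shots)
        d_lr = d_lr + rng.normal(0, jitter, n_shots)
    return MotionTrace(d_si=d_si, d_lr=d_lr)
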
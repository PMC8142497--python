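"""Variable-density Cartesian spiral-like phase-encode ordering (VD-CASPR).

The ky-kz phase-encode plane is undersampled with a radially tapered
density (fully sampled central disc, density falling as ``(1 - r)**2``
outside), and the selected points are ordered along spiral-like arms that
are traversed centre-to-periphery within a heartbeat and rotated by the
golden angle between successive heartbeats. The IR-prepared and reference
volumes are acquired in interleaved heartbeats over the same locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Shot", "SamplingSchedule", "generate_sampling_schedule", "GOLDEN_ANGLE_DEG"]

GOLDEN_ANGLE_DEG = 180.0 * (3.0 - np.sqrt(5.0))  # ~137.508 deg

#: radius (fraction of k-max) of the fully sampled central disc
CENTER_FRACTION = 0.08
#: total spiral twist (radians of angle advance from centre to k-max)
ARM_TWIST = np.pi
#: floor of the radial density taper: outer k-space is thinned, never
#: abandoned, so the parallel-imaging reconstruction can restore high
#: frequencies instead of extrapolating them
DENSITY_FLOOR = 0.25


@dataclass(frozen=True)
class Shot:
    heartbeat: int
    tag: str  # "IR" or "REF"
    locations: np.ndarray  # (n_segments, 2) integer (ky, kz)


@dataclass
class SamplingSchedule:
    matrix: tuple[int, int]
    accel: float
    segments_per_beat: int
    seed: int
    shots: list[Shot] = field(default_factory=list)

    @property
    def n_shots(self) -> int:
        return len(self.shots)

    def shots_for(self, tag: str) -> list[Shot]:
        return [s for s in self.shots if s.tag == tag]

    def locations_for(self, tag: str) -> np.ndarray:
        """All (ky, kz) of one volume, stacked in acquisition order."""
        return np.concatenate([s.locations for s in self.shots_for(tag)], axis=0)

    def mask(self, tag: str = "IR") -> np.ndarray:
        """Binary ky-kz sampling mask of one volume."""
        m = np.zeros(self.matrix, dtype=bool)
        loc = self.locations_for(tag)
        m[loc[:, 0], loc[:, 1]] = True
        return m

    def achieved_accel(self, tag: str = "IR") -> float:
        return self.matrix[0] * self.matrix[1] / len(self.locations_for(tag))

    def validate(self) -> None:
        n1, n2 = self.matrix
        for tag in ("IR", "REF"):
            loc = self.locations_for(tag)
            if loc[:, 0].min() < 0 or loc[:, 0].max() >= n1:
                raise ValueError("ky out of bounds")
            if loc[:, 1].min() < 0 or loc[:, 1].max() >= n2:
                raise ValueError("kz out of bounds")
            if len(np.unique(loc, axis=0)) != len(loc):
                raise ValueError(f"duplicate locations within volume {tag}")
        if len(self.shots_for("IR")) != len(self.shots_for("REF")):
            raise ValueError("IR/REF shot counts differ")


def _polar(matrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered (ky, kz) grid -> flat arrays of locations, radius, angle."""
    n1, n2 = matrix
    ky, kz = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    u = (ky - n1 // 2) / max(n1 / 2.0, 1.0)
    v = (kz - n2 // 2) / max(n2 / 2.0, 1.0)
    r = np.sqrt(u**2 + v**2)
    theta = np.arctan2(v, u)
    locs = np.stack([ky.ravel(), kz.ravel()], axis=1)
    return locs, r.ravel(), theta.ravel()


def _radial_cdf(matrix, n_bins: int = 256):
    """Target radial CDF over the grid's normalized elliptical radius.

    Mass per radius = (number of grid cells at that radius) * (density
    taper), with the taper fully sampled inside ``CENTER_FRACTION`` and
    ``DENSITY_FLOOR + (1 - DENSITY_FLOOR) * (1 - r)**2`` outside, so arm
    points drawn from this CDF reproduce the variable-density profile on
    the actual Cartesian cell population (corners included).
    """
    _, r, _ = _polar(matrix)
    r_max = float(r.max())
    hist, edges = np.histogram(r, bins=n_bins, range=(0.0, r_max + 1e-9))
    mid = 0.5 * (edges[:-1] + edges[1:])
    taper = DENSITY_FLOOR + (1.0 - DENSITY_FLOOR) * (1.0 - np.clip(mid, 0, 1)) ** 2
    taper[mid <= CENTER_FRACTION] = 1.0
    mass = hist * taper
    cdf = np.cumsum(mass)
    cdf = cdf / cdf[-1]
    return edges[1:], cdf


def _nearest_free(taken: np.ndarray, ky: int, kz: int, max_radius: int = 4):
    """Nearest unsampled cell to (ky, kz), spiralling outward; None if full."""
    n1, n2 = taken.shape
    best = None
    best_d = None
    for rad in range(max_radius + 1):
        for dy in range(-rad, rad + 1):
            for dz in range(-rad, rad + 1):
                if max(abs(dy), abs(dz)) != rad:
                    continue
                y, z = ky + dy, kz + dz
                if 0 <= y < n1 and 0 <= z < n2 and not taken[y, z]:
                    d = dy * dy + dz * dz
                    if best is None or d < best_d:
                        best, best_d = (y, z), d
        if best is not None and best_d <= rad * rad:
            return best
    return best


def generate_sampling_schedule(
    matrix, accel: float, segments_per_beat: int, seed: int = 0
) -> SamplingSchedule:
    """Generate the interleaved two-volume VD-CASPR sampling schedule.

    ``ceil(n_pe1*n_pe2/accel)`` distinct locations (rounded up to a whole
    number of ``segments_per_beat``-point arms; capped at the full matrix)
    are laid out generatively: each heartbeat's arm is a spiral in the
    ky-kz plane, rotated by the golden angle from the previous heartbeat's,
    whose points sit at radii drawn from the variable-density radial profile
    (fully sampled centre disc of radius ``CENTER_FRACTION``; ``(1-r)**2``
    taper floored at ``DENSITY_FLOOR`` outside) and are snapped to the
    nearest free Cartesian cell. The golden-angle arm rotation plus
    per-arm radial stratification yields low-discrepancy (hole-free)
    coverage. Points within an arm are ordered centre-to-periphery
    (centric). Each arm is acquired twice, in two consecutive heartbeats
    (IR then REF), so both volumes cover the same locations.
    """
    n1, n2 = int(matrix[0]), int(matrix[1])
    if n1 < 4 or n2 < 4:
        raise ValueError("matrix dims must be >= 4")
    if accel < 1:
        raise ValueError("accel must be >= 1")
    if segments_per_beat < 1:
        raise ValueError("segments_per_beat must be >= 1")
    total = n1 * n2
    if accel > total / segments_per_beat:
        raise ValueError("schedule impossible: accel too high for matrix/segments")

    n_target = int(np.ceil(total / accel))
    n_sel = int(np.ceil(n_target / segments_per_beat)) * segments_per_beat
    n_sel = min(n_sel, total)
    locs, r, theta = _polar((n1, n2))
    rng = np.random.default_rng(seed)
    ga = np.deg2rad(GOLDEN_ANGLE_DEG)

    if n_sel >= total and total % segments_per_beat != 0:
        # non-divisible fully sampled limit: partition all cells into
        # spiral-sector arms (the final arm is shorter)
        alpha = np.mod(theta - ARM_TWIST * r, 2 * np.pi)
        order = np.lexsort((r, alpha))
        chosen = np.arange(total)[order]
        n_full, rem = divmod(total, segments_per_beat)
        bounds = [(i * segments_per_beat, (i + 1) * segments_per_beat) for i in range(n_full)]
        if rem:
            bounds.append((n_full * segments_per_beat, total))
        arms = []
        for a, b in bounds:
            idx = chosen[a:b]
            arms.append(idx[np.argsort(r[idx], kind="stable")])
    else:
        n_arms = n_sel // segments_per_beat
        edges, cdf = _radial_cdf((n1, n2))
        r_of = lambda q: np.interp(q, cdf, edges)  # noqa: E731
        phi0 = rng.uniform(0, 2 * np.pi)
        golden_frac = (np.sqrt(5.0) - 1.0) / 2.0
        taken = np.zeros((n1, n2), dtype=bool)
        cy, cz = n1 // 2, n2 // 2
        arms_yx: list[list[tuple[int, int]]] = []
        shortfall: list[int] = []
        for h in range(n_arms):
            phi = phi0 + h * ga
            u = (h * golden_frac) % 1.0  # radial stratification offset
            pts: list[tuple[int, int]] = []
            for s in range(segments_per_beat):
                rho = r_of((s + u) / segments_per_beat)
                ang = phi + ARM_TWIST * rho
                ky = int(round(cy + rho * (n1 / 2.0) * np.cos(ang)))
                kz = int(round(cz + rho * (n2 / 2.0) * np.sin(ang)))
                ky = min(max(ky, 0), n1 - 1)
                kz = min(max(kz, 0), n2 - 1)
                cell = (ky, kz) if not taken[ky, kz] else _nearest_free(taken, ky, kz)
                if cell is None:
                    continue
                taken[cell] = True
                pts.append(cell)
            if len(pts) < segments_per_beat:
                shortfall.append(h)
            arms_yx.append(pts)
        # guarantee the fully sampled centre: swap missing centre cells for
        # the angularly-nearest arm's outermost point
        centre_cells = np.flatnonzero(r <= CENTER_FRACTION)
        for ci in centre_cells:
            ky, kz = locs[ci]
            if taken[ky, kz]:
                continue
            ang = np.arctan2(kz - cz, ky - cy)
            best_h = min(
                range(n_arms),
                key=lambda h: abs(np.angle(np.exp(1j * (phi0 + h * ga - ang))))
                if arms_yx[h]
                else np.inf,
            )
            arm = arms_yx[best_h]
            far = max(range(len(arm)),
                      key=lambda i: (arm[i][0] - cy) ** 2 + (arm[i][1] - cz) ** 2)
            taken[arm[far]] = False
            arm[far] = (int(ky), int(kz))
            taken[ky, kz] = True
        # backfill any shortfall with the cells farthest from the sampled set
        deficit = n_sel - int(taken.sum())
        if deficit > 0:
            from scipy import ndimage as _ndi

            for _ in range(deficit):
                dist = _ndi.distance_transform_edt(~taken)
                ky, kz = np.unravel_index(np.argmax(dist), dist.shape)
                taken[ky, kz] = True
                hsh = shortfall[0] if shortfall else int(rng.integers(n_arms))
                arms_yx[hsh].append((int(ky), int(kz)))
                if shortfall and len(arms_yx[hsh]) >= segments_per_beat:
                    shortfall.pop(0)
        arms = []
        for pts in arms_yx:
            a = np.array(pts, dtype=np.int64)
            rad = (a[:, 0] - cy) ** 2 * (n2 / n1) ** 2 + (a[:, 1] - cz) ** 2
            order = np.argsort(rad, kind="stable")  # centric ordering
            arms.append(np.ravel_multi_index((a[order, 0], a[order, 1]), (n1, n2)))

    shots: list[Shot] = []
    beat = 0
    for idx in arms:
        pts = locs[idx]
        shots.append(Shot(heartbeat=beat, tag="IR", locations=pts.copy()))
        shots.append(Shot(heartbeat=beat + 1, tag="REF", locations=pts.copy()))
        beat += 2

    sched = SamplingSchedule(
        matrix=(n1, n2),
        accel=float(accel),
        segments_per_beat=segments_per_beat,
        seed=seed,
        shots=shots,
    )
    sched.validate()
    return sched
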
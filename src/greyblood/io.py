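"""File formats: HDF5 raw container, NIfTI volumes, delimited tables, YAML config.

The raw container is an HDF5 file laid out after the community raw MR data
standard: one ``dataset`` group holding the k-space samples plus a per-shot
acquisition header (heartbeat index, volume tag, scheduled ky/kz locations)
and the sequence/trajectory parameters as attributes. Complex volumes go to
NIfTI-1 as a magnitude/phase pair along a fourth axis, voxel size in the
header zooms.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom import DigitalPhantom, MotionTrace, TissueParams
from .sense import Volume
from .sequence import RawAcquisition, SequenceParams
from .trajectory import SamplingSchedule, Shot

__all__ = [
    "write_raw",
    "read_raw",
    "write_volume",
    "read_volume",
    "write_schedule_table",
    "read_schedule_table",
    "write_motion_table",
    "save_phantom",
    "load_config",
    "array_checksum",
]

_SEQ_FIELDS = (
    "tr", "te1", "te2", "fa_ir", "fa_ref", "fa_inav",
    "n_segments", "n_inav_echoes", "ti", "rr", "inv_efficiency", "fat_offres_hz",
)


def array_checksum(arr: np.ndarray) -> str:
    """SHA-256 of an array's raw bytes (C-order), for provenance logs."""
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# Raw container
# ---------------------------------------------------------------------------


def write_raw(path, raw: RawAcquisition) -> None:
    path = Path(path)
    n_shots = raw.n_shots
    heartbeat = np.array([s.heartbeat for s in raw.schedule.shots], dtype=np.int64)
    tag = np.array([0 if s.tag == "IR" else 1 for s in raw.schedule.shots], dtype=np.uint8)
    locations = np.stack([s.locations for s in raw.schedule.shots]).astype(np.int64)
    with h5py.File(path, "w") as f:
        g = f.create_group("dataset")
        g.create_dataset("kspace", data=raw.kspace)
        g.create_dataset("inav", data=raw.inav)
        g.create_dataset("inav_lines", data=np.asarray(raw.inav_lines, dtype=np.int64))
        hdr = g.create_group("acq_headers")
        hdr.create_dataset("heartbeat", data=heartbeat)
        hdr.create_dataset("tag", data=tag)
        hdr.create_dataset("locations", data=locations)
        for k in _SEQ_FIELDS:
            g.attrs[f"seq.{k}"] = getattr(raw.seq, k)
        g.attrs["schedule.matrix"] = np.asarray(raw.schedule.matrix, dtype=np.int64)
        g.attrs["schedule.accel"] = raw.schedule.accel
        g.attrs["schedule.segments_per_beat"] = raw.schedule.segments_per_beat
        g.attrs["schedule.seed"] = raw.schedule.seed
        g.attrs["grid_shape"] = np.asarray(raw.grid_shape, dtype=np.int64)
        g.attrs["voxel_size"] = np.asarray(raw.voxel_size, dtype=float)
        g.attrs["noise_sigma"] = raw.noise_sigma
        g.attrs["n_shots"] = n_shots


def read_raw(path) -> RawAcquisition:
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise IOError(f"malformed raw container {path}: {e}") from e
    with f:
        if "dataset" not in f:
            raise IOError(f"malformed raw container {path}: missing group 'dataset'")
        g = f["dataset"]
        for name in ("kspace", "inav", "inav_lines", "acq_headers"):
            if name not in g:
                raise IOError(f"malformed raw container {path}: missing field '{name}'")
        hdr = g["acq_headers"]
        for name in ("heartbeat", "tag", "locations"):
            if name not in hdr:
                raise IOError(
                    f"malformed raw container {path}: missing header field '{name}'"
                )
        kspace = g["kspace"][()]
        inav = g["inav"][()]
        inav_lines = g["inav_lines"][()]
        heartbeat = hdr["heartbeat"][()]
        tag = hdr["tag"][()]
        locations = hdr["locations"][()]
        seq_kwargs = {}
        for k in _SEQ_FIELDS:
            key = f"seq.{k}"
            if key not in g.attrs:
                raise IOError(f"malformed raw container {path}: missing attr '{key}'")
            v = g.attrs[key]
            seq_kwargs[k] = int(v) if k in ("n_segments", "n_inav_echoes") else float(v)
        seq = SequenceParams(**seq_kwargs)
        shots = [
            Shot(
                heartbeat=int(heartbeat[i]),
                tag="IR" if tag[i] == 0 else "REF",
                locations=locations[i],
            )
            for i in range(len(heartbeat))
        ]
        schedule = SamplingSchedule(
            matrix=tuple(int(v) for v in g.attrs["schedule.matrix"]),
            accel=float(g.attrs["schedule.accel"]),
            segments_per_beat=int(g.attrs["schedule.segments_per_beat"]),
            seed=int(g.attrs["schedule.seed"]),
            shots=shots,
        )
        return RawAcquisition(
            kspace=kspace,
            inav=inav,
            inav_lines=inav_lines,
            schedule=schedule,
            seq=seq,
            grid_shape=tuple(int(v) for v in g.attrs["grid_shape"]),
            voxel_size=tuple(float(v) for v in g.attrs["voxel_size"]),
            noise_sigma=float(g.attrs["noise_sigma"]),
        )


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def write_volume(path, v: Volume) -> None:
    """Complex volume to NIfTI-1 as a (magnitude, phase) pair, float32."""
    path = Path(path)
    mag = np.abs(v.data).astype(np.float32)
    phase = np.angle(v.data).astype(np.float32)
    arr = np.stack([mag, phase], axis=3)
    affine = np.diag(list(v.voxel_size) + [1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(tuple(v.voxel_size) + (1.0,))
    img.header["descrip"] = v.tag.encode()[:79]
    nib.save(img, str(path))
    if v.provenance:
        Path(str(path) + ".provenance.txt").write_text("\n".join(v.provenance) + "\n")


def read_volume(path) -> Volume:
    path = Path(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[3] != 2:
        raise ValueError(f"{path}: expected a 4D magnitude/phase pair volume")
    data = arr[..., 0].astype(float) * np.exp(1j * arr[..., 1].astype(float))
    zooms = img.header.get_zooms()[:3]
    tag = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace")
    prov_path = Path(str(path) + ".provenance.txt")
    prov = prov_path.read_text().splitlines() if prov_path.exists() else []
    return Volume(data=data, voxel_size=tuple(float(z) for z in zooms), tag=tag,
                  provenance=prov)


def write_real_volume(path, data: np.ndarray, voxel_size) -> None:
    """Real-valued (e.g. signed PSIR, polarity, field map) volume to NIfTI."""
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(voxel_size))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------


def write_schedule_table(path, schedule: SamplingSchedule) -> None:
    lines = ["heartbeat\ttag\tky\tkz"]
    for shot in schedule.shots:
        for ky, kz in shot.locations:
            lines.append(f"{shot.heartbeat}\t{shot.tag}\t{ky}\t{kz}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_schedule_table(
    path, matrix, accel: float, segments_per_beat: int, seed: int = 0
) -> SamplingSchedule:
    rows = Path(path).read_text().strip().splitlines()
    if not rows or rows[0].split("\t") != ["heartbeat", "tag", "ky", "kz"]:
        raise IOError(f"{path}: not a schedule table")
    shots: list[Shot] = []
    cur_key = None
    cur_locs: list[tuple[int, int]] = []
    for row in rows[1:]:
        hb, tag, ky, kz = row.split("\t")
        key = (int(hb), tag)
        if key != cur_key:
            if cur_key is not None:
                shots.append(
                    Shot(cur_key[0], cur_key[1], np.array(cur_locs, dtype=np.int64))
                )
            cur_key, cur_locs = key, []
        cur_locs.append((int(ky), int(kz)))
    if cur_key is not None:
        shots.append(Shot(cur_key[0], cur_key[1], np.array(cur_locs, dtype=np.int64)))
    return SamplingSchedule(
        matrix=tuple(matrix), accel=accel, segments_per_beat=segments_per_beat,
        seed=seed, shots=shots,
    )


def write_motion_table(path, d_si, d_lr, tags, correlation=None) -> None:
    corr = correlation if correlation is not None else np.ones(len(d_si))
    lines = ["shot\ttag\td_si\td_lr\tcorrelation"]
    for i, (a, b, t, c) in enumerate(zip(d_si, d_lr, tags, corr)):
        lines.append(f"{i}\t{t}\t{a:.6f}\t{b:.6f}\t{c:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_phantom(path_prefix, phantom: DigitalPhantom) -> None:
    """Label grid to NIfTI plus a tissue-table TSV sidecar."""
    prefix = Path(path_prefix)
    affine = np.diag(list(phantom.voxel_size) + [1.0])
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), affine)
    img.header.set_zooms(tuple(phantom.voxel_size))
    nib.save(img, str(prefix) + "_labels.nii")
    lines = ["label\tname\tt1_ms\tt2s_ms\tpd\tfat_fraction"]
    for lab in sorted(phantom.tissue_table):
        tp = phantom.tissue_table[lab]
        lines.append(
            f"{lab}\t{tp.name}\t{tp.t1:g}\t{tp.t2s:g}\t{tp.pd:g}\t{tp.fat_fraction:g}"
        )
    Path(str(prefix) + "_tissues.tsv").write_text("\n".join(lines) + "\n")


def load_config(path) -> dict:
    """Nested key/value pipeline configuration from YAML."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
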
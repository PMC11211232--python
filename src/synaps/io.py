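"""HDF5 raw-data container and NIfTI volume export.

The raw container is a single HDF5 file per sequence with a documented
layout (one session directory pairs the anatomical and flow files):

    /data                complex64 (readout, sample, coil)
    /data_corrected      optional, after respiratory correction
    /schedule/*          per-readout records (directions, timestamps, ...)
    /coils               complex coil sensitivities (voxel, coil)
    /pt/data             pilot-tone matrix (channel, time), attrs fs_hz, gap
    /truth/*             optional ground-truth block (simulated data only)
    root attrs           format_version, meta (sequence config as JSON)
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import h5py
import numpy as np
import nibabel as nib

from .acquisition import CoilMaps, RawAcquisition
from .operators import Grid
from .phantom import PilotToneRecord
from .trajectory import ReadoutSchedule, SequenceConfig

__all__ = [
    "FORMAT_VERSION",
    "SessionManifest",
    "write_raw",
    "read_raw",
    "export_volumes",
]

FORMAT_VERSION = "1.0"

_SCHEDULE_FIELDS = (
    "interleave_index",
    "readout_index",
    "directions",
    "timestamps",
    "encoding_segment",
    "is_si",
)


@dataclass
class SessionManifest:
    """Paths of one paired acquisition session."""

    fiss_raw: str
    pc_raw: str
    pt_source: str
    config_snapshot: dict
    format_version: str = FORMAT_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_raw(path, raw: RawAcquisition, corrected: np.ndarray = None):
    """Write a :class:`RawAcquisition` losslessly to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        meta = dataclasses.asdict(raw.schedule.config)
        meta["grid"] = {
            "size": raw.grid.size,
            "voxel_mm": raw.grid.voxel_mm,
            "mode": raw.grid.mode,
        }
        f.attrs["meta"] = json.dumps(meta)
        f.create_dataset("data", data=raw.samples.astype(np.complex64))
        if corrected is not None:
            f.create_dataset("data_corrected", data=corrected.astype(np.complex64))
        sched = f.create_group("schedule")
        sched.attrs["columns"] = (
            "interleave_index, readout_index, directions (unit 3-vector), "
            "timestamps (s, shared clock), encoding_segment (-1 = none), is_si"
        )
        for name in _SCHEDULE_FIELDS:
            sched.create_dataset(name, data=getattr(raw.schedule, name))
        f.create_dataset("coils", data=raw.coil_maps.maps.astype(np.complex64))
        if raw.pt is not None:
            g = f.create_group("pt")
            g.create_dataset("data", data=raw.pt.data)
            g["data"].attrs["fs_hz"] = raw.pt.fs
            if raw.pt.gap_time_s is not None:
                g["data"].attrs["gap_time_s"] = raw.pt.gap_time_s
        if raw.truth is not None:
            g = f.create_group("truth")
            for k, v in raw.truth.items():
                g.create_dataset(k, data=v)


def read_raw(path) -> RawAcquisition:
    """Read a raw container written by :func:`write_raw`.

    Raises on a missing file and on a format-version mismatch (both
    versions named in the error).
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version", "<missing>")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"raw container version {version!r} does not match "
                f"library version {FORMAT_VERSION!r}"
            )
        meta = json.loads(f.attrs["meta"])
        gmeta = meta.pop("grid")
        config = SequenceConfig(**meta)
        grid = Grid(gmeta["size"], gmeta["voxel_mm"], gmeta["mode"])
        sched_kwargs = {
            name: f["schedule"][name][()] for name in _SCHEDULE_FIELDS
        }
        sched_kwargs["is_si"] = sched_kwargs["is_si"].astype(bool)
        schedule = ReadoutSchedule(config=config, **sched_kwargs)
        pt = None
        if "pt" in f:
            ds = f["pt"]["data"]
            pt = PilotToneRecord(
                data=ds[()],
                fs=float(ds.attrs["fs_hz"]),
                gap_time_s=(
                    float(ds.attrs["gap_time_s"]) if "gap_time_s" in ds.attrs else None
                ),
            )
        truth = None
        if "truth" in f:
            truth = {k: f["truth"][k][()] for k in f["truth"]}
        samples = f["data_corrected" if "data_corrected" in f else "data"][()]
        return RawAcquisition(
            samples=samples,
            schedule=schedule,
            coil_maps=CoilMaps(maps=f["coils"][()], grid=grid),
            grid=grid,
            pt=pt,
            truth=truth,
        )


def _as_nifti(arr: np.ndarray, voxel_mm: float, phase_duration_s: float = None):
    """4D NIfTI from (…, P) data; 2D slices become (ny, nz, 1, P)."""
    data = np.asarray(arr, np.float32)
    if data.ndim == 3:  # (ny, nz, P) single slice
        data = data[:, :, None, :]
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    zooms = [voxel_mm] * 3 + [phase_duration_s if phase_duration_s else 1.0]
    img.header.set_zooms(zooms)
    return img


def export_volumes(vol, prefix) -> list:
    """Export a cine / flow / combined volume as NIfTI files.

    Magnitude goes to ``<prefix>_mag.nii``; velocity components (cm/s,
    float32) to ``<prefix>_vx/_vy/_vz.nii``.  Returns the written paths.
    """
    prefix = str(prefix)
    phase_dur = None
    if getattr(vol, "rr_s", None):
        phase_dur = vol.rr_s / vol.n_phases
    paths = []
    img = _as_nifti(vol.magnitude, vol.voxel_mm, phase_dur)
    img.header["descrip"] = b"magnitude (a.u.)"
    p = prefix + "_mag.nii"
    nib.save(img, p)
    paths.append(p)
    if hasattr(vol, "velocity") and vol.velocity is not None:
        for k, suffix in enumerate(("_vx", "_vy", "_vz")):
            img = _as_nifti(vol.velocity[..., k], vol.voxel_mm, phase_dur)
            img.header["descrip"] = b"velocity (cm/s)"
            p = prefix + suffix + ".nii"
            nib.save(img, p)
            paths.append(p)
    return paths
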
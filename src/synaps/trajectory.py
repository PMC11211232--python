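"""Radial trajectories and readout schedules for the two free-running sequences.

Two sequences are scheduled back-to-back on a shared clock:

* FISS — bright-blood, fat-suppressed anatomy; each interleave holds
  24 readouts grouped as 6 modules x 4 readouts, no velocity encoding.
* PC — 4-point velocity-encoded phase contrast; each interleave holds
  21 readouts: 1 superior-inferior (SI) projection followed by 5 line
  groups of 4 readouts that share one direction and carry encoding
  segments 0..3.

In 3D mode directions follow a golden-angle spiral phyllotaxis over the
half-sphere; in 2D desk-scale mode the same scheduler emits golden-angle
in-plane spokes in the (y, z) plane.  SI readouts point along +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequenceConfig",
    "ReadoutSchedule",
    "fiss_config",
    "pc_config",
    "phyllotaxis_directions",
    "golden_angle_2d_directions",
    "build_schedule",
    "radial_offsets",
    "readout_kspace",
]

GOLDEN_RATIO = (1 + np.sqrt(5)) / 2
#: 3D phyllotaxis azimuthal increment, 2*pi*(1 - 1/phi^2)
AZIMUTH_INCREMENT = 2 * np.pi * (1 - 1 / GOLDEN_RATIO**2)
#: 2D golden angle, pi/phi (111.246 deg)
GOLDEN_ANGLE_2D = np.pi / GOLDEN_RATIO

FISS_READOUTS_PER_INTERLEAVE = 24  # 6 modules x 4 readouts
PC_READOUTS_PER_INTERLEAVE = 21  # 1 SI + 5 line groups x 4 segments
PC_LINES_PER_INTERLEAVE = 5
N_ENCODING_SEGMENTS = 4


@dataclass(frozen=True)
class SequenceConfig:
    name: str  # "FISS" | "PC"
    n_interleaves: int
    tr_ms: float
    te_ms: float
    fov_mm: float = 220.0
    resolution_mm: float = 2.0
    oversampling: int = 2
    venc_cm_s: float = None  # PC only
    mode: str = "3d"  # "3d" | "2d"

    def __post_init__(self):
        if self.name not in ("FISS", "PC"):
            raise ValueError(f"unknown sequence name {self.name!r}")
        if self.n_interleaves < 1:
            raise ValueError("n_interleaves must be >= 1")
        if self.name == "PC" and (self.venc_cm_s is None or self.venc_cm_s <= 0):
            raise ValueError("PC requires venc_cm_s > 0")
        n = self.fov_mm / self.resolution_mm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fov_mm / resolution_mm must be integral")

    @property
    def readouts_per_interleave(self) -> int:
        return (
            FISS_READOUTS_PER_INTERLEAVE
            if self.name == "FISS"
            else PC_READOUTS_PER_INTERLEAVE
        )

    @property
    def matrix_size(self) -> int:
        return int(round(self.fov_mm / self.resolution_mm))

    @property
    def samples_per_readout(self) -> int:
        return self.oversampling * self.matrix_size

    @property
    def kmax(self) -> float:
        """cycles/mm, 1/(2*resolution)."""
        return 1.0 / (2.0 * self.resolution_mm)


def fiss_config(**overrides) -> SequenceConfig:
    """Default FISS sequence: 2000 interleaves, TR 2.94 ms, TE 1.5 ms."""
    kw = dict(name="FISS", n_interleaves=2000, tr_ms=2.94, te_ms=1.5)
    kw.update(overrides)
    return SequenceConfig(**kw)


def pc_config(**overrides) -> SequenceConfig:
    """Default PC sequence: 4820 interleaves, TR 5.3 ms, TE 3.5 ms, venc 150."""
    kw = dict(name="PC", n_interleaves=4820, tr_ms=5.3, te_ms=3.5, venc_cm_s=150.0)
    kw.update(overrides)
    return SequenceConfig(**kw)


@dataclass
class ReadoutSchedule:
    """Flat per-readout records for one sequence."""

    config: SequenceConfig
    interleave_index: np.ndarray  # (R,) int
    readout_index: np.ndarray  # (R,) int, within interleave
    directions: np.ndarray  # (R, 3) unit vectors
    timestamps: np.ndarray  # (R,) seconds on the shared clock
    encoding_segment: np.ndarray  # (R,) int, -1 = none
    is_si: np.ndarray  # (R,) bool

    def __len__(self) -> int:
        return len(self.timestamps)

    def validate(self):
        norms = np.linalg.norm(self.directions, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)
        assert np.all(np.diff(self.timestamps) > 0)
        none_mask = self.encoding_segment < 0
        expected_none = self.is_si | (self.config.name == "FISS")
        assert np.array_equal(none_mask, expected_none)


def phyllotaxis_directions(
    n_interleaves: int, readouts_per_interleave: int
) -> np.ndarray:
    """Golden-angle spiral phyllotaxis over the half-sphere.

    Returns (n_interleaves, readouts_per_interleave, 3) unit vectors.  The
    polar index is interleaved: readout j of interleave i takes global
    spiral index j*n_interleaves + i, so each interleave spans the full
    polar range from pole to equator.
    """
    if n_interleaves < 1 or readouts_per_interleave < 1:
        raise ValueError("counts must be >= 1")
    total = n_interleaves * readouts_per_interleave
    n = np.arange(total, dtype=float)
    polar = (np.pi / 2) * np.sqrt((n + 0.5) / total)  # 0 (pole, +z) .. pi/2
    azimuth = n * AZIMUTH_INCREMENT
    dirs = np.stack(
        [
            np.sin(polar) * np.cos(azimuth),
            np.sin(polar) * np.sin(azimuth),
            np.cos(polar),
        ],
        axis=-1,
    )
    order = (
        np.arange(readouts_per_interleave)[None, :] * n_interleaves
        + np.arange(n_interleaves)[:, None]
    )  # (n_interleaves, m) -> global spiral index
    out = dirs[order]
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def golden_angle_2d_directions(
    n_interleaves: int, readouts_per_interleave: int
) -> np.ndarray:
    """In-plane golden-angle spokes in the (y, z) plane, same interleaving."""
    if n_interleaves < 1 or readouts_per_interleave < 1:
        raise ValueError("counts must be >= 1")
    total = n_interleaves * readouts_per_interleave
    n = np.arange(total, dtype=float)
    theta = np.mod(np.pi / 2 + n * GOLDEN_ANGLE_2D, np.pi)  # start at +z
    dirs = np.stack([np.zeros(total), np.cos(theta), np.sin(theta)], axis=-1)
    order = (
        np.arange(readouts_per_interleave)[None, :] * n_interleaves
        + np.arange(n_interleaves)[:, None]
    )
    return dirs[order]


SI_DIRECTION = np.array([0.0, 0.0, 1.0])


def build_schedule(config: SequenceConfig, start_time: float = 0.0) -> ReadoutSchedule:
    """Emit the full per-readout schedule of one sequence.

    Timestamps advance by TR per readout from ``start_time``.
    """
    n_int = config.n_interleaves
    m = config.readouts_per_interleave
    gen = (
        golden_angle_2d_directions if config.mode == "2d" else phyllotaxis_directions
    )
    if config.name == "FISS":
        directions = gen(n_int, m).reshape(n_int * m, 3)
        encoding = np.full(n_int * m, -1, dtype=int)
        is_si = np.zeros(n_int * m, dtype=bool)
    else:
        lines = gen(n_int, PC_LINES_PER_INTERLEAVE)  # (n_int, 5, 3)
        directions = np.empty((n_int, m, 3))
        encoding = np.empty((n_int, m), dtype=int)
        is_si = np.zeros((n_int, m), dtype=bool)
        directions[:, 0] = SI_DIRECTION
        encoding[:, 0] = -1
        is_si[:, 0] = True
        for g in range(PC_LINES_PER_INTERLEAVE):
            sl = slice(1 + g * N_ENCODING_SEGMENTS, 1 + (g + 1) * N_ENCODING_SEGMENTS)
            directions[:, sl] = lines[:, g : g + 1]
            encoding[:, sl] = np.arange(N_ENCODING_SEGMENTS)
        directions = directions.reshape(-1, 3)
        encoding = encoding.ravel()
        is_si = is_si.ravel()
    total = n_int * m
    interleave_index = np.repeat(np.arange(n_int), m)
    readout_index = np.tile(np.arange(m), n_int)
    timestamps = start_time + np.arange(total) * (config.tr_ms * 1e-3)
    return ReadoutSchedule(
        config=config,
        interleave_index=interleave_index,
        readout_index=readout_index,
        directions=directions,
        timestamps=timestamps,
        encoding_segment=encoding,
        is_si=is_si,
    )


def radial_offsets(samples: int, kmax: float) -> np.ndarray:
    """Symmetric radial offsets k_i = kmax*(2i - N)/N, i = 0..N-1 (includes 0)."""
    if samples % 2:
        raise ValueError("samples must be even")
    i = np.arange(samples)
    return kmax * (2 * i - samples) / samples


def readout_kspace(direction, samples: int, kmax: float) -> np.ndarray:
    """(samples, 3) k-space coordinates of one spoke, cycles/mm."""
    direction = np.asarray(direction, float)
    return radial_offsets(samples, kmax)[:, None] * direction[None, :]
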
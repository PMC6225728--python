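"""Shared domain types.

Unit convention (used everywhere in this package): coordinates are stored in
nanometres, time in seconds, diffusion coefficients in um^2/s (or um^2/s^alpha
for the anomalous model) and MSD values in um^2.  Conversion to and from pixel
units happens only at I/O boundaries (``pixel_size``, ``dt``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

NM_PER_UM = 1000.0
UM2_PER_NM2 = 1.0e-6


@dataclass(frozen=True)
class MotionModel:
    """Parameters of one particle's diffusion law.

    kind : {"brownian", "fbm", "confined"}
    D : diffusion coefficient, um^2/s (generalized, um^2/s^alpha, for fbm)
    alpha : anomalous exponent (fbm only), in (0, 2]
    A : confinement plateau, um^2 (confined only)
    tau : confinement relaxation time, s (confined only)
    D_macro : macroscopic coefficient, um^2/s (confined only)
    """

    kind: str
    D: float = 0.0
    alpha: float = 1.0
    A: float = 0.0
    tau: float = 1.0
    D_macro: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("brownian", "fbm", "confined"):
            raise ValueError(f"unknown motion kind: {self.kind!r}")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.kind == "fbm" and not (0 < self.alpha <= 2):
            raise ValueError("alpha must lie in (0, 2]")
        if self.kind == "confined":
            if self.A < 0:
                raise ValueError("A must be >= 0")
            if self.tau <= 0:
                raise ValueError("tau must be > 0")
            if self.D_macro < 0:
                raise ValueError("D_macro must be >= 0")

    def msd(self, t: np.ndarray) -> np.ndarray:
        """Closed-form 2D ensemble MSD (um^2) at lag times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "brownian":
            return 4.0 * self.D * t
        if self.kind == "fbm":
            return 4.0 * self.D * t ** self.alpha
        return self.A * (1.0 - np.exp(-t / self.tau)) + 4.0 * self.D_macro * t


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and noise for simulated movies and stacks.

    Defaults mirror the live-imaging setup this pipeline targets: 512x512
    frames at 4 frames/s for 120 s (480 frames, dt = 0.25 s), 66.3 nm pixels
    (three pixels = 198.9 nm), 0.5 um z-steps for stacks.
    """

    n_frames: int = 480
    dt: float = 0.25
    pixel_size: float = 66.3           # nm / pixel
    image_shape: tuple[int, int] = (512, 512)
    z_step: float = 0.5                # um, stacks only
    psf_sigma: float = 1.3             # pixels
    photon_scale: float = 500.0        # expected photons per spot; 0 -> noiseless
    background: float = 10.0           # photons / pixel
    read_noise: float = 2.0            # additive Gaussian sd, photon units
    edge_handling: str = "clip"        # {"clip", "drop"} for out-of-field spots
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.edge_handling not in ("clip", "drop"):
            raise ValueError("edge_handling must be 'clip' or 'drop'")

    @property
    def field_nm(self) -> tuple[float, float]:
        """(height, width) of the field of view in nm."""
        h, w = self.image_shape
        return (h * self.pixel_size, w * self.pixel_size)


@dataclass
class GroundTruth:
    """True particle paths produced by a simulator.

    positions : (n_traj, n_frames, ndim) array, nm; every path covers
        frames 0..n_frames-1.
    drift : (n_frames, ndim) per-frame offset already added to ``positions``
        (zeros if none).
    motion : one MotionModel per trajectory.
    dt : frame interval, s.
    """

    positions: np.ndarray
    drift: np.ndarray
    motion: list[MotionModel]
    dt: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.drift = np.asarray(self.drift, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must be (n_traj, n_frames, ndim)")
        if self.drift.shape != self.positions.shape[1:]:
            raise ValueError("drift must have one entry per frame per axis")
        if len(self.motion) != self.positions.shape[0]:
            raise ValueError("one MotionModel per trajectory required")

    @property
    def n_traj(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def ndim(self) -> int:
        return self.positions.shape[2]


@dataclass
class SpotRecord:
    """One detected punctum."""

    frame: int
    x: float                  # nm
    y: float                  # nm
    intensity: float
    sigma: float              # nm
    z: Optional[float] = None  # um, stacks only
    nucleus_id: int = 0


@dataclass
class Trajectory:
    """Time-ordered positions of one tracked locus, possibly with gaps.

    frames : strictly increasing present time indices (0-based).
    positions : (len(frames), 2) array of (x, y) in nm.
    n_total_frames : movie length N.
    dt : frame interval, s.
    """

    traj_id: int
    frames: np.ndarray
    positions: np.ndarray
    n_total_frames: int
    dt: float
    nucleus_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frames.ndim != 1 or np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if len(self.positions) != len(self.frames):
            raise ValueError("positions and frames must have equal length")

    @property
    def n_present(self) -> int:
        return len(self.frames)


@dataclass
class NucleusFoci:
    """3D foci of one nucleus in one channel. Positions in nm."""

    nucleus_id: int
    positions: np.ndarray          # (n, 3) nm
    intensities: Optional[np.ndarray] = None
    channel: str = "A"
    spot_diameter: Optional[float] = None  # nm

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = np.empty((0, 3))
        if self.positions.shape[1] != 3:
            raise ValueError("foci positions must be (n, 3)")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)

    @property
    def n_foci(self) -> int:
        return self.positions.shape[0]
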
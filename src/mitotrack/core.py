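"""Shared domain types: acquisition calibration, image sequences, detections, trajectories.

All physical positions are in micrometres and times in seconds.  Array data is
indexed ``(t, z, y, x)`` with 0-based indices; the physical ``x`` coordinate runs
along the image width (last axis), ``y`` along the height, ``z`` along the
slice axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionMetadata",
    "ImageSequence4D",
    "Detection",
    "Trajectory",
]


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Calibration of a 4-D (xyz-t) acquisition.

    Parameters
    ----------
    pixel_size_xy : float
        Lateral pixel size in micrometres per pixel.
    z_step : float
        Axial spacing in micrometres per slice.
    frame_interval : float
        Time between successive frames in seconds.
    n_frames, n_z, height, width : int
        Grid dimensions, ``(t, z, y, x)``.
    anterograde_axis : tuple of float
        Unit vector in the xy plane defining the positive (anterograde)
        direction.  Defaults to ``+x``.
    """

    pixel_size_xy: float
    z_step: float
    frame_interval: float
    n_frames: int
    n_z: int
    height: int
    width: int
    anterograde_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if not self.pixel_size_xy > 0:
            raise ValueError(f"pixel_size_xy must be > 0, got {self.pixel_size_xy}")
        if not self.z_step > 0:
            raise ValueError(f"z_step must be > 0, got {self.z_step}")
        if not self.frame_interval > 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        for name in ("n_frames", "n_z", "height", "width"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        ax = np.asarray(self.anterograde_axis, dtype=float)
        if ax.shape != (2,) or not np.isfinite(ax).all():
            raise ValueError("anterograde_axis must be a finite 2-vector")
        if abs(float(np.hypot(*ax)) - 1.0) > 1e-6:
            raise ValueError("anterograde_axis must have unit norm")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.n_frames, self.n_z, self.height, self.width)

    @property
    def axis3(self) -> np.ndarray:
        """Anterograde axis as a 3-vector (x, y, z=0)."""
        return np.array([self.anterograde_axis[0], self.anterograde_axis[1], 0.0])

    def voxel_to_um(self, zyx: np.ndarray) -> np.ndarray:
        """Convert fractional voxel indices ``(z, y, x)`` to ``(x, y, z)`` in um."""
        zyx = np.asarray(zyx, dtype=float)
        z, y, x = zyx[..., 0], zyx[..., 1], zyx[..., 2]
        return np.stack(
            [x * self.pixel_size_xy, y * self.pixel_size_xy, z * self.z_step], axis=-1
        )

    def um_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Convert positions ``(x, y, z)`` in um to fractional voxel ``(z, y, x)``."""
        xyz = np.asarray(xyz, dtype=float)
        x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
        return np.stack(
            [z / self.z_step, y / self.pixel_size_xy, x / self.pixel_size_xy], axis=-1
        )


@dataclass
class ImageSequence4D:
    """A calibrated non-negative intensity volume indexed ``(t, z, y, x)``."""

    intensities: np.ndarray
    metadata: AcquisitionMetadata

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 4:
            raise ValueError(f"expected 4-D (t, z, y, x) array, got ndim={arr.ndim}")
        if arr.shape != self.metadata.shape:
            raise ValueError(
                f"array shape {arr.shape} does not match metadata {self.metadata.shape}"
            )
        if not np.isfinite(arr).all():
            raise ValueError("intensities must be finite")
        if arr.min() < 0:
            raise ValueError("intensities must be >= 0")
        self.intensities = arr

    @property
    def n_frames(self) -> int:
        return self.metadata.n_frames

    def frame(self, t: int) -> np.ndarray:
        """The 3-D ``(z, y, x)`` volume at frame ``t``."""
        return self.intensities[t]


@dataclass(frozen=True)
class Detection:
    """One segmented particle in one frame."""

    frame: int
    centroid: tuple[float, float, float]  # (x, y, z) um
    volume: int  # voxels
    total_intensity: float
    peak_intensity: float
    label_id: int

    def __post_init__(self) -> None:
        if self.volume < 1:
            raise ValueError("volume must be >= 1 voxel")
        if self.total_intensity < 0 or self.peak_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if not np.isfinite(self.centroid).all():
            raise ValueError("centroid must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)


@dataclass
class Trajectory:
    """Time-ordered 3-D positions and features of one tracked particle.

    ``frames`` are strictly increasing integer frame indices; ``positions`` is
    an ``(n, 3)`` array of ``(x, y, z)`` in micrometres.  ``interpolated``
    flags samples that were filled across a detection gap rather than measured.
    """

    track_id: int
    frames: np.ndarray
    positions: np.ndarray
    intensities: np.ndarray | None = None
    volumes: np.ndarray | None = None
    interpolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.frames)
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match {n} frames"
            )
        if n and not (np.diff(self.frames) > 0).all():
            raise ValueError("frames must be strictly increasing")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if self.intensities is None:
            self.intensities = np.zeros(n)
        else:
            self.intensities = np.asarray(self.intensities, dtype=float)
        if self.volumes is None:
            self.volumes = np.zeros(n)
        else:
            self.volumes = np.asarray(self.volumes, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
        for name in ("intensities", "volumes", "interpolated"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match frames")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Missing frame ranges ``(first_missing, last_missing)`` inside the track."""
        out = []
        d = np.diff(self.frames)
        for i in np.flatnonzero(d > 1):
            out.append((int(self.frames[i]) + 1, int(self.frames[i + 1]) - 1))
        return out

    def is_uniform(self) -> bool:
        return len(self) < 2 or bool((np.diff(self.frames) == 1).all())

    def fill_gaps(self) -> "Trajectory":
        """Return a gap-free copy with linearly interpolated, flagged samples."""
        if self.is_uniform():
            return self
        full = np.arange(self.frames[0], self.frames[-1] + 1)
        pos = np.column_stack(
            [np.interp(full, self.frames, self.positions[:, k]) for k in range(3)]
        )
        inten = np.interp(full, self.frames, self.intensities)
        vol = np.interp(full, self.frames, self.volumes)
        interp = ~np.isin(full, self.frames)
        prev = np.zeros(len(full), dtype=bool)
        prev[np.searchsorted(full, self.frames)] = self.interpolated
        return Trajectory(
            self.track_id, full, pos, inten, vol, interpolated=interp | prev
        )
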
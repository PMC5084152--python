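"""File input/output: multi-page (OME-)TIFF image sequences and trajectory CSVs."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .core import AcquisitionMetadata, ImageSequence4D, Trajectory

__all__ = [
    "read_image_sequence",
    "write_image_sequence",
    "read_trajectories",
    "write_trajectories",
    "TRAJECTORY_COLUMNS",
]

TRAJECTORY_COLUMNS = [
    "track_id",
    "frame",
    "t_s",
    "x_um",
    "y_um",
    "z_um",
    "intensity",
    "volume_vox",
]

# calibration fields that must be known, from the file or from overrides
_REQUIRED = ("pixel_size_xy", "z_step", "frame_interval")


def write_image_sequence(seq: ImageSequence4D, path: str | Path) -> Path:
    """Write a calibrated sequence as an OME-TIFF (axes TZYX, z fastest)."""
    path = Path(path)
    md = seq.metadata
    tifffile.imwrite(
        path,
        seq.intensities,
        ome=True,
        metadata={
            "axes": "TZYX",
            "PhysicalSizeX": md.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": md.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": md.z_step,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": md.frame_interval,
            "TimeIncrementUnit": "s",
        },
    )
    return path


def _ome_calibration(tif: tifffile.TiffFile) -> dict:
    """Pull pixel size / z step / frame interval and axis sizes from OME-XML."""
    out: dict = {}
    if not tif.is_ome or not tif.ome_metadata:
        return out
    try:
        root = ET.fromstring(tif.ome_metadata)
    except ET.ParseError:
        return out
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pix = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    if pix is None:
        return out
    attr = pix.attrib
    if "PhysicalSizeX" in attr:
        out["pixel_size_xy"] = float(attr["PhysicalSizeX"])
    if "PhysicalSizeZ" in attr:
        out["z_step"] = float(attr["PhysicalSizeZ"])
    if "TimeIncrement" in attr:
        out["frame_interval"] = float(attr["TimeIncrement"])
    if "SizeT" in attr:
        out["n_frames"] = int(attr["SizeT"])
    if "SizeZ" in attr:
        out["n_z"] = int(attr["SizeZ"])
    return out


def read_image_sequence(
    path: str | Path,
    overrides: Mapping[str, object] | None = None,
    *,
    page_order: str = "tz",
) -> ImageSequence4D:
    """Read a multi-page TIFF / OME-TIFF into a calibrated :class:`ImageSequence4D`.

    Parameters
    ----------
    path : path
        Multi-page TIFF with a consistent ``(t, z)`` page layout.
    overrides : mapping, optional
        Metadata fields (``pixel_size_xy``, ``z_step``, ``frame_interval``,
        ``n_frames``, ``n_z``, ``anterograde_axis``) that supplement or replace
        what the file declares.  Calibration missing from both the file and the
        overrides raises a :class:`ValueError`.
    page_order : {"tz", "zt"}
        ``"tz"`` (default) means z varies fastest within each timepoint;
        ``"zt"`` is the transposed page dialect.
    """
    path = Path(path)
    overrides = dict(overrides or {})
    if page_order not in ("tz", "zt"):
        raise ValueError(f"page_order must be 'tz' or 'zt', got {page_order!r}")

    with tifffile.TiffFile(path) as tif:
        meta = _ome_calibration(tif)
        series = tif.series[0]
        data = series.asarray()

    meta.update(overrides)

    if data.ndim == 4:
        n_frames, n_z = data.shape[0], data.shape[1]
        meta.setdefault("n_frames", n_frames)
        meta.setdefault("n_z", n_z)
        if (meta["n_frames"], meta["n_z"]) != (n_frames, n_z):
            raise ValueError(
                f"page count mismatch: file holds (t={n_frames}, z={n_z}) but "
                f"metadata declares (t={meta['n_frames']}, z={meta['n_z']})"
            )
        pages = data.reshape(n_frames * n_z, *data.shape[2:])
    elif data.ndim == 3:
        pages = data
    elif data.ndim == 2:
        pages = data[None]
    else:
        raise ValueError(f"unsupported TIFF dimensionality {data.ndim}")

    n_pages = pages.shape[0]
    n_frames = meta.get("n_frames")
    n_z = meta.get("n_z")
    if n_frames is None and n_z is None:
        n_frames, n_z = n_pages, 1
    elif n_frames is None:
        n_frames = n_pages // int(n_z)
    elif n_z is None:
        n_z = n_pages // int(n_frames)
    n_frames, n_z = int(n_frames), int(n_z)
    if n_frames * n_z != n_pages:
        raise ValueError(
            f"page count mismatch: {n_pages} pages cannot form a "
            f"(t={n_frames}, z={n_z}) grid"
        )

    missing = [k for k in _REQUIRED if k not in meta]
    if missing:
        raise ValueError(
            f"missing calibration {missing}; supply via overrides (file carries none)"
        )

    if page_order == "tz":
        stack = pages.reshape(n_frames, n_z, *pages.shape[1:])
    else:
        stack = pages.reshape(n_z, n_frames, *pages.shape[1:]).transpose(1, 0, 2, 3)

    md = AcquisitionMetadata(
        pixel_size_xy=float(meta["pixel_size_xy"]),
        z_step=float(meta["z_step"]),
        frame_interval=float(meta["frame_interval"]),
        n_frames=n_frames,
        n_z=n_z,
        height=stack.shape[2],
        width=stack.shape[3],
        anterograde_axis=tuple(meta.get("anterograde_axis", (1.0, 0.0))),
    )
    return ImageSequence4D(np.asarray(stack, dtype=float), md)


def write_trajectories(
    trajectories: Iterable[Trajectory], path: str | Path, frame_interval: float = 1.0
) -> Path:
    """Write trajectories as a CSV (one row per track sample, sorted)."""
    path = Path(path)
    rows = []
    for traj in trajectories:
        for i, f in enumerate(traj.frames):
            rows.append(
                {
                    "track_id": traj.track_id,
                    "frame": int(f),
                    "t_s": float(f) * frame_interval,
                    "x_um": traj.positions[i, 0],
                    "y_um": traj.positions[i, 1],
                    "z_um": traj.positions[i, 2],
                    "intensity": traj.intensities[i],
                    "volume_vox": traj.volumes[i],
                }
            )
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    df = df.sort_values(["track_id", "frame"], kind="stable")
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read a trajectory CSV written by :func:`write_trajectories`.

    Rows are grouped by ``track_id`` and sorted by ``frame``; frame gaps are
    allowed and preserved (see :attr:`Trajectory.gaps`).
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns and c != "t_s"]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    for col in ("x_um", "y_um", "z_um"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric coordinate column {col!r}")
    out: list[Trajectory] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame", kind="stable")
        if grp["frame"].duplicated().any():
            dup = int(grp.loc[grp["frame"].duplicated(), "frame"].iloc[0])
            raise ValueError(f"duplicate timepoint: track {tid} frame {dup}")
        out.append(
            Trajectory(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(dtype=int),
                positions=grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float),
                volumes=grp["volume_vox"].to_numpy(dtype=float),
            )
        )
    return out
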
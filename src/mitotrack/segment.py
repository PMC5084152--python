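"""Particle segmentation: coarse probability-map thresholding plus
marker-controlled watershed, yielding per-frame detections.

The watershed is seeded by exactly the foreground markers found in the coarse
stage, so the number of segmented particles equals the number of markers — no
artificial splits or merges.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .config import PipelineConfig
from .core import AcquisitionMetadata, Detection, ImageSequence4D

__all__ = [
    "coarse_particle_mask",
    "find_markers",
    "watershed_segment",
    "extract_detections",
    "segment_frame",
    "segment_sequence",
]


def _min_volume(diameter_px: int, z_aniso: float, factor: float) -> int:
    # nominal particle half-diameter cubed, shrunk by the z anisotropy
    v = factor * (diameter_px / 2.0) ** 3 * min(1.0, z_aniso)
    return max(1, int(round(v)))


def coarse_particle_mask(
    pp_map: np.ndarray,
    threshold: float,
    *,
    diameter_px: int = 7,
    z_aniso: float = 1.0,
    min_volume_factor: float = 0.15,
) -> np.ndarray:
    """Threshold the probability map and drop components below a minimum volume."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    mask = np.asarray(pp_map) >= threshold
    min_vol = _min_volume(diameter_px, z_aniso, min_volume_factor)
    if min_vol > 1:
        mask = remove_small_objects(mask, max_size=min_vol - 1)
    return mask


def find_markers(
    pp_map: np.ndarray,
    mask: np.ndarray,
    threshold: float,
    *,
    diameter_px: int = 7,
) -> np.ndarray:
    """Foreground marker label image: probability-map local maxima inside the mask.

    Maxima are separated by at least half the particle diameter and must reach
    the coarse threshold; each marker gets a distinct positive label.
    """
    coords = peak_local_max(
        np.asarray(pp_map, dtype=float),
        min_distance=max(1, diameter_px // 2),
        threshold_abs=threshold,
        labels=mask.astype(int) if mask.any() else None,
        exclude_border=False,
    )
    markers = np.zeros(pp_map.shape, dtype=int)
    for i, c in enumerate(coords, start=1):
        markers[tuple(c)] = i
    return markers


def watershed_segment(
    volume: np.ndarray,
    mask: np.ndarray,
    markers: np.ndarray,
    *,
    relief: str = "intensity",
    pp_map: np.ndarray | None = None,
) -> np.ndarray:
    """Marker-controlled watershed restricted to the mask.

    The relief is the inverted (denoised) intensity by default; ``relief`` may
    instead be ``"pp"`` (inverted probability map) or ``"distance"`` (negated
    distance transform of the mask).  The resulting label count always equals
    the marker count and labels are relabelled contiguously 1..K.
    """
    markers = np.asarray(markers)
    mask = np.asarray(mask, dtype=bool)
    if ((markers > 0) & ~mask).any():
        raise ValueError("markers must lie inside the mask")
    n_markers = int(markers.max())
    if n_markers == 0:
        return np.zeros(mask.shape, dtype=int)
    if relief == "intensity":
        surface = -np.asarray(volume, dtype=float)
    elif relief == "pp":
        if pp_map is None:
            raise ValueError("relief='pp' requires pp_map")
        surface = -np.asarray(pp_map, dtype=float)
    elif relief == "distance":
        surface = -ndimage.distance_transform_edt(mask)
    else:
        raise ValueError(f"unknown relief {relief!r}")
    labels = watershed(surface, markers=markers, mask=mask)
    # relabel contiguously, preserving marker order
    out = np.zeros_like(labels)
    present = [l for l in range(1, n_markers + 1) if (labels == l).any()]
    for new, old in enumerate(present, start=1):
        out[labels == old] = new
    return out


def extract_detections(
    label_map: np.ndarray,
    volume: np.ndarray,
    metadata: AcquisitionMetadata,
    frame: int = 0,
) -> list[Detection]:
    """Intensity-weighted centroids and morphology summaries per label, in um."""
    label_map = np.asarray(label_map)
    volume = np.asarray(volume, dtype=float)
    if label_map.shape != volume.shape:
        raise ValueError("label_map and volume shapes differ")
    n = int(label_map.max())
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    centroids = ndimage.center_of_mass(volume, labels=label_map, index=idx)
    volumes = ndimage.sum_labels(np.ones_like(volume), labels=label_map, index=idx)
    totals = ndimage.sum_labels(volume, labels=label_map, index=idx)
    peaks = ndimage.maximum(volume, labels=label_map, index=idx)
    out = []
    for k, czyx in enumerate(centroids):
        xyz = metadata.voxel_to_um(np.asarray(czyx))
        out.append(
            Detection(
                frame=frame,
                centroid=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                volume=int(volumes[k]),
                total_intensity=float(totals[k]),
                peak_intensity=float(peaks[k]),
                label_id=k + 1,
            )
        )
    return out


def segment_frame(
    volume: np.ndarray,
    pp_map: np.ndarray,
    metadata: AcquisitionMetadata,
    config: PipelineConfig,
    frame: int = 0,
) -> tuple[np.ndarray, list[Detection]]:
    """Coarse mask -> markers -> watershed -> detections for one frame."""
    thr = config.threshold_for_frame(frame)
    z_aniso = metadata.pixel_size_xy / metadata.z_step
    mask = coarse_particle_mask(
        pp_map,
        thr,
        diameter_px=config.mito_diameter_px,
        z_aniso=z_aniso,
        min_volume_factor=config.min_volume_factor,
    )
    markers = find_markers(pp_map, mask, thr, diameter_px=config.mito_diameter_px)
    labels = watershed_segment(
        volume, mask, markers, relief=config.watershed_relief, pp_map=pp_map
    )
    return labels, extract_detections(labels, volume, metadata, frame)


def segment_sequence(
    seq: ImageSequence4D, pp_maps: np.ndarray, config: PipelineConfig | None = None
) -> list[list[Detection]]:
    """Per-frame detections for a whole (denoised) sequence."""
    cfg = config or PipelineConfig()
    out = []
    for t in range(seq.n_frames):
        _, dets = segment_frame(seq.intensities[t], pp_maps[t], seq.metadata, cfg, t)
        out.append(dets)
    return out
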
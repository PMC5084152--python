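"""Pipeline configuration: defaults, validation, JSON/YAML loading."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]

_DIAMETER_RANGE = (5, 13)


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass
class PipelineConfig:
    """User-settable parameters for tracking and motion analysis.

    Only a handful of parameters need tuning in practice: the average particle
    diameter in pixels, the segmentation threshold on the particle-probability
    map, the clustering (state) speed threshold, and the transient-analysis
    window size.
    """

    # segmentation
    mito_diameter_px: int = 7
    segmentation_threshold: float = 0.5
    #: optional per-frame overrides {frame_index: threshold}
    frame_thresholds: dict[int, float] = field(default_factory=dict)
    min_volume_factor: float = 0.15

    # motion analysis
    clustering_threshold_speed: float = 0.05  # um/s
    window_size: int = 16  # must be 2**k, k >= 2
    max_interpolated_fraction: float = 1.0  # windows with more are invalid if < 1

    # enhancement
    patch_radius: int = 1
    search_radius: int = 2
    nlm_h: float | None = None  # None -> tied to a robust noise estimate
    feature_mix: float = 1.0
    recompute_pp_after_denoise: bool = False

    # tracking
    # gate must absorb a full direction reversal of a ~1.5 um/s runner
    # between frames: ~2 * v * dt of prediction overshoot
    gating_distance_um: float = 5.0
    max_gap_frames: int = 3
    min_track_length_frames: int = 8
    feature_weight: float = 0.5
    confirm_hits: int = 2
    max_link_gap: int = 3
    max_link_dist_um: float = 5.0
    watershed_relief: str = "intensity"  # or "pp" / "distance"
    intensity_in_state: bool = True

    def __post_init__(self) -> None:
        lo, hi = _DIAMETER_RANGE
        if not lo <= int(self.mito_diameter_px) <= hi:
            raise ValueError(
                f"mito_diameter_px must be in [{lo}, {hi}], got {self.mito_diameter_px}"
            )
        if not 0.0 < float(self.segmentation_threshold) < 1.0:
            raise ValueError("segmentation_threshold must be in (0, 1)")
        for f, thr in self.frame_thresholds.items():
            if not 0.0 < float(thr) < 1.0:
                raise ValueError(f"frame threshold for frame {f} must be in (0, 1)")
        if not self.clustering_threshold_speed > 0:
            raise ValueError("clustering_threshold_speed must be > 0")
        if not (_is_power_of_two(int(self.window_size)) and self.window_size >= 4):
            raise ValueError(
                f"window_size must be a power of two >= 4, got {self.window_size}"
            )
        if self.patch_radius < 1 or self.search_radius < 1:
            raise ValueError("patch_radius and search_radius must be >= 1")
        if self.nlm_h is not None and not self.nlm_h > 0:
            raise ValueError("nlm_h must be > 0")
        if not self.gating_distance_um > 0:
            raise ValueError("gating_distance_um must be > 0")
        if self.max_gap_frames < 0 or self.min_track_length_frames < 1:
            raise ValueError("invalid tracking parameters")

    def threshold_for_frame(self, frame: int) -> float:
        return float(self.frame_thresholds.get(frame, self.segmentation_threshold))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a JSON or YAML file.

    Absent fields take their defaults; unknown keys are rejected to catch
    typos; invariants are validated on construction.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "frame_thresholds" in data and data["frame_thresholds"] is not None:
        data["frame_thresholds"] = {
            int(k): float(v) for k, v in dict(data["frame_thresholds"]).items()
        }
    return PipelineConfig(**data)
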
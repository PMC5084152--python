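"""End-to-end pipeline: enhance -> segment -> track -> analyze."""

from __future__ import annotations

import logging
import time

import numpy as np

from .config import PipelineConfig
from .core import ImageSequence4D, Trajectory
from .enhance import enhance_sequence
from .motion import StateSeries, analyze_trajectory
from .segment import segment_sequence
from .track import build_tracks, link_and_trim

__all__ = ["track_sequence", "analyze_trajectories"]

log = logging.getLogger(__name__)


def _timed(name: str, t0: float) -> None:
    log.info("%s finished in %.2f s", name, time.perf_counter() - t0)


def track_sequence(
    seq: ImageSequence4D, config: PipelineConfig | None = None
) -> list[Trajectory]:
    """Run particle enhancement, segmentation, tracking and linking/trimming."""
    cfg = config or PipelineConfig()
    t0 = time.perf_counter()
    denoised, pp_maps = enhance_sequence(seq, cfg)
    _timed("enhancement", t0)
    t0 = time.perf_counter()
    detections = segment_sequence(denoised, pp_maps, cfg)
    _timed("segmentation", t0)
    t0 = time.perf_counter()
    tracks = build_tracks(detections, cfg, seq.metadata)
    tracks = link_and_trim(
        tracks,
        max_link_gap=cfg.max_link_gap,
        max_link_dist=cfg.max_link_dist_um,
        min_length=cfg.min_track_length_frames,
    )
    _timed("tracking", t0)
    return tracks


def analyze_trajectories(
    trajectories: list[Trajectory],
    config: PipelineConfig | None = None,
    dt: float = 1.0,
    axis: np.ndarray | None = None,
) -> list[StateSeries]:
    """Motion-state series for every trajectory long enough to analyze."""
    cfg = config or PipelineConfig()
    t0 = time.perf_counter()
    out = []
    for traj in trajectories:
        _, series = analyze_trajectory(traj, cfg, axis=axis, dt=dt)
        out.append(series)
    _timed("motion analysis", t0)
    return out
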
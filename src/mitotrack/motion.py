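"""Transient-velocity decomposition and motion-state classification.

Each trajectory point is decomposed, inside a centred sliding window of N
positions, into a *sustained* velocity (the least-squares line-fit slope,
i.e. the short-term average velocity) and a *transient* speed (the mean
magnitude of the framewise-velocity deviations from that slope, i.e. motility
without net movement).  The (sustained, transient) plane is then split by a
single speed threshold into the four states:

    ST  sustained < theta and transient < theta   (truly stationary)
    DP  sustained < theta and transient >= theta  (wiggling in place)
    AR  sustained >= theta, signed component > 0  (anterograde run)
    RR  sustained >= theta, signed component <= 0 (retrograde run)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import Trajectory

__all__ = [
    "VelocitySample",
    "VelocityDecomposition",
    "StateSeries",
    "framewise_velocity",
    "decompose_window",
    "classify_point",
    "analyze_trajectory",
    "state_proportions_over_time",
    "states_to_dataframe",
]

log = logging.getLogger(__name__)

STATE_LABELS = ("ST", "DP", "AR", "RR")


@dataclass(frozen=True)
class VelocitySample:
    frame: int
    velocity: np.ndarray  # (3,) um/s


@dataclass(frozen=True)
class VelocityDecomposition:
    frame: int
    sustained_velocity: np.ndarray  # (3,) um/s, fitted slope
    sustained_signed_speed: float  # projection onto the anterograde axis
    sustained_speed: float  # magnitude of the slope vector
    transient_speed: float
    window: int
    valid: bool = True


@dataclass
class StateSeries:
    """Per-frame motion states (and decomposition scalars) for one trajectory."""

    track_id: int
    frames: np.ndarray
    states: np.ndarray  # '' where invalid
    valid: np.ndarray
    sustained_signed_speed: np.ndarray
    sustained_speed: np.ndarray
    transient_speed: np.ndarray

    def __post_init__(self) -> None:
        if (self.states[~self.valid] != "").any():
            raise ValueError("invalid frames must carry no state")


def framewise_velocity(traj: Trajectory, dt: float) -> list[VelocitySample]:
    """Finite-difference velocities v_i = (p_i - p_{i-1}) / dt, for i >= 1.

    The trajectory must be uniformly sampled (fill gaps first); a single-point
    trajectory is an error.
    """
    if len(traj) < 2:
        raise ValueError("trajectory must have at least 2 samples")
    if not traj.is_uniform():
        raise ValueError("trajectory has gaps; call fill_gaps() first")
    v = np.diff(traj.positions, axis=0) / dt
    return [
        VelocitySample(frame=int(traj.frames[i + 1]), velocity=v[i])
        for i in range(len(v))
    ]


def _ols_slope(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares slope of each column of y against t."""
    tc = t - t.mean()
    denom = float(tc @ tc)
    return (tc @ (y - y.mean(axis=0))) / denom


def decompose_window(
    traj: Trajectory,
    i: int,
    N: int,
    dt: float,
    axis: np.ndarray | None = None,
) -> VelocityDecomposition:
    """Decompose the velocity at sample index ``i`` over a centred N-window.

    The window spans samples ``i - N/2 .. i + N/2 - 1``; if it does not fully
    exist the result is flagged invalid.  Both components are translation
    invariant and the transient speed is exactly 0 on a perfect line.
    """
    if N < 4 or N & (N - 1):
        raise ValueError("window size must be a power of two >= 4")
    axis3 = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, dtype=float)
    lo, hi = i - N // 2, i + N // 2  # samples [lo, hi)
    if lo < 0 or hi > len(traj):
        return VelocityDecomposition(
            frame=int(traj.frames[i]) if 0 <= i < len(traj) else i,
            sustained_velocity=np.full(3, np.nan),
            sustained_signed_speed=np.nan,
            sustained_speed=np.nan,
            transient_speed=np.nan,
            window=N,
            valid=False,
        )
    pos = traj.positions[lo:hi]
    t = traj.frames[lo:hi].astype(float) * dt
    slope = _ols_slope(t, pos)
    v = np.diff(pos, axis=0) / dt  # N - 1 framewise velocities in the window
    transient = float(np.mean(np.linalg.norm(slope[None, :] - v, axis=1)))
    return VelocityDecomposition(
        frame=int(traj.frames[i]),
        sustained_velocity=slope,
        sustained_signed_speed=float(slope @ axis3),
        sustained_speed=float(np.linalg.norm(slope)),
        transient_speed=transient,
        window=N,
    )


def classify_point(dec: VelocityDecomposition, threshold: float) -> str:
    """Map one decomposition to ST / DP / AR / RR by the speed threshold."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    if not dec.valid:
        raise ValueError("cannot classify an invalid decomposition")
    if dec.sustained_speed < threshold:
        return "ST" if dec.transient_speed < threshold else "DP"
    if dec.sustained_signed_speed > 0:
        return "AR"
    if dec.sustained_signed_speed == 0.0:
        log.info(
            "frame %d: sustained motion purely off-axis; assigned RR", dec.frame
        )
    return "RR"


def analyze_trajectory(
    traj: Trajectory,
    config: PipelineConfig | None = None,
    axis: np.ndarray | None = None,
    dt: float = 1.0,
) -> tuple[list[VelocityDecomposition], StateSeries]:
    """Sliding-window decomposition and classification over one trajectory.

    Frames without a full window (the first N/2 and last N/2 - 1) are flagged
    invalid.  A trajectory shorter than the window yields an all-invalid
    series with a warning, not a failure.
    """
    cfg = config or PipelineConfig()
    N = cfg.window_size
    theta = cfg.clustering_threshold_speed
    traj = traj.fill_gaps()
    n = len(traj)
    if n < N:
        warnings.warn(
            f"trajectory {traj.track_id} shorter than window ({n} < {N}); "
            "no valid frames",
            stacklevel=2,
        )
    decs: list[VelocityDecomposition] = []
    states = np.full(n, "", dtype=object)
    valid = np.zeros(n, dtype=bool)
    sss = np.full(n, np.nan)
    ss = np.full(n, np.nan)
    ts = np.full(n, np.nan)
    for i in range(n):
        dec = decompose_window(traj, i, N, dt, axis)
        if dec.valid and cfg.max_interpolated_fraction < 1.0:
            frac = float(traj.interpolated[i - N // 2 : i + N // 2].mean())
            if frac > cfg.max_interpolated_fraction:
                dec = VelocityDecomposition(
                    dec.frame, dec.sustained_velocity, dec.sustained_signed_speed,
                    dec.sustained_speed, dec.transient_speed, N, valid=False,
                )
        decs.append(dec)
        if dec.valid:
            valid[i] = True
            states[i] = classify_point(dec, theta)
            sss[i] = dec.sustained_signed_speed
            ss[i] = dec.sustained_speed
            ts[i] = dec.transient_speed
    series = StateSeries(
        track_id=traj.track_id,
        frames=traj.frames.copy(),
        states=states,
        valid=valid,
        sustained_signed_speed=sss,
        sustained_speed=ss,
        transient_speed=ts,
    )
    return decs, series


def state_proportions_over_time(series: list[StateSeries]) -> pd.DataFrame:
    """Per-frame state fractions (summing to 1 over valid trajectories) and the
    mean sustained speed of running (AR/RR) points.
    """
    if not series:
        raise ValueError("need at least one state series")
    frames = np.unique(np.concatenate([s.frames for s in series]))
    rows = []
    any_valid = False
    for f in frames:
        counts = dict.fromkeys(STATE_LABELS, 0)
        run_speeds = []
        for s in series:
            k = np.searchsorted(s.frames, f)
            if k >= len(s.frames) or s.frames[k] != f or not s.valid[k]:
                continue
            counts[s.states[k]] += 1
            if s.states[k] in ("AR", "RR"):
                run_speeds.append(s.sustained_speed[k])
        n = sum(counts.values())
        if n == 0:
            continue
        any_valid = True
        row = {"frame": int(f), "n_valid": n}
        for lab in STATE_LABELS:
            row[f"p_{lab}"] = counts[lab] / n
        row["mean_run_speed"] = float(np.mean(run_speeds)) if run_speeds else np.nan
        rows.append(row)
    if not any_valid:
        raise ValueError("no valid frames in any series")
    return pd.DataFrame(rows)


def states_to_dataframe(series: list[StateSeries]) -> pd.DataFrame:
    """Long-format per-point table (the 2-D parameter-space scatter export)."""
    rows = []
    for s in series:
        for k in range(len(s.frames)):
            rows.append(
                {
                    "track_id": s.track_id,
                    "frame": int(s.frames[k]),
                    "sustained_signed_speed": s.sustained_signed_speed[k],
                    "sustained_speed": s.sustained_speed[k],
                    "transient_speed": s.transient_speed[k],
                    "state": s.states[k],
                    "valid": bool(s.valid[k]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "frame",
            "sustained_signed_speed",
            "sustained_speed",
            "transient_speed",
            "state",
            "valid",
        ],
    )
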
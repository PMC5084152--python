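"""Synthetic data: four-state particle motion model and noisy 4-D stack rendering.

Particles switch between four motion states — stationary (ST), dynamic pause
(DP), anterograde running (AR) and retrograde running (RR) — via a per-frame
Markov chain.  Runs advance at roughly 1 um/s along the anterograde axis; DP is
a zero-net oscillation about an anchor; ST holds position.  Trajectories are
rendered as anisotropic Gaussian blobs on parallel "groove" lines with
background, shot noise and exponential photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AcquisitionMetadata, ImageSequence4D, Trajectory

__all__ = [
    "STATES",
    "MotionModelParams",
    "ImagingParams",
    "GroundTruth",
    "simulate_state_sequence",
    "simulate_trajectory",
    "render_frame",
    "generate_dataset",
    "stationary_distribution",
]

STATES = ("ST", "DP", "AR", "RR")
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}

# Sticky defaults: ST long-lived, DP dwell ~8 frames (12 s at 1.5 s/frame),
# runs ~17 frames.  Rates are not measured anywhere; they are qualitative.
_DEFAULT_TRANSITION = np.array(
    [
        [0.970, 0.020, 0.005, 0.005],  # ST
        [0.050, 0.875, 0.0375, 0.0375],  # DP
        [0.020, 0.030, 0.940, 0.010],  # AR
        [0.020, 0.030, 0.010, 0.940],  # RR
    ]
)


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    w, v = np.linalg.eig(np.asarray(transition, dtype=float).T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class MotionModelParams:
    transition: np.ndarray = field(default_factory=lambda: _DEFAULT_TRANSITION.copy())
    run_speed_mean: float = 1.0  # um/s
    run_speed_sd: float = 0.2  # um/s, drawn once per run segment
    dp_oscillation_amplitude: float = 0.4  # um, stationary envelope of DP wobble
    dp_mean_duration: float = 12.0  # s, documentation of the default dwell
    axis_jitter_sd: float = 0.0  # um, off-axis (perpendicular + z) noise
    dp_ar1_rho: float = 0.3  # correlation of the DP oscillation process
    initial_distribution: np.ndarray | None = None  # default: stationary
    subframe_steps: int = 1  # >1 enables sub-frame direction switching

    def __post_init__(self) -> None:
        T = np.asarray(self.transition, dtype=float)
        if T.shape != (4, 4) or (T < 0).any():
            raise ValueError("transition must be a non-negative 4x4 matrix")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        self.transition = T
        if not self.run_speed_mean > 0:
            raise ValueError("run_speed_mean must be > 0")
        if not self.dp_mean_duration > 0:
            raise ValueError("dp_mean_duration must be > 0")
        if self.initial_distribution is not None:
            p = np.asarray(self.initial_distribution, dtype=float)
            if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("initial_distribution must be a length-4 simplex point")
            self.initial_distribution = p
        if self.subframe_steps < 1:
            raise ValueError("subframe_steps must be >= 1")


@dataclass
class ImagingParams:
    """Forward imaging model for rendering ground-truth tracks into stacks."""

    psf_sigma_xy: float = 0.35  # um
    psf_sigma_z: float = 0.75  # um
    background_level: float = 10.0
    peak_amplitude: float = 100.0
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    noise_sigma: float = 0.0  # used by the gaussian model
    bleach_rate: float = 0.0  # 1/s
    groove_spacing: float = 4.0  # um between parallel axon lines
    min_separation: float = 3.0  # um enforced between particles at all times

    def __post_init__(self) -> None:
        if not (self.psf_sigma_xy > 0 and self.psf_sigma_z > 0):
            raise ValueError("psf sigmas must be > 0")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class GroundTruth:
    """Paired truth for a simulated dataset."""

    states: np.ndarray  # (n_particles, n_frames) of int state indices
    positions: np.ndarray  # (n_particles, n_frames, 3) um, (x, y, z)
    motion_params: MotionModelParams
    seed: int

    @property
    def state_labels(self) -> np.ndarray:
        return np.array(STATES)[self.states]

    @property
    def n_particles(self) -> int:
        return self.states.shape[0]


def simulate_state_sequence(
    params: MotionModelParams,
    n_frames: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Markov-chain realization of the state labels, one per frame."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p0 = (
        params.initial_distribution
        if params.initial_distribution is not None
        else stationary_distribution(params.transition)
    )
    cum = np.cumsum(params.transition, axis=1)
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(4, p=p0)
    u = rng.random(n_frames - 1) if n_frames > 1 else np.empty(0)
    for i in range(1, n_frames):
        states[i] = int(np.searchsorted(cum[states[i - 1]], u[i - 1], side="right"))
    return states


def _perp_xy(axis3: np.ndarray) -> np.ndarray:
    return np.array([-axis3[1], axis3[0], 0.0])


def simulate_trajectory(
    states: np.ndarray,
    params: MotionModelParams,
    dt: float,
    seed: int | np.random.Generator,
    *,
    start: np.ndarray | None = None,
    axis: np.ndarray | None = None,
    track_id: int = 0,
) -> tuple[Trajectory, GroundTruth]:
    """Realize positions for a given per-frame state sequence.

    ST holds an anchor, DP oscillates about an anchor with zero net drift
    (an AR(1) process with stationary envelope ``dp_oscillation_amplitude``),
    AR/RR advance at a per-run constant speed along ``axis`` (default +x).
    ``axis_jitter_sd`` adds independent off-axis noise each frame.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    states = np.asarray(states)
    if states.dtype.kind in "US":
        states = np.array([_STATE_INDEX[s] for s in states])
    n = len(states)
    axis3 = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, dtype=float)
    axis3 = axis3 / np.linalg.norm(axis3)
    perp = _perp_xy(axis3)
    zhat = np.array([0.0, 0.0, 1.0])
    pos = np.zeros((n, 3))
    pos[0] = np.zeros(3) if start is None else np.asarray(start, dtype=float)

    sub = max(1, int(params.subframe_steps))
    amp = params.dp_oscillation_amplitude / 2.0  # stationary sd of the wobble
    rho = params.dp_ar1_rho
    anchor = pos[0].copy()
    osc = 0.0
    run_speed = _draw_speed(params, rng)
    on_axis = pos[0].copy()

    for i in range(1, n):
        s, sp = states[i], states[i - 1]
        if s != sp:
            if s in (0, 1):  # entering ST/DP: anchor where we are
                anchor = on_axis.copy()
                osc = 0.0
            if s in (2, 3):
                if sp in (0, 1):
                    on_axis = anchor + osc * axis3
                run_speed = _draw_speed(params, rng)
        if s == 0:  # ST
            on_axis = anchor
        elif s == 1:  # DP
            osc = rho * osc + np.sqrt(1.0 - rho**2) * amp * rng.standard_normal()
            on_axis = anchor + osc * axis3
        else:  # AR / RR
            sign = 1.0 if s == 2 else -1.0
            if sub == 1:
                on_axis = on_axis + sign * run_speed * dt * axis3
            else:
                # optional sub-frame stochastic direction switching
                step = 0.0
                d = sign
                for _ in range(sub):
                    step += d * run_speed * dt / sub
                    if rng.random() < 0.1:
                        d = -d
                on_axis = on_axis + step * axis3
        pos[i] = on_axis
    # off-axis jitter applied to every observed frame (including the first)
    if params.axis_jitter_sd > 0:
        jit = rng.standard_normal((n, 2)) * params.axis_jitter_sd
        pos = pos + jit[:, :1] * perp + jit[:, 1:] * zhat

    traj = Trajectory(
        track_id=track_id,
        frames=np.arange(n),
        positions=pos,
        intensities=np.ones(n),
        volumes=np.ones(n),
    )
    truth = GroundTruth(
        states=states[None, :],
        positions=pos[None, :, :],
        motion_params=params,
        seed=-1,
    )
    return traj, truth


def _draw_speed(params: MotionModelParams, rng: np.random.Generator) -> float:
    s = params.run_speed_mean + params.run_speed_sd * rng.standard_normal()
    return max(s, 0.05 * params.run_speed_mean)


def render_frame(
    positions: np.ndarray,
    params: ImagingParams,
    metadata: AcquisitionMetadata,
    t: int,
    seed: int | np.random.Generator | None = None,
    *,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Render one 3-D ``(z, y, x)`` volume from particle positions in um.

    The noiseless image is a sum of anisotropic Gaussian blobs whose amplitude
    decays as ``exp(-bleach_rate * t * frame_interval)``, plus a constant
    background.  Positions outside the field are clipped onto it.
    """
    md = metadata
    nz, ny, nx = md.n_z, md.height, md.width
    vol = np.full((nz, ny, nx), float(params.background_level))
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size:
        lim = np.array(
            [(nx - 1) * md.pixel_size_xy, (ny - 1) * md.pixel_size_xy, (nz - 1) * md.z_step]
        )
        positions = np.clip(positions, 0.0, lim)
    decay = np.exp(-params.bleach_rate * t * md.frame_interval)
    sig_vox = np.array(
        [
            params.psf_sigma_z / md.z_step,
            params.psf_sigma_xy / md.pixel_size_xy,
            params.psf_sigma_xy / md.pixel_size_xy,
        ]
    )
    ext = np.maximum(np.ceil(4 * sig_vox).astype(int), 1)
    for k, p in enumerate(positions):
        amp = float(amplitudes[k]) if amplitudes is not None else params.peak_amplitude
        czyx = md.um_to_voxel(p)  # fractional (z, y, x)
        c = np.round(czyx).astype(int)
        lo = np.maximum(c - ext, 0)
        hi = np.minimum(c + ext + 1, [nz, ny, nx])
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        d2 = (
            ((zz - czyx[0]) / sig_vox[0]) ** 2
            + ((yy - czyx[1]) / sig_vox[1]) ** 2
            + ((xx - czyx[2]) / sig_vox[2]) ** 2
        )
        vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * decay * np.exp(-0.5 * d2)
    if params.noise_model == "poisson":
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        vol = rng.poisson(vol).astype(float)
    elif params.noise_model == "gaussian" and params.noise_sigma > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        vol = np.maximum(vol + params.noise_sigma * rng.standard_normal(vol.shape), 0.0)
    return vol


def _groove_lines(metadata: AcquisitionMetadata, spacing_um: float) -> np.ndarray:
    """y positions (um) of parallel groove lines centred in the field."""
    h_um = (metadata.height - 1) * metadata.pixel_size_xy
    margin = max(2.0 * metadata.pixel_size_xy, 0.05 * h_um)
    n_lines = max(1, int((h_um - 2 * margin) // spacing_um) + 1)
    used = (n_lines - 1) * spacing_um
    start = (h_um - used) / 2.0
    return start + np.arange(n_lines) * spacing_um


def generate_dataset(
    n_particles: int,
    n_frames: int,
    motion: MotionModelParams,
    imaging: ImagingParams,
    metadata: AcquisitionMetadata,
    seed: int,
    *,
    max_tries: int = 300,
) -> tuple[ImageSequence4D, GroundTruth]:
    """Simulate particles on groove lines and render the full noisy stack.

    Particle trajectories are drawn with rejection so that every pair stays at
    least ``imaging.min_separation`` um apart in every frame; raises if the
    field cannot hold the requested count at that spacing.
    """
    if n_frames != metadata.n_frames:
        raise ValueError("metadata.n_frames must equal n_frames")
    rng = np.random.default_rng(seed)
    md = metadata
    dt = md.frame_interval
    w_um = (md.width - 1) * md.pixel_size_xy
    lines = _groove_lines(md, imaging.groove_spacing)
    z_mid = (md.n_z - 1) * md.z_step / 2.0
    margin = 4.0 * imaging.psf_sigma_xy

    all_pos = np.zeros((n_particles, n_frames, 3))
    all_states = np.zeros((n_particles, n_frames), dtype=int)
    accepted = 0
    for k in range(n_particles):
        ok = False
        for _ in range(max_tries):
            y = lines[rng.integers(len(lines))]
            x0 = margin + rng.random() * max(w_um - 2 * margin, 1e-6)
            states = simulate_state_sequence(motion, n_frames, rng)
            traj, _ = simulate_trajectory(
                states, motion, dt, rng, start=np.array([x0, y, z_mid])
            )
            cand = traj.positions
            if accepted:
                dmin = np.min(
                    np.linalg.norm(all_pos[:accepted] - cand[None], axis=-1)
                )
                if dmin < imaging.min_separation:
                    continue
            if cand[:, 0].min() < 0 or cand[:, 0].max() > w_um:
                continue
            all_pos[k] = cand
            all_states[k] = states
            accepted += 1
            ok = True
            break
        if not ok:
            raise ValueError(
                f"field too small for {n_particles} particles at "
                f"min separation {imaging.min_separation} um (placed {accepted})"
            )

    stack = np.empty((n_frames, md.n_z, md.height, md.width))
    for t in range(n_frames):
        stack[t] = render_frame(all_pos[:, t], imaging, md, t, rng)
    seq = ImageSequence4D(stack, md)
    truth = GroundTruth(states=all_states, positions=all_pos, motion_params=motion, seed=seed)
    return seq, truth
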
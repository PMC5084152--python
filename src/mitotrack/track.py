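"""Particle tracking: an interacting-multiple-model (IMM) Kalman filter bank,
globally optimal frame-to-frame assignment, and trajectory linking/trimming.

Three motion models are run in parallel per track — random walk, first-order
(constant velocity) and second-order (constant acceleration) linear motion —
over a shared 10-dimensional state (position, velocity, acceleration, each
3-D, plus intensity).  Model probabilities are mixed Bayesian-style each
frame, so the filter switches to whichever model currently explains the
motion best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import PipelineConfig
from .core import AcquisitionMetadata, Detection, Trajectory

__all__ = [
    "MotionModel",
    "IMMState",
    "default_models",
    "default_model_transition",
    "imm_predict",
    "imm_update",
    "assign_detections",
    "Assignment",
    "build_tracks",
    "link_and_trim",
]

_DIM = 10  # x y z vx vy vz ax ay az I
_POS = slice(0, 3)
_VEL = slice(3, 6)
_ACC = slice(6, 9)
_INT = 9


@dataclass(frozen=True)
class MotionModel:
    """One member of the filter bank.

    ``order`` 0 is a position random walk, 1 constant velocity, 2 constant
    acceleration.  Process-noise intensities are in physical units (um, s).
    """

    name: str
    order: int
    q_pos: float = 0.05  # um, per-step position diffusion (random model)
    q_vel: float = 0.5  # um/s per step velocity diffusion
    q_acc: float = 0.3  # um/s^2 per step
    q_int: float = 0.05  # relative intensity drift per step

    def transition(self, dt: float) -> np.ndarray:
        F = np.eye(_DIM)
        if self.order == 0:
            F[_VEL, _VEL] = 0.0
            np.fill_diagonal(F[3:6, 3:6], 0.0)
            np.fill_diagonal(F[6:9, 6:9], 0.0)
        elif self.order >= 1:
            for k in range(3):
                F[k, 3 + k] = dt
            if self.order == 1:
                np.fill_diagonal(F[6:9, 6:9], 0.0)
            else:
                for k in range(3):
                    F[k, 6 + k] = 0.5 * dt * dt
                    F[3 + k, 6 + k] = dt
        return F

    def process_noise(self, dt: float) -> np.ndarray:
        Q = np.zeros((_DIM, _DIM))
        if self.order == 0:
            np.fill_diagonal(Q[0:3, 0:3], (self.q_pos) ** 2 * dt)
        else:
            # white-noise acceleration / jerk style, dominant terms only
            np.fill_diagonal(Q[0:3, 0:3], (0.5 * self.q_vel * dt * dt) ** 2)
            np.fill_diagonal(Q[3:6, 3:6], (self.q_vel * dt) ** 2)
            if self.order == 2:
                np.fill_diagonal(Q[6:9, 6:9], (self.q_acc * dt) ** 2)
        Q[_INT, _INT] = (self.q_int) ** 2 * dt
        return Q


def default_models() -> tuple[MotionModel, ...]:
    return (
        MotionModel("random", 0),
        MotionModel("linear1", 1),
        MotionModel("linear2", 2),
    )


def default_model_transition(n: int = 3, stay: float = 0.90) -> np.ndarray:
    """Mildly sticky model-switching matrix (0.90 self, rest spread evenly)."""
    off = (1.0 - stay) / (n - 1) if n > 1 else 0.0
    P = np.full((n, n), off)
    np.fill_diagonal(P, stay)
    return P


def observation_matrix(with_intensity: bool = True) -> np.ndarray:
    H = np.zeros((4 if with_intensity else 3, _DIM))
    H[0, 0] = H[1, 1] = H[2, 2] = 1.0
    if with_intensity:
        H[3, _INT] = 1.0
    return H


@dataclass
class IMMState:
    """Bank of per-model Kalman states plus model probabilities."""

    means: np.ndarray  # (M, 10)
    covs: np.ndarray  # (M, 10, 10)
    mu: np.ndarray  # (M,) model probabilities, a simplex point
    model_transition: np.ndarray  # (M, M) row-stochastic
    models: tuple[MotionModel, ...] = field(default_factory=default_models)

    def __post_init__(self) -> None:
        M = len(self.models)
        self.means = np.asarray(self.means, dtype=float).reshape(M, _DIM)
        self.covs = np.asarray(self.covs, dtype=float).reshape(M, _DIM, _DIM)
        self.mu = np.asarray(self.mu, dtype=float)
        self.model_transition = np.asarray(self.model_transition, dtype=float)
        if self.mu.shape != (M,) or (self.mu < -1e-12).any():
            raise ValueError("mu must be a non-negative length-M vector")
        if abs(self.mu.sum() - 1.0) > 1e-9:
            raise ValueError("mu must sum to 1")
        if not np.allclose(self.model_transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("model transition rows must sum to 1")

    @property
    def combined_mean(self) -> np.ndarray:
        return np.einsum("m,md->d", self.mu, self.means)

    @property
    def combined_cov(self) -> np.ndarray:
        xc = self.combined_mean
        out = np.zeros((_DIM, _DIM))
        for m in range(len(self.models)):
            d = (self.means[m] - xc)[:, None]
            out += self.mu[m] * (self.covs[m] + d @ d.T)
        return out

    @property
    def position(self) -> np.ndarray:
        return self.combined_mean[_POS]

    @property
    def intensity(self) -> float:
        return float(self.combined_mean[_INT])

    @classmethod
    def from_detection(
        cls,
        det: Detection,
        *,
        sigma_pos: float,
        models: tuple[MotionModel, ...] | None = None,
        model_transition: np.ndarray | None = None,
        sigma_vel: float = 1.0,
        sigma_acc: float = 0.5,
    ) -> "IMMState":
        models = models or default_models()
        M = len(models)
        x0 = np.zeros(_DIM)
        x0[_POS] = det.position
        x0[_INT] = det.total_intensity
        P0 = np.zeros((_DIM, _DIM))
        np.fill_diagonal(P0[0:3, 0:3], sigma_pos**2)
        np.fill_diagonal(P0[3:6, 3:6], sigma_vel**2)
        np.fill_diagonal(P0[6:9, 6:9], sigma_acc**2)
        P0[_INT, _INT] = max((0.2 * det.total_intensity) ** 2, 1e-6)
        return cls(
            means=np.tile(x0, (M, 1)),
            covs=np.tile(P0, (M, 1, 1)),
            mu=np.full(M, 1.0 / M),
            model_transition=(
                model_transition
                if model_transition is not None
                else default_model_transition(M)
            ),
            models=models,
        )


def imm_predict(state: IMMState, dt: float) -> IMMState:
    """IMM time update: model mixing followed by per-model Kalman prediction.

    The returned state's ``mu`` holds the predicted model probabilities
    (``Pi' mu``); the combined estimate is their weighted mean.
    """
    M = len(state.models)
    Pi = state.model_transition
    c = Pi.T @ state.mu  # predicted model probabilities
    # mixing weights mu_{i|j}
    W = np.empty((M, M))
    for j in range(M):
        if c[j] > 1e-300:
            W[:, j] = Pi[:, j] * state.mu / c[j]
        else:
            W[:, j] = 1.0 / M
    mixed_means = np.einsum("ij,id->jd", W, state.means)
    mixed_covs = np.zeros_like(state.covs)
    for j in range(M):
        for i in range(M):
            d = (state.means[i] - mixed_means[j])[:, None]
            mixed_covs[j] += W[i, j] * (state.covs[i] + d @ d.T)
    means = np.empty_like(state.means)
    covs = np.empty_like(state.covs)
    for j, model in enumerate(state.models):
        F = model.transition(dt)
        Q = model.process_noise(dt)
        means[j] = F @ mixed_means[j]
        covs[j] = F @ mixed_covs[j] @ F.T + Q
    return IMMState(means, covs, c, Pi, state.models)


def _gauss_loglik(y: np.ndarray, S: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("innovation covariance not positive definite")
    k = len(y)
    return float(-0.5 * (k * np.log(2 * np.pi) + logdet + y @ np.linalg.solve(S, y)))


def imm_update(
    state: IMMState,
    measurement: np.ndarray,
    R: np.ndarray,
    H: np.ndarray | None = None,
) -> IMMState:
    """IMM measurement update with model-probability reweighting.

    ``measurement`` is ``(x, y, z[, intensity])``; per-model Gaussian
    likelihoods of the innovation reweight the predicted model probabilities.
    """
    z = np.asarray(measurement, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("measurement must be finite")
    if H is None:
        H = observation_matrix(with_intensity=(len(z) == 4))
    M = len(state.models)
    means = np.empty_like(state.means)
    covs = np.empty_like(state.covs)
    loglik = np.empty(M)
    I = np.eye(_DIM)
    for m in range(M):
        x, P = state.means[m], state.covs[m]
        S = H @ P @ H.T + R
        y = z - H @ x
        loglik[m] = _gauss_loglik(y, S)
        K = np.linalg.solve(S.T, (P @ H.T).T).T
        means[m] = x + K @ y
        A = I - K @ H
        covs[m] = A @ P @ A.T + K @ R @ K.T  # Joseph form
    w = state.mu * np.exp(loglik - loglik.max())
    total = w.sum()
    mu = w / total if total > 0 else np.full(M, 1.0 / M)
    return IMMState(means, covs, mu, state.model_transition, state.models)


@dataclass
class Assignment:
    """Result of one frame's track-to-detection matching."""

    matches: list[tuple[int, int]]  # (track index, detection index)
    births: list[int]  # unmatched detection indices
    misses: list[int]  # unmatched track indices
    total_cost: float


_BIG = 1e9


def assign_detections(
    predictions: list[dict],
    detections: list[Detection],
    gate: float,
    feature_weight: float = 0.5,
) -> Assignment:
    """Globally optimal one-to-one matching of predictions to detections.

    Each prediction is a dict with ``position`` (um), optional ``S`` (3x3
    position innovation covariance, enabling Mahalanobis costs), ``intensity``
    and ``volume``.  Pairs farther apart than ``gate`` (Euclidean, um) are
    forbidden; leftover detections become births, leftover tracks misses.
    """
    if not gate > 0:
        raise ValueError("gate must be > 0")
    nt, nd = len(predictions), len(detections)
    if nt == 0 or nd == 0:
        return Assignment([], list(range(nd)), list(range(nt)), 0.0)
    C = np.full((nt, nd), _BIG)
    for i, pred in enumerate(predictions):
        p = np.asarray(pred["position"], dtype=float)
        S = pred.get("S")
        Sinv = None
        if S is not None:
            try:
                Sinv = np.linalg.inv(S)
            except np.linalg.LinAlgError:
                Sinv = None
        for j, det in enumerate(detections):
            d = det.position - p
            eucl = float(np.linalg.norm(d))
            if eucl > gate:
                continue
            dist = float(np.sqrt(d @ Sinv @ d)) if Sinv is not None else eucl
            cost = dist
            if feature_weight > 0:
                fi = _rel_mismatch(pred.get("intensity"), det.total_intensity)
                fv = _rel_mismatch(pred.get("volume"), det.volume)
                cost += feature_weight * 0.5 * (fi + fv)
            C[i, j] = cost
    rows, cols = linear_sum_assignment(C)
    matches, total = [], 0.0
    matched_t, matched_d = set(), set()
    for i, j in zip(rows, cols):
        if C[i, j] < _BIG / 2:
            matches.append((int(i), int(j)))
            matched_t.add(int(i))
            matched_d.add(int(j))
            total += float(C[i, j])
    births = [j for j in range(nd) if j not in matched_d]
    misses = [i for i in range(nt) if i not in matched_t]
    return Assignment(matches, births, misses, total)


def _rel_mismatch(a: float | None, b: float) -> float:
    if a is None:
        return 0.0
    denom = 0.5 * (abs(a) + abs(b))
    return abs(a - b) / denom if denom > 0 else 0.0


class _Track:
    __slots__ = ("track_id", "state", "frames", "positions", "intensities",
                 "volumes", "misses", "hits", "confirmed")

    def __init__(self, track_id: int, state: IMMState, det: Detection):
        self.track_id = track_id
        self.state = state
        self.frames = [det.frame]
        self.positions = [det.position]
        self.intensities = [det.total_intensity]
        self.volumes = [float(det.volume)]
        self.misses = 0
        self.hits = 1
        self.confirmed = False

    def to_trajectory(self) -> Trajectory:
        return Trajectory(
            track_id=self.track_id,
            frames=np.asarray(self.frames),
            positions=np.asarray(self.positions),
            intensities=np.asarray(self.intensities),
            volumes=np.asarray(self.volumes),
        )


def build_tracks(
    detections_per_frame: list[list[Detection]],
    config: PipelineConfig,
    metadata: AcquisitionMetadata,
) -> list[Trajectory]:
    """Frame-sequential predict / assign / update loop over all detections.

    Unassigned detections start new tracks; tracks coast (prediction only)
    through up to ``max_gap_frames`` consecutive misses and are terminated
    after that.  Every track is returned, including unconfirmed short ones —
    trimming is :func:`link_and_trim`'s job.
    """
    if not detections_per_frame:
        raise ValueError("need at least one frame")
    cfg = config
    dt = metadata.frame_interval
    sigma_pos = 0.5 * metadata.pixel_size_xy
    with_int = cfg.intensity_in_state
    H = observation_matrix(with_intensity=with_int)
    models = default_models()
    Pi = default_model_transition(len(models))

    active: list[_Track] = []
    done: list[_Track] = []
    next_id = 0

    for frame, dets in enumerate(detections_per_frame):
        # --- predict
        preds: list[IMMState] = []
        pred_info: list[dict] = []
        for tr in active:
            ps = imm_predict(tr.state, dt)
            preds.append(ps)
            Ppos = ps.combined_cov[0:3, 0:3] + sigma_pos**2 * np.eye(3)
            pred_info.append(
                {
                    "position": ps.position,
                    "S": Ppos,
                    "intensity": ps.intensity,
                    "volume": tr.volumes[-1],
                }
            )
        # --- assign
        asg = assign_detections(
            pred_info, dets, cfg.gating_distance_um, cfg.feature_weight
        )
        # --- update matched
        for ti, dj in asg.matches:
            tr, det = active[ti], dets[dj]
            z = np.concatenate([det.position, [det.total_intensity]]) if with_int else det.position
            R = np.eye(len(z)) * sigma_pos**2
            if with_int:
                R[-1, -1] = max((0.1 * det.total_intensity) ** 2, 1e-6)
            tr.state = imm_update(preds[ti], z, R, H)
            tr.frames.append(frame)
            tr.positions.append(det.position)
            tr.intensities.append(det.total_intensity)
            tr.volumes.append(float(det.volume))
            tr.misses = 0
            tr.hits += 1
            if tr.hits >= cfg.confirm_hits:
                tr.confirmed = True
        # --- coast / terminate missed
        survivors: list[_Track] = []
        for ti in range(len(active)):
            tr = active[ti]
            if any(m[0] == ti for m in asg.matches):
                survivors.append(tr)
                continue
            tr.state = preds[ti]
            tr.misses += 1
            if tr.misses > cfg.max_gap_frames:
                done.append(tr)
            else:
                survivors.append(tr)
        active = survivors
        # --- births
        for dj in asg.births:
            det = dets[dj]
            st = IMMState.from_detection(
                det, sigma_pos=sigma_pos, models=models, model_transition=Pi
            )
            active.append(_Track(next_id, st, det))
            next_id += 1

    done.extend(active)
    done.sort(key=lambda t: t.track_id)
    return [t.to_trajectory() for t in done]


def link_and_trim(
    tracks: list[Trajectory],
    max_link_gap: int = 3,
    max_link_dist: float = 3.0,
    min_length: int = 8,
) -> list[Trajectory]:
    """Greedy cost-ordered end-to-start linking, gap interpolation and trimming.

    Track pairs with a temporal gap in ``(0, max_link_gap]`` whose predicted
    end position lies within ``max_link_dist`` um of the other track's start
    are linked lowest-cost-first (ties broken by earliest start frame, so the
    output is deterministic); no two links share a track end.  Linked and
    internal gaps are filled by linear interpolation and flagged.  Tracks
    spanning fewer than ``min_length`` frames are removed.
    """
    if max_link_gap < 1 or max_link_dist <= 0 or min_length < 1:
        raise ValueError("parameters must be positive")
    tracks = sorted(tracks, key=lambda t: (t.start_frame, t.track_id))
    n = len(tracks)

    def _extrapolate(tr: Trajectory, to_frame: int) -> np.ndarray:
        if len(tr) >= 2:
            k = min(3, len(tr) - 1)
            v = (tr.positions[-1] - tr.positions[-1 - k]) / (
                tr.frames[-1] - tr.frames[-1 - k]
            )
        else:
            v = np.zeros(3)
        return tr.positions[-1] + v * (to_frame - tr.frames[-1])

    candidates = []
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            gap = tracks[b].start_frame - tracks[a].end_frame
            if not 0 < gap <= max_link_gap:
                continue
            pred = _extrapolate(tracks[a], tracks[b].start_frame)
            dist = float(np.linalg.norm(pred - tracks[b].positions[0]))
            if dist <= max_link_dist:
                candidates.append((dist, tracks[a].start_frame, a, b))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))

    succ: dict[int, int] = {}
    used_start: set[int] = set()
    for _, _, a, b in candidates:
        if a in succ or b in used_start:
            continue
        succ[a] = b
        used_start.add(b)

    heads = [i for i in range(n) if i not in used_start]
    merged: list[Trajectory] = []
    for h in heads:
        chain = [h]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        parts = [tracks[i] for i in chain]
        frames = np.concatenate([p.frames for p in parts])
        pos = np.concatenate([p.positions for p in parts])
        inten = np.concatenate([p.intensities for p in parts])
        vols = np.concatenate([p.volumes for p in parts])
        interp = np.concatenate([p.interpolated for p in parts])
        traj = Trajectory(parts[0].track_id, frames, pos, inten, vols, interp)
        merged.append(traj.fill_gaps())

    out = [t for t in merged if t.end_frame - t.start_frame + 1 >= min_length]
    out.sort(key=lambda t: t.track_id)
    return out
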
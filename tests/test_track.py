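from itertools import permutations

import numpy as np
import pytest

from mitotrack.config import PipelineConfig
from mitotrack.core import AcquisitionMetadata, Detection, Trajectory
from mitotrack.track import (
    IMMState,
    MotionModel,
    assign_detections,
    build_tracks,
    default_model_transition,
    default_models,
    imm_predict,
    imm_update,
    link_and_trim,
    observation_matrix,
)


def _det(frame, pos, intensity=100.0, volume=20):
    return Detection(
        frame=frame, centroid=tuple(pos), volume=volume,
        total_intensity=intensity, peak_intensity=intensity / 10, label_id=1,
    )


def _single_model_state(model, x0, P0):
    return IMMState(
        means=x0[None], covs=P0[None], mu=np.array([1.0]),
        model_transition=np.array([[1.0]]), models=(model,),
    )


def plain_kalman(x, P, F, Q, H, R, zs):
    """Textbook Kalman filter: the reduction oracle for a single-model IMM."""
    out = []
    for z in zs:
        x = F @ x
        P = F @ P @ F.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (z - H @ x)
        P = (np.eye(len(x)) - K @ H) @ P
        out.append((x.copy(), P.copy()))
    return out


class TestIMMReduction:
    def test_single_model_imm_equals_plain_kalman(self, rng):
        """100 random steps: single-model IMM == plain KF to 1e-12."""
        model = MotionModel("linear1", 1)
        dt = 1.5
        F, Q = model.transition(dt), model.process_noise(dt)
        H = observation_matrix(True)
        R = np.diag([0.01, 0.01, 0.01, 1.0])
        x0 = np.zeros(10)
        x0[9] = 100.0
        P0 = np.eye(10)
        zs = [np.concatenate([rng.normal(0, 1, 3), [100 + rng.normal(0, 1)]])
              for _ in range(100)]
        state = _single_model_state(model, x0, P0)
        oracle = plain_kalman(x0.copy(), P0.copy(), F, Q, H, R, zs)
        for z, (ox, oP) in zip(zs, oracle):
            state = imm_predict(state, dt)
            state = imm_update(state, z, R, H)
            np.testing.assert_allclose(state.means[0], ox, atol=1e-12)
            np.testing.assert_allclose(state.covs[0], oP, atol=1e-12)


class TestIMMPredict:
    def test_linear1_arithmetic(self):
        model = MotionModel("linear1", 1, q_vel=0.0, q_int=0.0)
        x0 = np.zeros(10)
        x0[3] = 1.0  # vx = 1 um/s
        state = _single_model_state(model, x0, np.eye(10) * 0.0)
        pred = imm_predict(state, dt=1.5)
        assert pred.means[0][0] == pytest.approx(1.5, abs=1e-12)

    def test_random_walk_covariance_inflation_exact(self):
        model = MotionModel("random", 0, q_pos=0.1, q_int=0.0)
        x0 = np.zeros(10)
        x0[0:3] = [1.0, 2.0, 3.0]
        P0 = np.eye(10) * 0.5
        state = _single_model_state(model, x0, P0)
        pred = imm_predict(state, dt=2.0)
        np.testing.assert_allclose(pred.means[0][0:3], [1.0, 2.0, 3.0])
        # position covariance inflated by exactly q_pos^2 * dt
        np.testing.assert_allclose(
            np.diag(pred.covs[0])[0:3], 0.5 + 0.1**2 * 2.0, atol=1e-12
        )

    def test_predicted_mu_is_pi_transpose_mu(self):
        models = default_models()
        Pi = default_model_transition(3)
        mu = np.array([0.6, 0.3, 0.1])
        state = IMMState(
            means=np.zeros((3, 10)), covs=np.tile(np.eye(10), (3, 1, 1)),
            mu=mu, model_transition=Pi, models=models,
        )
        pred = imm_predict(state, 1.0)
        np.testing.assert_allclose(pred.mu, Pi.T @ mu)


class TestIMMUpdate:
    def test_equal_likelihoods_leave_mu_unchanged(self):
        models = default_models()
        x0 = np.zeros(10)
        x0[9] = 50.0
        state = IMMState(
            means=np.tile(x0, (3, 1)), covs=np.tile(np.eye(10), (3, 1, 1)),
            mu=np.array([0.5, 0.3, 0.2]),
            model_transition=default_model_transition(3), models=models,
        )
        H = observation_matrix(True)
        z = H @ x0  # exactly at every model's prediction
        upd = imm_update(state, z, np.eye(4) * 0.1, H)
        np.testing.assert_allclose(upd.mu, [0.5, 0.3, 0.2], atol=1e-12)

    def test_mu_stays_on_simplex(self, rng):
        state = _fresh_imm()
        H = observation_matrix(True)
        R = np.diag([0.01] * 3 + [1.0])
        for i in range(30):
            state = imm_predict(state, 1.5)
            z = np.array([i * 0.1, 0, 0, 100.0]) + rng.normal(0, 0.05, 4)
            state = imm_update(state, z, R, H)
            assert (state.mu >= 0).all()
            assert state.mu.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_velocity_track_selects_linear1(self):
        mu = _run_imm_on_track(
            lambda i: np.array([1.5 * i * 1.0, 0.0, 0.0]), n=50, noise=0.0
        )
        assert mu[1] > 0.5
        assert _bayes_factor_argmax(
            lambda i: np.array([1.5 * i * 1.0, 0.0, 0.0]), n=50, noise=0.0
        ) == 1

    def test_stationary_noisy_track_selects_random(self):
        rng = np.random.default_rng(0)
        track = lambda i: rng.normal(0, 0.05, 3)
        pts = [track(i) for i in range(50)]
        mu = _run_imm_on_track(lambda i: pts[i], n=50, noise=0.0)
        assert int(np.argmax(mu)) == 0
        assert _bayes_factor_argmax(lambda i: pts[i], n=50, noise=0.0) == 0


def _fresh_imm(intensity=100.0):
    det = _det(0, [0, 0, 0], intensity=intensity)
    return IMMState.from_detection(det, sigma_pos=0.1)


def _run_imm_on_track(pos_fn, n, noise):
    state = _fresh_imm()
    H = observation_matrix(True)
    R = np.diag([0.01] * 3 + [1.0])
    for i in range(1, n):
        state = imm_predict(state, 1.5)
        z = np.concatenate([pos_fn(i), [100.0]])
        state = imm_update(state, z, R, H)
    return state.mu


def _bayes_factor_argmax(pos_fn, n, noise):
    """Oracle: total log-likelihood of each fixed single-model Kalman filter."""
    H = observation_matrix(True)
    R = np.diag([0.01] * 3 + [1.0])
    scores = []
    for model in default_models():
        F, Q = model.transition(1.5), model.process_noise(1.5)
        x = np.zeros(10)
        x[9] = 100.0
        P = np.eye(10) * 0.01
        P[3:9, 3:9] = np.eye(6)
        total = 0.0
        for i in range(1, n):
            x = F @ x
            P = F @ P @ F.T + Q
            z = np.concatenate([pos_fn(i), [100.0]])
            S = H @ P @ H.T + R
            y = z - H @ x
            total += -0.5 * (np.linalg.slogdet(S)[1] + y @ np.linalg.solve(S, y))
            K = P @ H.T @ np.linalg.inv(S)
            x = x + K @ y
            P = (np.eye(10) - K @ H) @ P
        scores.append(total)
    return int(np.argmax(scores))


class TestAssignment:
    def test_track_at_origin_matches_detection_at_origin(self):
        asg = assign_detections(
            [{"position": np.zeros(3)}], [_det(0, [0, 0, 0])], gate=1.0
        )
        assert asg.matches == [(0, 0)]
        assert not asg.births and not asg.misses

    def test_detection_beyond_gate_is_birth_plus_miss(self):
        asg = assign_detections(
            [{"position": np.zeros(3)}], [_det(0, [10, 0, 0])], gate=1.0
        )
        assert asg.matches == []
        assert asg.births == [0]
        assert asg.misses == [0]

    @pytest.mark.parametrize("n", [5, 6])
    def test_cost_equals_brute_force_minimum(self, n, rng):
        for _ in range(20):
            preds = [{"position": rng.uniform(0, 3, 3)} for _ in range(n)]
            dets = [_det(0, rng.uniform(0, 3, 3)) for _ in range(n)]
            asg = assign_detections(preds, dets, gate=100.0, feature_weight=0.0)
            C = np.array(
                [[np.linalg.norm(dets[j].position - p["position"]) for j in range(n)]
                 for p in preds]
            )
            brute = min(sum(C[i, p[i]] for i in range(n)) for p in permutations(range(n)))
            assert asg.total_cost == pytest.approx(brute, abs=1e-9)

    def test_gate_must_be_positive(self):
        with pytest.raises(ValueError):
            assign_detections([], [], gate=0.0)


def _detections_from_positions(positions, intensities=None):
    """positions: (n_frames, n_particles, 3) -> per-frame detection lists."""
    out = []
    for f in range(positions.shape[0]):
        dets = []
        for k in range(positions.shape[1]):
            p = positions[f, k]
            if np.isnan(p).any():
                continue
            inten = 100.0 if intensities is None else intensities[k]
            dets.append(_det(f, p, intensity=inten))
        out.append(dets)
    return out


_MD = AcquisitionMetadata(0.2, 0.5, 1.5, 2, 5, 64, 128)


class TestBuildTracks:
    def test_noiseless_simulated_dataset_recovered(self):
        from mitotrack.simulate import (ImagingParams, MotionModelParams,
                                        generate_dataset)

        md = AcquisitionMetadata(0.2, 0.5, 1.5, 50, 5, 128, 160)
        seq, truth = generate_dataset(
            20, 50, MotionModelParams(), ImagingParams(noise_model="none"),
            md, seed=13,
        )
        pos = truth.positions.transpose(1, 0, 2)  # (T, n, 3)
        tracks = build_tracks(_detections_from_positions(pos), PipelineConfig(), md)
        assert len(tracks) == 20
        half_voxel = 0.5 * md.pixel_size_xy
        for tr in tracks:
            assert len(tr) == 50
            k = int(np.argmin(np.linalg.norm(truth.positions[:, 0] - tr.positions[0],
                                             axis=1)))
            err = np.linalg.norm(truth.positions[k, tr.frames] - tr.positions, axis=1)
            assert err.max() <= half_voxel

    def test_single_detection_single_frame(self):
        tracks = build_tracks([[_det(0, [1, 2, 3])]], PipelineConfig(), _MD)
        assert len(tracks) == 1
        assert len(tracks[0]) == 1
        np.testing.assert_allclose(tracks[0].positions[0], [1, 2, 3])

    def test_crossing_particles_identity_by_intensity(self):
        # A runs +x at 1 um/s, B runs -x; they cross at frame 10; 3:1 intensity
        n = 21
        dt = 1.5
        pos = np.zeros((n, 2, 3))
        for f in range(n):
            pos[f, 0] = [f * dt * 1.0, 5.0, 1.0]
            pos[f, 1] = [(n - 1 - f) * dt * 1.0, 5.0, 1.0]
        dets = _detections_from_positions(pos, intensities=[300.0, 100.0])
        cfg = PipelineConfig(feature_weight=2.0, gating_distance_um=4.0)
        tracks = build_tracks(dets, cfg, _MD)
        assert len(tracks) == 2
        for tr in tracks:
            # each track keeps a consistent intensity -> identity preserved
            assert tr.intensities.std() == pytest.approx(0.0, abs=1e-9)
            dx = np.diff(tr.positions[:, 0])
            assert (dx > 0).all() or (dx < 0).all()


class TestLinkAndTrim:
    def _track(self, tid, f0, n, x0, v=1.0):
        frames = np.arange(f0, f0 + n)
        pos = np.zeros((n, 3))
        pos[:, 0] = x0 + v * np.arange(n)
        return Trajectory(tid, frames, pos)

    def test_dropout_split_is_merged(self):
        a = self._track(0, 0, 10, 0.0)
        b = self._track(1, 12, 10, 12.0)  # 2-frame gap, consistent velocity
        out = link_and_trim([a, b], max_link_gap=3, max_link_dist=2.0, min_length=5)
        assert len(out) == 1
        tr = out[0]
        assert tr.start_frame == 0 and tr.end_frame == 21
        assert tr.is_uniform()
        assert tr.interpolated[10] and tr.interpolated[11]
        np.testing.assert_allclose(tr.positions[10, 0], 10.0, atol=1e-9)

    def test_short_track_without_partner_removed(self):
        a = self._track(0, 0, 4, 0.0)
        out = link_and_trim([a], min_length=5)
        assert out == []

    def test_disjoint_far_tracks_unchanged(self):
        a = self._track(0, 0, 12, 0.0)
        b = self._track(1, 0, 12, 500.0)
        out = link_and_trim([a, b], min_length=5)
        assert len(out) == 2
        np.testing.assert_array_equal(out[0].frames, a.frames)
        np.testing.assert_array_equal(out[1].frames, b.frames)

    def test_simulated_dropout_end_to_end(self):
        from mitotrack.simulate import MotionModelParams, simulate_trajectory

        params = MotionModelParams(run_speed_sd=0.0, axis_jitter_sd=0.0)
        traj, _ = simulate_trajectory(np.full(30, 2), params, 1.5, 0,
                                      start=np.array([1.0, 5.0, 1.0]))
        pos = traj.positions[:, None, :].copy()
        pos[14:16] = np.nan  # forced 2-frame detection dropout
        dets = _detections_from_positions(pos)
        cfg = PipelineConfig(max_gap_frames=0)  # force a split, then re-link
        tracks = build_tracks(dets, cfg, _MD)
        assert len(tracks) == 2
        merged = link_and_trim(tracks, max_link_gap=3, max_link_dist=5.0,
                               min_length=5)
        assert len(merged) == 1
        assert merged[0].is_uniform()
        assert merged[0].interpolated.sum() == 2

    def test_parameters_validated(self):
        with pytest.raises(ValueError):
            link_and_trim([], max_link_gap=0)
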
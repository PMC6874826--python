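"""Kalman tracker: prediction, association, update, lifecycle.

The association test compares the Hungarian solution against exhaustive
enumeration of every one-to-one assignment satisfying the minimum-IOU
constraint. The measurement-update test compares the 7x7 matrix pipeline
against an exact rational-arithmetic evaluation of the same recursions on
the three independent (position, rate) subsystems and the scalar aspect
subsystem that the block structure of F, Q, H, R decouples.
"""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from standcount.geometry import Box, Detection, box_to_state, iou
from standcount.tracking import (
    FilterParams,
    associate,
    group_by_frame,
    init_tracker,
    predict,
    step,
    track_video,
    trackers_to_table,
    update,
)

from conftest import random_box


def make_tracker(state, cov=None, params=None, tid=0):
    params = params or FilterParams()
    from standcount.tracking import Tracker

    return Tracker(
        id=tid,
        state=np.asarray(state, dtype=float),
        covariance=np.asarray(cov, dtype=float) if cov is not None else params.P0.copy(),
        frame_created=0,
    )


class TestFilterParams:
    def test_default_matrices_match_published_constants(self):
        p = FilterParams()
        F = np.eye(7)
        F[0, 4] = F[1, 5] = F[2, 6] = 1.0
        assert np.array_equal(p.F, F)
        assert np.array_equal(p.Q, np.diag([1, 1, 1, 1, 1e-2, 1e-2, 1e-4]))
        assert np.array_equal(p.H, np.hstack([np.eye(4), np.zeros((4, 3))]))
        assert np.array_equal(p.R, np.diag([1.0, 1.0, 10.0, 10.0]))
        assert p.min_iou == 0.1

    def test_asymmetric_noise_matrix_rejected(self):
        Q = np.diag([1.0] * 7)
        Q[0, 1] = 5.0
        with pytest.raises(ValueError):
            FilterParams(Q=Q)


class TestPredict:
    def test_zero_velocity_is_fixed_point(self):
        t = make_tracker([100, 50, 400, 1, 0, 0, 0])
        x, _ = predict(t, FilterParams())
        assert np.array_equal(x, [100, 50, 400, 1, 0, 0, 0])

    def test_constant_velocity_advance(self):
        t = make_tracker([100, 50, 400, 1, 2, -1, 4])
        x, _ = predict(t, FilterParams())
        assert np.array_equal(x, [102, 49, 404, 1, 2, -1, 4])

    def test_covariance_propagation_is_exact(self, rng):
        p = FilterParams()
        A = rng.normal(size=(7, 7))
        P = A @ A.T  # random symmetric PSD
        t = make_tracker([10, 10, 100, 1, 1, 1, 1], cov=P)
        _, P_prior = predict(t, p)
        assert np.allclose(P_prior - p.F @ P @ p.F.T, p.Q, atol=1e-9)

    def test_nonfinite_state_rejected(self):
        t = make_tracker([np.nan, 0, 100, 1, 0, 0, 0])
        with pytest.raises(ValueError):
            predict(t, FilterParams())


def brute_force_best_assignment(iou_mat: np.ndarray, min_iou: float) -> float:
    """Maximum total IOU over all one-to-one assignments with every pair > min_iou."""
    n_det, n_trk = iou_mat.shape
    best = 0.0
    for k in range(min(n_det, n_trk) + 1):
        for det_subset in itertools.combinations(range(n_det), k):
            for trk_perm in itertools.permutations(range(n_trk), k):
                if all(iou_mat[j, t] > min_iou for j, t in zip(det_subset, trk_perm)):
                    best = max(best, sum(iou_mat[j, t] for j, t in zip(det_subset, trk_perm)))
    return best


class TestAssociate:
    def _dets(self, boxes):
        return [Detection(0, b) for b in boxes]

    def test_single_good_pair_matches(self):
        a = Box(0, 0, 10, 10)
        b = Box(2, 0, 12, 10)  # iou = 8/12
        res = associate(self._dets([a]), [b], 0.1)
        assert res.matches == [(0, 0)]
        assert res.unmatched_detections == [] and res.unmatched_trackers == []

    def test_pair_below_iou_floor_stays_unmatched(self):
        a = Box(0, 0, 10, 10)
        b = Box(9, 9, 19, 19)  # iou = 1/199 < 0.1
        res = associate(self._dets([a]), [b], 0.1)
        assert res.matches == []
        assert res.unmatched_detections == [0] and res.unmatched_trackers == [0]

    def test_iou_exactly_at_floor_is_excluded(self):
        # overlap 8x10 / union 152x10 is irrelevant; construct iou == 0.25 floor
        a = Box(0, 0, 4, 10)
        b = Box(2, 0, 8, 10)  # inter 20, union 80 -> 0.25
        res = associate(self._dets([a]), [b], min_iou=0.25)
        assert res.matches == []  # strict inequality required

    def test_two_by_two_beats_greedy(self):
        # IOU matrix [[0.8, 0.3], [0.4, 0.7]]: diagonal total 1.5 > 0.7 + 0.4
        d0, d1 = Box(0, 0, 10, 10), Box(100, 0, 110, 10)
        # tracker boxes chosen so iou(d0,t0)>iou(d0,t1) etc.
        dets = self._dets([d0, d1])
        trks = [Box(1, 0, 11, 10), Box(101, 0, 111, 10)]
        res = associate(dets, trks, 0.1)
        assert sorted(res.matches) == [(0, 0), (1, 1)]

    def test_empty_inputs(self):
        res = associate([], [], 0.1)
        assert res.matches == [] and res.unmatched_detections == [] and res.unmatched_trackers == []
        res = associate(self._dets([Box(0, 0, 1, 1)]), [], 0.1)
        assert res.unmatched_detections == [0]

    def test_matches_exhaustive_enumeration_on_random_instances(self, rng):
        """Total matched IOU equals the constrained brute-force optimum, 200 instances."""
        for _ in range(200):
            n_det, n_trk = rng.integers(0, 6, size=2)
            dets = self._dets([random_box(rng, span=40) for _ in range(n_det)])
            trks = [random_box(rng, span=40) for _ in range(n_trk)]
            res = associate(dets, trks, 0.1)
            iou_mat = np.array(
                [[iou(d.box, t) for t in trks] for d in dets]
            ).reshape(n_det, n_trk)
            got = sum(iou_mat[j, k] for j, k in res.matches)
            assert all(iou_mat[j, k] > 0.1 for j, k in res.matches)
            assert got == pytest.approx(brute_force_best_assignment(iou_mat, 0.1), abs=1e-9)


def _rational_posterior(p_pos, p_rate, q_pos, q_rate, r_meas, x_pos, x_rate, z):
    """Exact predict+update of one decoupled (position, rate) subsystem.

    With diagonal initial covariance the 7-dim filter splits into three
    independent 2-dim systems (u, du), (v, dv), (s, ds) and the scalar r.
    All recursions are evaluated in exact rational arithmetic.
    """
    p_pos, p_rate, q_pos, q_rate, r_meas = map(Fraction, (p_pos, p_rate, q_pos, q_rate, r_meas))
    x_pos, x_rate, z = map(Fraction, (x_pos, x_rate, z))
    # predict: x' = [x_pos + x_rate, x_rate]; P' = F P F^T + Q with P diagonal
    xp = x_pos + x_rate
    P00 = p_pos + p_rate + q_pos
    P01 = p_rate
    P11 = p_rate + q_rate
    # update: H = [1, 0]
    S = P00 + r_meas
    K0, K1 = P00 / S, P01 / S
    y = z - xp
    post_pos = xp + K0 * y
    post_rate = x_rate + K1 * y
    # Joseph form: (I-KH) P (I-KH)^T + K R K^T
    IKH = [[1 - K0, 0], [-K1, 1]]
    P = [[P00, P01], [P01, P11]]
    M = [[sum(IKH[i][k] * P[k][j] for k in range(2)) for j in range(2)] for i in range(2)]
    J = [[sum(M[i][k] * IKH[j][k] for k in range(2)) for j in range(2)] for i in range(2)]
    KRK = [[K0 * r_meas * K0, K0 * r_meas * K1], [K1 * r_meas * K0, K1 * r_meas * K1]]
    Ppost = [[J[i][j] + KRK[i][j] for j in range(2)] for i in range(2)]
    return (post_pos, post_rate), Ppost, S


class TestUpdate:
    def test_zero_innovation_preserves_prior_state(self):
        p = FilterParams()
        t = make_tracker([100, 50, 400, 1, 0, 0, 0])
        # detection whose measurement equals H @ predicted state
        m = box_to_state(Box(90, 40, 110, 60))
        assert np.allclose([m.u, m.v, m.s, m.r], [100, 50, 400, 1])
        x_post, _, diag = update(t, Detection(1, Box(90, 40, 110, 60)), p)
        assert np.allclose(diag.y, 0.0, atol=1e-9)
        assert np.allclose(x_post, [100, 50, 400, 1, 0, 0, 0], atol=1e-9)

    def test_measured_variances_contract(self):
        p = FilterParams()
        t = make_tracker([100, 50, 400, 1, 2, -1, 4])
        x_prior, P_prior = predict(t, p)
        _, P_post, _ = update(t, Detection(1, Box(90, 40, 110, 60)), p)
        assert np.all(np.diag(P_post)[:4] <= np.diag(P_prior)[:4] + 1e-12)

    def test_full_step_matches_rational_arithmetic(self):
        """One predict+update against the exact decoupled-subsystem evaluation."""
        p = FilterParams()
        t = make_tracker([100.0, 50.0, 400.0, 1.0, 2.0, -1.0, 4.0])
        det_box = Box(93.0, 38.0, 113.0, 58.0)  # z = (103, 48, 400, 1)
        z = box_to_state(det_box).as_array()
        assert np.allclose(z, [103, 48, 400, 1])

        x_prior, P_prior = predict(t, p)
        x_post, P_post, diag = update(t, Detection(1, det_box), p, prior=(x_prior, P_prior))

        subsystems = {  # (state idx pos, rate): measurement noise, z
            (0, 4): (1, 103),   # u
            (1, 5): (1, 48),    # v
            (2, 6): (10, 400),  # s
        }
        for (i, j), (r_meas, zi) in subsystems.items():
            (e_pos, e_rate), Pp, S = _rational_posterior(
                p_pos=10, p_rate=10**4, q_pos=1, q_rate=p.Q[j, j],
                r_meas=r_meas, x_pos=t.state[i], x_rate=t.state[j], z=zi,
            )
            assert x_post[i] == pytest.approx(float(e_pos), abs=1e-9)
            assert x_post[j] == pytest.approx(float(e_rate), abs=1e-9)
            assert P_post[i, i] == pytest.approx(float(Pp[0][0]), abs=1e-9)
            assert P_post[i, j] == pytest.approx(float(Pp[0][1]), abs=1e-9)
            assert P_post[j, j] == pytest.approx(float(Pp[1][1]), abs=1e-9)
            assert diag.S[i, i] == pytest.approx(float(S), abs=1e-9)
        # scalar aspect-ratio subsystem: prior var 10+1, S = 11+10, K = 11/21
        assert diag.S[3, 3] == pytest.approx(21.0, abs=1e-9)
        assert x_post[3] == pytest.approx(1.0, abs=1e-9)  # z_r == prior r
        assert P_post[3, 3] == pytest.approx(float(Fraction(11, 21) ** 2 * 10 + Fraction(10, 21) ** 2 * 11), abs=1e-9)

    def test_covariance_symmetric_psd_over_random_steps(self, rng):
        """Joseph form keeps P symmetric PSD through 1000 random predict/update steps."""
        p = FilterParams()
        t = make_tracker([100, 100, 400, 1, 0, 0, 0])
        for _ in range(1000):
            x_prior, P_prior = predict(t, p)
            cx, cy = rng.uniform(50, 150, size=2)
            w = rng.uniform(10, 30)
            h = rng.uniform(10, 30)
            d = Detection(1, Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2))
            x_post, P_post, _ = update(t, d, p, prior=(x_prior, P_prior))
            for P in (P_prior, P_post):
                assert np.linalg.norm(P - P.T) < 1e-9
                assert np.linalg.eigvalsh(P).min() > -1e-9
            t.state, t.covariance = x_post, P_post


class TestLifecycle:
    def test_init_tracker_zero_rates_and_unique_ids(self):
        p = FilterParams()
        d = Detection(0, Box(0, 0, 10, 20))
        t1 = init_tracker(d, p, 0)
        t2 = init_tracker(d, p, 0)
        assert np.array_equal(t1.state[4:], [0, 0, 0])
        assert t1.id != t2.id
        assert t1.lifetime == 1
        x, _ = predict(t1, p)
        assert np.array_equal(x[:4], t1.state[:4])  # zero rates: positions unchanged

    def test_no_detections_terminates_all(self):
        p = FilterParams()
        t1 = init_tracker(Detection(0, Box(0, 0, 10, 10)), p, 0)
        t2 = init_tracker(Detection(0, Box(50, 0, 60, 10)), p, 0)
        active, terminated = step([t1, t2], [], p, 1)
        assert active == []
        assert {t.id for t in terminated} == {t1.id, t2.id}
        assert all(t.status == "terminated" for t in terminated)

    def test_unmatched_detections_spawn_trackers(self):
        p = FilterParams()
        dets = [Detection(0, Box(100 * i, 0, 100 * i + 10, 10)) for i in range(3)]
        active, terminated = step([], dets, p, 0)
        assert len(active) == 3 and terminated == []
        assert all(np.array_equal(t.state[4:], [0, 0, 0]) for t in active)

    def test_mixed_frame_indices_rejected(self):
        p = FilterParams()
        dets = [Detection(0, Box(0, 0, 1, 1)), Detection(1, Box(5, 5, 6, 6))]
        with pytest.raises(ValueError, match="frame"):
            step([], dets, p, 0)

    def test_constant_velocity_track_persists(self):
        """A target moving 5 px/frame with exact detections keeps one tracker for 20 frames."""
        dets = [
            Detection(f, Box(10 + 5 * f, 100, 60 + 5 * f, 140)) for f in range(20)
        ]
        trackers = track_video(dets)
        assert len(trackers) == 1
        assert trackers[0].lifetime == 20
        assert trackers[0].status == "active"

    def test_velocity_estimate_converges(self):
        """u-rate estimate is within 5% of the true 5 px/frame after 30 updates."""
        dets = [Detection(f, Box(10 + 5 * f, 100, 60 + 5 * f, 140)) for f in range(31)]
        trackers = track_video(dets)
        assert len(trackers) == 1
        du = trackers[0].state[4]
        assert du == pytest.approx(5.0, rel=0.05)

    def test_single_frame_yields_unit_lifetimes(self):
        dets = [Detection(0, Box(30 * i, 0, 30 * i + 20, 20)) for i in range(4)]
        trackers = track_video(dets)
        assert len(trackers) == 4
        assert all(t.lifetime == 1 for t in trackers)

    def test_empty_stream(self):
        assert track_video([]) == []

    def test_tracker_conservation(self, rng):
        """Trackers ever created == detections never matched to an existing tracker."""
        from standcount.synthetic import NoiseConfig, SceneConfig, corrupt, simulate

        sim = simulate(SceneConfig(n_seedlings=6, seed=3))
        dets = corrupt(sim, NoiseConfig(miss_prob=0.05, seed=4))
        p = FilterParams()
        trackers = track_video(dets, p)
        n_unmatched_dets = sum(1 for t in trackers for _ in [t])  # one creation per tracker
        total_boxes = sum(len(t.history) for t in trackers)
        assert total_boxes == len(dets)  # every detection lands in exactly one tracker
        assert n_unmatched_dets == len(trackers)

    def test_deterministic(self):
        dets = [Detection(f, Box(10 + 5 * f, 100, 60 + 5 * f, 140)) for f in range(10)]
        t1 = trackers_to_table(track_video(dets))
        t2 = trackers_to_table(track_video(dets))
        assert t1.drop(columns="tracker_id").equals(t2.drop(columns="tracker_id"))

    def test_group_by_frame_orders_frames(self):
        dets = [Detection(2, Box(0, 0, 1, 1)), Detection(0, Box(0, 0, 1, 1))]
        frames = group_by_frame(dets)
        assert [f for f, _ in frames] == [0, 2]
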
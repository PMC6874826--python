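"""Kalman-filter multi-object tracking of per-frame seedling detections.

Each tracked plant carries a 7-dimensional state

    t = [u, v, s, r, du, dv, ds]

where (u, v) is the box center in pixels, s the box area in px^2, r the
width/height aspect ratio, and (du, dv, ds) the per-frame rates of change of
center and area. The motion model is constant velocity in (u, v, s) with r
held fixed; time is measured in frames, so no dt appears.

Per frame the tracker set evolves by: predict every active tracker one frame
ahead; associate predicted boxes with the frame's detections by minimizing
total negative IOU (Hungarian assignment) subject to a minimum-IOU floor;
run the Kalman measurement update on matched trackers; start a new tracker
from every unmatched detection (rate components zero); terminate every
tracker left unmatched. A tracker's lifetime is the number of frames in
which it existed, counting its creation frame.

The covariance measurement update uses the Joseph form
``(I - KH) P (I - KH)^T + K R K^T``, which keeps P symmetric positive
semidefinite under roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Box, Detection, box_to_state, iou, state_to_box

__all__ = [
    "FilterParams",
    "Tracker",
    "Association",
    "UpdateDiagnostics",
    "predict",
    "associate",
    "update",
    "init_tracker",
    "step",
    "track_video",
    "group_by_frame",
    "trackers_to_table",
    "tracker_boxes_to_table",
]

_DIM_STATE = 7
_DIM_MEAS = 4


def _default_F() -> np.ndarray:
    F = np.eye(_DIM_STATE)
    F[0, 4] = F[1, 5] = F[2, 6] = 1.0
    return F


def _default_Q() -> np.ndarray:
    return np.diag([1.0, 1.0, 1.0, 1.0, 1e-2, 1e-2, 1e-4])


def _default_H() -> np.ndarray:
    H = np.zeros((_DIM_MEAS, _DIM_STATE))
    H[0, 0] = H[1, 1] = H[2, 2] = H[3, 3] = 1.0
    return H


def _default_R() -> np.ndarray:
    return np.diag([1.0, 1.0, 10.0, 10.0])


def _default_P0() -> np.ndarray:
    # Moderate uncertainty on the four observed components, large on the
    # three rate components, which a single detection says nothing about.
    return np.diag([10.0, 10.0, 10.0, 10.0, 1e4, 1e4, 1e4])


@dataclass
class FilterParams:
    """Fixed matrices of the constant-velocity box filter plus the IOU floor.

    Defaults reproduce the published constants: F couples each of (u, v, s)
    to its rate and leaves r constant; Q = diag(1, 1, 1, 1, 1e-2, 1e-2,
    1e-4); H picks out the four observed components; R = diag(1, 1, 10, 10).
    Q keeps a unit variance on the r component even though F never moves r —
    the matrices are used verbatim, not simplified. P0 is this package's
    choice (no published value exists): diagonal, with variance 10 on
    observed components and 1e4 on rates. ``min_iou`` is the association
    floor: a detection-tracker pair may only match when IOU strictly exceeds
    it (default 0.1).
    """

    F: np.ndarray = field(default_factory=_default_F)
    Q: np.ndarray = field(default_factory=_default_Q)
    H: np.ndarray = field(default_factory=_default_H)
    R: np.ndarray = field(default_factory=_default_R)
    P0: np.ndarray = field(default_factory=_default_P0)
    min_iou: float = 0.1

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.P0 = np.asarray(self.P0, dtype=float)
        if self.F.shape != (_DIM_STATE, _DIM_STATE):
            raise ValueError("F must be 7x7")
        if self.H.shape != (_DIM_MEAS, _DIM_STATE):
            raise ValueError("H must be 4x7")
        for name, M in (("Q", self.Q), ("R", self.R), ("P0", self.P0)):
            if M.shape[0] != M.shape[1] or not np.allclose(M, M.T):
                raise ValueError(f"{name} must be square symmetric")
        if not (0.0 <= self.min_iou < 1.0):
            raise ValueError("min_iou must lie in [0, 1)")


@dataclass
class Tracker:
    """One tracked object: filter state, covariance, and bookkeeping."""

    id: int
    state: np.ndarray            # length-7 posterior (or initial) state
    covariance: np.ndarray       # 7x7 posterior covariance P
    frame_created: int
    lifetime: int = 1            # frames in which the tracker existed, creation included
    status: str = "active"       # "active" | "terminated"
    history: list[tuple[int, Box]] = field(default_factory=list)

    @property
    def frame_last_seen(self) -> int:
        return self.history[-1][0] if self.history else self.frame_created

    def predicted_box(self, params: FilterParams) -> Box:
        """Box of the one-frame-ahead predicted state (used as the association anchor)."""
        x, _ = predict(self, params)
        return _prior_box(x)


@dataclass(frozen=True)
class Association:
    """Result of one-to-one detection/tracker assignment in a frame."""

    matches: list[tuple[int, int]]          # (detection_index, tracker_index)
    unmatched_detections: list[int]
    unmatched_trackers: list[int]


@dataclass(frozen=True)
class UpdateDiagnostics:
    """Intermediate matrices of one measurement update, for inspection/tests."""

    S: np.ndarray   # 4x4 innovation covariance
    K: np.ndarray   # 7x4 Kalman gain
    y: np.ndarray   # 4-vector innovation


def predict(t: Tracker, p: FilterParams) -> tuple[np.ndarray, np.ndarray]:
    """Time update: return the a-priori state F x and covariance F P F^T + Q."""
    x = np.asarray(t.state, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"tracker {t.id} has non-finite state {x}")
    x_prior = p.F @ x
    P_prior = p.F @ t.covariance @ p.F.T + p.Q
    P_prior = (P_prior + P_prior.T) / 2.0  # enforce symmetry under roundoff
    return x_prior, P_prior


def associate(
    detections: Sequence[Detection],
    predicted_boxes: Sequence[Box],
    min_iou: float = 0.1,
) -> Association:
    """Assign detections to predicted tracker boxes by maximum total IOU.

    The cost of a pair is the negative IOU of their boxes, and a pair is
    only admissible when its IOU strictly exceeds ``min_iou``. The
    constraint is folded into the cost matrix before solving: inadmissible
    pairs get zero gain, the Hungarian algorithm maximizes total IOU on the
    rectangular matrix, and assigned inadmissible pairs are then discarded.
    Because an inadmissible pair contributes nothing to the objective, this
    yields an exact optimum of the constrained assignment problem. Surplus
    detections and trackers are reported unmatched.
    """
    n_det, n_trk = len(detections), len(predicted_boxes)
    if n_det == 0 or n_trk == 0:
        return Association([], list(range(n_det)), list(range(n_trk)))

    iou_mat = np.zeros((n_det, n_trk))
    for j, d in enumerate(detections):
        for k, b in enumerate(predicted_boxes):
            iou_mat[j, k] = iou(d.box, b)

    gain = np.where(iou_mat > min_iou, iou_mat, 0.0)
    rows, cols = linear_sum_assignment(-gain)
    matches = [(int(j), int(k)) for j, k in zip(rows, cols) if iou_mat[j, k] > min_iou]
    matched_d = {j for j, _ in matches}
    matched_t = {k for _, k in matches}
    return Association(
        matches=matches,
        unmatched_detections=[j for j in range(n_det) if j not in matched_d],
        unmatched_trackers=[k for k in range(n_trk) if k not in matched_t],
    )


def update(
    t: Tracker,
    d: Detection,
    p: FilterParams,
    prior: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, UpdateDiagnostics]:
    """Measurement update of one tracker with its associated detection.

    ``prior`` is the (state, covariance) pair from :func:`predict`; when
    omitted it is recomputed here. Returns the posterior state, the
    Joseph-form posterior covariance, and the intermediate matrices.
    """
    x_prior, P_prior = prior if prior is not None else predict(t, p)
    H, R = p.H, p.R
    S = H @ P_prior @ H.T + R
    K = P_prior @ H.T @ np.linalg.inv(S)
    I_KH = np.eye(_DIM_STATE) - K @ H
    P_post = I_KH @ P_prior @ I_KH.T + K @ R @ K.T
    P_post = (P_post + P_post.T) / 2.0
    z = box_to_state(d.box).as_array()
    y = z - H @ x_prior
    x_post = x_prior + K @ y
    return x_post, P_post, UpdateDiagnostics(S=S, K=K, y=y)


def _prior_box(x_prior: np.ndarray) -> Box:
    """Box of a predicted state, with area/aspect floored at a tiny positive value.

    A strongly negative area rate (a box shrinking at the image border) can
    extrapolate to s <= 0; the floored box is effectively a point, so such a
    tracker simply cannot out-compete real overlaps during association.
    """
    from .geometry import MeasurementState

    u, v, s, r = x_prior[:4]
    return state_to_box(MeasurementState(u, v, max(s, 1e-6), max(r, 1e-6)))


class _IdCounter:
    def __init__(self) -> None:
        self.next = 0

    def __call__(self) -> int:
        i = self.next
        self.next += 1
        return i


def init_tracker(
    d: Detection,
    p: FilterParams,
    frame: int,
    _ids: _IdCounter | None = None,
) -> Tracker:
    """Start a tracker from an unmatched detection; rate components are zero."""
    m = box_to_state(d.box)
    state = np.array([m.u, m.v, m.s, m.r, 0.0, 0.0, 0.0])
    tid = (_ids or _GLOBAL_IDS)()
    return Tracker(
        id=tid,
        state=state,
        covariance=p.P0.copy(),
        frame_created=frame,
        lifetime=1,
        history=[(frame, d.box)],
    )


_GLOBAL_IDS = _IdCounter()


def step(
    active: list[Tracker],
    frame_dets: Sequence[Detection],
    p: FilterParams,
    frame: int,
    _ids: _IdCounter | None = None,
) -> tuple[list[Tracker], list[Tracker]]:
    """Advance the tracker set by one frame; returns (active, terminated).

    Order of operations: predict -> associate -> update matched (lifetime
    += 1) -> initialize a tracker per unmatched detection -> terminate every
    unmatched tracker. Any tracker with no associated detection this frame is
    removed immediately; there is no grace period.
    """
    if any(d.frame_index != frame for d in frame_dets):
        frames = sorted({d.frame_index for d in frame_dets})
        raise ValueError(f"detections carry frame indices {frames}, expected all == {frame}")

    priors = [predict(t, p) for t in active]
    predicted_boxes = [_prior_box(x) for x, _ in priors]
    assoc = associate(frame_dets, predicted_boxes, p.min_iou)

    for j, k in assoc.matches:
        t = active[k]
        x_post, P_post, _ = update(t, frame_dets[j], p, prior=priors[k])
        t.state, t.covariance = x_post, P_post
        t.lifetime += 1
        t.history.append((frame, frame_dets[j].box))

    new_trackers = [init_tracker(frame_dets[j], p, frame, _ids) for j in assoc.unmatched_detections]

    terminated = []
    survivors = []
    matched_t = {k for _, k in assoc.matches}
    for k, t in enumerate(active):
        if k in matched_t:
            survivors.append(t)
        else:
            t.status = "terminated"
            terminated.append(t)
    return survivors + new_trackers, terminated


def group_by_frame(stream: Iterable[Detection]) -> list[tuple[int, list[Detection]]]:
    """Group a detection stream into (frame_index, detections) in ascending order."""
    by_frame: dict[int, list[Detection]] = {}
    for d in stream:
        by_frame.setdefault(d.frame_index, []).append(d)
    return sorted(by_frame.items())


def track_video(stream: Iterable[Detection], p: FilterParams | None = None) -> list[Tracker]:
    """Track a whole detection stream; returns every tracker ever created.

    Frames are processed in ascending order starting from an empty tracker
    set; frames with no detections still run (terminating all current
    trackers). The returned list is the union of terminated trackers and
    those still active at the end of the video, each carrying its final
    lifetime and per-frame box history.
    """
    p = p or FilterParams()
    ids = _IdCounter()
    frames = group_by_frame(stream)
    if not frames:
        return []
    first, last = frames[0][0], frames[-1][0]
    dets_at = dict(frames)
    active: list[Tracker] = []
    finished: list[Tracker] = []
    for frame in range(first, last + 1):
        active, terminated = step(active, dets_at.get(frame, []), p, frame, ids)
        finished.extend(terminated)
    return finished + active


# ---------------------------------------------------------------------------
# Tracker table output
# ---------------------------------------------------------------------------

def trackers_to_table(trackers: Sequence[Tracker]):
    """Summary table: one row per tracker with creation frame and lifetime."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "tracker_id": t.id,
                "frame_created": t.frame_created,
                "frame_terminated": t.frame_last_seen if t.status == "terminated" else -1,
                "lifetime": t.lifetime,
            }
            for t in trackers
        ],
        columns=["tracker_id", "frame_created", "frame_terminated", "lifetime"],
    )


def tracker_boxes_to_table(trackers: Sequence[Tracker]):
    """Per-frame box table: tracker_id, frame, x, y, w, h."""
    import pandas as pd

    rows = []
    for t in trackers:
        for frame, box in t.history:
            x, y, w, h = box.to_xywh()
            rows.append({"tracker_id": t.id, "frame": frame, "x": x, "y": y, "w": w, "h": h})
    return pd.DataFrame(rows, columns=["tracker_id", "frame", "x", "y", "w", "h"])
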
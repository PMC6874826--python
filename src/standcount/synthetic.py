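"""Synthetic moving-camera crop-row scenes with known ground truth.

Emulates the acquisition geometry of row-scan stand counting: a camera
held a fixed height above the ground translates along a crop row at
constant speed while seedlings sit at roughly regular spacing. Only
bounding boxes are simulated — the tracker consumes boxes, not pixels — so
the world is one-dimensional: each seedling occupies a fixed interval of
the row, and the camera's field of view is a window of the frame width
sliding along it at a constant pixel speed. A seedling emits a
ground-truth box in every frame in which its world box intersects the
window (clipped to the frame), which reproduces the entry/exit slivers at
the image borders that real detections show.

Default geometry corresponds to a handheld scan at ~0.6 m/s, 30 FPS,
1920x1080 frames, with the camera ~0.5 m above the row (about 1900 px per
meter of ground): ~150 px seed spacing (0.08 m/seed), ~90 px cotyledon
boxes, 30 px camera travel per frame, so each plant stays in view for
roughly 65 frames.

A separate corruption stage turns clean ground-truth boxes into realistic
detector output: independent per-frame misses, Gaussian center/size
jitter, a confidence model, and spurious false-positive boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .geometry import Box, Detection, write_detections_csv

__all__ = ["SceneConfig", "NoiseConfig", "SimOutput", "simulate", "corrupt", "render_frame"]

def _min_visible_px(camera_speed: float) -> float:
    """Narrowest sliver of a plant the simulated detector reports at the frame edge.

    Tied to the camera speed so that an entering box of width w always
    overlaps its successor (width w + speed) with IOU >= (speed/4) /
    (5*speed/4) = 0.2, keeping clean edge tracks associable: slivers below
    this are real detectors' misses anyway.
    """
    return max(2.0, camera_speed / 4.0)


@dataclass
class SceneConfig:
    """Geometry of one synthetic row scan. All lengths in pixels.

    n_seedlings: number of plants along the row.
    spacing_mean / spacing_jitter: mean and Gaussian sd of the gap between
        consecutive plant centers.
    width_mean/width_sd, height_mean/height_sd: per-plant box size
        distribution (truncated below at 20 px).
    camera_speed: camera travel per frame; must stay below the typical box
        width or consecutive boxes of one plant stop overlapping.
    frame_w, frame_h: image size.
    fps: frame rate, used only downstream for the lifetime threshold.
    row_length: optional fixed row length; None sizes the row to the
        seedlings. The camera always traverses until the last plant has
        left the view, so every plant is seen.
    seed: RNG seed for the scene layout.
    """

    n_seedlings: int = 20
    spacing_mean: float = 150.0
    spacing_jitter: float = 30.0
    width_mean: float = 90.0
    width_sd: float = 15.0
    height_mean: float = 80.0
    height_sd: float = 12.0
    camera_speed: float = 30.0
    frame_w: int = 1920
    frame_h: int = 1080
    fps: float = 30.0
    row_length: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seedlings <= 0:
            raise ValueError("n_seedlings must be positive")
        for name in ("spacing_mean", "width_mean", "height_mean", "camera_speed", "fps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.camera_speed >= self.frame_w:
            raise ValueError("camera_speed must be below the frame width")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class NoiseConfig:
    """Detector imperfection model applied to clean ground-truth boxes.

    center_jitter_std / size_jitter_std: Gaussian pixel noise on box center
        and on width/height.
    miss_prob: independent probability that a visible plant goes undetected
        in a frame.
    false_positive_rate: expected spurious boxes per frame (Poisson).
    confidence_mean / confidence_sd: clipped-Gaussian score model for true
        detections; false positives draw from a lower-scoring model.
    seed: RNG seed for the corruption.
    """

    center_jitter_std: float = 2.0
    size_jitter_std: float = 2.0
    miss_prob: float = 0.1
    false_positive_rate: float = 0.1
    confidence_mean: float = 0.9
    confidence_sd: float = 0.05
    fp_confidence_mean: float = 0.6
    fp_confidence_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_prob <= 1.0):
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.center_jitter_std < 0 or self.size_jitter_std < 0:
            raise ValueError("jitter standard deviations must be >= 0")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NoiseConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SimOutput:
    """Ground truth and detection streams for one simulated video."""

    config: SceneConfig
    tracks: dict[int, list[tuple[int, Box]]]   # seedling id -> per-frame boxes
    clean: list[Detection]
    corrupted: Optional[list[Detection]] = None
    n_frames: int = 0
    world_boxes: list[tuple[float, float, float, float]] = field(default_factory=list)

    @property
    def true_count(self) -> int:
        return self.config.n_seedlings

    def write_detections(self, path: str | Path, corrupted: bool = True) -> None:
        stream = self.corrupted if (corrupted and self.corrupted is not None) else self.clean
        write_detections_csv(stream, path)

    def write_tracks(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for sid, track in self.tracks.items():
            for frame, box in track:
                x, y, w, h = box.to_xywh()
                rows.append({"seedling_id": sid, "frame": frame, "x": x, "y": y, "w": w, "h": h})
        pd.DataFrame(rows, columns=["seedling_id", "frame", "x", "y", "w", "h"]).to_csv(
            path, index=False
        )


def simulate(cfg: SceneConfig) -> SimOutput:
    """Generate ground-truth tracks and a clean (noise-free) detection stream.

    Deterministic under ``cfg.seed``. Raises if a fixed ``row_length`` is
    too short to hold all seedlings (the camera would never reach them).
    """
    rng = np.random.default_rng(cfg.seed)

    # Plant centers along the row, starting beyond the first camera window so
    # every plant enters from the frame edge and gets a full transit.
    gaps = cfg.spacing_mean + rng.normal(0.0, cfg.spacing_jitter, size=cfg.n_seedlings)
    gaps = np.maximum(gaps, cfg.spacing_mean * 0.2)
    centers_x = cfg.frame_w + np.cumsum(gaps)
    # IOU-based association is only physically possible when a plant is wider
    # than the per-frame camera travel (otherwise consecutive boxes of the
    # same plant barely overlap); the acquisition this emulates kept camera
    # speed well below plant size, so the width distribution is truncated at
    # 1.5x the per-frame travel (self-overlap IOU >= 0.2 at the floor).
    width_floor = max(20.0, 1.5 * cfg.camera_speed)
    widths = np.maximum(rng.normal(cfg.width_mean, cfg.width_sd, size=cfg.n_seedlings), width_floor)
    heights = np.maximum(rng.normal(cfg.height_mean, cfg.height_sd, size=cfg.n_seedlings), 20.0)
    centers_y = cfg.frame_h * 0.5 + rng.normal(0.0, cfg.frame_h * 0.05, size=cfg.n_seedlings)
    centers_y = np.clip(centers_y, heights / 2 + 1, cfg.frame_h - heights / 2 - 1)

    row_end = float(centers_x[-1] + widths[-1] / 2)
    if cfg.row_length is not None:
        if cfg.row_length < row_end:
            raise ValueError(
                f"row_length {cfg.row_length} px is shorter than the seedling layout "
                f"({row_end:.0f} px); the camera would never reach the last plants"
            )
        row_end = float(cfg.row_length)
    # Traverse until the last plant has fully left the view.
    n_frames = int(np.ceil(row_end / cfg.camera_speed)) + 1

    world = [
        (
            float(centers_x[i] - widths[i] / 2),
            float(centers_y[i] - heights[i] / 2),
            float(centers_x[i] + widths[i] / 2),
            float(centers_y[i] + heights[i] / 2),
        )
        for i in range(cfg.n_seedlings)
    ]

    min_visible = _min_visible_px(cfg.camera_speed)
    tracks: dict[int, list[tuple[int, Box]]] = {i: [] for i in range(cfg.n_seedlings)}
    clean: list[Detection] = []
    for frame in range(n_frames):
        offset = frame * cfg.camera_speed
        for sid, (x0, y0, x1, y1) in enumerate(world):
            ix0, ix1 = max(x0 - offset, 0.0), min(x1 - offset, float(cfg.frame_w))
            if ix1 - ix0 < min_visible:
                continue
            box = Box(ix0, y0, ix1, y1)
            tracks[sid].append((frame, box))
            clean.append(Detection(frame_index=frame, box=box, class_label="seedling", confidence=1.0))

    if any(not trk for trk in tracks.values()):
        raise ValueError("some seedlings were never visible; check geometry")
    return SimOutput(config=cfg, tracks=tracks, clean=clean, n_frames=n_frames, world_boxes=world)


def corrupt(clean: SimOutput, noise: NoiseConfig) -> list[Detection]:
    """Apply the detector imperfection model to a clean stream.

    Each ground-truth box is independently dropped with ``miss_prob``, then
    jittered in center and size and assigned a confidence; false positives
    (random boxes with lower confidence) are added per frame at a Poisson
    rate. Deterministic under ``noise.seed``; also stored on
    ``clean.corrupted``.
    """
    rng = np.random.default_rng(noise.seed)
    cfg = clean.config
    out: list[Detection] = []
    for d in clean.clean:
        if rng.random() < noise.miss_prob:
            continue
        cx = (d.box.x_min + d.box.x_max) / 2 + rng.normal(0.0, noise.center_jitter_std)
        cy = (d.box.y_min + d.box.y_max) / 2 + rng.normal(0.0, noise.center_jitter_std)
        w = max(d.box.width + rng.normal(0.0, noise.size_jitter_std), 4.0)
        h = max(d.box.height + rng.normal(0.0, noise.size_jitter_std), 4.0)
        conf = float(np.clip(rng.normal(noise.confidence_mean, noise.confidence_sd), 0.0, 1.0))
        out.append(
            Detection(
                frame_index=d.frame_index,
                box=Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
                class_label="seedling",
                confidence=conf,
            )
        )
    if noise.false_positive_rate > 0:
        for frame in range(clean.n_frames):
            for _ in range(rng.poisson(noise.false_positive_rate)):
                w = rng.uniform(30.0, cfg.width_mean)
                h = rng.uniform(30.0, cfg.height_mean)
                cx = rng.uniform(w / 2, cfg.frame_w - w / 2)
                cy = rng.uniform(h / 2, cfg.frame_h - h / 2)
                conf = float(np.clip(rng.normal(noise.fp_confidence_mean, noise.fp_confidence_sd), 0.0, 1.0))
                out.append(
                    Detection(
                        frame_index=frame,
                        box=Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
                        class_label="seedling",
                        confidence=conf,
                    )
                )
    out.sort(key=lambda d: d.frame_index)
    clean.corrupted = out
    return out


def render_frame(sim: SimOutput, frame: int, seed: int = 0) -> np.ndarray:
    """Rasterize one frame as a simple RGB image (soil texture + leaf discs).

    A coarse stand-in for real imagery so the preprocessing stage can be
    exercised end to end; rendering fidelity is not a goal. Deterministic
    under ``seed``.
    """
    cfg = sim.config
    rng = np.random.default_rng(seed + frame)
    img = np.empty((cfg.frame_h, cfg.frame_w, 3), dtype=np.uint8)
    soil = rng.integers(70, 110, size=(cfg.frame_h, cfg.frame_w), dtype=np.int16)
    img[:, :, 0] = (soil + 30).clip(0, 255).astype(np.uint8)
    img[:, :, 1] = (soil + 10).clip(0, 255).astype(np.uint8)
    img[:, :, 2] = soil.clip(0, 255).astype(np.uint8)

    yy, xx = np.mgrid[0 : cfg.frame_h, 0 : cfg.frame_w]
    for sid, track in sim.tracks.items():
        boxes = {f: b for f, b in track}
        if frame not in boxes:
            continue
        b = boxes[frame]
        cx, cy = (b.x_min + b.x_max) / 2, (b.y_min + b.y_max) / 2
        rad = max(b.width, 8.0) / 4.0
        # two cotyledon discs left and right of the stem
        for dx in (-rad, rad):
            mask = (xx - (cx + dx)) ** 2 + (yy - cy) ** 2 <= rad**2
            img[mask] = (40, 160, 60)
    return img
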
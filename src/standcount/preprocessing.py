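"""Frame extraction and illumination normalization.

Field video is collected outdoors under changing light; before detection,
each frame is contrast-enhanced with CLAHE (contrast-limited adaptive
histogram equalization) applied to the value channel of the HSV color
space only, so hue and saturation — the cues that separate green seedlings
from soil — are untouched.

Frames for counting are taken at the native video rate; frames for building
detection training sets are typically subsampled (e.g. 6 FPS).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
from skimage import exposure
from skimage.color import hsv2rgb, rgb2hsv
from skimage.util import img_as_ubyte

__all__ = ["clahe_enhance", "extract_frames"]


def clahe_enhance(
    img: np.ndarray,
    clip_limit: float = 0.02,
    tiles: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """CLAHE on the HSV value channel of an 8-bit RGB image.

    The image is converted to HSV, the V channel is equalized with a
    contrast-limited adaptive histogram over a ``tiles`` grid, and the result
    is converted back to 8-bit RGB. Hue and saturation pass through
    unchanged (up to 8-bit re-quantization). ``clip_limit`` is the
    normalized clipping fraction in [0, 1] (scikit-image convention); higher
    values allow stronger local contrast amplification. Defaults (0.02,
    8x8 tiles) are this package's choice — no published values exist.

    A constant (flat) image is a fixed point, and repeated application to a
    flat image stays flat. The operation is deterministic and never changes
    image geometry.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    hsv = rgb2hsv(img)
    v = hsv[:, :, 2]
    if np.ptp(v) > 0:
        kernel = (max(1, img.shape[0] // tiles[0]), max(1, img.shape[1] // tiles[1]))
        hsv[:, :, 2] = exposure.equalize_adapthist(v, kernel_size=kernel, clip_limit=clip_limit)
    # flat V: equalization of a constant channel is the identity
    return img_as_ubyte(hsv2rgb(hsv))


def _iter_source(video) -> tuple[Iterable[np.ndarray], float | None]:
    """Yield frames from an array stack, an image directory, or a video file."""
    if isinstance(video, np.ndarray):
        if video.ndim != 4:
            raise ValueError("array input must be a frame stack (n, h, w, 3)")
        return iter(video), None
    if isinstance(video, (list, tuple)):
        return iter(video), None
    path = Path(video)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
        if not files:
            raise ValueError(f"no image frames found in {path}")
        import imageio.v3 as iio

        return (iio.imread(f) for f in files), None
    if not path.exists():
        raise FileNotFoundError(path)
    import imageio.v3 as iio

    meta = iio.immeta(path)
    return iio.imiter(path), float(meta.get("fps")) if meta.get("fps") else None


def extract_frames(
    video,
    rate: float | str = "native",
    native_fps: float | None = None,
) -> list[np.ndarray]:
    """Sample frames from a video uniformly at ``rate`` frames per second.

    ``video`` may be a video file path, a directory of numbered image
    frames, a (n, h, w, 3) array stack, or a sequence of frames. ``rate``
    equal to "native" keeps every frame; otherwise frames are taken at a
    uniform stride of native_fps / rate (which must be >= 1 — a video cannot
    be upsampled). ``native_fps`` must be given when the container does not
    report one.
    """
    frames, meta_fps = _iter_source(video)
    if rate == "native":
        return [np.asarray(f) for f in frames]

    rate = float(rate)
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    fps = native_fps if native_fps is not None else meta_fps
    if fps is None:
        raise ValueError("native_fps required: source does not report a frame rate")
    if rate > fps:
        raise ValueError(f"cannot sample {rate} FPS from a {fps} FPS source")
    stride = fps / rate
    out = []
    next_pick = 0.0
    for i, f in enumerate(frames):
        if i >= next_pick - 1e-9:
            out.append(np.asarray(f))
            next_pick += stride
    return out
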
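"""Per-sensor 2-D depth-image processing.

The person is isolated in each sensor's depth stream before any 3-D work:
a non-zero 2x2 median filter halves the resolution and removes spikes, a
per-pixel minimum over an empty-scene sequence models the static background,
background subtraction keeps only pixels strictly in front of it, and a
binarization + connected-component filter removes small noise blobs.

Depth values are integer millimetres; 0 means "no data" and 5000 is the
background sentinel (the system's working range is 200-5000 mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure

DEPTH_MIN_MM = 200
DEPTH_MAX_MM = 5000

__all__ = [
    "DepthFrame",
    "DEPTH_MIN_MM",
    "DEPTH_MAX_MM",
    "downsample_depth",
    "build_background",
    "subtract_background",
    "binarize_and_filter",
    "write_depth_png",
    "read_depth_png",
]


@dataclass
class DepthFrame:
    """One depth image (mm, uint16) with its timestamp and sensor id."""

    depth: np.ndarray
    timestamp: float
    sensor_id: str

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 2:
            raise ValueError("depth image must be 2-D")


def _nonzero_median_2x2(blocks: np.ndarray) -> np.ndarray:
    """Median of the non-zero entries of each length-4 block (0 if all zero).

    Even counts take the arithmetic mean of the two central values; the
    result is rounded half-up back to integer millimetres.
    """
    # sort with zeros pushed to the end so the first k entries are the
    # ascending non-zero values
    as_inf = np.where(blocks == 0, np.inf, blocks.astype(float))
    srt = np.sort(as_inf, axis=-1)
    k = (blocks != 0).sum(axis=-1)
    n = blocks.shape[0]
    idx = np.arange(n)
    med = np.zeros(n, dtype=float)
    odd = k % 2 == 1
    med[odd] = srt[idx[odd], (k[odd] - 1) // 2]
    even = (~odd) & (k > 0)
    med[even] = 0.5 * (srt[idx[even], k[even] // 2 - 1] + srt[idx[even], k[even] // 2])
    return np.floor(med + 0.5).astype(np.uint16)


def downsample_depth(frame: DepthFrame) -> DepthFrame:
    """Half the resolution with a non-zero median over each 2x2 block.

    All-zero blocks stay 0, which keeps propagating as "no data".
    """
    d = frame.depth
    r, c = d.shape
    if r % 2 or c % 2:
        raise ValueError("depth image dimensions must be even")
    blocks = d.reshape(r // 2, 2, c // 2, 2).transpose(0, 2, 1, 3).reshape(-1, 4)
    out = _nonzero_median_2x2(blocks).reshape(r // 2, c // 2)
    return DepthFrame(out, frame.timestamp, frame.sensor_id)


def build_background(frames) -> np.ndarray:
    """Per-pixel minimum depth over an empty-scene sequence.

    Cells are initialised to 5000 mm and only updated by values strictly
    inside the (200, 5000) working range, so pixels never validly observed
    keep the sentinel.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("background sequence is empty")
    shape = frames[0].depth.shape
    bg = np.full(shape, DEPTH_MAX_MM, dtype=np.uint16)
    for f in frames:
        d = f.depth
        if d.shape != shape:
            raise ValueError("all background frames must share one shape")
        valid = (d > DEPTH_MIN_MM) & (d < DEPTH_MAX_MM)
        np.minimum(bg, np.where(valid, d, DEPTH_MAX_MM), out=bg)
    return bg


def subtract_background(frame: DepthFrame, bg: np.ndarray) -> DepthFrame:
    """Keep pixels strictly in front of the background model.

    A pixel survives iff ``frame < bg`` and ``frame > 200``; everything else
    becomes the 5000 mm sentinel.
    """
    d = frame.depth
    if d.shape != bg.shape:
        raise ValueError("frame and background shapes differ")
    keep = (d < bg) & (d > DEPTH_MIN_MM)
    out = np.where(keep, d, DEPTH_MAX_MM).astype(np.uint16)
    return DepthFrame(out, frame.timestamp, frame.sensor_id)


def binarize_and_filter(bs: DepthFrame, cc_min_px: int = 1000) -> tuple[np.ndarray, DepthFrame]:
    """Binarize a background-subtracted frame and drop small blobs.

    The frame is linearly scaled from [0, 5000] to [0, 255] (real-valued);
    pixels scaling below 250 are foreground (255), the rest background (0)
    — equivalently depth >= 4901.96 mm is background.  8-connected
    components smaller than ``cc_min_px`` pixels are removed, and the
    depth frame is zeroed wherever the final mask is zero.
    """
    d = bs.depth.astype(float)
    scaled = d * (255.0 / 5000.0)
    # 0 means "no data", not a near depth: keep it background so the
    # operation is idempotent on its own output
    mask = (scaled < 250.0) & (d != 0)
    if cc_min_px > 1:
        labels = measure.label(mask, connectivity=2)
        if labels.max() > 0:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            keep = counts >= cc_min_px
            mask = keep[labels]
    mask_img = np.where(mask, 255, 0).astype(np.uint8)
    masked = np.where(mask, bs.depth, 0).astype(np.uint16)
    return mask_img, DepthFrame(masked, bs.timestamp, bs.sensor_id)


def write_depth_png(path, frame: DepthFrame) -> None:
    """16-bit grayscale PNG (mm) plus a JSON sidecar with the metadata."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, frame.depth.astype(np.uint16))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"timestamp": frame.timestamp, "sensor_id": frame.sensor_id}))


def read_depth_png(path) -> DepthFrame:
    import imageio.v3 as iio

    path = Path(path)
    depth = np.asarray(iio.imread(path)).astype(np.uint16)
    meta = json.loads(path.with_suffix(".json").read_text())
    return DepthFrame(depth, float(meta["timestamp"]), str(meta["sensor_id"]))
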
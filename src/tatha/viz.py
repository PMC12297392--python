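"""Overlay and bounding-box renderings of segmentation results.

Overlays paint truth-only, prediction-only, and overlap pixels in distinct
colors on the grayscale image; box renderings draw one rectangle per
connected component of a mask, via ROI extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import extract_roi


@dataclass
class OverlayStyle:
    truth_color: tuple = (0, 200, 0)       # truth only: green
    pred_color: tuple = (220, 0, 0)        # prediction only: red
    overlap_color: tuple = (230, 200, 0)   # agreement: yellow
    alpha: float = 0.6
    box_thickness: int = 2

    def validate(self) -> None:
        if len({self.truth_color, self.pred_color, self.overlap_color}) != 3:
            raise ValueError("overlay colors must be distinct")


def _to_rgb(img: np.ndarray) -> np.ndarray:
    base = np.clip(np.asarray(img, dtype=np.float64), 0, 1) * 255.0
    return np.repeat(base[..., None], 3, axis=-1)


def render_overlay(img: np.ndarray, truth: np.ndarray, pred: np.ndarray,
                   style: OverlayStyle | None = None) -> np.ndarray:
    """RGB uint8 overlay of truth/prediction agreement on the image."""
    style = style or OverlayStyle()
    style.validate()
    t = np.asarray(truth).astype(bool)
    p = np.asarray(pred).astype(bool)
    if t.shape != np.asarray(img).shape or p.shape != t.shape:
        raise ValueError("image, truth and pred shapes must match")
    rgb = _to_rgb(img)
    a = style.alpha
    for sel, color in (((t & ~p), style.truth_color),
                       ((p & ~t), style.pred_color),
                       ((t & p), style.overlap_color)):
        rgb[sel] = (1 - a) * rgb[sel] + a * np.asarray(color, dtype=np.float64)
    return rgb.round().astype(np.uint8)


def render_boxes(img: np.ndarray, mask: np.ndarray,
                 color: tuple = (255, 140, 0), thickness: int = 2,
                 margin: int = 0) -> np.ndarray:
    """Draw one bounding box per connected component of the mask."""
    m = np.asarray(mask).astype(bool)
    if m.shape != np.asarray(img).shape:
        raise ValueError("image and mask shapes must match")
    rgb = _to_rgb(img)
    labels, n = ndimage.label(m)
    col = np.asarray(color, dtype=np.float64)
    for k in range(1, n + 1):
        box = extract_roi(labels == k, margin=margin, shape=m.shape)
        t = thickness
        y0, y1, x0, x1 = box.y_min, box.y_max, box.x_min, box.x_max
        rgb[y0:min(y0 + t, y1), x0:x1] = col
        rgb[max(y1 - t, y0):y1, x0:x1] = col
        rgb[y0:y1, x0:min(x0 + t, x1)] = col
        rgb[y0:y1, max(x1 - t, x0):x1] = col
    return rgb.round().astype(np.uint8)
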
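"""Image and mask readers/writers and report serialization.

Images load to [0,1] float64 regardless of source depth (8/16-bit int or
float); RGB inputs are collapsed by luminance with a warning.  Masks
binarize by the ``value > 0`` rule so 0/255 and 0/1 dialects both work.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def load_image(path) -> np.ndarray:
    """Read a single-channel image normalized to [0,1] float."""
    path = Path(path)
    try:
        a = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if a.size == 0:
        raise IOError(f"empty image {path}")
    if a.ndim == 3:
        if a.shape[-1] == 4:
            a = a[..., :3]
        warnings.warn(f"{path}: multi-channel image converted by luminance",
                      stacklevel=2)
        a = a.astype(np.float64) @ _LUMA if np.issubdtype(a.dtype, np.floating) \
            else (a.astype(np.float64) @ _LUMA)
        if not np.issubdtype(np.asarray(a).dtype, np.floating):
            a = a.astype(np.float64)
        # luminance of integer images still needs dtype scaling below
    if np.issubdtype(np.asarray(a).dtype, np.floating):
        out = np.asarray(a, dtype=np.float64)
        if out.max() > 1.0 + 1e-9:      # float file in 0..255 or 0..65535
            out = out / (255.0 if out.max() <= 255 else 65535.0)
    else:
        out = a.astype(np.float64) / np.iinfo(a.dtype).max
    return np.clip(out, 0.0, 1.0)


def load_mask(path) -> np.ndarray:
    """Read a binary mask; any positive value counts as foreground."""
    path = Path(path)
    try:
        a = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    if a.ndim != 2:
        raise IOError(f"mask {path} is multi-channel; expected single-channel")
    uniq = np.unique(a)
    if len(uniq) > 2 or (len(uniq) == 2 and not np.isin(uniq, (0, 1)).all()
                         and not np.isin(uniq, (0, 255)).all()):
        warnings.warn(f"{path}: non-standard label values {uniq[:5]} "
                      "binarized by value > 0", stacklevel=2)
    return (a > 0).astype(np.uint8)


def save_image(path, img: np.ndarray) -> None:
    """Write a [0,1] float image: .tif keeps float32, else 8-bit PNG."""
    path = Path(path)
    img = np.asarray(img, dtype=np.float64)
    if path.suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, img.astype(np.float32))
    else:
        iio.imwrite(path, np.clip(img * 255.0, 0, 255).round().astype(np.uint8))


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def save_roi(path, roi) -> None:
    Path(path).write_text(json.dumps(roi.as_dict()) + "\n")


def save_metrics_json(path, reports: list) -> None:
    rows = [r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in reports]
    Path(path).write_text(json.dumps(rows, indent=2) + "\n")
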
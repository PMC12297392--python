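"""Speckle-aware preprocessing chain for thyroid ultrasound images.

The chain mirrors the order a sonographic segmentation pipeline applies it:

1. edge-preserving speckle reduction by explicit 4-neighbour anisotropic
   diffusion (Perona-Malik conduction),
2. contrast enhancement by global histogram equalization or CLAHE
   (contrast-limited adaptive histogram equalization),
3. gradient-based edge refinement (Sobel magnitude/orientation, optional
   non-maximum suppression, dual-threshold hysteresis),
4. region-of-interest extraction as a bounding box around mask foreground.

All operators work on 2-D float images with intensities in [0, 1]
(row-major, 0-based coordinates; boxes are half-open on the max side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage


class PreprocessError(ValueError):
    """Invalid input or parameters for a preprocessing stage."""


class EmptyRoiError(PreprocessError):
    """Raised when ROI extraction is asked for a mask with no foreground."""


def as_image(arr: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Validate and coerce ``arr`` to a float64 2-D intensity raster.

    Accepts integer input (scaled by its dtype maximum) or float input
    already in [0, 1].  Rejects non-finite values and images smaller than
    8x8, which are too small for every downstream stencil.
    """
    a = np.asarray(arr)
    if a.ndim != 2:
        raise PreprocessError(f"{name} must be 2-D, got shape {a.shape}")
    if a.shape[0] < 8 or a.shape[1] < 8:
        raise PreprocessError(f"{name} must be at least 8x8, got {a.shape}")
    if np.issubdtype(a.dtype, np.integer):
        a = a.astype(np.float64) / np.iinfo(a.dtype).max
    else:
        a = a.astype(np.float64)
    if not np.all(np.isfinite(a)):
        raise PreprocessError(f"{name} contains non-finite pixels")
    return a


# ---------------------------------------------------------------------------
# anisotropic diffusion
# ---------------------------------------------------------------------------

@dataclass
class DiffusionParams:
    """Explicit-scheme diffusion settings.

    ``lambda_step`` is the update step of the 4-neighbour explicit scheme;
    it must stay in (0, 0.25] for stability.  ``kappa`` scales the
    Perona-Malik conduction c = exp(-(|grad|/kappa)^2): gradients well above
    ``kappa`` are treated as edges and barely diffused.
    """

    iterations: int = 15
    lambda_step: float = 0.2
    kappa: float = 0.1

    def validate(self) -> None:
        if self.iterations < 1:
            raise PreprocessError("iterations must be >= 1")
        if not (0.0 < self.lambda_step <= 0.25):
            raise PreprocessError(
                f"lambda_step must be in (0, 0.25], got {self.lambda_step}"
            )
        if self.kappa <= 0:
            raise PreprocessError("kappa must be > 0")


def anisotropic_diffusion(img: np.ndarray, params: DiffusionParams) -> np.ndarray:
    """Iterative edge-preserving smoothing, I <- I + lambda * sum_i c_i * dI_i.

    The four directional differences dI_i are taken toward N/S/E/W
    neighbours under reflective (Neumann) boundaries, each weighted by its
    own conduction coefficient c_i = exp(-(dI_i / kappa)^2).  The scheme is
    in divergence form, so total intensity is conserved up to the final
    clipping to [0, 1].
    """
    params.validate()
    out = as_image(img).copy()
    lam, kappa = params.lambda_step, params.kappa
    for _ in range(params.iterations):
        # reflective-boundary neighbour differences (boundary diff = 0)
        d_n = np.zeros_like(out)
        d_s = np.zeros_like(out)
        d_e = np.zeros_like(out)
        d_w = np.zeros_like(out)
        d_n[1:, :] = out[:-1, :] - out[1:, :]
        d_s[:-1, :] = out[1:, :] - out[:-1, :]
        d_w[:, 1:] = out[:, :-1] - out[:, 1:]
        d_e[:, :-1] = out[:, 1:] - out[:, :-1]
        flux = 0.0
        for d in (d_n, d_s, d_e, d_w):
            flux = flux + np.exp(-((d / kappa) ** 2)) * d
        out = out + lam * flux
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# histogram equalization / CLAHE
# ---------------------------------------------------------------------------

@dataclass
class ClaheParams:
    """CLAHE settings.

    ``clip_limit`` is expressed as a multiple of the uniform bin height
    (tile pixels / levels); the per-tile histogram is clipped at
    T_clip = clip_limit * tile_pixels / levels and the clipped excess is
    redistributed uniformly over all bins.
    """

    levels: int = 256
    clip_limit: float = 2.0
    tile_rows: int = 8
    tile_cols: int = 8

    def validate(self) -> None:
        if self.levels < 2:
            raise PreprocessError("levels must be >= 2")
        if self.clip_limit <= 0:
            raise PreprocessError("clip_limit must be > 0")
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise PreprocessError("tile grid must be >= 1x1")


def _quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Map [0,1] floats to integer bins 0..levels-1."""
    return np.clip((img * (levels - 1)).round().astype(np.int64), 0, levels - 1)


def _equalization_lut(bins: np.ndarray, levels: int) -> np.ndarray:
    """Transfer function T(r) = (L-1)/(MN) * cumsum(h)(r), scaled to [0,1]."""
    hist = np.bincount(bins.ravel(), minlength=levels).astype(np.float64)
    cdf = np.cumsum(hist)
    return (levels - 1) / cdf[-1] * cdf / (levels - 1)  # == cdf / n_pixels


def equalize_histogram(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Global histogram equalization on ``levels`` intensity bins.

    The mapping is the normalized CDF of the quantized histogram, hence
    monotone non-decreasing.  A constant image has a degenerate histogram
    and is returned unchanged.
    """
    if levels < 2:
        raise PreprocessError("levels must be >= 2")
    a = as_image(img)
    if np.ptp(a) == 0:
        return a.copy()
    bins = _quantize(a, levels)
    return _equalization_lut(bins, levels)[bins]


def _clipped_lut(bins: np.ndarray, levels: int, clip_limit: float) -> np.ndarray:
    """Per-tile clipped-and-redistributed equalization transfer function."""
    n = bins.size
    hist = np.bincount(bins.ravel(), minlength=levels).astype(np.float64)
    t_clip = clip_limit * n / levels
    excess = np.sum(np.maximum(hist - t_clip, 0.0))
    hist = np.minimum(hist, t_clip) + excess / levels
    cdf = np.cumsum(hist)
    return cdf / cdf[-1]


def clahe(img: np.ndarray, params: ClaheParams) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is split into a tile grid; each tile's histogram is clipped at
    T_clip and the excess redistributed uniformly, giving one monotone
    transfer function per tile.  Pixels are mapped by bilinear interpolation
    between the transfer functions of the four nearest tile centres (edge
    pixels fall back to the nearest tiles), so tile seams are invisible.

    With a single tile and an effectively infinite clip limit this reduces
    exactly to :func:`equalize_histogram`.
    """
    params.validate()
    a = as_image(img)
    h, w = a.shape
    tr, tc = params.tile_rows, params.tile_cols
    if h < tr or w < tc:
        raise PreprocessError(f"tile grid {tr}x{tc} larger than image {a.shape}")
    if np.ptp(a) == 0:
        return a.copy()

    levels = params.levels
    bins = _quantize(a, levels)
    # tile boundaries (last tile absorbs the remainder)
    row_edges = np.linspace(0, h, tr + 1).astype(int)
    col_edges = np.linspace(0, w, tc + 1).astype(int)
    luts = np.empty((tr, tc, levels))
    centers_r = np.empty(tr)
    centers_c = np.empty(tc)
    for i in range(tr):
        for j in range(tc):
            tile = bins[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            luts[i, j] = _clipped_lut(tile, levels, params.clip_limit)
    for i in range(tr):
        centers_r[i] = (row_edges[i] + row_edges[i + 1] - 1) / 2.0
    for j in range(tc):
        centers_c[j] = (col_edges[j] + col_edges[j + 1] - 1) / 2.0

    # bilinear interpolation between tile-centre transfer functions
    rr = np.arange(h, dtype=np.float64)
    cc = np.arange(w, dtype=np.float64)
    i1 = np.clip(np.searchsorted(centers_r, rr), 1, tr - 1) if tr > 1 else np.zeros(h, int)
    j1 = np.clip(np.searchsorted(centers_c, cc), 1, tc - 1) if tc > 1 else np.zeros(w, int)
    i0 = np.maximum(i1 - 1, 0)
    j0 = np.maximum(j1 - 1, 0)
    if tr > 1:
        wr = np.clip((rr - centers_r[i0]) / (centers_r[i1] - centers_r[i0]), 0.0, 1.0)
    else:
        wr = np.zeros(h)
    if tc > 1:
        wc = np.clip((cc - centers_c[j0]) / (centers_c[j1] - centers_c[j0]), 0.0, 1.0)
    else:
        wc = np.zeros(w)

    out = np.zeros_like(a)
    pix = bins
    for (ii, wi) in ((i0, 1.0 - wr), (i1, wr)):
        for (jj, wj) in ((j0, 1.0 - wc), (j1, wc)):
            vals = luts[ii[:, None], jj[None, :], pix]
            out += (wi[:, None] * wj[None, :]) * vals
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# edge refinement
# ---------------------------------------------------------------------------

@dataclass
class EdgeResult:
    """Sobel gradient field plus (optionally) a hysteresis edge mask.

    ``orientation`` is arctan(dI/dy / dI/dx) in (-pi/2, pi/2]; pixels where
    both derivatives vanish get orientation 0, pixels where only dI/dx
    vanishes get +pi/2.
    """

    magnitude: np.ndarray
    orientation: np.ndarray
    edge_mask: np.ndarray | None = None


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


def sobel_gradients(img: np.ndarray) -> EdgeResult:
    """3x3 Sobel gradient magnitude and orientation with reflective borders."""
    a = as_image(img)
    gx = ndimage.convolve(a, _SOBEL_X, mode="reflect")
    gy = ndimage.convolve(a, _SOBEL_Y, mode="reflect")
    mag = np.hypot(gx, gy)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arctan(gy / gx)
    theta = np.where(gx == 0, np.where(gy != 0, np.pi / 2, 0.0), theta)
    return EdgeResult(magnitude=mag, orientation=theta)


def _nms(mag: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Thin ridges: keep a pixel only if it is a local max along its
    gradient direction, quantized to 0/45/90/135 degrees."""
    h, w = mag.shape
    padded = np.pad(mag, 1, mode="constant")
    # quantize orientation into 4 sectors of the gradient direction
    ang = np.mod(theta, np.pi)
    sector = np.zeros_like(ang, dtype=int)
    sector[(ang >= np.pi / 8) & (ang < 3 * np.pi / 8)] = 1
    sector[(ang >= 3 * np.pi / 8) & (ang < 5 * np.pi / 8)] = 2
    sector[(ang >= 5 * np.pi / 8) & (ang < 7 * np.pi / 8)] = 3
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    keep = np.zeros_like(mag, dtype=bool)
    core = padded[1:h + 1, 1:w + 1]
    for s, (dr, dc) in offsets.items():
        fwd = padded[1 + dr:h + 1 + dr, 1 + dc:w + 1 + dc]
        bwd = padded[1 - dr:h + 1 - dr, 1 - dc:w + 1 - dc]
        sel = sector == s
        keep[sel] = (core[sel] >= fwd[sel]) & (core[sel] >= bwd[sel])
    return np.where(keep, mag, 0.0)


def hysteresis_edges(
    edge: EdgeResult, low: float, high: float, use_nms: bool = True
) -> EdgeResult:
    """Dual-threshold edge selection.

    Pixels with magnitude >= ``high`` are strong seeds; pixels with
    low <= magnitude < high survive only if 8-connected to a seed through
    other surviving pixels.  With ``use_nms`` the magnitude field is first
    thinned by non-maximum suppression along the quantized orientation.
    """
    if not (0 <= low < high):
        raise PreprocessError(f"need 0 <= low < high, got low={low}, high={high}")
    mag = edge.magnitude
    if use_nms:
        mag = _nms(mag, edge.orientation)
    candidate = (mag >= low) & (mag > 0)
    strong = mag >= high
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        mask = np.zeros_like(candidate)
    else:
        seeded = np.zeros(n + 1, dtype=bool)
        seeded[np.unique(labels[strong])] = True
        seeded[0] = False
        mask = seeded[labels]
    return EdgeResult(magnitude=edge.magnitude, orientation=edge.orientation,
                      edge_mask=mask)


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned box, 0-based, half-open on the max side.

    x indexes columns, y indexes rows, matching the usual (x, y) bounding
    box convention for images.
    """

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise PreprocessError(f"degenerate box {self}")

    def as_dict(self) -> dict:
        return {"x_min": self.x_min, "x_max": self.x_max,
                "y_min": self.y_min, "y_max": self.y_max}

    def crop(self, img: np.ndarray) -> np.ndarray:
        return img[self.y_min:self.y_max, self.x_min:self.x_max]


def extract_roi(mask: np.ndarray, margin: int = 0,
                shape: tuple[int, int] | None = None) -> RoiBox:
    """Tightest half-open box around all mask foreground, grown by
    ``margin`` and clamped to ``shape`` (defaults to the mask's shape)."""
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise PreprocessError("mask must be 2-D")
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        raise EmptyRoiError("mask has no foreground pixels")
    h, w = shape if shape is not None else m.shape
    return RoiBox(
        x_min=max(int(cols.min()) - margin, 0),
        x_max=min(int(cols.max()) + 1 + margin, w),
        y_min=max(int(rows.min()) - margin, 0),
        y_max=min(int(rows.max()) + 1 + margin, h),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    """Stage toggles and parameters for the full preprocessing chain."""

    enable_diffusion: bool = True
    enable_clahe: bool = True
    enable_edges: bool = True
    enable_roi: bool = False
    use_median_prefilter: bool = False
    median_size: int = 3
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    clahe: ClaheParams = field(default_factory=ClaheParams)
    hysteresis_low: float = 0.2
    hysteresis_high: float = 0.5
    use_nms: bool = True
    roi_margin: int = 8


@dataclass
class PreprocessResult:
    image: np.ndarray
    edges: EdgeResult | None
    roi: RoiBox | None


def preprocess_pipeline(
    img: np.ndarray,
    config: PreprocessConfig | None = None,
    mask: np.ndarray | None = None,
) -> PreprocessResult:
    """Apply the enabled stages in order: diffusion, contrast, edges, ROI.

    Disabled stages are identities.  ROI needs a foreground mask; without
    one the box is None.  Stage failures are re-raised with the stage name
    attached so a caller can tell where a bad parameter bit.
    """
    cfg = config or PreprocessConfig()
    out = as_image(img)
    edges: EdgeResult | None = None
    roi: RoiBox | None = None

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # attach stage name for diagnosis
            raise type(exc)(f"[stage {name}] {exc}") from exc

    if cfg.use_median_prefilter:
        out = _stage("median", lambda: ndimage.median_filter(out, size=cfg.median_size))
    if cfg.enable_diffusion:
        out = _stage("diffusion", lambda: anisotropic_diffusion(out, cfg.diffusion))
    if cfg.enable_clahe:
        out = _stage("clahe", lambda: clahe(out, cfg.clahe))
    if cfg.enable_edges:
        edges = _stage("edges", lambda: hysteresis_edges(
            sobel_gradients(out), cfg.hysteresis_low, cfg.hysteresis_high,
            use_nms=cfg.use_nms))
    if cfg.enable_roi and mask is not None:
        roi = _stage("roi", lambda: extract_roi(mask, margin=cfg.roi_margin,
                                                shape=out.shape))
    return PreprocessResult(image=out, edges=edges, roi=roi)
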
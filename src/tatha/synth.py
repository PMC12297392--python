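"""Synthetic thyroid-ultrasound phantoms with paired nodule masks.

Real thyroid B-mode images (e.g. the open DDTI collection) show a mid-gray
echotexture corrupted by multiplicative speckle, with nodules appearing as
low-contrast, roughly elliptical hypoechoic regions.  The generator
emulates exactly those statistics so the preprocessing, network, and
evaluation code can be exercised end to end without any download:

* background: smooth low-frequency field around a configurable gray level,
* nodules: 1-3 rotated filled ellipses whose intensity is multiplied by
  (1 - contrast), with a Gaussian-feathered boundary,
* speckle: pixelwise unit-mean gamma multiplicative noise (shape k sets
  the variance, var = 1/k),
* point-spread blur: final Gaussian smoothing.

What it does not emulate: acoustic shadowing, anatomy other than
ellipses, depth-dependent gain, or scanner post-processing.  Every sample
is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

# canonical split sizes of the emulated study dataset (70:15:14 holdout)
DEFAULT_SPLITS = {"train": 450, "val": 95, "test": 92}
MINI_SPLITS = {"train": 45, "val": 10, "test": 10}
FOLD_VAL_RANGE = (93, 147)  # observed validation-size spread across folds


class PhantomSpecError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom image/mask pair."""

    size: int = 256
    n_nodules: int = 1
    axis_range: tuple = (12, 48)
    nodule_contrast: float = 0.35
    speckle_shape: float = 4.0
    psf_sigma: float = 1.5
    background_level: float = 0.55
    feather_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.n_nodules <= 3):
            raise PhantomSpecError("n_nodules must be in [1, 3]")
        lo, hi = self.axis_range
        if lo < 2 or hi < lo:
            raise PhantomSpecError(f"bad axis_range {self.axis_range}")
        if hi >= self.size // 2:
            raise PhantomSpecError("nodule cannot fit inside the image")
        if not (0.0 < self.nodule_contrast < 1.0):
            raise PhantomSpecError("contrast must be in (0, 1)")
        if self.speckle_shape <= 0:
            raise PhantomSpecError("speckle_shape must be > 0")


@dataclass
class PhantomSample:
    image: np.ndarray
    mask: np.ndarray
    nodule_params: list  # (center_rc, axes, angle_rad, contrast) per nodule


def _ellipse_mask(size: int, center, axes, angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dc + sa * dr
    v = -sa * dc + ca * dr
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom: background field, nodules, speckle, blur, mask."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.size

    # smooth low-frequency background: blurred coarse noise around the mean
    coarse = rng.normal(0.0, 1.0, size=(size // 16 + 2, size // 16 + 2))
    bg = ndimage.zoom(coarse, size / coarse.shape[0], order=3)[:size, :size]
    bg = spec.background_level * (1.0 + 0.12 * bg / max(np.abs(bg).max(), 1e-9))

    mask = np.zeros((size, size), dtype=np.uint8)
    attenuation = np.ones((size, size))
    params = []
    lo, hi = spec.axis_range
    margin = hi + 4
    placed: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.n_nodules):
        axes = rng.uniform(lo, hi, size=2)
        # keep nodules disjoint when room allows (50 placement attempts)
        for _try in range(50):
            center = rng.uniform(margin, size - margin, size=2)
            if all(np.hypot(*(center - c)) > axes.max() + r + 2
                   for c, r in placed):
                break
        placed.append((center, float(axes.max())))
        angle = rng.uniform(0, np.pi)
        ell = _ellipse_mask(size, center, axes, angle)
        mask |= ell.astype(np.uint8)
        soft = ndimage.gaussian_filter(ell.astype(np.float64), spec.feather_sigma)
        attenuation *= 1.0 - spec.nodule_contrast * soft
        params.append((tuple(center), tuple(axes), float(angle),
                       spec.nodule_contrast))

    clean = bg * attenuation
    speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape,
                        size=(size, size))
    noisy = clean * speckle
    if spec.psf_sigma > 0:
        noisy = ndimage.gaussian_filter(noisy, spec.psf_sigma)
    return PhantomSample(image=np.clip(noisy, 0.0, 1.0),
                         mask=mask, nodule_params=params)


@dataclass
class Dataset:
    """Seeded phantom collection with split labels."""

    samples: list = field(default_factory=list)      # PhantomSample
    split: list = field(default_factory=list)        # 'train'|'val'|'test'
    sample_ids: list = field(default_factory=list)   # unique ints

    def indices(self, split: str) -> list:
        return [i for i, s in enumerate(self.split) if s == split]

    def subset(self, idx) -> tuple[np.ndarray, np.ndarray]:
        imgs = np.stack([self.samples[i].image for i in idx])
        masks = np.stack([self.samples[i].mask for i in idx])
        return imgs, masks


def generate_dataset(n_train: int | None = None, n_val: int | None = None,
                     n_test: int | None = None,
                     spec: PhantomSpec | None = None,
                     seed: int = 0, mini: bool = False) -> Dataset:
    """Disjoint seeded train/val/test phantoms.

    Default counts follow the emulated study's 450/95/92 holdout; ``mini``
    switches to a 45/10/10 smoke-scale split.
    """
    base = MINI_SPLITS if mini else DEFAULT_SPLITS
    counts = {
        "train": n_train if n_train is not None else base["train"],
        "val": n_val if n_val is not None else base["val"],
        "test": n_test if n_test is not None else base["test"],
    }
    if min(counts.values()) < 1:
        raise ValueError("all split counts must be >= 1")
    spec = spec or PhantomSpec()
    root = np.random.default_rng(seed)
    ds = Dataset()
    sample_id = 0
    for split_name in ("train", "val", "test"):
        for _ in range(counts[split_name]):
            sub_seed = int(root.integers(0, 2**31 - 1))
            n_nod = int(root.integers(1, 4))
            s = replace(spec, seed=sub_seed, n_nodules=n_nod)
            ds.samples.append(generate_phantom(s))
            ds.split.append(split_name)
            ds.sample_ids.append(sample_id)
            sample_id += 1
    return ds


def make_folds(n_folds: int = 15, n_train: int = 450, n_test: int = 92,
               pool_extra: int = 0, seed: int = 0,
               resample_validation: bool = True) -> list[dict]:
    """Cross-validation folds over a phantom pool.

    Each fold fixes the training count and test count and resamples a
    validation set whose size is drawn uniformly from the observed
    93-147 spread (or fixed at the minimum when resampling is off).
    Returns per-fold dicts of disjoint index arrays into a pool of size
    ``n_train + max_val + n_test + pool_extra``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = FOLD_VAL_RANGE
    # scale the validation spread down proportionally for small configs
    if n_train < DEFAULT_SPLITS["train"]:
        scale = n_train / DEFAULT_SPLITS["train"]
        lo = max(2, int(round(lo * scale)))
        hi = max(lo + 1, int(round(hi * scale)))
    pool = n_train + hi + n_test + pool_extra
    folds = []
    for fold_id in range(n_folds):
        n_val = int(rng.integers(lo, hi + 1)) if resample_validation else lo
        perm = rng.permutation(pool)
        folds.append({
            "fold": fold_id + 1,
            "train": perm[:n_train],
            "val": perm[n_train:n_train + n_val],
            "test": perm[n_train + n_val:n_train + n_val + n_test],
        })
    return folds
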
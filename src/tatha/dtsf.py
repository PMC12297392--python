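"""Weighted ensemble fusion of per-pixel segmentation maps (DTSF).

Several independently initialized extractor networks (ThyroFEN units) each
produce a probability map for the same image; the framework fuses them by
a convex, weight-normalized pixelwise combination

    fused = sum_i w_i * map_i,   w_i >= 0,  sum w_i = 1.

Weights are fit on a validation set by a softmax over each extractor's
mean Dice (temperature tau), so better extractors dominate smoothly and
tied extractors share weight equally.  The fused map is thresholded at
0.5 to resolve masked/unmasked conflicts by weighted vote.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .losses import dice_coefficient


@dataclass
class ExtractorOutput:
    """One network's probability map plus provenance identifiers."""

    prob_map: np.ndarray
    extractor_id: str
    params_digest: str


@dataclass
class EnsembleWeights:
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1 (use normalize_weights)")


def _digest(state: dict) -> str:
    h = hashlib.sha256()
    for k in sorted(state):
        h.update(k.encode())
        h.update(np.ascontiguousarray(state[k]).tobytes())
    return h.hexdigest()[:16]


def thyrofen_extract(img: np.ndarray, tnet, extractor_id: str | None = None
                     ) -> ExtractorOutput:
    """Deterministic forward pass of one extractor network."""
    prob = tnet.predict(img)
    if prob.ndim == 3 and prob.shape[-1] == 1:
        prob = prob[..., 0]
    return ExtractorOutput(
        prob_map=np.asarray(prob, dtype=np.float64),
        extractor_id=extractor_id or f"tnet-seed{tnet.config.seed}",
        params_digest=_digest(tnet.net.state_dict()),
    )


def normalize_weights(raw) -> EnsembleWeights:
    """Scale non-negative raw weights to sum to one."""
    w = np.asarray(raw, dtype=np.float64)
    if w.size == 0 or (w < 0).any() or w.sum() <= 0:
        raise ValueError("need at least one positive, no negative, raw weight")
    return EnsembleWeights(w / w.sum())


def dtsf_combine(outputs: list[ExtractorOutput], w: EnsembleWeights) -> np.ndarray:
    """Pixelwise convex combination of the extractor probability maps."""
    if len(outputs) != len(w.weights):
        raise ValueError(
            f"{len(outputs)} outputs vs {len(w.weights)} weights")
    shapes = {o.prob_map.shape for o in outputs}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent map shapes {shapes}")
    combined = np.zeros(outputs[0].prob_map.shape, dtype=np.float64)
    for o, wi in zip(outputs, w.weights):
        combined += wi * o.prob_map
    return combined


def fit_ensemble_weights(outputs_per_image: list, truths: list,
                         tau: float = 10.0) -> EnsembleWeights:
    """Softmax-over-validation-Dice weights.

    ``outputs_per_image[j][i]`` is extractor i's map for validation image
    j.  Each extractor's mean Dice across the set is scaled by ``tau`` and
    softmaxed: tau -> 0 gives uniform weights, tau -> inf a hard argmax.
    """
    if len(outputs_per_image) == 0 or len(outputs_per_image) != len(truths):
        raise ValueError("need >= 1 validation image with matching truths")
    n_extractors = len(outputs_per_image[0])
    dices = np.zeros(n_extractors)
    for maps, g in zip(outputs_per_image, truths):
        if len(maps) != n_extractors:
            raise ValueError("ragged extractor outputs")
        for i, m in enumerate(maps):
            prob = m.prob_map if isinstance(m, ExtractorOutput) else m
            dices[i] += dice_coefficient(prob, g)
    dices /= len(truths)
    z = tau * (dices - dices.max())     # stable softmax
    w = np.exp(z)
    return EnsembleWeights(w / w.sum())


def ensemble_predict(img: np.ndarray, tnets: list, weights: EnsembleWeights
                     ) -> np.ndarray:
    """Fused probability map for one image from a list of networks."""
    outs = [thyrofen_extract(img, t) for t in tnets]
    return dtsf_combine(outs, weights)
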
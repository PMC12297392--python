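"""Compound segmentation loss (Banerjee Coefficient) and evaluation metrics.

The loss blends three overlap terms between a probability map P and a
binary ground-truth mask G, all built from soft set cardinalities

    |P n G| = sum p*g,   |P - G| = sum p*(1-g),   |G - P| = sum (1-p)*g:

    L = w_t * (1 - Tversky) + w_d * (1 - Dice) + w_f * (1 - Tversky)^gamma

with published weights 0.23 / 0.65 / 0.12.  The Tversky index trades false
positives against false negatives through alpha/beta, and the focal third
term re-emphasises hard examples.  Evaluation metrics (accuracy, Dice, IoU,
sensitivity, specificity, F1) use hard masks at a threshold; AUC and
average precision use the raw probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


class ShapeMismatchError(ValueError):
    pass


def _check_pair(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ShapeMismatchError(f"shape mismatch {p.shape} vs {g.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    if not np.isin(np.unique(g), (0.0, 1.0)).all():
        raise ValueError("ground-truth mask must be binary")
    return p, g


@dataclass
class LossParams:
    """Weights and shape parameters of the compound loss.

    alpha/beta weight false positives vs false negatives in the Tversky
    term (alpha=0.7, beta=0.3 emphasises recall on small lesions); gamma is
    the focal exponent; epsilon smooths every ratio so empty masks are
    well-defined.
    """

    w_tversky: float = 0.23
    w_dice: float = 0.65
    w_focal: float = 0.12
    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 0.75
    epsilon: float = 1e-6

    def validate(self) -> None:
        if min(self.w_tversky, self.w_dice, self.w_focal) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def soft_cardinalities(p: np.ndarray, g: np.ndarray):
    """Return (inter, p_minus_g, g_minus_p, size_p, size_g) as soft sums."""
    p, g = _check_pair(p, g)
    inter = float(np.sum(p * g))
    p_minus_g = float(np.sum(p * (1.0 - g)))
    g_minus_p = float(np.sum((1.0 - p) * g))
    return inter, p_minus_g, g_minus_p, float(p.sum()), float(g.sum())


def tversky_index(p, g, alpha: float = 0.7, beta: float = 0.3,
                  epsilon: float = 1e-6) -> float:
    """TI = (|PnG| + eps) / (|PnG| + alpha|P-G| + beta|G-P| + eps).

    alpha = beta = 0.5 recovers the Dice coefficient exactly.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    inter, pmg, gmp, _, _ = soft_cardinalities(p, g)
    return (inter + epsilon) / (inter + alpha * pmg + beta * gmp + epsilon)


def dice_coefficient(p, g, epsilon: float = 1e-6) -> float:
    """Dice = (2|PnG| + eps) / (|P| + |G| + eps); 1.0 when both are empty."""
    inter, _, _, size_p, size_g = soft_cardinalities(p, g)
    return (2.0 * inter + epsilon) / (size_p + size_g + epsilon)


def banerjee_loss(p, g, params: LossParams | None = None) -> float:
    """Compound Tversky + Dice + focal-Tversky loss.

    Zero when P == G; approaches w_t + w_d + w_f (= 1.0 at the default
    weights) for disjoint non-empty masks as epsilon -> 0.
    """
    prm = params or LossParams()
    prm.validate()
    ti = tversky_index(p, g, prm.alpha, prm.beta, prm.epsilon)
    dc = dice_coefficient(p, g, prm.epsilon)
    return (prm.w_tversky * (1.0 - ti)
            + prm.w_dice * (1.0 - dc)
            + prm.w_focal * (1.0 - ti) ** prm.gamma)


def banerjee_loss_grad(p: np.ndarray, g: np.ndarray,
                       params: LossParams | None = None) -> np.ndarray:
    """Analytic dL/dp, elementwise, for gradient-based training.

    Both the Tversky and Dice terms are ratios of linear functionals of p,
    so the quotient rule gives closed-form per-pixel gradients; the focal
    term chains through (1 - TI)^gamma.
    """
    prm = params or LossParams()
    prm.validate()
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    eps = prm.epsilon
    inter = np.sum(p * g)
    pmg = np.sum(p * (1.0 - g))
    gmp = np.sum((1.0 - p) * g)
    size_p, size_g = p.sum(), g.sum()

    den_t = inter + prm.alpha * pmg + prm.beta * gmp + eps
    ti = (inter + eps) / den_t
    # d(inter)/dp = g ; d|P-G|/dp = 1-g ; d|G-P|/dp = -g
    dden_t = g + prm.alpha * (1.0 - g) - prm.beta * g
    dti = (g * den_t - (inter + eps) * dden_t) / den_t**2

    den_d = size_p + size_g + eps
    ddice = (2.0 * g * den_d - (2.0 * inter + eps)) / den_d**2

    one_minus_ti = max(1.0 - ti, 1e-12)
    dfocal = -prm.gamma * one_minus_ti ** (prm.gamma - 1.0) * dti
    return (-prm.w_tversky * dti - prm.w_dice * ddice + prm.w_focal * dfocal)


# ---------------------------------------------------------------------------
# hard metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise cross-tabulation of two binary masks."""
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ShapeMismatchError(f"shape mismatch {p.shape} vs {t.shape}")
    for name, a in (("pred", p), ("truth", t)):
        if not np.isin(np.unique(a), (0, 1)).all():
            raise ValueError(f"{name} mask must be binary; threshold first")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)), tn=int(np.sum(~p & ~t)),
    )


@dataclass
class MetricReport:
    accuracy: float
    dice: float
    iou: float
    auc: float
    sensitivity: float
    specificity: float
    f1: float
    average_precision: float
    loss: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def evaluate(prob: np.ndarray, truth: np.ndarray, threshold: float = 0.5,
             loss_params: LossParams | None = None) -> MetricReport:
    """Full metric panel for one probability map against its mask.

    Hard metrics are computed from the confusion table at ``threshold``;
    AUC is the trapezoidal area under the ROC over all distinct probability
    cut points, and average precision is the area under the
    precision-recall curve (the pixelwise reading of "mAP" for a binary
    task).  A single-class ground truth leaves AUC/AP undefined (NaN, with
    a warning).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    p, g = _check_pair(prob, truth)
    hard = (p >= threshold).astype(np.uint8)
    cm = confusion(hard, g.astype(np.uint8))
    acc = cm.tp + cm.tn
    dice_hard = _safe_div(2.0 * cm.tp, 2.0 * cm.tp + cm.fp + cm.fn)
    if cm.tp + cm.fp + cm.fn == 0:          # both masks empty
        dice_hard = 1.0
        iou = 1.0
    else:
        iou = _safe_div(cm.tp, cm.tp + cm.fp + cm.fn)
    y = g.ravel().astype(int)
    if y.min() == y.max():
        warnings.warn("ground truth has a single class; AUC/AP undefined",
                      RuntimeWarning, stacklevel=2)
        auc = float("nan")
        ap = float("nan")
    else:
        auc = float(roc_auc_score(y, p.ravel()))
        ap = float(average_precision_score(y, p.ravel()))
    return MetricReport(
        accuracy=acc / cm.total,
        dice=dice_hard,
        iou=iou,
        auc=auc,
        sensitivity=_safe_div(cm.tp, cm.tp + cm.fn),
        specificity=_safe_div(cm.tn, cm.tn + cm.fp),
        f1=dice_hard,
        average_precision=ap,
        loss=banerjee_loss(p, g, loss_params),
    )
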
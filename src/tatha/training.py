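"""Training loop with validation-loss early stopping, and cross-validation.

The network is trained with Adam on the compound (Tversky/Dice/focal)
loss; training halts once validation loss has not improved for
``early_stop_patience`` epochs and the best-validation weights are
restored.  The per-epoch history records the loss and overlap curves on
both splits.  Cross-validation retrains from a fresh seeded
initialization per fold and reports accuracy/Dice/AUC on that fold's
test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .losses import LossParams, banerjee_loss, banerjee_loss_grad, evaluate
from .nn import Adam
from .tnet import TNet, TNetConfig, build_tnet


class DivergenceError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Optimizer and schedule settings.

    The study-scale schedule uses batch sizes 16-32 and 20-100 epochs;
    smaller values are accepted for smoke-scale runs on reduced images.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0
    loss: LossParams = field(default_factory=LossParams)

    def validate(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        self.loss.validate()


@dataclass
class FoldResult:
    fold_id: int
    accuracy: float
    dice: float
    auc: float


def _as_nhwc(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float32)
    return a[..., None] if a.ndim == 3 else a


def _batch_loss_and_grad(probs: np.ndarray, masks: np.ndarray,
                         params: LossParams):
    n = len(probs)
    losses = np.empty(n)
    grads = np.empty_like(probs, dtype=np.float64)
    for i in range(n):
        p = probs[i, ..., 0].astype(np.float64)
        g = masks[i, ..., 0].astype(np.float64)
        losses[i] = banerjee_loss(p, g, params)
        grads[i, ..., 0] = banerjee_loss_grad(p, g, params)
    return float(losses.mean()), (grads / n).astype(np.float32)


def fit(tnet: TNet,
        train_images: np.ndarray, train_masks: np.ndarray,
        val_images: np.ndarray, val_masks: np.ndarray,
        cfg: TrainConfig | None = None) -> dict:
    """Train in place; return the per-epoch history.

    History keys: train_loss, val_loss, val_dice, val_iou, val_f1,
    stopped_epoch, best_epoch.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    xtr = _as_nhwc(train_images)
    ytr = _as_nhwc(train_masks)
    xva = _as_nhwc(val_images)
    yva = _as_nhwc(val_masks)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr=cfg.learning_rate)

    history: dict = {"train_loss": [], "val_loss": [], "val_dice": [],
                     "val_iou": [], "val_f1": []}
    best_val = np.inf
    best_state = tnet.net.state_dict()
    best_epoch = 0
    bad_epochs = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(xtr))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            probs = tnet.predict(xtr[idx], training=True)
            loss, grad = _batch_loss_and_grad(probs, ytr[idx], cfg.loss)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"training loss became non-finite at epoch {epoch}")
            tnet.net.backward(grad)
            opt.step(tnet.net)
            epoch_losses.append(loss)

        val_probs = tnet.predict(xva, training=False)
        val_losses = []
        dices, ious, f1s = [], [], []
        for i in range(len(xva)):
            p = val_probs[i, ..., 0].astype(np.float64)
            g = yva[i, ..., 0].astype(np.float64)
            val_losses.append(banerjee_loss(p, g, cfg.loss))
            hard = (p >= 0.5)
            inter = float(np.sum(hard * g))
            union = float(hard.sum() + g.sum())
            dices.append(2 * inter / union if union else 1.0)
            denom = float(hard.sum() + g.sum() - inter)
            ious.append(inter / denom if denom else 1.0)
            f1s.append(dices[-1])
        val_loss = float(np.mean(val_losses))
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["val_dice"].append(float(np.mean(dices)))
        history["val_iou"].append(float(np.mean(ious)))
        history["val_f1"].append(float(np.mean(f1s)))

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = tnet.net.state_dict()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.early_stop_patience:
                break

    tnet.net.load_state_dict(best_state)
    history["stopped_epoch"] = len(history["train_loss"])
    history["best_epoch"] = best_epoch
    return history


def train(tnet: TNet, dataset, cfg: TrainConfig | None = None) -> dict:
    """Train on a phantom :class:`~tatha.synth.Dataset`'s train/val splits."""
    tr = dataset.indices("train")
    va = dataset.indices("val")
    if not tr or not va:
        raise ValueError("dataset needs non-empty train and val splits")
    xtr, ytr = dataset.subset(tr)
    xva, yva = dataset.subset(va)
    return fit(tnet, xtr, ytr, xva, yva, cfg)


def cross_validate(images: np.ndarray, masks: np.ndarray, folds: list,
                   net_config: TNetConfig, cfg: TrainConfig | None = None
                   ) -> list[FoldResult]:
    """Train one fresh seeded network per fold; evaluate on its test split."""
    cfg = cfg or TrainConfig()
    results = []
    for fold in folds:
        fid = int(fold["fold"])
        try:
            net = build_tnet(
                TNetConfig(**{**asdict_config(net_config), "seed":
                              net_config.seed + fid}))
            fit(net, images[fold["train"]], masks[fold["train"]],
                images[fold["val"]], masks[fold["val"]], cfg)
            accs, dices, aucs = [], [], []
            probs = net.predict(_as_nhwc(images[fold["test"]]))
            for i, t_idx in enumerate(fold["test"]):
                rep = evaluate(probs[i, ..., 0].astype(np.float64),
                               masks[t_idx].astype(np.float64),
                               loss_params=cfg.loss)
                accs.append(rep.accuracy)
                dices.append(rep.dice)
                aucs.append(rep.auc)
            results.append(FoldResult(
                fold_id=fid, accuracy=float(np.mean(accs)),
                dice=float(np.mean(dices)), auc=float(np.nanmean(aucs))))
        except Exception as exc:
            raise RuntimeError(f"fold {fid} failed: {exc}") from exc
    return results


def asdict_config(cfg: TNetConfig) -> dict:
    return {
        "input_size": cfg.input_size,
        "encoder_filters": cfg.encoder_filters,
        "attention_ratio": cfg.attention_ratio,
        "dilation": cfg.dilation,
        "output_mode": cfg.output_mode,
        "seed": cfg.seed,
    }


def fold_results_frame(results: list[FoldResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.fold_id, r.accuracy, r.dice, r.auc) for r in results],
        columns=["fold", "accuracy", "dice", "auc"])
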
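"""Losses, learning-rate schedule, self-supervised pretraining, fine-tuning.

The pretext objective is L = L_A + L_R: a mean-squared reconstruction loss
over masked patches plus an alignment loss between predictor features and
layer-normalized momentum-encoder targets.  The momentum encoder is an
exponential moving average of the online embedder+encoder and never
receives gradients.  Optimization is decoupled-weight-decay Adam with a
linear warmup followed by cosine decay and a layer-wise learning-rate
multiplier (deeper layers learn slower by a constant factor per layer).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import Tensor, AdamW, ema_update, layer_norm
from .model import AFTAModel, ModelConfig, lr_depth_map
from .patching import sample_mask, partition_patches
from .containers import LabeledEpochSet
from .metrics import evaluate_predictions, MetricsReport

logger = logging.getLogger(__name__)

__all__ = ["LossReport", "ScheduleConfig", "loss_reconstruction",
           "loss_alignment", "loss_classification", "loss_prediction",
           "loss_adaptive", "lr_at", "pretrain", "finetune",
           "save_checkpoint", "load_checkpoint", "PretrainResult"]


@dataclass
class LossReport:
    """Per-step losses; L is exactly L_A + L_R."""

    L_R: float
    L_A: float
    L: float
    L_task: float = 0.0
    L_adaptive: float = 0.0


@dataclass
class ScheduleConfig:
    """Optimization schedule; defaults follow the full-scale regime."""

    peak_lr: float = 5e-4
    warmup_epochs: int = 15
    layer_decay: float = 0.65
    weight_decay: float = 0.05
    batch_size: int = 120
    max_epochs: int = 100
    dropout: float = 0.3
    time_mask_ratio: float = 0.5
    channel_mask_ratio: float = 0.8
    momentum: float = 0.99
    seed: int = 0
    max_steps: int | None = None          # cap for desk-scale runs

    def __post_init__(self):
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be positive")
        if not 0 < self.layer_decay <= 1:
            raise ValueError("layer_decay must lie in (0, 1]")
        if self.warmup_epochs > self.max_epochs:
            raise ValueError("warmup cannot exceed max_epochs")

    @classmethod
    def tiny(cls, **kwargs) -> "ScheduleConfig":
        base = dict(batch_size=8, warmup_epochs=5, max_epochs=100,
                    dropout=0.0, max_steps=300)
        base.update(kwargs)
        return cls(**base)


# -- losses ------------------------------------------------------------------

def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def loss_reconstruction(rec, patches, n_masked: int | None = None) -> Tensor:
    """Mean over masked patches of the squared Euclidean residual norm.

    `rec` and `patches` are (..., |M|, d) aligned on the masked set; the
    mean is over all leading axes and |M|, the sum over the d samples.
    An empty masked set yields 0 with a warning.
    """
    rec, patches = _lift(rec), _lift(patches)
    if rec.shape != patches.shape:
        raise ValueError(f"shape mismatch {rec.shape} vs {patches.shape}")
    m = n_masked if n_masked is not None else (
        rec.shape[-2] if rec.ndim >= 2 else 0)
    if m == 0:
        warnings.warn("empty masked set: reconstruction loss defined as 0")
        return Tensor(0.0)
    diff = rec - patches
    return (diff * diff).sum(axis=-1).mean()


def loss_alignment(pred, menc, normalize_targets: bool = True) -> Tensor:
    """Mean squared distance from predictor features to (layer-normalized)
    momentum targets.  Targets are detached by construction."""
    pred = _lift(pred)
    menc = _lift(menc).detach()
    if pred.shape != menc.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {menc.shape}")
    if pred.size == 0:
        warnings.warn("no slots to align: alignment loss defined as 0")
        return Tensor(0.0)
    target = layer_norm(menc) if normalize_targets else menc
    diff = pred - target.detach()
    return (diff * diff).sum(axis=-1).mean()


def loss_classification(y_onehot, y_hat, eps: float = 1e-12) -> Tensor:
    """Cross-entropy -sum_i y_i log(y_hat_i), averaged over any batch axis."""
    y = _lift(y_onehot).detach()
    p = _lift(y_hat)
    ce = -(y * (p + eps).log()).sum(axis=-1)
    return ce.mean() if ce.ndim else ce


def loss_prediction(y, y_hat) -> Tensor:
    """Mean squared error."""
    y, y_hat = _lift(y).detach(), _lift(y_hat)
    diff = y_hat - y
    return (diff * diff).mean()


def loss_adaptive(L_task, theta, lam: float) -> Tensor:
    """Task loss plus the threshold regularizer lambda * theta^2."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    L_task, theta = _lift(L_task), _lift(theta)
    return L_task + (theta * theta) * lam


# -- schedule ----------------------------------------------------------------

def lr_at(epoch: int, layer_index: int, cfg: ScheduleConfig) -> float:
    """Learning rate at `epoch` for a layer `layer_index` levels below the
    output: linear warmup to the peak, cosine decay to zero afterwards,
    scaled by layer_decay**layer_index."""
    if not 0 <= epoch < cfg.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.max_epochs})")
    if epoch < cfg.warmup_epochs:
        base = cfg.peak_lr * epoch / cfg.warmup_epochs
    else:
        span = max(cfg.max_epochs - cfg.warmup_epochs, 1)
        frac = (epoch - cfg.warmup_epochs) / span
        base = cfg.peak_lr * 0.5 * (1.0 + np.cos(np.pi * frac))
    return base * cfg.layer_decay ** layer_index


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(path: str | Path, model: AFTAModel,
                    sched: ScheduleConfig | None = None,
                    epoch: int = 0,
                    rng_state: dict | None = None) -> None:
    """Single-file archive: parameter tree + config echo + counters."""
    path = Path(path)
    meta = {"model_config": model.cfg.to_dict(),
            "schedule": asdict(sched) if sched else None,
            "epoch": epoch,
            "input_scale": model.input_scale,
            "rng_state": rng_state}
    np.savez(path, __meta__=json.dumps(meta), **model.state())


def load_checkpoint(path: str | Path) -> tuple[AFTAModel, dict]:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz",
                 allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = ModelConfig(**meta["model_config"])
    model = AFTAModel(cfg)
    model.load_state(state)
    model.input_scale = meta.get("input_scale", 1.0)
    return model, meta


# -- pretraining -------------------------------------------------------------

@dataclass
class PretrainResult:
    model: AFTAModel
    trace: list[LossReport] = field(default_factory=list)

    @property
    def recon_losses(self) -> np.ndarray:
        return np.array([r.L_R for r in self.trace])


def _as_patch_array(dataset, patch_len: int) -> np.ndarray:
    """(n, C, T) epochs -> (n, C, T/d, d) patch stacks."""
    if isinstance(dataset, LabeledEpochSet):
        data = dataset.as_array()
    else:
        data = np.asarray(dataset, dtype=np.float64)
    n, C, T = data.shape
    if T % patch_len != 0:
        raise ValueError(f"patch length {patch_len} does not divide T={T}")
    return data.reshape(n, C, T // patch_len, patch_len)


def pretrain(dataset, model_cfg: ModelConfig, sched: ScheduleConfig,
             log_path: str | Path | None = None) -> PretrainResult:
    """Self-supervised masked-reconstruction pretraining.

    Per step: sample a mask, embed the visible tokens, encode, predict
    masked-slot features, compute momentum targets, reconstruct, take an
    optimizer step on L_A + L_R (plus the threshold regularizer when the
    adaptive mask is soft), then update the momentum encoder.
    """
    patches = _as_patch_array(dataset, model_cfg.patch_len)
    n = patches.shape[0]
    if sched.dropout != model_cfg.dropout:   # the schedule owns dropout
        model_cfg = ModelConfig(**{**model_cfg.to_dict(),
                                   "dropout": sched.dropout})
    model = AFTAModel(model_cfg)
    target = AFTAModel(model_cfg)          # momentum copy, never trained
    target.load_ssl_state(model.ssl_state())
    # amplitude normalization: losses live on the standardized scale
    sigma = float(patches.std()) or 1.0
    model.input_scale = target.input_scale = sigma
    depths = lr_depth_map(model)
    scales = {k: sched.layer_decay ** d for k, d in depths.items()}
    opt = AdamW(model.parameters(), lr=0.0, weight_decay=sched.weight_decay,
                lr_scales=scales)
    rng = np.random.default_rng(sched.seed)
    steps_per_epoch = max(n // sched.batch_size, 1)
    total_steps = sched.max_steps or steps_per_epoch * sched.max_epochs
    trace: list[LossReport] = []
    log_fh = open(log_path, "w") if log_path else None
    order = rng.permutation(n)
    cursor = 0
    try:
        for step in range(total_steps):
            if cursor + sched.batch_size > n:
                order = rng.permutation(n)
                cursor = 0
            idx = order[cursor:cursor + sched.batch_size]
            cursor += sched.batch_size
            batch = patches[idx]
            mask = sample_mask(model_cfg.n_time_patches, model_cfg.n_channels,
                               sched.time_mask_ratio,
                               sched.channel_mask_ratio, seed=rng)
            out = model.forward_pretrain(batch, mask, training=True, rng=rng)
            targets = batch[:, mask.masked_pairs[:, 0],
                            mask.masked_pairs[:, 1], :] / sigma
            L_R = loss_reconstruction(out["rec"], targets,
                                      n_masked=mask.n_masked)
            menc = target.encode_targets(batch, mask)
            L_A = loss_alignment(out["pred"], menc)
            L = L_A + L_R
            assert np.isclose(L.item(), L_A.item() + L_R.item(), rtol=0,
                              atol=1e-12), "loss decomposition violated"
            if not np.isfinite(L.item()):
                save_checkpoint(Path(log_path or ".").parent
                                / "diverged_checkpoint.npz", model, sched)
                raise FloatingPointError(
                    f"loss diverged at step {step}: {L.item()}")
            penalty = model.theta_penalty()
            total = L + penalty if isinstance(penalty, Tensor) else L
            epoch_now = min(step // steps_per_epoch, sched.max_epochs - 1)
            opt.lr = lr_at(epoch_now, 0, sched)
            opt.zero_grad()
            if mask.n_masked > 0:
                total.backward()
                opt.step()
            target.load_ssl_state(ema_update(
                model.ssl_state(), target.ssl_state(), sched.momentum))
            report = LossReport(L_R=L_R.item(), L_A=L_A.item(), L=L.item(),
                                L_task=L.item(),
                                L_adaptive=float(total.item()))
            trace.append(report)
            if log_fh:
                log_fh.write(json.dumps(
                    {"step": step, "epoch": epoch_now, "lr": opt.lr,
                     **report.__dict__}) + "\n")
    finally:
        if log_fh:
            log_fh.close()
    return PretrainResult(model=model, trace=trace)


# -- fine-tuning -------------------------------------------------------------

def _split_holdout(labels: np.ndarray, holdout_frac: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/held-out split."""
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n_test = max(int(round(holdout_frac * len(idx))), 1)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def finetune(model: AFTAModel, labeled: LabeledEpochSet, task: str,
             sched: ScheduleConfig, n_epochs: int = 5,
             holdout_frac: float = 0.25, freeze_encoder: bool = False,
             targets: np.ndarray | None = None
             ) -> tuple[AFTAModel, MetricsReport | float]:
    """Fine-tune a pretrained model for classification or regression.

    Classification trains a softmax head with cross-entropy (plus the
    threshold regularizer) and reports metrics on a stratified held-out
    split; "predict" regresses `targets` with mean squared error and
    returns held-out MSE.
    """
    if task not in ("classify", "predict"):
        raise ValueError(f"unknown task {task!r}")
    n_classes = len(labeled.class_names)
    if task == "classify" and model.cfg.n_classes != n_classes:
        raise ValueError(
            f"model head has {model.cfg.n_classes} classes, data has {n_classes}")
    patches = _as_patch_array(labeled, model.cfg.patch_len)
    if model.input_scale == 1.0:          # not pretrained: scale from data
        model.input_scale = float(patches.std()) or 1.0
    labels = labeled.labels
    rng = np.random.default_rng(sched.seed)
    train_idx, test_idx = _split_holdout(labels, holdout_frac, rng)
    params = model.parameters()
    if freeze_encoder:
        params = {k: v for k, v in params.items()
                  if not k.startswith(("embedder.", "encoder."))}
    opt = AdamW(params, lr=0.0, weight_decay=sched.weight_decay)
    steps_per_epoch = max(len(train_idx) // sched.batch_size, 1)
    for ep in range(n_epochs):
        opt.lr = lr_at(min(ep + sched.warmup_epochs, sched.max_epochs - 1),
                       0, sched)
        order = rng.permutation(train_idx)
        for s in range(steps_per_epoch):
            idx = order[s * sched.batch_size:(s + 1) * sched.batch_size]
            if len(idx) == 0:
                continue
            feats = model.features(patches[idx], training=True, rng=rng)
            if task == "classify":
                probs = model.classify_head(feats)
                onehot = np.eye(n_classes)[labels[idx]]
                L_task = loss_classification(onehot, probs)
            else:
                pred = model.regress_head(feats)
                y = targets[idx].reshape(len(idx), -1)
                L_task = loss_prediction(y, pred)
            penalty = model.theta_penalty()
            total = L_task + penalty if isinstance(penalty, Tensor) else L_task
            opt.zero_grad()
            total.backward()
            opt.step()
    if task == "classify":
        probs = model.classify(patches[test_idx])
        preds = probs.argmax(axis=1)
        scores = probs[:, 1] if n_classes == 2 else None
        report = evaluate_predictions(labels[test_idx], preds, n_classes,
                                      scores=scores)
        return model, report
    pred = model.regress_head(model.features(patches[test_idx])).data
    mse = float(np.mean((pred - targets[test_idx].reshape(len(test_idx), -1))
                        ** 2))
    return model, mse
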
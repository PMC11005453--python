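"""Training pipeline: augmentation, cross-validation splits, loss, loop.

Training follows the plain 2-D nnUNet recipe: the loss is the equally
weighted sum of soft-Dice and cross-entropy on the two-channel head, the
optimiser is SGD with Nesterov momentum 0.99 and polynomial learning-rate
decay from 0.01, and the protocol is 5-fold cross-validation with an 80:20
train/validation division. Paired image/mask augmentation applies identical
geometric transforms to both (mask via nearest neighbour) and photometric
transforms to the image only: rotation, contrast increase, additive noise,
translation, and flipping.

A single seed fixes every stochastic choice - splits, initialisation,
augmentation draws, batch order, dropout - so two runs with the same
configuration are bit-for-bit identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.model_selection import KFold

from . import nn
from .backbone import BackboneConfig, UNTCA
from .metrics import MetricReport, dice as dice_score, mask_from_probs
from .synth import SegmentationSample

__all__ = [
    "TrainConfig",
    "AugmentToggles",
    "augment",
    "flip_horizontal",
    "flip_vertical",
    "rotate_sample",
    "translate_sample",
    "adjust_contrast",
    "add_noise",
    "kfold_split",
    "segmentation_loss",
    "train_loop",
    "evaluate",
    "predict_probs",
    "save_checkpoint",
    "load_checkpoint",
    "TrainResult",
]


@dataclass(frozen=True)
class AugmentToggles:
    rotate: bool = True
    contrast: bool = True
    noise: bool = True
    translate: bool = True
    flip: bool = True

    @property
    def any(self) -> bool:
        return any(dataclasses.astuple(self))


@dataclass
class TrainConfig:
    steps: int = 1000
    batch_size: int = 2
    learning_rate: float = 0.01
    momentum: float = 0.99
    nesterov: bool = True
    poly_power: float = 0.9
    seed: int = 0
    folds: int = 5
    val_fraction: float = 0.2
    augment: AugmentToggles = field(default_factory=AugmentToggles)
    eval_every: int = 50
    noise_std: float = 0.02
    max_translate_frac: float = 0.1

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError(
                f"val_fraction must be in (0, 1), got {self.val_fraction}")


# ---------------------------------------------------------------------------
# Paired augmentation
# ---------------------------------------------------------------------------

def _copy(sample: SegmentationSample, image, mask) -> SegmentationSample:
    return SegmentationSample(image=image, mask=mask.astype(np.uint8),
                              tag=sample.tag, name=sample.name)


def flip_horizontal(sample: SegmentationSample) -> SegmentationSample:
    return _copy(sample, sample.image[:, ::-1].copy(), sample.mask[:, ::-1].copy())


def flip_vertical(sample: SegmentationSample) -> SegmentationSample:
    return _copy(sample, sample.image[::-1].copy(), sample.mask[::-1].copy())


def rotate_sample(sample: SegmentationSample, angle: float) -> SegmentationSample:
    """Rotate image (bilinear) and mask (nearest) about the centre.

    Multiples of 90 degrees are exact grid isometries and preserve the
    foreground pixel count.
    """
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        return _copy(sample, np.rot90(sample.image, k).copy(),
                     np.rot90(sample.mask, k).copy())
    img = ndimage.rotate(sample.image, angle, reshape=False, order=1,
                         mode="constant", cval=float(sample.image.min()))
    msk = ndimage.rotate(sample.mask, angle, reshape=False, order=0,
                         mode="constant", cval=0)
    return _copy(sample, np.clip(img, 0, 1), msk > 0)


def translate_sample(sample: SegmentationSample, dy: int,
                     dx: int) -> SegmentationSample:
    img = ndimage.shift(sample.image, (dy, dx), order=1, mode="constant",
                        cval=float(sample.image.min()))
    msk = ndimage.shift(sample.mask, (dy, dx), order=0, mode="constant", cval=0)
    return _copy(sample, np.clip(img, 0, 1), msk > 0)


def adjust_contrast(sample: SegmentationSample, factor: float) -> SegmentationSample:
    m = sample.image.mean()
    return _copy(sample, np.clip(m + factor * (sample.image - m), 0, 1),
                 sample.mask)


def add_noise(sample: SegmentationSample, std: float,
              rng: np.random.Generator) -> SegmentationSample:
    img = np.clip(sample.image + rng.normal(0, std, sample.image.shape), 0, 1)
    return _copy(sample, img, sample.mask)


def augment(sample: SegmentationSample, toggles: AugmentToggles,
            rng: np.random.Generator, noise_std: float = 0.02,
            max_translate_frac: float = 0.1) -> SegmentationSample:
    """Randomly composed augmentation; identity when all toggles are off."""
    if sample.image.shape != sample.mask.shape:
        raise ValueError("image and mask must share spatial size")
    if not toggles.any:
        return sample
    out = sample
    if toggles.rotate and rng.random() < 0.5:
        if rng.random() < 0.5:
            out = rotate_sample(out, 90.0 * rng.integers(1, 4))
        else:
            out = rotate_sample(out, rng.uniform(-30.0, 30.0))
    if toggles.flip and rng.random() < 0.5:
        out = flip_horizontal(out) if rng.random() < 0.5 else flip_vertical(out)
    if toggles.translate and rng.random() < 0.5:
        lim = max(int(max_translate_frac * out.image.shape[0]), 1)
        out = translate_sample(out, int(rng.integers(-lim, lim + 1)),
                               int(rng.integers(-lim, lim + 1)))
    if toggles.contrast and rng.random() < 0.5:
        out = adjust_contrast(out, rng.uniform(1.0, 1.5))
    if toggles.noise and rng.random() < 0.5:
        out = add_noise(out, noise_std, rng)
    return out


# ---------------------------------------------------------------------------
# Cross-validation splits
# ---------------------------------------------------------------------------

def kfold_split(n_items: int, k: int, seed: int):
    """k (train, val) index partitions; validation folds are disjoint and
    cover all indices, giving each fold roughly an (k-1):1 division."""
    if n_items < k:
        raise ValueError(f"need at least k={k} items, got {n_items}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(train.tolist(), val.tolist())
            for train, val in kf.split(np.arange(n_items))]


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def segmentation_loss(logits: nn.Tensor, target: np.ndarray,
                      eps: float = 1e-6) -> nn.Tensor:
    """Equally weighted soft-Dice + cross-entropy on two-channel logits."""
    B, C, H, W = logits.shape
    t_fg = np.asarray(target, dtype=np.float64).reshape(B, H, W)
    onehot = np.stack([1.0 - t_fg, t_fg], axis=1)
    shift = nn.Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    logsum = nn.log(nn.tsum(nn.exp(z), axis=1, keepdims=True))
    logp = z - logsum
    ce = -nn.tmean(nn.tsum(nn.mul(logp, nn.Tensor(onehot)), axis=1))
    p_fg = nn.narrow(nn.softmax(logits, axis=1), 1, 1, 1)
    inter = nn.tsum(nn.mul(p_fg, nn.Tensor(t_fg[:, None])))
    denom = nn.tsum(p_fg) + float(t_fg.sum())
    soft_dice = nn.div(inter * 2.0 + eps, denom + eps)
    return ce * 0.5 + (1.0 - soft_dice) * 0.5


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: UNTCA, model_cfg: BackboneConfig,
                    train_cfg: TrainConfig, step: int, metrics: dict) -> None:
    """Single-file archive: weights + full configuration + seed."""
    meta = {
        "model_cfg": dataclasses.asdict(model_cfg),
        "train_cfg": dataclasses.asdict(train_cfg),
        "step": step,
        "metrics": metrics,
    }
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[UNTCA, dict]:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    mc = dict(meta["model_cfg"])
    for key in ("width_schedule", "token_widths"):
        if mc.get(key) is not None:
            mc[key] = tuple(mc[key])
    model_cfg = BackboneConfig(**mc)
    model = UNTCA(model_cfg, seed=meta["train_cfg"]["seed"])
    model.load_state_dict(state)
    model.eval()
    return model, meta


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------

def predict_probs(model: UNTCA, images) -> list[np.ndarray]:
    """Foreground-probability maps for a list of (H, W) images."""
    was_training = model.training
    model.eval()
    out = []
    for img in images:
        x = nn.Tensor(np.asarray(img, dtype=np.float64)[None, None])
        out.append(model(x).data[0, 1])
    if was_training:
        model.train()
    return out


def evaluate(model: UNTCA, samples) -> MetricReport:
    probs = predict_probs(model, [s.image for s in samples])
    return MetricReport.compute(probs, [s.mask for s in samples],
                                tags=[s.tag for s in samples],
                                names=[s.name for s in samples])


# ---------------------------------------------------------------------------
# The loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: UNTCA
    history: list
    best_val_dice: float
    checkpoint_path: str | None


def train_loop(train_samples, model_cfg: BackboneConfig,
               train_cfg: TrainConfig, val_samples=None,
               out_dir=None) -> TrainResult:
    """Train a model; returns the model, the metric log, and the best
    checkpoint (saved when ``out_dir`` is given, selected by validation Dice,
    or training Dice when no validation set exists)."""
    samples = list(train_samples)
    if not samples:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(train_cfg.seed)
    model = UNTCA(model_cfg, seed=train_cfg.seed)
    opt = nn.SGD(model.parameters(), lr=train_cfg.learning_rate,
                 momentum=train_cfg.momentum, nesterov=train_cfg.nesterov)
    ckpt_path = str(Path(out_dir) / "best.npz") if out_dir is not None else None

    history, best = [], -1.0
    running = []
    for step in range(train_cfg.steps):
        idx = rng.choice(len(samples), size=min(train_cfg.batch_size,
                                                len(samples)), replace=False)
        batch = [augment(samples[i], train_cfg.augment, rng,
                         train_cfg.noise_std, train_cfg.max_translate_frac)
                 for i in idx]
        x = nn.Tensor(np.stack([b.image for b in batch])[:, None])
        t = np.stack([b.mask for b in batch]).astype(np.float64)
        logits = model.logits(x)
        loss = segmentation_loss(logits, t)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.lr = train_cfg.learning_rate * \
            (1.0 - step / train_cfg.steps) ** train_cfg.poly_power
        opt.step()
        probs = 1.0 / (1.0 + np.exp(logits.data[:, 0] - logits.data[:, 1]))
        batch_dice = float(np.mean([
            dice_score(mask_from_probs(probs[i]), t[i]) for i in range(len(batch))]))
        running.append({"step": step, "loss": float(loss.data),
                        "batch_dice": batch_dice})

        last = step == train_cfg.steps - 1
        if (step + 1) % train_cfg.eval_every == 0 or last:
            entry = {"step": step,
                     "loss": float(np.mean([r["loss"] for r in running])),
                     "train_dice": float(np.mean([r["batch_dice"]
                                                  for r in running]))}
            running = []
            if val_samples:
                report = evaluate(model, val_samples)
                entry["val_dice"] = float(report.per_image["dice"].mean())
                entry["val_report"] = report
                score = entry["val_dice"]
            else:
                score = entry["train_dice"]
            history.append(entry)
            if score > best:
                best = score
                if ckpt_path is not None:
                    save_checkpoint(ckpt_path, model, model_cfg, train_cfg,
                                    step, {"score": score})
    return TrainResult(model=model, history=history, best_val_dice=best,
                       checkpoint_path=ckpt_path)
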
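"""Training, inference and evaluation orchestration.

The training protocol follows the patch regime the architecture was
designed around: each epoch draws a fresh set of random 64×64 crops
centred inside the FOV across the training images and optimises the
compound loss with Adam (learning rate 1e-4, batch size 8).  Whole-image
inference tiles the image into 96×96 patches with stride 32, runs the
fused vessel head on each, and averages overlapping predictions.
"""

from __future__ import annotations

import datetime
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import imaging, metrics as metrics_mod, nn
from .imaging import FundusSample, PreprocessConfig, ValidationError
from .losses import LossConfig, total_loss
from .metrics import MetricsReport, aggregate, evaluate_sample
from .model import ModelConfig, SGBNet


@dataclass
class TrainConfig:
    variant: str = "sgbnet"
    patches_per_epoch: int = 10000
    patch_size: int = 64
    batch_size: int = 8
    epochs: int = 50
    lr: float = 1e-4
    optimizer: str = "adam"
    grad_accumulation: int = 1       # alternative reading of "batch of eight"
    loss: LossConfig = field(default_factory=LossConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    pretrained: bool = False
    device: str = "cpu"
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.lr <= 0:
            raise ValidationError("lr must be positive")
        if self.optimizer != "adam":
            raise ValidationError("only the adam optimizer is supported")


@dataclass
class InferConfig:
    patch_size: int = 96
    stride: int = 32
    threshold: float = 0.5
    checkpoint: str = None

    def __post_init__(self):
        if not self.patch_size >= self.stride >= 1:
            raise ValidationError("need patch_size >= stride >= 1")


def set_global_seed(seed: int):
    """Seed every random source the package can touch."""
    np.random.seed(seed % (2 ** 32))
    random.seed(seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Logger:
    def __init__(self, path=None, echo=False):
        self.fh = open(path, "a") if path else None
        self.echo = echo
        self.lines = []

    def log(self, msg):
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        line = f"{stamp} {msg}"
        self.lines.append(line)
        if self.fh:
            self.fh.write(line + "\n")
            self.fh.flush()
        if self.echo:
            print(line)

    def close(self):
        if self.fh:
            self.fh.close()


def _draw_epoch_patches(samples, cfg: TrainConfig, epoch_seed: int):
    """Pool `patches_per_epoch` random crops across the training images."""
    per = max(1, cfg.patches_per_epoch // len(samples))
    imgs, vess, bnds = [], [], []
    for k, s in enumerate(samples):
        tp = imaging.sample_train_patches(
            s, n=per, size=cfg.patch_size,
            rng_seed=(epoch_seed * 1_000_003 + k) % (2 ** 31))
        imgs.append(tp.image.patches)
        vess.append(tp.vessel.patches)
        bnds.append(tp.boundary.patches)
    imgs = np.concatenate(imgs)[: cfg.patches_per_epoch]
    vess = np.concatenate(vess)[: cfg.patches_per_epoch]
    bnds = np.concatenate(bnds)[: cfg.patches_per_epoch]
    order = np.random.default_rng(epoch_seed).permutation(len(imgs))
    return imgs[order], vess[order], bnds[order]


def train_on_samples(samples, cfg: TrainConfig = None, val_samples=None,
                     out_dir=None, max_steps=None, model=None, echo=False):
    """Train a model on in-memory samples; returns (model, history).

    ``max_steps`` caps the total number of optimiser steps (handy for
    short runs); otherwise epochs × patches/batch steps are taken.
    A per-step log line records the loss breakdown; a checkpoint is
    written per epoch when ``out_dir`` is given, plus ``best.ckpt`` by
    validation Dice when validation samples exist.
    """
    cfg = cfg or TrainConfig()
    if not samples:
        raise ValidationError("no training samples")
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    logger = _Logger(out_dir / "train.log" if out_dir else None, echo=echo)

    samples = [imaging.preprocess(s, cfg.preprocess) for s in samples]
    if val_samples:
        val_samples = [imaging.preprocess(s, cfg.preprocess)
                       for s in val_samples]

    if model is None:
        model = SGBNet(variant=cfg.variant, seed=cfg.seed, config=cfg.model,
                       pretrained=cfg.pretrained)
    model.train()
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    history = {"loss": [], "val_dice": []}
    best_dice = -1.0
    step = 0
    done = False
    for epoch in range(cfg.epochs):
        imgs, vess, bnds = _draw_epoch_patches(
            samples, cfg, epoch_seed=cfg.seed * 977 + epoch)
        for i in range(0, len(imgs), cfg.batch_size):
            xb = imgs[i:i + cfg.batch_size].astype(np.float32)
            if len(xb) < cfg.batch_size:
                break
            vb = vess[i:i + cfg.batch_size].astype(np.float32)
            bb = bnds[i:i + cfg.batch_size].astype(np.float32)
            out = model(xb[:, None])
            loss, parts = total_loss(out, vb[:, None], bb[:, None], cfg.loss)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}: "
                    f"{ {k: v.item() for k, v in parts.items()} }")
            opt.zero_grad()
            loss.backward()
            if (step + 1) % cfg.grad_accumulation == 0:
                opt.step()
            history["loss"].append(loss.item())
            logger.log(
                f"epoch {epoch} step {step} loss {loss.item():.5f} "
                f"seg_t0 {parts['seg_t0'].item():.5f} "
                f"focal_t1 {parts['focal_t1'].item():.5f} "
                f"seg_t2 {parts['seg_t2'].item():.5f}")
            step += 1
            if max_steps is not None and step >= max_steps:
                done = True
                break
        if out_dir:
            model.save_checkpoint(out_dir / f"epoch{epoch:03d}.ckpt")
        if val_samples:
            dice = _validation_dice(model, val_samples, cfg)
            history["val_dice"].append(dice)
            logger.log(f"epoch {epoch} val_dice {dice:.4f}")
            if out_dir and dice > best_dice:
                best_dice = dice
                model.save_checkpoint(out_dir / "best.ckpt")
            model.train()
        if done:
            break
    logger.close()
    return model, history


def _validation_dice(model, val_samples, cfg: TrainConfig):
    infer = InferConfig()
    reports = []
    for s in val_samples:
        prob = predict_sample(model, s, infer, preprocessed=True)
        reports.append(metrics_mod.confusion(
            prob, s.vessel_mask, s.fov_mask, infer.threshold))
    return aggregate(reports).dice


def train(cfg: TrainConfig, train_manifest, val_manifest=None, out_dir=None,
          max_steps=None, echo=False):
    """Manifest-file front end of :func:`train_on_samples`."""
    samples = imaging.read_manifest(train_manifest)
    if val_manifest:
        val = imaging.read_manifest(val_manifest)
    elif cfg.val_fraction > 0 and len(samples) >= 5:
        rng = np.random.default_rng(cfg.seed)
        n_val = max(1, int(round(cfg.val_fraction * len(samples))))
        idx = rng.permutation(len(samples))
        val = [samples[i] for i in idx[:n_val]]
        samples = [samples[i] for i in idx[n_val:]]
    else:
        val = None
    return train_on_samples(samples, cfg, val_samples=val, out_dir=out_dir,
                            max_steps=max_steps, echo=echo)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_image(model, image, infer: InferConfig = None,
                  preprocess_cfg: PreprocessConfig = None,
                  batch_size: int = 8):
    """Probability map for one image via tiled overlap-averaged inference."""
    infer = infer or InferConfig()
    img = np.asarray(image)
    if img.ndim == 3:
        sample = FundusSample(
            image=img, vessel_mask=np.zeros(img.shape[:2], np.uint8),
            fov_mask=np.ones(img.shape[:2], np.uint8),
            boundary_mask=np.zeros(img.shape[:2], np.uint8))
        img = imaging.preprocess(sample, preprocess_cfg).image
    pset = imaging.grid_patches(img, infer.patch_size, infer.stride)
    preds = np.empty_like(pset.patches, dtype=np.float32)
    model.eval()
    with nn.no_grad():
        for i in range(0, len(pset), batch_size):
            xb = pset.patches[i:i + batch_size].astype(np.float32)[:, None]
            out = model(xb)
            preds[i:i + batch_size] = out.t0.data[:, 0]
    pred_set = imaging.PatchSet(
        patches=preds, coords=pset.coords, patch_size=pset.patch_size,
        source_shape=pset.source_shape, stride=pset.stride,
        padded_shape=pset.padded_shape)
    return imaging.stitch(pred_set)


def predict_sample(model, sample: FundusSample, infer: InferConfig = None,
                   preprocess_cfg: PreprocessConfig = None,
                   preprocessed=False):
    if preprocessed:
        img = sample.image
        if img.ndim == 3:
            from skimage import color
            img = color.rgb2gray(img).astype(np.float32)
        return predict_image(model, img, infer)
    return predict_image(model, sample.image, infer, preprocess_cfg)


def resolve_checkpoint(path):
    """A run directory resolves to best.ckpt when present, else the last
    epoch checkpoint; a file path is returned unchanged."""
    path = Path(path)
    if path.is_dir():
        best = path / "best.ckpt"
        if best.exists():
            return best
        epochs = sorted(path.glob("epoch*.ckpt"))
        if not epochs:
            raise ValidationError(f"no checkpoints under {path}")
        return epochs[-1]
    if not path.exists():
        raise ValidationError(f"checkpoint {path} does not exist")
    return path


def predict(infer: InferConfig, image_path, out_dir,
            preprocess_cfg: PreprocessConfig = None):
    """Checkpoint-driven prediction; writes float map and binary mask."""
    import imageio.v3 as iio

    if infer.checkpoint is None:
        raise ValidationError("InferConfig.checkpoint is required")
    model = SGBNet.load_checkpoint(resolve_checkpoint(infer.checkpoint))
    image = imaging._read_image(image_path)
    prob = predict_image(model, image, infer, preprocess_cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = Path(image_path).stem
    np.savetxt(out_dir / f"{stem}_prob.txt", prob, fmt="%.6f")
    iio.imwrite(out_dir / f"{stem}_mask.png",
                ((prob >= infer.threshold) * 255).astype(np.uint8))
    return prob


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_samples(preds, samples, fov_mode="fov", threshold=0.5):
    """Per-image reports plus the dataset aggregate.

    ``fov_mode`` "fov" restricts scoring to the FOV interior; "full"
    scores every pixel.
    """
    if fov_mode not in ("fov", "full"):
        raise ValidationError("fov_mode must be 'fov' or 'full'")
    reports = []
    for prob, s in zip(preds, samples):
        mask = s.fov_mask if fov_mode == "fov" else np.ones_like(s.fov_mask)
        reports.append(evaluate_sample(prob, s.vessel_mask, mask, threshold))
    return reports, aggregate(reports)


def evaluation_json(reports, agg) -> str:
    payload = {
        "per_image": [r.to_dict() for r in reports],
        "aggregate": agg.to_dict(),
    }
    return json.dumps(payload, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# config (de)serialisation
# ---------------------------------------------------------------------------

def config_to_yaml(cfg) -> str:
    return yaml.safe_dump(asdict(cfg), sort_keys=True)


def train_config_from_dict(d: dict) -> TrainConfig:
    d = dict(d or {})
    if "loss" in d:
        d["loss"] = LossConfig(**d["loss"])
    if "preprocess" in d:
        d["preprocess"] = PreprocessConfig(**d["preprocess"])
    if "model" in d:
        m = dict(d["model"])
        for key in ("channels", "blocks", "ae_widths"):
            if key in m:
                m[key] = tuple(m[key])
        d["model"] = ModelConfig(**m)
    return TrainConfig(**d)
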
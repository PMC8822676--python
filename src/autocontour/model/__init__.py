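"""Per-organ 2D U-Net: construction, loss, augmentation, training, inference.

The training objective is the sum of a soft Dice loss and the mean binary
cross-entropy::

    L = (1 - 2|Y.P| / (|Y| + |P| + s)) + mean(-[Y log P + (1-Y) log(1-P)])

with Y the binary ground truth, P the sigmoid output, soft intersection
``sum(Y*P)``, smoothing ``s=1e-6`` (defines the empty/empty limit) and P
clipped to ``[1e-7, 1-1e-7]``.  One independent model is trained per organ.

Optimization is Adam from an initial learning rate of 5e-5, multiplied by
0.25 whenever validation loss plateaus, floored at 1e-6.  Bounded random
affine augmentation (rotation, translation, zoom, shear) is applied on the
fly to each training pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from ..dicom_io import CTVolume
from ..preprocess import (
    OrganConfig,
    TrainingSample,
    preprocess_slice,
    resample_inplane,
    uncrop_center,
)
from ._nn import Adam, UNet

__all__ = [
    "AugmentBounds",
    "ModelParams",
    "PredictionVolume",
    "TrainingHistory",
    "ReduceLROnPlateau",
    "build_unet",
    "combined_loss",
    "sample_affine_params",
    "augment_pair",
    "train",
    "predict_volume",
    "save_weights",
    "load_weights",
]

EPS_CLIP = 1e-7
DICE_SMOOTH = 1e-6


@dataclass(frozen=True)
class AugmentBounds:
    """Maximum magnitudes of the random affine training augmentation."""

    max_rotation_deg: float = 10.0
    max_translation_frac: float = 0.15
    max_zoom_frac: float = 0.10
    max_shear_deg: float = 0.2

    def __post_init__(self):
        for v in asdict(self).values():
            if v < 0:
                raise ValueError("augmentation bounds must be nonnegative")


@dataclass
class ModelParams:
    """Architecture and optimization settings for one organ's U-Net."""

    depth: int = 4
    base_filters: int = 32
    convs_per_block: int = 2
    dropout_rate: float = 0.5
    lr_init: float = 5e-5
    lr_factor: float = 0.25
    lr_min: float = 1e-6
    plateau_patience: int = 10
    epochs: int = 200
    batch_size: int = 32
    val_fraction: float = 0.15
    input_size: int = 256
    aug: AugmentBounds = field(default_factory=AugmentBounds)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lr_min <= self.lr_init):
            raise ValueError("require 0 < lr_min <= lr_init")
        if not (0 < self.lr_factor < 1):
            raise ValueError("require 0 < lr_factor < 1")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class PredictionVolume:
    """Per-voxel organ probabilities aligned to a CT grid."""

    probs: np.ndarray  # (slices, rows, cols) in [0, 1]
    organ: str
    ct_ref: str


@dataclass
class TrainingHistory:
    """Per-epoch train loss, validation loss, and learning rate."""

    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    lr: List[float] = field(default_factory=list)

    def append(self, tl: float, vl: float, lr: float) -> None:
        self.train_loss.append(float(tl))
        self.val_loss.append(float(vl))
        self.lr.append(float(lr))

    def __len__(self) -> int:
        return len(self.train_loss)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without validation-loss improvement, never going below ``lr_min``."""

    def __init__(self, lr_init: float, factor: float = 0.25,
                 patience: int = 10, lr_min: float = 1e-6):
        self.lr = float(lr_init)
        self.factor = factor
        self.patience = patience
        self.lr_min = lr_min
        self.best = math.inf
        self.wait = 0

    def update(self, val_loss: float) -> float:
        """Record one epoch's validation loss; return the LR for the next epoch."""
        if val_loss < self.best:
            self.best = float(val_loss)
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr = max(self.lr * self.factor, self.lr_min)
                self.wait = 0
        return self.lr


def build_unet(params: ModelParams, in_channels: int = 1) -> UNet:
    """Construct the seeded per-organ U-Net described by ``params``."""
    return UNet(
        depth=params.depth,
        base_filters=params.base_filters,
        dropout_rate=params.dropout_rate,
        seed=params.seed,
        input_size=params.input_size,
        in_channels=in_channels,
        convs_per_block=params.convs_per_block,
    )


# ---------------------------------------------------------------------------
# Loss


def combined_loss(y: np.ndarray, p: np.ndarray, return_terms: bool = False):
    """Soft Dice loss plus mean binary cross-entropy (see module docstring)."""
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    # smoothing in numerator and denominator defines the empty/empty case as 0;
    # the [eps, 1-eps] clip guards only the BCE logs
    inter = float((y * p).sum())
    dice_term = 1.0 - (2.0 * inter + DICE_SMOOTH) / (y.sum() + p.sum() + DICE_SMOOTH)
    pc = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
    bce_term = float(np.mean(-(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))))
    total = dice_term + bce_term
    if return_terms:
        return total, dice_term, bce_term
    return total


def _batch_loss_terms(y: np.ndarray, p: np.ndarray):
    """Per-sample Dice (batch-averaged) and mean BCE, float32 inner work.

    Training reduces the loss the way 2D segmentation frameworks do: the
    Dice term is computed per sample over its own pixels, then averaged over
    the batch; :func:`combined_loss` applied to one sample's (Y, P) pair is
    the single-array reference definition.
    """
    y = y.astype(np.float32, copy=False)
    p = p.astype(np.float32, copy=False)
    axes = tuple(range(1, y.ndim))
    inter = (y * p).sum(axis=axes, dtype=np.float64)
    denom = (y.sum(axis=axes, dtype=np.float64)
             + p.sum(axis=axes, dtype=np.float64) + DICE_SMOOTH)
    numer = 2.0 * inter + DICE_SMOOTH
    dice_term = float(np.mean(1.0 - numer / denom))
    pc = np.clip(p, EPS_CLIP, 1.0 - EPS_CLIP)
    bce = -(y * np.log(pc) + (1.0 - y) * np.log1p(-pc))
    bce_term = float(bce.sum(dtype=np.float64)) / y.size
    return dice_term, bce_term, inter, denom, numer


def _loss_and_logit_grad(y: np.ndarray, p: np.ndarray) -> Tuple[float, np.ndarray]:
    """Batch loss and its gradient w.r.t. the pre-sigmoid logits."""
    dice_term, bce_term, inter, denom, numer = _batch_loss_terms(y, p)
    y = y.astype(np.float32, copy=False)
    p = p.astype(np.float32, copy=False)
    n = y.shape[0]
    shape = (n,) + (1,) * (y.ndim - 1)
    inv_denom = (1.0 / denom).reshape(shape).astype(np.float32)
    numer_f = numer.reshape(shape).astype(np.float32)
    # per sample: d(dice)/dp = -(2 y denom - numer) / denom^2, then / batch
    ddice_dp = (-2.0 * y * inv_denom + numer_f * inv_denom * inv_denom) / np.float32(n)
    dz = ddice_dp * (p * (1.0 - p)) + (p - y) * np.float32(1.0 / y.size)
    return dice_term + bce_term, dz.astype(np.float32, copy=False)


# ---------------------------------------------------------------------------
# Augmentation


def sample_affine_params(bounds: AugmentBounds, rng: np.random.Generator) -> Dict[str, float]:
    """Draw one augmentation parameter set, uniform within the bounds."""
    return {
        "rotation_deg": rng.uniform(-bounds.max_rotation_deg, bounds.max_rotation_deg),
        "translate_r_frac": rng.uniform(-bounds.max_translation_frac,
                                        bounds.max_translation_frac),
        "translate_c_frac": rng.uniform(-bounds.max_translation_frac,
                                        bounds.max_translation_frac),
        "zoom_frac": rng.uniform(-bounds.max_zoom_frac, bounds.max_zoom_frac),
        "shear_deg": rng.uniform(-bounds.max_shear_deg, bounds.max_shear_deg),
    }


def _affine_matrix(params: Dict[str, float], shape: Tuple[int, int]) -> np.ndarray:
    """Forward 3x3 homogeneous transform (output <- input), about the center."""
    theta = math.radians(params["rotation_deg"])
    phi = math.radians(params["shear_deg"])
    s = 1.0 + params["zoom_frac"]
    rows, cols = shape
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    shear = np.array([[1.0, math.tan(phi)], [0.0, 1.0]])
    a = rot @ shear * s
    t = np.array([params["translate_r_frac"] * rows,
                  params["translate_c_frac"] * cols])
    m = np.eye(3)
    m[:2, :2] = a
    m[:2, 2] = np.array([cr, cc]) - a @ np.array([cr, cc]) + t
    return m


def augment_pair(image: np.ndarray, label: np.ndarray, bounds: AugmentBounds,
                 rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one random affine transform identically to an image/label pair.

    The image is interpolated bilinearly, the label nearest-neighbor (stays
    binary).  All-zero bounds give the identity transform.
    """
    params = sample_affine_params(bounds, rng)
    if all(v == 0.0 for v in params.values()):
        return image, label
    m = _affine_matrix(params, image.shape)
    inv = np.linalg.inv(m)
    img_out = ndimage.affine_transform(
        image, inv[:2, :2], offset=inv[:2, 2], order=1, mode="constant", cval=0.0
    )
    lab_out = ndimage.affine_transform(
        label.astype(np.float32), inv[:2, :2], offset=inv[:2, 2], order=0,
        mode="constant", cval=0.0,
    )
    return img_out.astype(np.float32), lab_out > 0.5


# ---------------------------------------------------------------------------
# Training


def _stack(samples: Sequence[TrainingSample]) -> Tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples]).astype(np.float32)[..., None]
    y = np.stack([s.label for s in samples]).astype(np.float32)[..., None]
    return x, y


def _eval_loss(net: UNet, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    """Mean loss (training reduction) over batches, without augmentation or
    dropout."""
    losses, weights = [], []
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        p = net.forward(xb, training=False)
        dice, bce, *_ = _batch_loss_terms(yb, p)
        losses.append(dice + bce)
        weights.append(len(xb))
    return float(np.average(losses, weights=weights))


def train(train_set: Sequence[TrainingSample], val_set: Sequence[TrainingSample],
          params: ModelParams, net: Optional[UNet] = None,
          log_fn=None) -> Tuple[UNet, TrainingHistory]:
    """Train one organ's U-Net with Adam, plateau LR decay, and on-the-fly
    bounded affine augmentation.

    The weights snapshot with the best validation loss is restored at the
    end (checkpoint-and-restore; soft-Dice training can destabilize after
    converging, and the best-validation state is the one worth keeping).
    Returns the trained network and the per-epoch history.  Fully
    reproducible given ``params.seed`` on a fixed NumPy/BLAS build.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must both be nonempty")
    net = net or build_unet(params)
    opt = Adam(net)
    sched = ReduceLROnPlateau(params.lr_init, params.lr_factor,
                              params.plateau_patience, params.lr_min)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xA46]))
    history = TrainingHistory()
    xv, yv = _stack(val_set)
    n = len(train_set)
    lr = sched.lr
    best_val = math.inf
    best_weights = net.get_weights()
    for epoch in range(params.epochs):
        order = rng.permutation(n)
        epoch_losses, epoch_sizes = [], []
        for i in range(0, n, params.batch_size):
            batch = [train_set[j] for j in order[i:i + params.batch_size]]
            pairs = [augment_pair(s.image, s.label, params.aug, rng) for s in batch]
            xb = np.stack([im for im, _ in pairs]).astype(np.float32)[..., None]
            yb = np.stack([lb for _, lb in pairs]).astype(np.float32)[..., None]
            p = net.forward(xb, training=True, rng=rng)
            loss, dz = _loss_and_logit_grad(yb, p)
            if not math.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            net.backward(dz)
            opt.step(lr)
            epoch_losses.append(loss)
            epoch_sizes.append(len(batch))
        train_loss = float(np.average(epoch_losses, weights=epoch_sizes))
        val_loss = _eval_loss(net, xv, yv, params.batch_size)
        if not math.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        history.append(train_loss, val_loss, lr)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = net.get_weights()
        lr = sched.update(val_loss)
        if log_fn is not None:
            log_fn(epoch, train_loss, val_loss, lr)
    net.set_weights(best_weights)
    return net, history


# ---------------------------------------------------------------------------
# Inference


def predict_volume(net: UNet, volume: CTVolume, organ: OrganConfig,
                   batch_size: int = 8) -> PredictionVolume:
    """Run slice-wise inference and map probabilities back to the CT grid.

    Each slice follows the training preprocessing (1 mm resample, central
    crop, organ window); the 256x256 probability map is then placed back
    through the inverse crop and inverse resample.  Voxels outside the
    cropped field of view get probability 0.
    """
    rvol = resample_inplane(volume)
    preset = organ.window_preset
    x = np.stack([preprocess_slice(rvol.voxels[k], preset)
                  for k in range(rvol.n_slices)]).astype(np.float32)[..., None]
    if x.shape[1] != net.input_size or x.shape[2] != net.input_size:
        raise ValueError("preprocessed slice size does not match the network input")
    probs = np.concatenate([
        net.forward(x[i:i + batch_size], training=False)
        for i in range(0, len(x), batch_size)
    ])[..., 0]

    r_shape = rvol.voxels.shape[1:]
    native_rows, native_cols = volume.voxels.shape[1:]
    row_sp, col_sp = volume.pixel_spacing
    rr = np.arange(native_rows, dtype=np.float64) * row_sp
    cc = np.arange(native_cols, dtype=np.float64) * col_sp
    coords = np.meshgrid(rr, cc, indexing="ij")
    out = np.empty(volume.shape, dtype=np.float32)
    for k in range(volume.n_slices):
        full = uncrop_center(probs[k], r_shape, fill_value=0.0)
        if (row_sp, col_sp) == (1.0, 1.0):
            out[k] = full
        else:
            out[k] = ndimage.map_coordinates(
                full.astype(np.float64), coords, order=1, mode="constant", cval=0.0
            )
    return PredictionVolume(
        probs=np.clip(out, 0.0, 1.0), organ=organ.name, ct_ref=volume.series_uid
    )


# ---------------------------------------------------------------------------
# Persistence


def save_weights(net: UNet, path: str | Path, organ: str = "",
                 params: Optional[ModelParams] = None,
                 extra: Optional[dict] = None) -> Path:
    """Persist weights as ``.npz`` plus a JSON sidecar manifest."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **net.get_weights())
    manifest = {
        "organ": organ,
        "architecture": {
            "depth": net.depth,
            "base_filters": net.base_filters,
            "convs_per_block": net.convs_per_block,
            "dropout_rate": net.dropout_rate,
            "input_size": net.input_size,
            "seed": net.seed,
        },
        "params": asdict(params) if params is not None else None,
        "numpy_version": np.__version__,
    }
    if extra:
        manifest.update(extra)
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def load_weights(path: str | Path) -> Tuple[UNet, dict]:
    """Rebuild a network from a ``.npz`` checkpoint and its manifest."""
    path = Path(path)
    manifest = json.loads(Path(str(path) + ".manifest.json").read_text())
    arch = manifest["architecture"]
    net = UNet(
        depth=arch["depth"], base_filters=arch["base_filters"],
        dropout_rate=arch["dropout_rate"], seed=arch["seed"],
        input_size=arch["input_size"], convs_per_block=arch["convs_per_block"],
    )
    with np.load(path) as data:
        net.set_weights({k: data[k] for k in data.files})
    return net, manifest
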
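"""U-Net tumor segmentation: architecture, training, prediction and metrics.

The network is the classic encoder-decoder with skip connections: a
sequence of 9 resolution blocks whose channel widths rise from 64 through
128, 256, 512 to 1024 and descend symmetrically back to 64, each block a
pair of 3x3 convolutions with ReLU and batch normalization, 2x2 max pooling
between encoder blocks, 2x2 transposed-convolution upsampling with channel
concatenation in the decoder, and a single-channel logit output head
trained with binary cross-entropy with logits and Adam. The input is a
single-channel B-mode image (256x256 by default; any size divisible by 16
works, and scaled-down channel sequences are accepted for cheap training).

Segmentation quality is scored with pixel confusion counts and the derived
accuracy / precision / recall / Dice metrics (Dice == F1 for binary masks),
plus the tumor-to-image area ratio used to flag hard cases.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .bmode import BModeImage, resize_image, resize_mask

__all__ = [
    "UNetConfig", "TrainConfig", "AugmentParams", "UNet", "build_unet",
    "augment", "train", "predict_mask", "ConfusionCounts", "confusion",
    "SegMetrics", "metrics", "evaluate", "area_ratio", "flag_area_ratio",
    "kfold_by_group", "save_checkpoint", "load_checkpoint",
]

DEFAULT_CHANNELS = (64, 128, 256, 512, 1024, 512, 256, 128, 64)


@dataclass(frozen=True)
class UNetConfig:
    """Architecture description; must be symmetric with an odd block count."""

    block_channels: tuple[int, ...] = DEFAULT_CHANNELS
    kernel: int = 3
    input_size: int = 256
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        ch = tuple(self.block_channels)
        if len(ch) < 3 or len(ch) % 2 == 0:
            raise ValueError("block_channels must have an odd length >= 3")
        n = len(ch) // 2
        if ch[:n] != ch[:-n - 1:-1]:
            raise ValueError("encoder/decoder channel sequence must be symmetric")
        if self.input_size % (2 ** n):
            raise ValueError(f"input size must be divisible by {2 ** n}")
        object.__setattr__(self, "block_channels", ch)

    @property
    def n_levels(self) -> int:
        return len(self.block_channels) // 2


@dataclass(frozen=True)
class AugmentParams:
    rotation_deg: float = 15.0
    flip_prob: float = 0.5
    elastic_alpha: float = 34.0   # displacement magnitude, grid units
    elastic_sigma: float = 4.0    # displacement field smoothness

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(rotation_deg=0.0, flip_prob=0.0, elastic_alpha=0.0)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    learning_rate: float = 1e-2
    batch_size: int = 8
    augmentation: AugmentParams = field(default_factory=AugmentParams)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("need at least one epoch")


def _double_conv(c_in: int, c_out: int, k: int, rng) -> nn.Sequential:
    # conv -> ReLU -> batch norm, twice (activation-then-normalization order)
    return nn.Sequential(
        nn.Conv2d(c_in, c_out, k, rng), nn.ReLU(), nn.BatchNorm2d(c_out),
        nn.Conv2d(c_out, c_out, k, rng), nn.ReLU(), nn.BatchNorm2d(c_out),
    )


class UNet:
    """Encoder-decoder segmentation network mapping 1xHxW -> 1xHxW logits."""

    def __init__(self, config: UNetConfig | None = None, seed: int = 0):
        self.config = config or UNetConfig()
        rng = np.random.default_rng(seed)
        ch = self.config.block_channels
        n = self.config.n_levels
        k = self.config.kernel
        enc_ch = ch[:n]
        self.enc = []
        c_prev = self.config.in_channels
        for c in enc_ch:
            self.enc.append(_double_conv(c_prev, c, k, rng))
            c_prev = c
        self.pools = [nn.MaxPool2x2() for _ in range(n)]
        self.bottleneck = _double_conv(c_prev, ch[n], k, rng)
        c_prev = ch[n]
        self.ups, self.dec = [], []
        for c in ch[n + 1:]:
            self.ups.append(nn.ConvTranspose2x2(c_prev, c, rng))
            self.dec.append(_double_conv(2 * c, c, k, rng))
            c_prev = c
        self.head = nn.Conv2d(c_prev, self.config.out_channels, 1, rng)
        self._skips = None

    # -- graph (NHWC tensors throughout) ----------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=3)
            x = block.forward(x, train)
        if train:
            self._skips = skips
        return self.head.forward(x, train)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.head.backward(grad)
        skip_grads = [None] * len(self.enc)
        n = len(self.dec)
        for i in range(n - 1, -1, -1):
            grad = self.dec[i].backward(grad)
            c_skip = self._skips[n - 1 - i].shape[3]
            skip_grads[n - 1 - i] = grad[..., :c_skip]
            grad = self.ups[i].backward(np.ascontiguousarray(grad[..., c_skip:]))
        grad = self.bottleneck.backward(grad)
        for i in range(len(self.enc) - 1, -1, -1):
            grad = self.pools[i].backward(grad)
            grad = grad + skip_grads[i]
            grad = self.enc[i].backward(grad)
        self._skips = None

    def _modules(self) -> list[tuple[str, nn.Layer]]:
        mods = []
        for i, m in enumerate(self.enc):
            mods.append((f"enc{i}", m))
        mods.append(("bottleneck", self.bottleneck))
        for i, (u, d) in enumerate(zip(self.ups, self.dec)):
            mods.append((f"up{i}", u))
            mods.append((f"dec{i}", d))
        mods.append(("head", self.head))
        return mods

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for _, m in self._modules():
            out.extend(m.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, m in self._modules():
            for k, v in m.state().items():
                out[f"{name}/{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, m in self._modules():
            sub = {k.split("/", 1)[1]: v for k, v in state.items()
                   if k.startswith(name + "/")}
            m.load_state(sub)


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    return UNet(config, seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, mask: np.ndarray, params: AugmentParams,
            rng: np.random.Generator | int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform identically to image and mask.

    Rotation (bilinear for the image, nearest for the mask), horizontal flip,
    then elastic deformation from a Gaussian-smoothed random displacement
    field. Identity parameters return the pair unchanged; the mask stays
    binary throughout.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes must match")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    img = np.asarray(image, dtype=np.float64)
    msk = (np.asarray(mask) > 0).astype(np.float64)

    if params.rotation_deg > 0:
        angle = rng.uniform(-params.rotation_deg, params.rotation_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(msk, angle, reshape=False, order=0, mode="nearest")
    if params.flip_prob > 0 and rng.random() < params.flip_prob:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if params.elastic_alpha > 0:
        dz = ndimage.gaussian_filter(rng.uniform(-1, 1, img.shape),
                                     params.elastic_sigma) * params.elastic_alpha
        dx = ndimage.gaussian_filter(rng.uniform(-1, 1, img.shape),
                                     params.elastic_sigma) * params.elastic_alpha
        rr, cc = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]),
                             indexing="ij")
        coords = np.array([rr + dz, cc + dx])
        img = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
        msk = ndimage.map_coordinates(msk, coords, order=0, mode="nearest")
    return np.ascontiguousarray(img), (msk > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model: UNet, train_set, val_set, config: TrainConfig | None = None
          ) -> dict[str, list[float]]:
    """Train with Adam / BCE-with-logits; keep the best-validation weights.

    ``train_set`` / ``val_set`` expose ``.images`` (n, H, W) in [0, 1] and
    ``.masks`` (n, H, W) binary. Augmentation is applied on the fly to the
    training set only; validation loss is computed on the raw pairs. Raises
    on non-finite loss (divergence).
    """
    config = config or TrainConfig()
    if len(train_set.images) == 0 or len(val_set.images) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    n = len(train_set.images)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            imgs, msks = [], []
            for i in idx:
                im, mk = augment(train_set.images[i], train_set.masks[i],
                                 config.augmentation, rng)
                imgs.append(im)
                msks.append(mk)
            x = np.asarray(imgs, dtype=np.float32)[..., None]
            y = np.asarray(msks, dtype=np.float32)[..., None]
            logits = model.forward(x, train=True)
            loss, grad = nn.bce_with_logits(logits, y)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss}")
            model.backward(grad)
            opt.step()
            ep_loss += loss
            n_batches += 1
        history["train_loss"].append(ep_loss / n_batches)
        history["val_loss"].append(_eval_loss(model, val_set, config.batch_size))
        if history["val_loss"][-1] < best[0]:
            best = (history["val_loss"][-1], copy.deepcopy(model.state_dict()))
    if best[1] is not None:
        model.load_state_dict(best[1])
    return history


def _eval_loss(model: UNet, dataset, batch_size: int) -> float:
    total, count = 0.0, 0
    for start in range(0, len(dataset.images), batch_size):
        x = np.asarray(dataset.images[start:start + batch_size],
                       dtype=np.float32)[..., None]
        y = np.asarray(dataset.masks[start:start + batch_size],
                       dtype=np.float32)[..., None]
        logits = model.forward(x, train=False)
        loss, _ = nn.bce_with_logits(logits, y)
        total += loss * len(x)
        count += len(x)
    return total / count


def predict_mask(model: UNet, bmode: BModeImage | np.ndarray,
                 threshold: float = 0.5,
                 native_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Segment one frame: resize to the network input, threshold the sigmoid
    output at ``threshold``, and map the mask back to native coordinates by
    nearest-neighbor."""
    if isinstance(bmode, BModeImage):
        img = bmode.normalized()
        native_shape = native_shape or bmode.shape
    else:
        img = np.asarray(bmode, dtype=np.float64)
        native_shape = native_shape or img.shape
    size = model.config.input_size
    x = resize_image(img, (size, size)).astype(np.float32)[None, ..., None]
    logits = model.forward(x, train=False)[0, ..., 0]
    mask = (nn.sigmoid(logits) >= threshold).astype(np.uint8)
    return resize_mask(mask, native_shape)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies of a predicted mask against ground truth."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes must match")
    for arr in (pred, gt):
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("masks must be binary (0/1)")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & g)), tn=int(np.sum(~p & ~g)),
        fp=int(np.sum(p & ~g)), fn=int(np.sum(~p & g)),
    )


@dataclass(frozen=True)
class SegMetrics:
    accuracy: float
    precision: float
    recall: float
    dice: float

    @property
    def f1(self) -> float:
        # F1 is identically the Dice score for binary segmentation
        return self.dice


def metrics(counts: ConfusionCounts) -> SegMetrics:
    """Accuracy, precision, recall and Dice from confusion counts.

    Degenerate conventions: when both masks are empty the overlap metrics are
    1; when exactly one is empty they are 0.
    """
    if counts.total <= 0:
        raise ValueError("confusion counts are empty")
    accuracy = (counts.tp + counts.tn) / counts.total
    both_empty = counts.tp + counts.fp + counts.fn == 0
    if both_empty:
        return SegMetrics(accuracy=accuracy, precision=1.0, recall=1.0, dice=1.0)
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    dice = 2.0 * counts.tp / (2.0 * counts.tp + counts.fp + counts.fn)
    return SegMetrics(accuracy=accuracy, precision=precision, recall=recall, dice=dice)


def area_ratio(mask: np.ndarray) -> float:
    """Tumor-to-image area ratio: mask pixel count over total pixels."""
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary (0/1)")
    return float(mask.sum() / mask.size)


def flag_area_ratio(ratio: float, lo: float = 0.05, hi: float = 0.175) -> bool:
    """True when the ratio falls outside the reliable segmentation window."""
    return ratio < lo or ratio > hi


@dataclass
class SegReport:
    overall: SegMetrics
    per_image_dice: list[float]
    area_ratios: list[float]
    flagged: list[bool]


def evaluate(model: UNet, dataset) -> SegReport:
    """Evaluate a trained model on a labeled dataset (no augmentation)."""
    total = ConfusionCounts(0, 0, 0, 0)
    dices, ratios = [], []
    for img, msk in zip(dataset.images, dataset.masks):
        pred = predict_mask(model, img)
        c = confusion(pred, (msk > 0).astype(np.uint8))
        total = total + c
        dices.append(metrics(c).dice)
        ratios.append(area_ratio((msk > 0).astype(np.uint8)))
    return SegReport(overall=metrics(total), per_image_dice=dices,
                     area_ratios=ratios, flagged=[flag_area_ratio(r) for r in ratios])


def kfold_by_group(groups: np.ndarray, n_folds: int = 4,
                   seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """k-fold splits that keep all frames of one phantom in the same fold
    (split by subject identity, not by frame, to prevent leakage)."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if n_folds < 2 or n_folds > len(uniq):
        raise ValueError("n_folds must be between 2 and the number of groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    fold_of = {g: i % n_folds for i, g in enumerate(perm)}
    assignments = np.array([fold_of[g] for g in groups])
    splits = []
    for f in range(n_folds):
        test = np.nonzero(assignments == f)[0]
        trn = np.nonzero(assignments != f)[0]
        splits.append((trn, test))
    return splits


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet, path, train_config: TrainConfig | None = None) -> None:
    """Weights as .npz plus a JSON sidecar holding the configs."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {"unet_config": asdict(model.config)}
    if train_config is not None:
        sidecar["train_config"] = asdict(train_config)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> UNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(sidecar["unet_config"])
    cfg_d["block_channels"] = tuple(cfg_d["block_channels"])
    model = UNet(UNetConfig(**cfg_d))
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
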
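"""Dual-branch 3D U-Net for Couinaud segment segmentation.

A shared encoder-decoder produces two voxelwise outputs of the same
spatial shape as the input patch: a liver-boundary probability map
(auxiliary head) and 9-class segment probabilities (background + S1-S8,
the final output).  Training is end-to-end SGD with momentum under a
step-decay learning-rate schedule (initial 1e-3, x0.1 every 50 epochs at
full scale) and a Dice loss on both heads; inference runs the full
preprocessing + sliding-window + fusion pipeline.

In addition to the z-scored image, the network input carries three
normalized world-coordinate channels by default.  Couinaud segments are
defined by near-planar anatomical dividers at consistent absolute
positions, and a positional prior lets even a shallow, CPU-scale network
resolve them; it can be disabled via ``ModelConfig.coord_channels``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .grid import LabelMap, VolumeGrid
from .preprocessing import (
    PreprocessConfig,
    fuse_patch_predictions,
    resample_to_spacing,
    sliding_window_starts,
    zscore_normalize,
)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ShapeError",
    "UNet3D",
    "build_network",
    "boundary_target",
    "dice_loss",
    "lr_at_epoch",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

log = logging.getLogger(__name__)

DICE_EPS = 1e-5


class ShapeError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Network hyperparameters.

    Full-scale defaults are depth 4 / base 16; tests and desk-scale runs
    use depth 2 / base 8 (configurable).  ``num_classes`` is fixed at 9:
    background plus the eight Couinaud segments.
    """

    base_channels: int = 16
    depth: int = 4
    num_classes: int = 9
    boundary_head: bool = True
    batch_norm: bool = True
    coord_channels: bool = True
    head_input_skip: bool = True

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.num_classes != 9:
            raise ValueError("num_classes must be 9 (background + 8 segments)")

    @property
    def in_channels(self) -> int:
        return 1 + (3 if self.coord_channels else 0)


@dataclass
class TrainConfig:
    """Optimization schedule.  Full-scale defaults follow the reference
    protocol (SGD, lr 1e-3 decayed x0.1 every 50 epochs, batch 8, 150
    epochs); scaled-down runs override epochs/batch/lr explicitly."""

    lr_initial: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every_epochs: int = 50
    epochs: int = 150
    batch_size: int = 8
    momentum: float = 0.9
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (w_seg, w_boundary)
    # Dice alone has a vanishing gradient for classes the softmax has
    # suppressed (no log term); a voxelwise cross-entropy companion keeps
    # them trainable.  Set to 0 for the pure-Dice reading.
    ce_weight: float = 1.0
    patch_shape: tuple[int, int, int] = (160, 160, 160)
    patches_per_case: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_initial <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("lr_initial, epochs and batch_size must be positive")
        w_seg, w_bnd = self.loss_weights
        if w_seg < 0 or w_bnd < 0 or (w_seg == 0 and w_bnd == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")


def lr_at_epoch(train_config: TrainConfig, epoch: int) -> float:
    """Step-decayed learning rate: ``lr0 * factor^(epoch // every)``."""
    if not 0 <= epoch < train_config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {train_config.epochs})")
    steps = epoch // train_config.lr_decay_every_epochs
    return train_config.lr_initial * train_config.lr_decay_factor**steps


def boundary_target(liver_mask: VolumeGrid | np.ndarray) -> np.ndarray:
    """1-voxel-thick liver shell: mask minus its 6-connected erosion."""
    mask = np.asarray(liver_mask.data if isinstance(liver_mask, VolumeGrid) else liver_mask) > 0
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~interior


class UNet3D:
    """Shared encoder-decoder with segment and boundary heads."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32) -> None:
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        ch = [config.base_channels * 2**i for i in range(config.depth)]
        self.enc: list[nn.ConvBlock] = []
        cin = config.in_channels
        for c in ch:
            self.enc.append(nn.ConvBlock(cin, c, rng, config.batch_norm, dtype))
            cin = c
        self.pools = [nn.MaxPool2() for _ in range(config.depth - 1)]
        self.ups = [nn.Upsample2() for _ in range(config.depth - 1)]
        self.dec: list[nn.ConvBlock] = []
        for i in range(config.depth - 2, -1, -1):
            self.dec.append(nn.ConvBlock(ch[i + 1] + ch[i], ch[i], rng, config.batch_norm, dtype))
        # the heads optionally see the raw input channels next to the decoder
        # features: segment dividers are near-planar in the coordinate
        # channels, so a direct linear route accelerates their recovery
        head_in = ch[0] + (config.in_channels if config.head_input_skip else 0)
        self.seg_head = nn.Conv3d(head_in, config.num_classes, 1, rng=rng, dtype=dtype)
        self.bnd_head = (
            nn.Conv3d(head_in, 1, 1, rng=rng, dtype=dtype) if config.boundary_head else None
        )
        # zero-initialized heads start from uniform class probabilities,
        # which keeps the early Dice gradients symmetric across classes
        for head in (self.seg_head, self.bnd_head):
            if head is not None:
                head.params["W"][:] = 0.0
                head.params["b"][:] = 0.0

    # -- parameter plumbing ----------------------------------------------

    def named_params(self):
        for i, blk in enumerate(self.enc):
            yield from blk.named_params(f"enc{i}.")
        for i, blk in enumerate(self.dec):
            yield from blk.named_params(f"dec{i}.")
        for name in self.seg_head.params:
            yield f"seg_head.{name}", self.seg_head, name
        if self.bnd_head is not None:
            for name in self.bnd_head.params:
                yield f"bnd_head.{name}", self.bnd_head, name

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: layer.params[key].copy() for name, layer, key in self.named_params()}
        i = 0
        for blk in [*self.enc, *self.dec]:
            for layer in blk.layers:
                if isinstance(layer, nn.BatchNorm3d):
                    state[f"bn{i}.running_mean"] = layer.running_mean.copy()
                    state[f"bn{i}.running_var"] = layer.running_var.copy()
                    i += 1
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.named_params():
            layer.params[key][:] = state[name]
        i = 0
        for blk in [*self.enc, *self.dec]:
            for layer in blk.layers:
                if isinstance(layer, nn.BatchNorm3d):
                    layer.running_mean[:] = state[f"bn{i}.running_mean"]
                    layer.running_var[:] = state[f"bn{i}.running_var"]
                    i += 1

    # -- forward / backward ----------------------------------------------

    def _check_shape(self, x: np.ndarray) -> None:
        div = 2 ** (self.config.depth - 1)
        if any(s % div for s in x.shape[2:]):
            raise ShapeError(
                f"spatial shape {x.shape[2:]} not divisible by {div} "
                f"(depth {self.config.depth})"
            )

    def forward(self, x: np.ndarray, train: bool = True):
        """Input (B, C, X, Y, Z) -> (seg_logits (B, 9, ...), bnd_logits (B, 1, ...) | None)."""
        self._check_shape(x)
        skips = []
        h = x.astype(self.dtype, copy=False)
        for i, blk in enumerate(self.enc):
            h = blk.forward(h, train)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        self._skip_channels = []
        for i, blk in enumerate(self.dec):
            h = self.ups[i].forward(h, train)
            skip = skips.pop()
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, train)
        if self.config.head_input_skip:
            h = np.concatenate([h, x.astype(self.dtype, copy=False)], axis=1)
        self._head_feat_channels = h.shape[1] - (
            self.config.in_channels if self.config.head_input_skip else 0
        )
        seg = self.seg_head.forward(h, train)
        bnd = self.bnd_head.forward(h, train) if self.bnd_head is not None else None
        return seg, bnd

    def backward(self, d_seg: np.ndarray, d_bnd: np.ndarray | None) -> None:
        """Accumulate parameter gradients for one forward pass."""
        depth = self.config.depth
        dh = self.seg_head.backward(d_seg)
        if self.bnd_head is not None and d_bnd is not None:
            dh = dh + self.bnd_head.backward(d_bnd)
        if self.config.head_input_skip:
            dh = dh[:, : self._head_feat_channels]  # input branch gets no gradient
        # decoder: dec[j] works at encoder level i = depth-2-j
        skip_grads: dict[int, np.ndarray] = {}
        for j in range(len(self.dec) - 1, -1, -1):
            dcat = self.dec[j].backward(dh)
            c = self._skip_channels[j]
            level = depth - 2 - j
            skip_grads[level] = dcat[:, :c]
            dh = self.ups[j].backward(dcat[:, c:])
        # bottleneck, then back up the encoder adding skip gradients
        dh = self.enc[depth - 1].backward(dh)
        for i in range(depth - 2, -1, -1):
            dh = self.pools[i].backward(dh)
            dh = dh + skip_grads[i]
            dh = self.enc[i].backward(dh)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    m = logits.max(axis=axis, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=axis, keepdims=True)


def dice_loss(
    pred_probs: np.ndarray, target_onehot: np.ndarray, smooth: float = DICE_EPS,
    foreground_only: bool = True,
):
    """Soft Dice loss and its gradient with respect to the probabilities.

    ``1 - mean_c (2 sum(p_c t_c) + eps) / (sum p_c + sum t_c + eps)`` with
    the mean over foreground classes (channel 0 excluded when
    ``foreground_only`` and there is more than one channel).  Sums run
    over batch and space jointly, so absent classes still contribute
    through the smoothing term (deterministic).  Returns ``(loss, dprobs)``.
    """
    if pred_probs.shape != target_onehot.shape:
        raise ShapeError("prediction and target shapes differ")
    C = pred_probs.shape[1]
    classes = range(1, C) if (foreground_only and C > 1) else range(C)
    axes = (0, 2, 3, 4)
    p_sum = pred_probs.sum(axis=axes)
    t_sum = target_onehot.sum(axis=axes)
    pt_sum = (pred_probs * target_onehot).sum(axis=axes)
    loss = 0.0
    dprobs = np.zeros_like(pred_probs, dtype=np.float64)
    n = len(list(classes))
    for c in classes:
        num = 2.0 * pt_sum[c] + smooth
        den = p_sum[c] + t_sum[c] + smooth
        loss += 1.0 - num / den
        # d/dp_c of (num/den): (2 t den - num) / den^2
        dprobs[:, c] = -(2.0 * target_onehot[:, c] * den - num) / den**2
    loss /= n
    dprobs /= n
    return float(loss), dprobs


def softmax_dice_grad(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Backprop dL/dp through the channel softmax to the logits."""
    inner = (dprobs * probs).sum(axis=1, keepdims=True)
    return (probs * (dprobs - inner)).astype(probs.dtype)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def build_network(config: ModelConfig, seed: int = 0, dtype=np.float32) -> UNet3D:
    """Construct a dual-head 3D U-Net with seeded initialization."""
    return UNet3D(config, seed=seed, dtype=dtype)


def _coord_grids(shape, dtype=np.float32) -> np.ndarray:
    """Three channels of per-axis coordinates normalized to [-1, 1]."""
    chans = []
    for a, n in enumerate(shape):
        c = np.linspace(-1.0, 1.0, n, dtype=dtype) if n > 1 else np.zeros(1, dtype=dtype)
        shp = [1, 1, 1]
        shp[a] = n
        chans.append(np.broadcast_to(c.reshape(shp), shape))
    return np.stack(chans, axis=0).astype(dtype)


def _prepare_case(
    image: VolumeGrid, labels: LabelMap, model_config: ModelConfig,
    preprocess_config: PreprocessConfig,
):
    """Resample + z-score one case; returns (input (C,...), labels (...), boundary (...))."""
    img = image
    lab = labels
    if not np.allclose(image.spacing, preprocess_config.target_spacing_mm):
        img = resample_to_spacing(image, preprocess_config.target_spacing_mm, "linear")
        lab = resample_to_spacing(labels, preprocess_config.target_spacing_mm, "nearest")
    img = zscore_normalize(img, preprocess_config.clip_percentiles)
    chans = [np.asarray(img.data, dtype=np.float32)[None]]
    if model_config.coord_channels:
        chans.append(_coord_grids(img.shape))
    x = np.concatenate(chans, axis=0)
    lab_arr = np.asarray(lab.data).astype(np.int64)
    bnd = boundary_target(lab_arr > 0).astype(np.float32)
    return x, lab_arr, bnd


def _onehot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], num_classes, *labels.shape[1:]), dtype=np.float32)
    for c in range(num_classes):
        out[:, c] = labels == c
    return out


def train(
    cases,
    model_config: ModelConfig,
    train_config: TrainConfig,
    preprocess_config: PreprocessConfig | None = None,
    checkpoint_every: int = 0,
    checkpoint_dir=None,
):
    """Train the dual-head network on (image, labels) pairs.

    ``cases`` is a sequence of ``PhantomCase``-like objects (attributes
    ``image`` and ``labels``) or ``(image, labels)`` tuples.  Returns
    ``(model, history)`` with one history row per epoch (epoch, lr, mean
    total/segment/boundary loss).  Every randomness source derives from
    ``train_config.seed``.  Raises on non-finite loss.
    """
    if len(cases) == 0:
        raise ValueError("need at least one training case")
    preprocess_config = preprocess_config or PreprocessConfig()
    prepared = []
    for case in cases:
        image, labels = (
            (case.image, case.labels) if hasattr(case, "image") else (case[0], case[1])
        )
        prepared.append(_prepare_case(image, labels, model_config, preprocess_config))

    model = build_network(model_config, seed=train_config.seed)
    opt = nn.SGD(model.named_params(), momentum=train_config.momentum)
    w_seg, w_bnd = train_config.loss_weights
    patch = train_config.patch_shape
    history = []

    for epoch in range(train_config.epochs):
        lr = lr_at_epoch(train_config, epoch)
        rng = np.random.default_rng([train_config.seed & 0x7FFFFFFF, 7, epoch])
        # one random crop offset per (case, repeat); repetition sampling
        # keeps small datasets compatible with any batch size
        draws = [(i,) for i in range(len(prepared)) for _ in range(train_config.patches_per_case)]
        while len(draws) < train_config.batch_size:
            draws.append((int(rng.integers(len(prepared))),))
        order = rng.permutation(len(draws))
        samples = []
        for k in order:
            i = draws[k][0]
            x, lab, bnd = prepared[i]
            offs = tuple(
                int(rng.integers(0, max(1, s - p + 1)))
                for s, p in zip(x.shape[1:], patch)
            )
            samples.append((i, offs))

        ep_loss = ep_seg = ep_bnd = 0.0
        n_batches = 0
        for b0 in range(0, len(samples), train_config.batch_size):
            batch = samples[b0 : b0 + train_config.batch_size]
            xs, ls, bs = [], [], []
            for i, offs in batch:
                x, lab, bnd = prepared[i]
                sl = tuple(slice(o, o + p) for o, p in zip(offs, patch))
                xs.append(x[(slice(None), *sl)])
                ls.append(lab[sl])
                bs.append(bnd[sl])
            xb = np.stack(xs)
            lb = np.stack(ls)
            bb = np.stack(bs)[:, None]

            seg_logits, bnd_logits = model.forward(xb, train=True)
            probs = softmax(seg_logits)
            onehot = _onehot(lb, model_config.num_classes)
            loss_seg, dprobs = dice_loss(probs, onehot)
            d_seg = softmax_dice_grad(probs, w_seg * dprobs)
            if train_config.ce_weight > 0:
                n_vox = probs[:, 0].size
                p_true = np.clip((probs * onehot).sum(axis=1), 1e-8, None)
                loss_ce = float(-np.log(p_true).mean())
                loss_seg = loss_seg + train_config.ce_weight * loss_ce
                d_seg = d_seg + (
                    w_seg * train_config.ce_weight * (probs - onehot) / n_vox
                ).astype(d_seg.dtype)
            loss_bnd = 0.0
            d_bnd = None
            if bnd_logits is not None:
                p_bnd = sigmoid(bnd_logits)
                loss_bnd, dp_bnd = dice_loss(p_bnd, bb, foreground_only=False)
                d_bnd = (w_bnd * dp_bnd * p_bnd * (1.0 - p_bnd)).astype(np.float32)
            total = w_seg * loss_seg + w_bnd * loss_bnd
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (seg={loss_seg}, bnd={loss_bnd})"
                )
            model.backward(d_seg, d_bnd)
            opt.step(lr)
            ep_loss += total
            ep_seg += loss_seg
            ep_bnd += loss_bnd
            n_batches += 1

        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "loss": ep_loss / n_batches,
                "loss_seg": ep_seg / n_batches,
                "loss_boundary": ep_bnd / n_batches,
            }
        )
        log.info("epoch %d lr %.2e loss %.4f", epoch, lr, ep_loss / n_batches)
        if checkpoint_every and checkpoint_dir and (epoch + 1) % checkpoint_every == 0:
            save_checkpoint(model, f"{checkpoint_dir}/epoch{epoch + 1:04d}.npz")
    return model, history


def predict(
    volume: VolumeGrid,
    model: UNet3D,
    preprocess_config: PreprocessConfig | None = None,
    patch_shape: tuple[int, int, int] | None = None,
    overlap_fraction: float = 0.5,
):
    """Full inference pipeline on a native-spacing volume.

    resample -> z-score (+ coordinate channels) -> sliding window ->
    fuse -> argmax -> resample labels back to the native grid (nearest).
    Returns ``(LabelMap on the native grid, class probabilities on the
    processing grid)``.
    """
    preprocess_config = preprocess_config or PreprocessConfig()
    patch = tuple(patch_shape or preprocess_config.patch_shape)
    proc = volume
    if not np.allclose(volume.spacing, preprocess_config.target_spacing_mm):
        proc = resample_to_spacing(volume, preprocess_config.target_spacing_mm, "linear")
    normed = zscore_normalize(proc, preprocess_config.clip_percentiles)
    chans = [np.asarray(normed.data, dtype=np.float32)[None]]
    if model.config.coord_channels:
        chans.append(_coord_grids(normed.shape))
    x = np.concatenate(chans, axis=0)

    # pad so every axis accommodates the patch
    spatial = x.shape[1:]
    pad = []
    for n, p in zip(spatial, patch):
        deficit = max(0, p - n)
        pad.append((deficit // 2, deficit - deficit // 2))
    xp = np.pad(x, [(0, 0), *pad], mode="constant")
    padded_shape = xp.shape[1:]

    strides = [max(1, int(round(p * (1.0 - overlap_fraction)))) for p in patch]
    starts = [
        sliding_window_starts(n, p, s) for n, p, s in zip(padded_shape, patch, strides)
    ]
    patches = []
    import itertools

    for offset in itertools.product(*starts):
        sl = tuple(slice(o, o + p) for o, p in zip(offset, patch))
        seg_logits, _ = model.forward(xp[(slice(None), *sl)][None], train=False)
        patches.append((softmax(seg_logits)[0], offset))
    fused = fuse_patch_predictions(patches, padded_shape)
    crop = tuple(slice(b, b + n) for (b, _), n in zip(pad, spatial))
    probs = fused[(slice(None), *crop)]
    labels_proc = LabelMap(
        np.argmax(probs, axis=0).astype(np.int16), proc.spacing, proc.origin
    )

    if labels_proc.shape == volume.shape and np.allclose(proc.spacing, volume.spacing):
        return labels_proc, probs
    # nearest-neighbor mapping back onto the native voxel centers
    idx = []
    for a in range(3):
        centers = np.arange(volume.shape[a]) * volume.spacing[a]
        j = np.round(centers / proc.spacing[a]).astype(int)
        idx.append(np.clip(j, 0, labels_proc.shape[a] - 1))
    native = np.asarray(labels_proc.data)[np.ix_(*idx)]
    return LabelMap(native.astype(np.int16), volume.spacing, volume.origin), probs


def save_checkpoint(model: UNet3D, path) -> None:
    """Self-describing checkpoint: parameters + config (version tagged)."""
    meta = json.dumps({"format": "couinaud3d/v1", "model": asdict(model.config)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> UNet3D:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != "couinaud3d/v1":
            raise ValueError("unrecognized checkpoint format")
        config = ModelConfig(**meta["model"])
        model = build_network(config, seed=0)
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    return model
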
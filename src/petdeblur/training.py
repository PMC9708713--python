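"""Preprocessing, patch-based training and overlapping-tile inference.

Volumes are standardized by the mean of the standard-quality image of each
pair (the ground truth shares its pair's factor, so the mapping the network
learns is scale-free); factors are kept in a :class:`NormalizationRecord`
and re-applied to predictions, restoring Bq/cm^3 before any quantitative
analysis.  Training minimizes mean absolute error over randomly sampled
paired patches with AdamW, a reduce-on-plateau learning-rate schedule and
early stopping, holding out volumes (not patches) for validation and test.
Whole volumes are predicted by sliding overlapping patches and blending the
overlaps with normalized window weights.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._grid import resample_centered
from .errors import ConfigurationError
from .network import Network, NetworkSpec, build_network

#: Default training grid (1 mm isotropic) for full-size head volumes.
TRAINING_GRID_SHAPE = (192, 256, 256)
TRAINING_VOXEL_MM = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class NormalizationRecord:
    """Standardization factor (mean of the standard-quality volume)."""

    volume_id: str
    factor: float

    def __post_init__(self):
        if not self.factor > 0:
            raise ConfigurationError("normalization factor must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults are the full-scale settings (patch 32^3, 20 patches per volume,
    MAE loss, AdamW at lr 1e-4, batch 50, at most 200 epochs, reduce lr x0.1
    after 10 stagnant validation epochs, stop after 60).  Desk-scale runs
    shrink the patch count, batch and epochs; see ``petdeblur.experiment``.
    """

    patch_size: int = 32
    patches_per_volume: int = 20
    lr: float = 1e-4
    lr_reduce_factor: float = 0.1
    lr_patience_epochs: int = 10
    weight_decay: float = 1e-2
    batch_size: int = 50
    max_epochs: int = 200
    early_stop_patience: int = 60
    min_rel_improvement: float = 1e-6
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    resample_patches_each_epoch: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.patch_size < 16:
            raise ConfigurationError("patch_size must be at least 16")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")
        if self.lr_patience_epochs >= self.max_epochs:
            raise ConfigurationError("lr patience must be below max_epochs")
        if not (0 < self.lr_reduce_factor < 1):
            raise ConfigurationError("lr_reduce_factor must lie in (0, 1)")


@dataclass(frozen=True)
class TilingConfig:
    """Overlapping-tile inference parameters.

    ``blend_window`` weights each patch's contribution ("cosine" = Hann
    taper, "uniform" = flat); overlaps are renormalized so weights sum to
    one at every voxel.  ``trim_margin`` additionally zeroes the weight of
    a margin at every patch face that does not touch the volume boundary,
    so voxels are only predicted by patches that give them full
    receptive-field context; ``None`` picks the largest margin compatible
    with full coverage, capped by the network's receptive half-width.
    """

    patch_size: int = 32
    stride: int = 8
    blend_window: str = "cosine"
    trim_margin: int | None = None

    def validate(self) -> None:
        if self.stride > self.patch_size:
            raise ConfigurationError("stride must not exceed patch_size")
        if self.stride < 1:
            raise ConfigurationError("stride must be positive")
        if self.blend_window not in ("cosine", "uniform"):
            raise ConfigurationError("blend_window must be 'cosine' or 'uniform'")


def resample_to_training_grid(
    values: np.ndarray,
    voxel_size_mm,
    target_shape: tuple[int, int, int] = TRAINING_GRID_SHAPE,
    target_voxel_mm=TRAINING_VOXEL_MM,
) -> np.ndarray:
    """Trilinearly resample onto the common training grid (centered FOV,
    zero fill outside the source)."""
    for n, v, tn, tv in zip(values.shape, voxel_size_mm, target_shape, target_voxel_mm):
        if n * v > tn * tv + 1e-6:
            raise ConfigurationError(
                f"source extent {n * v:.1f} mm exceeds target extent "
                f"{tn * tv:.1f} mm; crop the source first"
            )
    return resample_centered(values, voxel_size_mm, target_voxel_mm, target_shape)


def preprocess_pair(
    sq: np.ndarray, gt: np.ndarray, volume_id: str = ""
) -> tuple[np.ndarray, np.ndarray, NormalizationRecord]:
    """Standardize a pair by the mean of the standard-quality volume."""
    factor = float(np.mean(sq))
    if factor <= 0:
        raise ConfigurationError("standard-quality volume mean must be positive")
    record = NormalizationRecord(volume_id=volume_id, factor=factor)
    return sq / factor, gt / factor, record


def denormalize(values: np.ndarray, record: NormalizationRecord) -> np.ndarray:
    return values * record.factor


def sample_patches(
    sq_norm: np.ndarray,
    gt_norm: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``patches_per_volume`` aligned patch pairs.

    Patch centers are drawn uniformly from voxels where the ground truth is
    positive and the patch fits inside the volume; sampling is without
    replacement when enough candidates exist.
    """
    p = cfg.patch_size
    shape = gt_norm.shape
    if any(n < p for n in shape):
        raise ConfigurationError(f"volume {shape} cannot host a {p}^3 patch")
    lo, hi = p // 2, [n - p + p // 2 for n in shape]
    candidates = gt_norm > 0
    for axis, h in enumerate(hi):
        sl = [slice(None)] * 3
        sl[axis] = slice(0, lo)
        candidates[tuple(sl)] = False
        sl[axis] = slice(h + 1, None)
        candidates[tuple(sl)] = False
    idx = np.flatnonzero(candidates)
    if idx.size == 0:
        raise ConfigurationError("no positive ground-truth voxels to center patches on")
    k = cfg.patches_per_volume
    picks = rng.choice(idx, size=k, replace=idx.size < k)
    sq_patches = np.empty((k, p, p, p), dtype=sq_norm.dtype)
    gt_patches = np.empty((k, p, p, p), dtype=gt_norm.dtype)
    for out_i, flat in enumerate(picks):
        c = np.unravel_index(int(flat), shape)
        s = tuple(slice(ci - p // 2, ci - p // 2 + p) for ci in c)
        sq_patches[out_i] = sq_norm[s]
        gt_patches[out_i] = gt_norm[s]
    return sq_patches, gt_patches


class AdamW:
    """Adam with decoupled weight decay (decay applied to conv weights only)."""

    def __init__(self, params, lr, weight_decay=1e-2, betas=(0.9, 0.999), eps=1e-8):
        self.params = params  # list of (name, value, grad, is_decayed)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(v, dtype=np.float64) for _, v, _, _ in params]
        self.v = [np.zeros_like(v, dtype=np.float64) for _, v, _, _ in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (name, value, grad, decayed), m, v in zip(self.params, self.m, self.v):
            g = grad.astype(np.float64)
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if decayed and self.weight_decay:
                update = update + self.weight_decay * value
            value -= (self.lr * update).astype(value.dtype)


@dataclass
class TrainResult:
    """Best-validation checkpoint plus the per-epoch loss history."""

    network: Network
    history: pd.DataFrame
    split: dict[str, list[int]]
    records: list[NormalizationRecord]
    best_epoch: int
    best_val_loss: float


def split_volumes(
    n: int, fractions: tuple[float, float, float], rng: np.random.Generator
) -> dict[str, list[int]]:
    """Volume-level train/val/test split (each partition non-empty)."""
    if n < 3:
        raise ConfigurationError("need at least 3 volumes to split")
    order = rng.permutation(n)
    n_val = max(1, round(fractions[1] * n))
    n_test = max(1, round(fractions[2] * n))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ConfigurationError(f"split leaves no training volumes for n={n}")
    return {
        "train": sorted(int(i) for i in order[:n_train]),
        "val": sorted(int(i) for i in order[n_train:n_train + n_val]),
        "test": sorted(int(i) for i in order[n_train + n_val:]),
    }


def _mae_and_grad(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad


def train(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    net_spec: NetworkSpec,
    cfg: TrainConfig,
    split: dict[str, list[int]] | None = None,
) -> TrainResult:
    """Train a network on (standard-quality, ground-truth) volume pairs.

    ``pairs`` hold raw Bq/cm^3 volumes on a common grid; standardization,
    the volume-level split, patch sampling, optimization, the LR plateau
    schedule and early stopping all follow the config.  The returned network
    carries the parameters of the best validation epoch.  Fully reproducible
    from ``cfg.seed``.
    """
    cfg.validate()
    net_spec.validate()
    rng = np.random.default_rng(cfg.seed)
    if split is None:
        split = split_volumes(len(pairs), cfg.split, rng)
    for part in ("train", "val"):
        if not split.get(part):
            raise ConfigurationError(f"empty {part} partition")

    norm_pairs, records = [], []
    for i, (sq, gt) in enumerate(pairs):
        sq_n, gt_n, rec = preprocess_pair(
            np.asarray(sq, dtype=np.float32),
            np.asarray(gt, dtype=np.float32),
            volume_id=str(i),
        )
        norm_pairs.append((sq_n, gt_n))
        records.append(rec)

    net = build_network(net_spec, seed=int(rng.integers(2**31)))
    opt = AdamW(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    # Validation patches are drawn once so the early-stopping monitor is a
    # fixed quantity across epochs.
    val_rng = np.random.default_rng(int(rng.integers(2**31)))
    val_sq, val_gt = [], []
    for i in split["val"]:
        s, g = sample_patches(*norm_pairs[i], cfg, val_rng)
        val_sq.append(s)
        val_gt.append(g)
    val_sq = np.concatenate(val_sq)
    val_gt = np.concatenate(val_gt)

    train_patches = None
    history_rows = []
    best_val = np.inf
    best_state = None
    best_epoch = -1
    stagnant = 0
    lr = cfg.lr

    for epoch in range(cfg.max_epochs):
        t0 = time.perf_counter()
        if train_patches is None or cfg.resample_patches_each_epoch:
            epoch_rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 1000 + epoch]).generate_state(1)[0]
            )
            sq_list, gt_list = [], []
            for i in split["train"]:
                s, g = sample_patches(*norm_pairs[i], cfg, epoch_rng)
                sq_list.append(s)
                gt_list.append(g)
            train_patches = (np.concatenate(sq_list), np.concatenate(gt_list))
        xs, ys = train_patches
        order = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 2000 + epoch]).generate_state(1)[0]
        ).permutation(len(xs))

        net.training = True
        train_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            pred = net.forward(xs[batch])
            loss, grad = _mae_and_grad(pred, ys[batch])
            net.backward(grad)
            opt.lr = lr
            opt.step()
            train_losses.append(loss)
        net.training = False

        val_losses = [
            _mae_and_grad(net.forward(val_sq[s:s + cfg.batch_size]),
                          val_gt[s:s + cfg.batch_size])[0]
            for s in range(0, len(val_sq), cfg.batch_size)
        ]
        val_loss = float(np.mean(val_losses))
        improved = not np.isfinite(best_val) or (
            val_loss < best_val * (1.0 - cfg.min_rel_improvement)
        )
        if improved:
            best_val = val_loss
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
            stagnant = 0
        else:
            stagnant += 1
        if stagnant > 0 and stagnant % cfg.lr_patience_epochs == 0:
            lr *= cfg.lr_reduce_factor
        history_rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(train_losses)),
                "val_loss": val_loss,
                "lr": lr,
                "seconds": time.perf_counter() - t0,
            }
        )
        if stagnant > cfg.early_stop_patience:
            break

    if best_state is not None:
        net.load_state_dict(best_state)
    return TrainResult(
        network=net,
        history=pd.DataFrame(history_rows),
        split=split,
        records=records,
        best_epoch=best_epoch,
        best_val_loss=best_val,
    )


# -- tiled inference -------------------------------------------------------

def _window_1d(n: int, kind: str) -> np.ndarray:
    if kind == "uniform":
        return np.ones(n)
    # Hann taper over voxel centers; strictly positive everywhere.
    return np.sin(np.pi * (np.arange(n) + 0.5) / n) ** 2


def _tile_starts(size: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, size - patch + 1, stride))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def predict_volume(
    net: Network,
    sq_volume: np.ndarray,
    tiling: TilingConfig,
    record: NormalizationRecord | None = None,
    batch_tiles: int = 8,
) -> np.ndarray:
    """Predict a whole volume by blending overlapping patch predictions.

    The input is standardized by ``record.factor`` (computed from the volume
    itself when no record is given), tiled with the configured patch size
    and stride (edge tiles clamped inside the volume), pushed through the
    network in eval mode, and blended: each voxel's output is the
    window-weighted average of all patch predictions covering it, then
    rescaled back to Bq/cm^3.  Patch faces that do not touch the volume
    boundary have a receptive-field-aware margin excluded from blending so
    every contribution carries full spatial context.
    """
    tiling.validate()
    p, stride = tiling.patch_size, tiling.stride
    vol = np.asarray(sq_volume, dtype=np.float32)
    if any(n < p for n in vol.shape):
        raise ConfigurationError(f"volume {vol.shape} smaller than patch {p}")
    if record is None:
        record = NormalizationRecord(volume_id="", factor=float(vol.mean()))
    xn = vol / np.float32(record.factor)

    margin = tiling.trim_margin
    if margin is None:
        rf_half = (net.spec.receptive_field - 1) // 2
        margin = min(rf_half, (p - stride) // 2)
    if p - 2 * margin < stride:
        raise ConfigurationError(
            f"trim_margin {margin} breaks coverage for patch {p}, stride {stride}"
        )

    window = _window_1d(p, tiling.blend_window)
    w3 = window[:, None, None] * window[None, :, None] * window[None, None, :]

    starts = [_tile_starts(n, p, stride) for n in vol.shape]
    tiles = [(a, b, c) for a in starts[0] for b in starts[1] for c in starts[2]]
    num = np.zeros(vol.shape, dtype=np.float64)
    den = np.zeros(vol.shape, dtype=np.float64)

    was_training, net.training = net.training, False
    try:
        for group in range(0, len(tiles), batch_tiles):
            chunk = tiles[group:group + batch_tiles]
            batch = np.stack(
                [xn[a:a + p, b:b + p, c:c + p] for a, b, c in chunk]
            )
            pred = net.forward(batch)
            for patch_pred, (a, b, c) in zip(pred, chunk):
                w = w3
                if margin > 0:
                    w = w3.copy()
                    for axis, (start, size) in enumerate(
                        zip((a, b, c), vol.shape)
                    ):
                        sl = [slice(None)] * 3
                        if start > 0:
                            sl[axis] = slice(0, margin)
                            w[tuple(sl)] = 0.0
                        if start + p < size:
                            sl[axis] = slice(p - margin, None)
                            w[tuple(sl)] = 0.0
                region = np.s_[a:a + p, b:b + p, c:c + p]
                num[region] += w * patch_pred.astype(np.float64)
                den[region] += w
    finally:
        net.training = was_training
    if not np.all(den > 0):
        raise ConfigurationError("tiling failed to cover the volume")
    return (num / den) * record.factor
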
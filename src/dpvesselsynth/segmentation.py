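"""Patch-based U-Net vessel segmentation: training, selection, inference.

The utility of generated image-label pairs is read out end-to-end: a slim
U-Net is trained on (possibly synthetic) patches with a soft-Dice loss,
the best of a hyper-parameter grid is selected by mean validation-volume
Dice, and the winner is evaluated on held-out volumes via slice-wise
patch tiling.

The network is an encoder-decoder with skip connections: two encoder
levels (3x3 convolution + ReLU, 2x2 max pool), a bottleneck with optional
dropout, and two decoder levels (2x nearest upsampling, skip
concatenation, 3x3 convolution + ReLU) followed by a 1x1 convolution and
sigmoid.  Slim channel widths keep CPU training practical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .metrics import bahd, dsc
from .phantoms import PatchSet, PhantomVolume

__all__ = [
    "SegConfig",
    "SegReport",
    "UNet",
    "default_grid",
    "dice_loss_grad",
    "train_unet",
    "select_model",
    "predict_patches",
    "predict_volume",
    "evaluate_volumes",
]


@dataclass(frozen=True)
class SegConfig:
    """U-Net training hyper-parameters (one grid point)."""

    learning_rate: float = 1e-3
    dropout: float = 0.0
    augment: bool = False
    epochs: int = 10
    batch_size: int = 8
    base_channels: int = 8
    seed: int = 0


def default_grid(epochs: int = 10, batch_size: int = 8, seed: int = 0) -> list[SegConfig]:
    """The 8-point grid: lr {1e-3, 1e-4} x dropout {0, 0.1} x augment {off, on}."""
    grid = []
    for lr in (1e-3, 1e-4):
        for dr in (0.0, 0.1):
            for aug in (False, True):
                grid.append(
                    SegConfig(
                        learning_rate=lr,
                        dropout=dr,
                        augment=aug,
                        epochs=epochs,
                        batch_size=batch_size,
                        seed=seed,
                    )
                )
    return grid


@dataclass
class SegReport:
    """Per-volume DSC and bAHD with mean/SD aggregation.

    Volumes for which the bAHD is undefined (empty prediction or empty
    ground truth) carry NaN in ``bahd_values``; aggregation ignores NaNs.
    """

    volume_ids: list[str]
    dsc_values: list[float]
    bahd_values: list[float]
    dataset_tag: str = "test"
    config: SegConfig | None = None

    @property
    def mean_dsc(self) -> float:
        return float(np.mean(self.dsc_values))

    @property
    def sd_dsc(self) -> float:
        return float(np.std(self.dsc_values))

    @property
    def mean_bahd(self) -> float:
        vals = np.asarray(self.bahd_values, dtype=float)
        return float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")

    @property
    def sd_bahd(self) -> float:
        vals = np.asarray(self.bahd_values, dtype=float)
        return float(np.nanstd(vals)) if np.any(np.isfinite(vals)) else float("nan")


class UNet:
    """Two-level slim U-Net over P x P patches (P divisible by 4)."""

    def __init__(self, cfg: SegConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        f = cfg.base_channels
        self.cfg = cfg
        self.enc1 = nn.Conv2d(1, f, 3, rng, pad=1)
        self.enc2 = nn.Conv2d(f, 2 * f, 3, rng, pad=1)
        self.bott = nn.Conv2d(2 * f, 4 * f, 3, rng, pad=1)
        self.dec2 = nn.Conv2d(4 * f + 2 * f, 2 * f, 3, rng, pad=1)
        self.dec1 = nn.Conv2d(2 * f + f, f, 3, rng, pad=1)
        self.head = nn.Conv2d(f, 1, 1, rng)
        self.pool1, self.pool2 = nn.MaxPool2x(), nn.MaxPool2x()
        self.up1, self.up2 = nn.Upsample2x(), nn.Upsample2x()
        self.acts = [nn.ReLU() for _ in range(5)]
        self.drop = nn.Dropout(cfg.dropout, np.random.default_rng(cfg.seed + 7))
        self._convs = [self.enc1, self.enc2, self.bott, self.dec2, self.dec1, self.head]

    def named_params(self) -> list[tuple[nn.Layer, str]]:
        return [(l, n) for l in self._convs for n in l.params]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Input (B, 1, P, P) -> vessel probability (B, 1, P, P)."""
        x = np.asarray(x, dtype=nn.DTYPE)
        a1 = self.acts[0].forward(self.enc1.forward(x, train), train)
        a2 = self.acts[1].forward(self.enc2.forward(self.pool1.forward(a1, train), train), train)
        b = self.drop.forward(
            self.acts[2].forward(self.bott.forward(self.pool2.forward(a2, train), train), train),
            train,
        )
        u2 = np.concatenate([self.up1.forward(b, train), a2], axis=1)
        d2 = self.acts[3].forward(self.dec2.forward(u2, train), train)
        u1 = np.concatenate([self.up2.forward(d2, train), a1], axis=1)
        d1 = self.acts[4].forward(self.dec1.forward(u1, train), train)
        self._logits = self.head.forward(d1, train)
        self._probs = 1.0 / (1.0 + np.exp(-np.clip(self._logits, -60, 60)))
        self._c_b = b.shape[1]
        self._c_d2 = d2.shape[1]
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        dprobs = np.asarray(dprobs, dtype=nn.DTYPE)
        dlogits = dprobs * self._probs * (1 - self._probs)
        dd1 = self.head.backward(dlogits)
        du1 = self.dec1.backward(self.acts[4].backward(dd1))
        d_up2, da1_skip = du1[:, : self._c_d2], du1[:, self._c_d2 :]
        dd2 = self.up2.backward(d_up2)
        du2 = self.dec2.backward(self.acts[3].backward(dd2))
        d_up1, da2_skip = du2[:, : self._c_b], du2[:, self._c_b :]
        db = self.up1.backward(d_up1)
        da2 = self.pool2.backward(
            self.bott.backward(self.acts[2].backward(self.drop.backward(db)))
        )
        da2 = da2 + da2_skip
        da1 = self.pool1.backward(self.enc2.backward(self.acts[1].backward(da2)))
        da1 = da1 + da1_skip
        self.enc1.backward(self.acts[0].backward(da1))


def dice_loss_grad(probs: np.ndarray, labels: np.ndarray, smooth: float = 1.0):
    """Soft-Dice loss over the whole batch and its gradient w.r.t. probs.

    loss = 1 - (2 sum(p g) + s) / (sum(p) + sum(g) + s).  A batch-global
    Dice matches the class-imbalanced setting (patches may be all
    background).
    """
    p, g = probs, labels
    inter = float((p * g).sum())
    denom = float(p.sum() + g.sum()) + smooth
    dice = (2 * inter + smooth) / denom
    dloss_dp = -(2 * g * denom - (2 * inter + smooth)) / denom**2
    return 1.0 - dice, dloss_dp


def _augment_batch(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Label-consistent flips and 90-degree rotations, per sample."""
    x, y = x.copy(), y.copy()
    for i in range(x.shape[0]):
        k = int(rng.integers(0, 4))
        if k:
            x[i, 0] = np.rot90(x[i, 0], k)
            y[i, 0] = np.rot90(y[i, 0], k)
        if rng.random() < 0.5:
            x[i, 0] = np.fliplr(x[i, 0])
            y[i, 0] = np.fliplr(y[i, 0])
    return x, y


def train_unet(pairs: PatchSet, cfg: SegConfig) -> UNet:
    """Train a U-Net on labeled patches with soft-Dice loss and Adam."""
    if len(pairs) == 0:
        raise ValueError("training patch set is empty")
    X = pairs.images()[:, None, :, :].astype(float)
    Y = pairs.labels()[:, None, :, :].astype(float)
    if Y.sum() == 0:
        import warnings

        warnings.warn("all training labels are empty; the model may be degenerate")
    ss = np.random.SeedSequence(cfg.seed)
    rng_shuffle, rng_aug, rng_init = (np.random.default_rng(s) for s in ss.spawn(3))
    model = UNet(cfg, rng_init)
    opt = nn.Adam(model, cfg.learning_rate)  # type: ignore[arg-type]
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng_shuffle.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            if cfg.augment:
                xb, yb = _augment_batch(xb, yb, rng_aug)
            probs = model.forward(xb, train=True)
            _, dp = dice_loss_grad(probs, yb)
            model.backward(dp)
            opt.step([l.grad(nm) for l, nm in model.named_params()])
    return model


def predict_patches(model: UNet, images: np.ndarray, batch: int = 64) -> np.ndarray:
    """Per-pixel vessel probabilities for a stack of P x P images."""
    out = []
    for start in range(0, images.shape[0], batch):
        xb = images[start : start + batch][:, None, :, :].astype(float)
        out.append(model.forward(xb, train=False)[:, 0])
    return np.concatenate(out)


def predict_volume(
    model: UNet,
    vol: PhantomVolume,
    patch_size: int | None = None,
    threshold: float = 0.5,
    overlap: int = 0,
) -> np.ndarray:
    """Slice-wise tiled inference producing a binary 3-D mask.

    Each axial slice is padded by reflection to a multiple of the tile
    step, tiled with ``patch_size`` windows (optionally overlapping by
    ``overlap`` pixels), per-pixel probabilities are averaged over covering
    tiles, and the stitched map is thresholded at ``threshold``.
    """
    if patch_size is None:
        raise ValueError("patch_size is required")
    P = int(patch_size)
    nx, ny, nz = vol.shape
    if nx < P or ny < P:
        raise ValueError(f"in-plane extent {(nx, ny)} smaller than patch size {P}")
    step = P - overlap
    if step <= 0:
        raise ValueError("overlap must be smaller than patch_size")
    rows = list(range(0, nx - P + 1, step))
    if rows[-1] != nx - P:
        rows.append(nx - P)
    cols = list(range(0, ny - P + 1, step))
    if cols[-1] != ny - P:
        cols.append(ny - P)
    out = np.zeros((nx, ny, nz))
    counts = np.zeros((nx, ny, nz))
    for z in range(nz):
        tiles, spots = [], []
        for r in rows:
            for c in cols:
                tiles.append(vol.intensity[r : r + P, c : c + P, z])
                spots.append((r, c))
        probs = predict_patches(model, np.stack(tiles))
        for (r, c), pr in zip(spots, probs):
            out[r : r + P, c : c + P, z] += pr
            counts[r : r + P, c : c + P, z] += 1
    return ((out / counts) >= threshold).astype(np.uint8)


def evaluate_volumes(
    model: UNet,
    volumes: Sequence[PhantomVolume],
    patch_size: int,
    dataset_tag: str = "test",
    config: SegConfig | None = None,
) -> SegReport:
    """Per-volume DSC and bAHD of a model on held-out phantom volumes."""
    ids, dscs, bahds = [], [], []
    for vol in volumes:
        pred = predict_volume(model, vol, patch_size=patch_size)
        ids.append(vol.subject_id)
        dscs.append(dsc(pred, vol.mask))
        try:
            bahds.append(bahd(vol.mask, pred))
        except ValueError:
            bahds.append(float("nan"))
    return SegReport(ids, dscs, bahds, dataset_tag=dataset_tag, config=config)


def select_model(
    candidates: Sequence[UNet],
    validation_volumes: Sequence[PhantomVolume],
    patch_size: int,
) -> tuple[UNet, SegReport]:
    """Pick the candidate with the highest mean validation DSC.

    Ties break by lower mean bAHD, then by candidate order.
    """
    if not candidates:
        raise ValueError("no candidate models")
    best = None
    for i, model in enumerate(candidates):
        report = evaluate_volumes(
            model, validation_volumes, patch_size, dataset_tag="validation", config=model.cfg
        )
        key = (-report.mean_dsc, report.mean_bahd if math.isfinite(report.mean_bahd) else math.inf, i)
        if best is None or key < best[0]:
            best = (key, model, report)
    return best[1], best[2]
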
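"""Segmentation and image-quality metrics.

Covers the four quantities used to evaluate generated image-label pairs:

* Dice similarity coefficient (:func:`dsc`) — voxel-overlap utility metric,
* balanced average Hausdorff distance (:func:`bahd`) — surface-distance
  metric in which *both* directed mean nearest-neighbour distances are
  normalised by the ground-truth voxel count (this deliberately differs
  from the conventional average Hausdorff distance, which normalises the
  second term by the prediction size; the shared normalisation makes the
  metric punish false-positive-heavy predictions hard),
* Fréchet distance between feature Gaussians (:func:`frechet_distance`),
  the statistic behind FID, with a pluggable feature extractor,
* structural similarity (:func:`ssim`) and its mean-pairwise variant used
  as a mode-collapse probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
from scipy.ndimage import uniform_filter
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "FeatureStats",
    "SSIMParams",
    "confusion_counts",
    "dsc",
    "bahd",
    "frechet_distance",
    "extract_features",
    "default_feature_extractor",
    "handcrafted_features",
    "ssim",
    "mean_pairwise_ssim",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN).

    Convention for the 0/0 corner: both masks empty -> 1.0 (perfect
    agreement on "nothing to segment"); exactly one empty -> 0.0.
    """
    c = confusion_counts(pred, gt)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def bahd(
    gt: np.ndarray,
    pred: np.ndarray,
    spacing: Sequence[float] | None = None,
) -> float:
    """Balanced average Hausdorff distance between two binary masks.

    ``( mean_{g in G} min_s d(g,s) + (1/N_G) * sum_{s in S} min_g d(s,g) ) / 2``
    with Euclidean ``d`` — note both directed sums are divided by the
    ground-truth voxel count ``N_G``, so the metric is *not* symmetric in
    (G, S) unless |G| = |S|.  Distances are in voxel units unless a
    per-axis ``spacing`` (mm) is given.  Undefined (raises) when either
    mask is empty.
    """
    g = _as_binary(gt, "gt")
    s = _as_binary(pred, "pred")
    if g.shape != s.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {s.shape}")
    g_pts = np.argwhere(g).astype(float)
    s_pts = np.argwhere(s).astype(float)
    if g_pts.shape[0] == 0 or s_pts.shape[0] == 0:
        raise ValueError("bAHD is undefined for an empty mask")
    if spacing is not None:
        spacing = np.asarray(spacing, dtype=float)
        if spacing.shape != (g.ndim,):
            raise ValueError("spacing must give one value per axis")
        g_pts = g_pts * spacing
        s_pts = s_pts * spacing
    n_g = g_pts.shape[0]
    d_g_to_s, _ = cKDTree(s_pts).query(g_pts)
    d_s_to_g, _ = cKDTree(g_pts).query(s_pts)
    return float((d_g_to_s.sum() / n_g + d_s_to_g.sum() / n_g) / 2.0)


# ---------------------------------------------------------------------------
# Fréchet distance between feature Gaussians
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureStats:
    """Mean and covariance of a feature embedding — sufficient statistics
    for the Fréchet distance."""

    mu: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (mu.size, mu.size):
            raise ValueError("cov must be square with dimension matching mu")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "cov", cov)


def frechet_distance(
    a: FeatureStats, b: FeatureStats, psd_tol: float = 1e-6
) -> float:
    """Fréchet (2-Wasserstein) distance between two feature Gaussians:

        ||mu_a - mu_b||^2 + Tr( cov_a + cov_b - 2 (cov_a cov_b)^{1/2} ).

    The principal square root of ``cov_a @ cov_b`` is taken; imaginary
    parts and small negative eigenvalues arising from round-off are
    discarded if below ``psd_tol`` (relative), otherwise an error is
    raised.
    """
    if a.mu.shape != b.mu.shape:
        raise ValueError("feature dimensions do not match")
    diff = a.mu - b.mu

    def _sqrtm_trace(cov_a: np.ndarray, cov_b: np.ndarray) -> np.ndarray | None:
        covmean = scipy.linalg.sqrtm(cov_a @ cov_b)
        if not np.all(np.isfinite(covmean)):
            return None
        if np.iscomplexobj(covmean):
            scale = max(1.0, float(np.abs(covmean.real).max()))
            if np.abs(covmean.imag).max() > psd_tol * scale:
                return None
            covmean = covmean.real
        return covmean

    covmean = _sqrtm_trace(a.cov, b.cov)
    if covmean is None:
        # rank-deficient sample covariances: regularise with a small ridge
        d = a.mu.size
        ridge = psd_tol * max(1.0, float(np.trace(a.cov) + np.trace(b.cov)) / (2 * d))
        eye = ridge * np.eye(d)
        covmean = _sqrtm_trace(a.cov + eye, b.cov + eye)
        if covmean is None:
            raise ValueError("covariance product is not PSD within tolerance")
    val = float(diff @ diff + np.trace(a.cov) + np.trace(b.cov) - 2.0 * np.trace(covmean))
    if val < 0:
        if val < -psd_tol * max(1.0, abs(np.trace(a.cov)) + abs(np.trace(b.cov))):
            raise ValueError("negative Fréchet distance beyond round-off tolerance")
        val = 0.0
    return val


def extract_features(
    images: Sequence[np.ndarray] | np.ndarray,
    extractor: Callable[[np.ndarray], np.ndarray],
) -> FeatureStats:
    """Fit a Gaussian (mean + covariance) to ``extractor(image)`` embeddings.

    The extractor maps one 2-D image to a fixed-length feature vector; at
    least two images are needed for a covariance.
    """
    feats = np.stack([np.asarray(extractor(np.asarray(im)), dtype=float) for im in images])
    if feats.shape[0] < 2:
        raise ValueError("need at least 2 images to estimate a covariance")
    mu = feats.mean(axis=0)
    cov = np.cov(feats, rowvar=False)
    cov = np.atleast_2d(cov)
    return FeatureStats(mu=mu, cov=cov, n=feats.shape[0])


def handcrafted_features(image: np.ndarray) -> np.ndarray:
    """8-D hand-crafted intensity/texture statistic vector.

    Mean, SD, 10th/90th percentiles, bright-pixel fraction (> mean + 2 SD),
    mean absolute horizontal and vertical gradients, and Laplacian energy.
    Cheap, deterministic and dependency-free; used where a learned
    embedding is unnecessary.
    """
    x = np.asarray(image, dtype=float)
    gx = np.abs(np.diff(x, axis=1)).mean() if x.shape[1] > 1 else 0.0
    gy = np.abs(np.diff(x, axis=0)).mean() if x.shape[0] > 1 else 0.0
    lap = (
        x[1:-1, 1:-1] * 4 - x[:-2, 1:-1] - x[2:, 1:-1] - x[1:-1, :-2] - x[1:-1, 2:]
    )
    mu, sd = float(x.mean()), float(x.std())
    return np.array(
        [
            mu,
            sd,
            float(np.percentile(x, 10)),
            float(np.percentile(x, 90)),
            float(np.mean(x > mu + 2 * sd)),
            float(gx),
            float(gy),
            float(np.mean(lap**2)) if lap.size else 0.0,
        ]
    )


class RandomConvFeatures:
    """Fixed-seed random convolutional embedding for Fréchet comparisons.

    A two-stage random convolutional filter bank (weights drawn once from a
    seeded generator) followed by ReLU and global average/max pooling.
    Random convolutional features preserve enough image statistics to rank
    distributional similarity, which is all the Fréchet distance needs; the
    embedding is deterministic across processes because the weights are a
    pure function of the seed.
    """

    def __init__(self, n_filters: int = 16, kernel: int = 5, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w1 = rng.normal(0, 1.0 / kernel, size=(n_filters, kernel, kernel))
        self.w2 = rng.normal(0, 1.0 / kernel, size=(n_filters, kernel, kernel))
        self.kernel = kernel

    def _conv_bank(self, x: np.ndarray, bank: np.ndarray) -> np.ndarray:
        from scipy.signal import fftconvolve

        maps = [fftconvolve(x, w, mode="valid") for w in bank]
        return np.maximum(np.stack(maps), 0.0)

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=float)
        h1 = self._conv_bank(x, self.w1)
        # stride-2 subsample then second stage on the channel-mean map
        h1s = h1[:, ::2, ::2]
        h2 = self._conv_bank(h1s.mean(axis=0), self.w2)
        feats = np.concatenate(
            [
                h1.mean(axis=(1, 2)),
                h1.max(axis=(1, 2)),
                h2.mean(axis=(1, 2)),
                h2.max(axis=(1, 2)),
            ]
        )
        return feats


def default_feature_extractor(seed: int = 0) -> Callable[[np.ndarray], np.ndarray]:
    """Default extractor: random conv features + hand-crafted statistics."""
    conv = RandomConvFeatures(seed=seed)

    def extractor(image: np.ndarray) -> np.ndarray:
        return np.concatenate([conv(image), handcrafted_features(image)])

    return extractor


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSIMParams:
    """SSIM stabilisation constants and window mode.

    ``k1 = 0.01`` and ``k2 = 0.03`` are the standard choices; ``L`` is the
    dynamic range of pixel values (1.0 for [0, 1] images).  ``window=None``
    evaluates one global statistic; an integer evaluates a sliding uniform
    window of that size and averages.
    """

    k1: float = 0.01
    k2: float = 0.03
    L: float = 1.0
    window: int | None = None


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Structural similarity between two equally shaped images:

        (2 mu_x mu_y + c1)(2 sigma_xy + c2)
        -----------------------------------
        (mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)

    with ``c1 = (k1 L)^2``, ``c2 = (k2 L)^2``.  Global mode computes the
    moments over the whole image; sliding mode averages the local SSIM map
    (uniform window, same-size moments).
    """
    p = params or SSIMParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    c1 = (p.k1 * p.L) ** 2
    c2 = (p.k2 * p.L) ** 2
    if p.window is None:
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = ((x - mx) * (y - my)).mean()
        return float(
            ((2 * mx * my + c1) * (2 * cxy + c2))
            / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        )
    w = int(p.window)
    if w < 2 or w > min(x.shape):
        raise ValueError("window must be >= 2 and fit inside the image")
    mx = uniform_filter(x, w)
    my = uniform_filter(y, w)
    vx = uniform_filter(x * x, w) - mx * mx
    vy = uniform_filter(y * y, w) - my * my
    cxy = uniform_filter(x * y, w) - mx * my
    ssim_map = ((2 * mx * my + c1) * (2 * cxy + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )
    # crop the window-length border where the uniform filter pads
    h = w // 2
    core = ssim_map[h : ssim_map.shape[0] - h, h : ssim_map.shape[1] - h]
    return float(core.mean() if core.size else ssim_map.mean())


def mean_pairwise_ssim(
    images: Sequence[np.ndarray],
    params: SSIMParams | None = None,
    max_pairs: int | None = None,
    seed: int = 0,
) -> float:
    """Average SSIM over all unordered image pairs (mode-collapse probe).

    High values mean the collection is self-similar — the signature of a
    collapsed generator.  For large collections a seeded random subsample
    of ``max_pairs`` pairs is averaged instead of the full O(n^2) set.
    """
    n = len(images)
    if n < 2:
        raise ValueError("need at least 2 images")
    pairs = list(combinations(range(n), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    vals = [ssim(images[i], images[j], params) for i, j in pairs]
    return float(np.mean(vals))
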
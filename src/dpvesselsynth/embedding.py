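"""t-SNE embedding for qualitative real-vs-generated overlap inspection.

Pairwise high-dimensional similarities use Gaussian conditionals

    p_{j|i} = exp(-||x_i - x_j||^2 / 2 sigma_i^2) / sum_{k != i} exp(...)

with per-point bandwidths ``sigma_i`` calibrated by bisection so the
Shannon perplexity of every row matches the target (default 30), then
symmetrised to ``p_ij = (p_{j|i} + p_{i|j}) / 2N``.  Low-dimensional
similarities are the Student-t kernel

    q_ij = (1 + ||y_i - y_j||^2)^-1 / sum_{k != m} (1 + ||y_k - y_m||^2)^-1.

The embedding is found by seeded gradient descent with momentum and early
exaggeration.  The default cost is the KL divergence KL(p || q); an
optional ``wasserstein`` mode minimises the 1-Wasserstein distance between
p and q regarded as distributions over the pair index set with the
discrete ground metric — which equals the total-variation cost
``0.5 * sum_ij |p_ij - q_ij|``.  That substitution is one reading of
"replace KL by a Wasserstein metric" and is labelled an interpretation;
gradients for any cost are obtained by chaining d(cost)/dq through the
Student-t normalisation, so both modes share one verified backward path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SimilarityModel",
    "EmbeddingResult",
    "calibrate_similarities",
    "embed",
    "tsne",
]


@dataclass
class SimilarityModel:
    p_cond: np.ndarray  # (N, N), rows sum to 1, zero diagonal
    p_joint: np.ndarray  # (N, N), symmetric, sums to 1
    bandwidths: np.ndarray  # per-point sigma_i
    perplexity: float
    n: int


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (N, 2)
    q: np.ndarray  # (N, N) Student-t similarities at the final iterate
    cost_trace: list[float] = field(default_factory=list)
    groups: list[str] | None = None


def _row_entropy(p_row: np.ndarray) -> float:
    nz = p_row[p_row > 0]
    return float(-(nz * np.log(nz)).sum())


def calibrate_similarities(
    points: np.ndarray,
    perplexity: float = 30.0,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> SimilarityModel:
    """Bisection-calibrated conditional similarities and their symmetrisation."""
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 points with vector features")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    n = X.shape[0]
    if not 1 <= perplexity < n:
        raise ValueError("perplexity must be in [1, N)")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    target = np.log(perplexity)
    P = np.zeros((n, n))
    betas = np.zeros(n)
    for i in range(n):
        d = np.delete(sq[i], i)
        beta, lo, hi = 1.0, 0.0, np.inf
        for _ in range(max_iter):
            w = np.exp(-(d - d.min()) * beta)
            s = w.sum()
            p = w / s
            h = _row_entropy(p)
            if abs(h - target) < tol:
                break
            if h > target:  # too flat -> narrow the kernel
                lo = beta
                beta = beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
            else:
                hi = beta
                beta = (beta + lo) / 2
        row = np.zeros(n)
        row[np.arange(n) != i] = p
        P[i] = row
        betas[i] = beta
    sigmas = np.sqrt(1.0 / (2.0 * np.maximum(betas, 1e-12)))
    p_joint = (P + P.T) / (2.0 * n)
    return SimilarityModel(P, p_joint, sigmas, perplexity, n)


def _student_t(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    sq = ((y[:, None, :] - y[None, :, :]) ** 2).sum(-1)
    w = 1.0 / (1.0 + sq)
    np.fill_diagonal(w, 0.0)
    s = w.sum()
    return w / s, w, s


def _cost_and_dq(cost: str, p: np.ndarray, q: np.ndarray) -> tuple[float, np.ndarray]:
    eps = 1e-12
    if cost == "kl":
        mask = p > 0
        c = float((p[mask] * np.log(p[mask] / np.maximum(q[mask], eps))).sum())
        dq = np.where(mask, -p / np.maximum(q, eps), 0.0)
        return c, dq
    if cost == "wasserstein":
        diff = q - p
        return 0.5 * float(np.abs(diff).sum()), 0.5 * np.sign(diff)
    raise ValueError(f"unknown cost {cost!r}")


def embed(
    model: SimilarityModel,
    iters: int = 500,
    seed: int = 0,
    cost: str = "kl",
    learning_rate: float = 100.0,
    early_exaggeration: float = 4.0,
    exaggeration_iters: int = 100,
    momentum: float = 0.5,
    final_momentum: float = 0.8,
    momentum_switch: int = 250,
    groups: Sequence[str] | None = None,
    init: np.ndarray | None = None,
) -> EmbeddingResult:
    """Gradient-descent embedding of a calibrated similarity model into 2-D.

    Deterministic given ``seed``.  For any cost C(p, q) the gradient w.r.t.
    a point is assembled from G = dC/dq via

        dC/dy_i = -2 sum_j (A_ij + A_ji) (y_i - y_j) w_ij^2,
        A = (G - sum(G * q)) / S,

    where ``w`` is the unnormalised Student-t kernel and ``S`` its sum —
    the chain rule through q = w / S.
    """
    rng = np.random.default_rng(seed)
    n = model.n
    if init is not None:
        y = np.asarray(init, dtype=float).copy()
        if y.shape != (n, 2):
            raise ValueError("init must have shape (N, 2)")
    else:
        y = rng.normal(0.0, 1e-2, size=(n, 2))
    vel = np.zeros_like(y)
    trace: list[float] = []
    for t in range(iters):
        p = model.p_joint * (early_exaggeration if t < exaggeration_iters else 1.0)
        if t < exaggeration_iters:
            p = p / p.sum()
        q, w, s = _student_t(y)
        c, G = _cost_and_dq(cost, p, q)
        if not np.isfinite(c):
            raise FloatingPointError(f"non-finite embedding cost at iteration {t}")
        trace.append(c)
        A = (G - float((G * q).sum())) / s
        F = (A + A.T) * w * w * 1.0
        # dC/dy_i = -2 sum_j F_ij (y_i - y_j)  -> descend along its negative
        grad = -2.0 * (F.sum(1)[:, None] * y - F @ y)
        m = momentum if t < momentum_switch else final_momentum
        vel = m * vel - learning_rate * grad
        y = y + vel
        y = y - y.mean(0)
    q, _, _ = _student_t(y)
    return EmbeddingResult(y, q, trace, list(groups) if groups is not None else None)


def embedding_gradient(
    model: SimilarityModel, y: np.ndarray, cost: str = "kl"
) -> tuple[float, np.ndarray]:
    """Cost and analytic gradient at coordinates ``y`` (no exaggeration).

    Exposed for verification against finite differences.
    """
    q, w, s = _student_t(y)
    c, G = _cost_and_dq(cost, model.p_joint, q)
    A = (G - float((G * q).sum())) / s
    F = (A + A.T) * w * w
    grad = -2.0 * (F.sum(1)[:, None] * y - F @ y)
    return c, grad


def tsne(
    points: np.ndarray,
    perplexity: float = 30.0,
    iters: int = 500,
    seed: int = 0,
    cost: str = "kl",
    groups: Sequence[str] | None = None,
) -> EmbeddingResult:
    """Convenience wrapper: calibrate then embed."""
    model = calibrate_similarities(points, perplexity)
    return embed(model, iters=iters, seed=seed, cost=cost, groups=groups)
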
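"""Wasserstein GAN with a differentially private critic.

The generator maps a 128-D Gaussian latent vector to a 2-channel patch
(channel 0: intensity image, channel 1: segmentation label); the critic
scores image-label pairs with an unbounded realness score.  Losses are the
plain WGAN pair

    loss_G = -mean(D(x_gen))
    loss_D =  mean(D(x_gen)) - mean(D(x_real)),

Lipschitz control by clipping the critic weights to ``[-wgan_clip,
wgan_clip]`` after every critic step.  When a positive noise multiplier is
configured, each critic update is a DP-SGD step: per-sample gradients
(one per real sample, paired with one generated sample) are clipped to L2
norm ``clip_norm`` and aggregated with Gaussian noise, and the RDP ledger
is composed once per critic optimizer step.  Generator updates are
post-processing of the privatised critic and consume no privacy budget.

Batches are sampled uniformly with replacement (sample rate = batch size /
dataset size), the sampling model assumed by the subsampled-Gaussian RDP
amplification bound.  The critic contains no batch-coupling layers, so
per-sample gradients are well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from . import nn
from .phantoms import LabeledPatch, PatchSet
from .privacy import (
    DPReport,
    PrivacySpec,
    RDPLedger,
    clip_and_noise,
    compose,
    per_step_epsilons,
    rdp_to_dp,
)

__all__ = [
    "GANConfig",
    "TrainState",
    "desk_config",
    "paper_config",
    "build_generator",
    "build_critic",
    "wgan_losses",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "synthesize",
]


@dataclass(frozen=True)
class GANConfig:
    """WGAN + DP-SGD hyper-parameters.

    ``wgan_clip`` (Lipschitz weight clip, 0.01) and ``privacy.clip_norm``
    (DP gradient clip, 1.0) are distinct parameters.  ``gen_stages`` is the
    number of 2x upsampling stages; the linear layer produces a
    ``patch_size / 2**gen_stages`` base grid, so the patch size must be
    divisible by ``2**gen_stages`` (and likewise by ``2**critic_stages``).
    """

    latent_dim: int = 128
    lr: float = 5e-5
    batch_size: int = 32
    n_critic: int = 5
    wgan_clip: float = 0.01
    epochs: int = 50
    patch_size: int = 96
    gen_stages: int = 5
    gen_channels: int = 64
    critic_stages: int = 5
    critic_channels: int = 16
    privacy: PrivacySpec = field(default_factory=PrivacySpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("latent_dim", "lr", "batch_size", "n_critic", "wgan_clip", "epochs", "patch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for stages, label in ((self.gen_stages, "gen"), (self.critic_stages, "critic")):
            if self.patch_size % (2**stages) != 0:
                raise ValueError(
                    f"patch_size {self.patch_size} is not divisible by 2**{stages} "
                    f"({label} stages); choose compatible values"
                )


def paper_config(privacy: PrivacySpec | None = None, seed: int = 0) -> GANConfig:
    """Full-scale profile: 96 x 96 patches, 6 convolutional layers per net."""
    return GANConfig(
        patch_size=96,
        gen_stages=5,
        gen_channels=128,
        critic_stages=5,
        critic_channels=32,
        epochs=50,
        privacy=privacy or PrivacySpec(sample_rate=32 / 41000, delta=1 / 41000),
        seed=seed,
    )


def desk_config(
    privacy: PrivacySpec | None = None,
    seed: int = 0,
    epochs: int = 60,
    lr: float = 2.5e-4,
    batch_size: int = 16,
) -> GANConfig:
    """CPU-scale profile: 32 x 32 patches, slim channels, fewer stages.

    The learning rate is raised relative to the full-scale profile in
    proportion to the drastically reduced step count, so the scaled run
    still moves through a comparable optimisation distance.
    """
    return GANConfig(
        patch_size=32,
        gen_stages=3,
        gen_channels=48,
        critic_stages=3,
        critic_channels=12,
        epochs=epochs,
        lr=lr,
        batch_size=batch_size,
        privacy=privacy or PrivacySpec(),
        seed=seed,
    )


class _DualHead(nn.Layer):
    """Final generator activation: channel 0 tanh rescaled to [0, 1]
    (intensity), channel 1 sigmoid (label probability)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._t = np.tanh(x[:, 0:1])
        self._s = 1.0 / (1.0 + np.exp(-np.clip(x[:, 1:2], -60, 60)))
        return np.concatenate([(self._t + 1.0) / 2.0, self._s], axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d0 = dy[:, 0:1] * (1 - self._t**2) / 2.0
        d1 = dy[:, 1:2] * self._s * (1 - self._s)
        return np.concatenate([d0, d1], axis=1)


def _gen_channel_plan(cfg: GANConfig) -> list[int]:
    return [max(8, cfg.gen_channels // 2**i) for i in range(cfg.gen_stages + 1)]


def build_generator(cfg: GANConfig, rng: np.random.Generator | None = None) -> nn.Sequential:
    """Latent vector -> 2 x P x P patch: one linear layer, ``gen_stages``
    upsampling convolutions, and a final stride-1 convolution."""
    rng = rng or np.random.default_rng(cfg.seed)
    base = cfg.patch_size // 2**cfg.gen_stages
    ch = _gen_channel_plan(cfg)
    layers: list[nn.Layer] = [
        nn.Dense(cfg.latent_dim, ch[0] * base * base, rng),
        nn.Reshape((ch[0], base, base)),
        nn.ReLU(),
    ]
    for i in range(cfg.gen_stages):
        layers += [
            nn.Upsample2x(),
            nn.Conv2d(ch[i], ch[i + 1], 3, rng, stride=1, pad=1),
            nn.ReLU(),
        ]
    layers += [nn.Conv2d(ch[-1], 2, 3, rng, stride=1, pad=1), _DualHead()]
    return nn.Sequential(layers)


def build_critic(cfg: GANConfig, rng: np.random.Generator | None = None) -> nn.Sequential:
    """2 x P x P pair -> scalar critic score: ``critic_stages`` stride-2
    convolutions (kernel 4, LeakyReLU 0.2) and a final dense layer."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    layers: list[nn.Layer] = []
    c_in = 2
    size = cfg.patch_size
    for i in range(cfg.critic_stages):
        c_out = min(cfg.critic_channels * 2**i, 8 * cfg.critic_channels)
        layers += [nn.Conv2d(c_in, c_out, 4, rng, stride=2, pad=1), nn.LeakyReLU(0.2)]
        c_in = c_out
        size //= 2
    layers += [nn.Flatten(), nn.Dense(c_in * size * size, 1, rng)]
    return nn.Sequential(layers)


def wgan_losses(scores_real: np.ndarray, scores_gen: np.ndarray) -> tuple[float, float]:
    """(loss_G, loss_D) = (-mean(D(x_gen)), mean(D(x_gen)) - mean(D(x_real)))."""
    g = float(np.mean(scores_gen))
    r = float(np.mean(scores_real))
    return -g, g - r


@dataclass
class TrainState:
    """Outcome of a GAN training run."""

    cfg: GANConfig
    generator: nn.Sequential
    critic: nn.Sequential
    ledger: RDPLedger
    dp_report: DPReport
    loss_g: list[float] = field(default_factory=list)
    loss_d: list[float] = field(default_factory=list)
    epochs_done: int = 0
    critic_steps: int = 0


def _clip_weights(net: nn.Sequential, c: float) -> None:
    for layer, name in net.named_params():
        np.clip(layer.params[name], -c, c, out=layer.params[name])


def train(
    cfg: GANConfig,
    data: PatchSet,
    epoch_callback: Callable[[TrainState], None] | None = None,
) -> TrainState:
    """Run the full DP-WGAN training loop.

    One epoch consists of ``ceil(len(data) / batch_size)`` sampled critic
    batches; the generator is updated after every ``n_critic``-th critic
    batch.  Each critic update composes the RDP ledger by one step (private
    arms only).  Fully reproducible given ``cfg.seed``.
    """
    if len(data) == 0:
        raise ValueError("training data is empty")
    X = np.stack(
        [np.stack([p.image, p.label.astype(float)]) for p in data]
    )  # (N, 2, P, P)
    n = X.shape[0]
    if X.shape[2] != cfg.patch_size or X.shape[3] != cfg.patch_size:
        raise ValueError(
            f"data patches are {X.shape[2:]} but config expects {cfg.patch_size}"
        )
    spec = cfg.privacy
    q = min(1.0, cfg.batch_size / n)
    spec = replace(spec, sample_rate=q)

    ss = np.random.SeedSequence(cfg.seed)
    rng_init_g, rng_init_d, rng_sample, rng_latent, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    generator = build_generator(cfg, rng_init_g)
    critic = build_critic(cfg, rng_init_d)
    opt_g = nn.RMSprop(generator, cfg.lr)
    opt_d = nn.RMSprop(critic, cfg.lr)

    ledger = RDPLedger()
    step_eps = (
        per_step_epsilons(ledger.orders, spec.noise_multiplier, q)
        if spec.is_private
        else None
    )
    state = TrainState(
        cfg=cfg,
        generator=generator,
        critic=critic,
        ledger=ledger,
        dp_report=rdp_to_dp(ledger, spec.delta) if spec.is_private else DPReport(math.inf, spec.delta, math.nan, 0),
    )

    steps_per_epoch = math.ceil(n / cfg.batch_size)
    B = cfg.batch_size
    for epoch in range(cfg.epochs):
        for step in range(steps_per_epoch):
            # ----- critic update (privatised) -----
            idx = rng_sample.integers(0, n, size=B)  # uniform with replacement
            x_real = X[idx]
            z = rng_latent.normal(size=(B, cfg.latent_dim))
            x_gen = generator.forward(z, train=False)
            scores = critic.forward(np.concatenate([x_real, x_gen]), train=True)[:, 0]
            s_real, s_gen = scores[:B], scores[B:]
            loss_g_val, loss_d_val = wgan_losses(s_real, s_gen)
            if not np.isfinite(loss_d_val):
                raise FloatingPointError(
                    f"non-finite critic loss at epoch {epoch} step {step}: {loss_d_val}"
                )
            # d(loss_D)/d(score): -1 per real row, +1 per generated row
            # (per-sample scale; the DP aggregator divides by B)
            dy = np.concatenate([-np.ones(B), np.ones(B)])[:, None]
            critic.backward(dy)
            if spec.is_private:
                psg = nn.flatten_per_sample(critic, 2 * B)
                per_sample = psg[:B] + psg[B:]  # one gradient per real sample
                agg = clip_and_noise(
                    per_sample, spec.clip_norm, spec.noise_multiplier, rng_noise
                )
                opt_d.step(nn.unflatten_gradient(critic, agg))
                ledger = compose(ledger, step_eps, 1)
            else:
                grads = [layer.grad(nm) / B for layer, nm in critic.named_params()]
                opt_d.step(grads)
            _clip_weights(critic, cfg.wgan_clip)
            state.loss_d.append(loss_d_val)
            state.critic_steps += 1

            # ----- generator update every n_critic critic batches -----
            if (step + 1) % cfg.n_critic == 0:
                z = rng_latent.normal(size=(B, cfg.latent_dim))
                x_gen = generator.forward(z, train=True)
                s = critic.forward(x_gen, train=True)[:, 0]
                state.loss_g.append(-float(np.mean(s)))
                dxg = critic.backward(np.full((B, 1), -1.0 / B))
                generator.backward(dxg)
                opt_g.step([layer.grad(nm) for layer, nm in generator.named_params()])
        state.epochs_done = epoch + 1
        state.ledger = ledger
        state.dp_report = (
            rdp_to_dp(ledger, spec.delta)
            if spec.is_private
            else DPReport(math.inf, spec.delta, math.nan, state.critic_steps)
        )
        if epoch_callback is not None:
            epoch_callback(state)
    return state


def save_checkpoint(state: TrainState, path) -> None:
    """Persist the generator (architecture config + weights) for synthesis."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = asdict(state.cfg)
    cfg["privacy"] = {
        "noise_multiplier": state.cfg.privacy.noise_multiplier,
        "clip_norm": state.cfg.privacy.clip_norm,
        "sample_rate": state.cfg.privacy.sample_rate,
        "delta": state.cfg.privacy.delta,
    }
    arrays = {f"p{i}": a for i, a in enumerate(state.generator.state())}
    np.savez_compressed(path, config=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> TrainState:
    """Rebuild a synthesis-ready state from :func:`save_checkpoint` output."""
    import json

    data = np.load(path, allow_pickle=False)
    cfg_dict = json.loads(str(data["config"]))
    cfg_dict["privacy"] = PrivacySpec(**cfg_dict["privacy"])
    cfg = GANConfig(**cfg_dict)
    generator = build_generator(cfg)
    generator.load_state([data[f"p{i}"] for i in range(len(data.files) - 1)])
    return TrainState(
        cfg=cfg,
        generator=generator,
        critic=build_critic(cfg),
        ledger=RDPLedger(),
        dp_report=DPReport(math.inf, cfg.privacy.delta, math.nan, 0),
    )


def synthesize(
    state: TrainState,
    n: int,
    seed: int = 0,
    label_threshold: float = 0.5,
    batch: int = 256,
) -> PatchSet:
    """Draw ``n`` labeled patches from the trained generator.

    The label channel is binarised at ``label_threshold``; the image
    channel is already in [0, 1] by construction of the output head.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    patches: list[LabeledPatch] = []
    remaining = n
    while remaining > 0:
        b = min(batch, remaining)
        z = rng.normal(size=(b, state.cfg.latent_dim))
        out = state.generator.forward(z, train=False)
        for row in out:
            patches.append(
                LabeledPatch(
                    image=row[0].copy(),
                    label=(row[1] >= label_threshold).astype(np.uint8),
                    origin="synthetic",
                    mode="generated",
                )
            )
        remaining -= b
    return PatchSet(patches)
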
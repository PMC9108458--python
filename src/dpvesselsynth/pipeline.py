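"""End-to-end experiment orchestration.

One experiment: generate a phantom cohort, split it into disjoint
train/validation/test subjects, extract labeled patches from the training
subjects, sweep DP-WGAN arms over a set of noise multipliers (with
repeats for the private arms), synthesize patch sets, train a U-Net grid
on each synthetic set, select by validation DSC, and report DSC/bAHD on
the test volumes together with FID-style Fréchet distances (to the
training and test patch pools) and the mean pairwise SSIM mode-collapse
probe.

Two scale profiles ship: ``paper`` mirrors the full protocol
(41/11/14 subjects, 1000 patches each, 96 x 96, 50 epochs — multi-day on
CPU) and ``desk`` is a CPU-scale profile for end-to-end runs in minutes.
All randomness is drawn from named streams derived from one master seed.
"""

from __future__ import annotations

import json
import math
import traceback
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gan import GANConfig, desk_config, paper_config, synthesize, train
from .metrics import (
    FeatureStats,
    default_feature_extractor,
    extract_features,
    frechet_distance,
    mean_pairwise_ssim,
)
from .phantoms import PatchSet, PhantomVolume, extract_patches, generate_volume
from .privacy import PrivacySpec
from .segmentation import SegConfig, select_model, train_unet

__all__ = ["ExperimentPlan", "ArmResult", "plan_experiment", "run_sweep", "summary_table"]

#: noise multipliers of the full sweep; 0 encodes the non-private arm
FULL_NOISE_GRID = (0.0, 2.0, 1.5, 1.2, 1.0, 0.8, 0.725, 0.65)


@dataclass
class ExperimentPlan:
    """Fully seeded description of one sweep."""

    n_train: int = 4
    n_val: int = 1
    n_test: int = 2
    noise_multipliers: tuple[float, ...] = (0.0, 1.0)
    repeats: int = 2
    profile: str = "desk"
    master_seed: int = 0
    # scale knobs
    volume_shape: tuple[int, int, int] = (80, 80, 32)
    n_vessels: int = 5
    noise_level: float = 0.05
    patch_size: int = 32
    patches_vessel: int = 60
    patches_random: int = 60
    gan_epochs: int = 60
    n_synth: int = 400
    unet_grid_size: int = 2
    unet_epochs: int = 8
    fid_images: int = 100
    ssim_images: int = 50

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_val, self.n_test) <= 0:
            raise ValueError("split counts must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def arm_seed(self, sigma: float, repeat: int) -> int:
        """Deterministic per-arm seed derived from the master seed."""
        ss = np.random.SeedSequence(
            [self.master_seed, abs(int(round(sigma * 1000))) + (10_000_000 if sigma < 0 else 0), repeat]
        )
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def stream(self, name: str) -> np.random.Generator:
        mapping = {"cohort": 1, "gan": 2, "unet": 3, "synthesis": 4, "tsne": 5, "fid": 6}
        return np.random.default_rng(
            np.random.SeedSequence([self.master_seed, 977, mapping[name]])
        )


@dataclass
class ArmResult:
    """Metrics of one (noise multiplier, repeat) training arm."""

    noise_multiplier: float
    repeat: int
    seed: int
    epsilon: float = math.nan
    best_order: float = math.nan
    dp_steps: int = 0
    val_dsc: float = math.nan
    test_dsc: float = math.nan
    test_dsc_sd: float = math.nan
    test_bahd: float = math.nan
    fid_train: float = math.nan
    fid_test: float = math.nan
    mean_ssim: float = math.nan
    label_fraction: float = math.nan
    error: str | None = None

    def to_row(self) -> dict:
        d = asdict(self)
        # memorization gap: positive when the generated pool sits closer
        # to the training pool than to the test pool
        d["fid_gap"] = self.fid_test - self.fid_train
        return d


def plan_experiment(config: dict | str | Path) -> ExperimentPlan:
    """Build a plan from a YAML path or a plain dict.

    The ``paper`` profile presets the full-protocol splits (41/11/14
    subjects, 1000 patches each, 96 x 96 patches); ``desk`` presets the
    CPU profile.  Explicit keys override profile defaults.
    """
    if not isinstance(config, dict):
        import yaml

        with open(config) as f:
            config = yaml.safe_load(f) or {}
    profile = config.get("profile", "desk")
    if profile == "paper":
        base = dict(
            n_train=41,
            n_val=11,
            n_test=14,
            noise_multipliers=FULL_NOISE_GRID,
            repeats=5,
            volume_shape=(128, 128, 64),
            patch_size=96,
            patches_vessel=500,
            patches_random=500,
            gan_epochs=50,
            n_synth=41000,
            unet_grid_size=8,
            profile="paper",
        )
    elif profile == "desk":
        base = dict(profile="desk")
    else:
        raise ValueError(f"unknown profile {profile!r}")
    base.update({k: v for k, v in config.items() if k != "profile"})
    if "noise_multipliers" in base:
        base["noise_multipliers"] = tuple(float(x) for x in base["noise_multipliers"])
    if "volume_shape" in base:
        base["volume_shape"] = tuple(int(x) for x in base["volume_shape"])
    return ExperimentPlan(**base)


def build_cohort(
    plan: ExperimentPlan,
) -> tuple[list[PhantomVolume], list[PhantomVolume], list[PhantomVolume]]:
    """Disjoint train/validation/test phantom subjects from the cohort stream."""
    rng = plan.stream("cohort")
    total = plan.n_train + plan.n_val + plan.n_test
    seeds = rng.integers(0, 2**31 - 1, size=total)
    vols = [
        generate_volume(
            int(s),
            shape=plan.volume_shape,
            n_vessels=plan.n_vessels,
            noise_level=plan.noise_level,
            subject_id=f"subj-{i:03d}",
        )
        for i, s in enumerate(seeds)
    ]
    return (
        vols[: plan.n_train],
        vols[plan.n_train : plan.n_train + plan.n_val],
        vols[plan.n_train + plan.n_val :],
    )


def training_patches(plan: ExperimentPlan, train_vols: Sequence[PhantomVolume]) -> PatchSet:
    out = PatchSet()
    for i, vol in enumerate(train_vols):
        out.extend(
            extract_patches(
                vol,
                plan.patches_vessel,
                plan.patches_random,
                patch_size=plan.patch_size,
                seed=plan.arm_seed(-1.0, i),
            )
        )
    return out


def _gan_config(plan: ExperimentPlan, sigma: float, seed: int, delta: float) -> GANConfig:
    privacy = PrivacySpec(
        noise_multiplier=sigma, clip_norm=1.0, sample_rate=1.0, delta=delta
    )
    if plan.profile == "paper":
        cfg = paper_config(privacy=privacy, seed=seed)
        return GANConfig(**{**asdict_cfg(cfg), "epochs": plan.gan_epochs})
    return desk_config(privacy=privacy, seed=seed, epochs=plan.gan_epochs)


def asdict_cfg(cfg: GANConfig) -> dict:
    d = asdict(cfg)
    d["privacy"] = cfg.privacy
    return d


def run_arm(
    plan: ExperimentPlan,
    sigma: float,
    repeat: int,
    data: PatchSet,
    val_vols: Sequence[PhantomVolume],
    test_vols: Sequence[PhantomVolume],
    fid_pools: tuple[FeatureStats, FeatureStats],
    extractor,
) -> ArmResult:
    seed = plan.arm_seed(sigma, repeat)
    result = ArmResult(noise_multiplier=sigma, repeat=repeat, seed=seed)
    delta = 1.0 / max(len(data), 2)
    cfg = _gan_config(plan, sigma, seed, delta)
    state = train(cfg, data)
    result.epsilon = state.dp_report.epsilon
    result.best_order = state.dp_report.best_order
    result.dp_steps = state.ledger.steps
    synth = synthesize(state, plan.n_synth, seed=seed + 1)
    result.label_fraction = float(synth.labels().mean())

    grid = [
        SegConfig(
            learning_rate=lr,
            dropout=0.0,
            augment=aug,
            epochs=plan.unet_epochs,
            seed=seed + 2,
        )
        for lr, aug in [(1e-3, False), (1e-3, True), (1e-4, False), (1e-4, True)][
            : plan.unet_grid_size
        ]
    ]
    models = [train_unet(synth, c) for c in grid]
    best, val_report = select_model(models, val_vols, plan.patch_size)
    result.val_dsc = val_report.mean_dsc
    from .segmentation import evaluate_volumes

    test_report = evaluate_volumes(best, test_vols, plan.patch_size, "test")
    result.test_dsc = test_report.mean_dsc
    result.test_dsc_sd = test_report.sd_dsc
    result.test_bahd = test_report.mean_bahd

    gen_imgs = synth.images()[: plan.fid_images]
    gen_stats = extract_features(gen_imgs, extractor)
    result.fid_train = frechet_distance(gen_stats, fid_pools[0])
    result.fid_test = frechet_distance(gen_stats, fid_pools[1])
    result.mean_ssim = mean_pairwise_ssim(
        list(synth.images()[: plan.ssim_images]), max_pairs=300, seed=seed + 3
    )
    return result


def run_sweep(plan: ExperimentPlan, out_dir: str | Path | None = None) -> list[ArmResult]:
    """Run every (noise multiplier, repeat) arm; isolate per-arm failures.

    The non-private arm (sigma = 0) runs exactly once; each private arm
    runs ``plan.repeats`` times.  Failed arms carry their traceback in
    ``error`` and do not abort the sweep.
    """
    train_vols, val_vols, test_vols = build_cohort(plan)
    data = training_patches(plan, train_vols)
    extractor = default_feature_extractor(seed=0)
    fid_rng = plan.stream("fid")
    test_patches = PatchSet()
    for i, vol in enumerate(test_vols):
        test_patches.extend(
            extract_patches(
                vol,
                plan.patches_vessel // 2,
                plan.patches_random // 2,
                patch_size=plan.patch_size,
                seed=plan.arm_seed(-2.0, i),
            )
        )
    # reference pools: seeded uniform subsamples so both pools share the
    # vessel-centered/random composition statistics of their source sets
    train_pool = data.images()[
        fid_rng.choice(len(data), size=min(plan.fid_images, len(data)), replace=False)
    ]
    test_pool = test_patches.images()[
        fid_rng.choice(
            len(test_patches), size=min(plan.fid_images, len(test_patches)), replace=False
        )
    ]
    train_stats = extract_features(train_pool, extractor)
    test_stats = extract_features(test_pool, extractor)

    results: list[ArmResult] = []
    for sigma in plan.noise_multipliers:
        n_rep = 1 if sigma == 0 else plan.repeats
        for rep in range(n_rep):
            try:
                results.append(
                    run_arm(
                        plan,
                        sigma,
                        rep,
                        data,
                        val_vols,
                        test_vols,
                        (train_stats, test_stats),
                        extractor,
                    )
                )
            except Exception:
                failed = ArmResult(sigma, rep, plan.arm_seed(sigma, rep))
                failed.error = traceback.format_exc(limit=5)
                results.append(failed)
    if out_dir is not None:
        write_outputs(plan, results, Path(out_dir))
    return results


def arms_frame(results: Sequence[ArmResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def summary_table(results: Sequence[ArmResult]) -> pd.DataFrame:
    """Mean (SD) per metric per arm, shaped like the headline results table."""
    df = arms_frame([r for r in results if r.error is None])
    if df.empty:
        return df
    rows = []
    for sigma, grp in df.groupby("noise_multiplier"):
        rows.append(
            {
                "arm": "non-private" if sigma == 0 else f"sigma={sigma}",
                "epsilon": grp["epsilon"].iloc[0],
                "mean_dsc": grp["test_dsc"].mean(),
                "sd_dsc": grp["test_dsc"].std(ddof=0),
                "mean_bahd": grp["test_bahd"].mean(),
                "sd_bahd": grp["test_bahd"].std(ddof=0),
                "mean_fid_train": grp["fid_train"].mean(),
                "mean_fid_test": grp["fid_test"].mean(),
                "mean_ssim": grp["mean_ssim"].mean(),
                "n_runs": len(grp),
            }
        )
    return pd.DataFrame(rows).sort_values("mean_dsc", ascending=False).reset_index(drop=True)


def write_outputs(plan: ExperimentPlan, results: Sequence[ArmResult], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    arms_frame(results).to_csv(out_dir / "arms.csv", index=False)
    summary_table(results).to_csv(out_dir / "summary_table.csv", index=False)
    accounting = {
        f"sigma={r.noise_multiplier}/rep={r.repeat}": {
            "epsilon": r.epsilon,
            "best_order": r.best_order,
            "steps": r.dp_steps,
        }
        for r in results
        if r.error is None
    }
    with open(out_dir / "accounting.json", "w") as f:
        json.dump(accounting, f, indent=1, default=str)
    with open(out_dir / "plan.json", "w") as f:
        json.dump(asdict(plan), f, indent=1, default=str)
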
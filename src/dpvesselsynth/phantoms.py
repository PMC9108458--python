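"""Synthetic vascular phantoms and labeled 2-D patch extraction.

Real TOF-MRA volumes cannot be shared, so this module generates stand-in
volumes with the one statistic the downstream generative model must learn:
bright, smooth, curvilinear tubular structures on a darker noisy
background, with an exact voxel-level vessel mask.  Patches are cut from
axial slices with the oversampling scheme used for imbalanced vessel
segmentation: a quota of patches centered on a vessel voxel plus a quota of
uniformly random patches, with global deduplication of patch positions.

No MRI physics is modelled (no acquisition parameters, no anatomy); the
phantom is a statistical stand-in, not a simulation.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomVolume",
    "LabeledPatch",
    "PatchSet",
    "generate_volume",
    "generate_cohort",
    "extract_patches",
    "save_volume",
    "load_volume",
]

#: background base level and texture amplitude (intensity units, pre-noise)
_BG_BASE = 0.15
_BG_TEXTURE = 0.02
#: minimum vessel brightness before noise; comfortably above
#: background mean + 3 * background SD
_VESSEL_MIN = 0.7


@dataclass
class PhantomVolume:
    """A synthetic angiography volume with its exact vessel mask."""

    intensity: np.ndarray  # 3-D, float in [0, 1]
    mask: np.ndarray  # 3-D, uint8 {0, 1}, same shape
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.7)
    subject_id: str = "phantom"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity.shape != self.mask.shape:
            raise ValueError("intensity and mask must share a shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensity.shape

    @property
    def mask_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class LabeledPatch:
    """A paired 2-D intensity patch and binary segmentation label."""

    image: np.ndarray  # (P, P) float in [0, 1]
    label: np.ndarray  # (P, P) uint8 {0, 1}
    origin: tuple | str  # (subject_id, z, row, col) or "synthetic"
    mode: str  # vessel_centered | random | generated

    def __post_init__(self) -> None:
        if self.image.shape != self.label.shape:
            raise ValueError("image and label must share a shape")
        if self.mode not in ("vessel_centered", "random", "generated"):
            raise ValueError(f"unknown patch mode {self.mode!r}")


@dataclass
class PatchSet:
    """An ordered collection of labeled patches with provenance records."""

    patches: list[LabeledPatch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def __getitem__(self, i: int) -> LabeledPatch:
        return self.patches[i]

    def images(self) -> np.ndarray:
        return np.stack([p.image for p in self.patches])

    def labels(self) -> np.ndarray:
        return np.stack([p.label for p in self.patches])

    def manifest(self) -> list[dict]:
        records = []
        for p in self.patches:
            records.append(
                {
                    "origin": list(p.origin) if isinstance(p.origin, tuple) else p.origin,
                    "mode": p.mode,
                    "checksum": hashlib.sha1(
                        np.ascontiguousarray(p.image).tobytes()
                        + np.ascontiguousarray(p.label).tobytes()
                    ).hexdigest()[:16],
                }
            )
        return records

    def extend(self, other: "PatchSet") -> None:
        self.patches.extend(other.patches)

    def subset(self, indices: Sequence[int]) -> "PatchSet":
        return PatchSet([self.patches[i] for i in indices])

    def save(self, path: str | Path) -> None:
        """Persist as a zip holding a compressed array container + JSON manifest."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        import io

        buf = io.BytesIO()
        np.savez_compressed(buf, images=self.images(), labels=self.labels())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("arrays.npz", buf.getvalue())
            zf.writestr("manifest.json", json.dumps(self.manifest(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PatchSet":
        with zipfile.ZipFile(Path(path)) as zf:
            import io

            with zf.open("arrays.npz") as f:
                arrays = np.load(io.BytesIO(f.read()))
                images, labels = arrays["images"], arrays["labels"]
            manifest = json.loads(zf.read("manifest.json"))
        patches = []
        for img, lab, rec in zip(images, labels, manifest):
            origin = tuple(rec["origin"]) if isinstance(rec["origin"], list) else rec["origin"]
            patches.append(LabeledPatch(img, lab.astype(np.uint8), origin, rec["mode"]))
        return cls(patches)


def _random_walk_centerline(
    rng: np.random.Generator, shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth random-walk centerline with a slowly varying radius.

    Returns (points, radii): unit-step 3-D positions clipped to the volume
    and per-point radii in [1, 4] voxels.
    """
    lo = np.array([2.0, 2.0, 2.0])
    hi = np.asarray(shape, dtype=float) - 3.0
    # start in the central 60% so every vessel contributes interior voxels
    # (in-plane patch extraction needs vessel centers away from the faces)
    pos = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    n_steps = int(rng.integers(max(10, min(shape) // 2), int(1.2 * max(shape))))
    radius = float(rng.uniform(1.0, 3.0))
    pts, radii = [], []
    for _ in range(n_steps):
        pts.append(pos.copy())
        radii.append(radius)
        direction = direction + 0.25 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # reflect at the walls so walks do not stick to volume faces
        nxt = pos + direction
        for ax in range(3):
            if nxt[ax] < lo[ax] or nxt[ax] > hi[ax]:
                direction[ax] = -direction[ax]
        pos = np.clip(pos + direction, lo, hi)
        radius = float(np.clip(radius + 0.15 * rng.normal(), 1.0, 4.0))
    return np.asarray(pts), np.asarray(radii)


def rasterize_tube(
    shape: tuple[int, int, int], points: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Exact tube support: union of balls around the centerline samples.

    A voxel belongs to the tube iff its center lies within ``radii[t]`` of
    ``points[t]`` for some t.  Stamping is local (per-ball bounding boxes)
    but the result equals the brute-force all-voxel scan by construction.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    for p, r in zip(points, radii):
        lo = np.maximum(np.floor(p - r).astype(int), 0)
        hi = np.minimum(np.ceil(p + r).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        xs, ys, zs = np.meshgrid(
            *(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij"
        )
        d2 = (xs - p[0]) ** 2 + (ys - p[1]) ** 2 + (zs - p[2]) ** 2
        sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        sub[d2 <= r**2] = 1
    return mask


def generate_volume(
    seed: int,
    shape: tuple[int, int, int] = (64, 64, 32),
    n_vessels: int = 5,
    noise_level: float = 0.05,
    subject_id: str | None = None,
    min_axis: int = 32,
) -> PhantomVolume:
    """Generate one synthetic vascular volume.

    Vessels are random-walk centerlines with radius varying in 1–4 voxels,
    rendered bright (pre-noise intensity at least 0.7 against a background
    of 0.15 +/- 0.02) with a Gaussian radial brightness profile; the mask is
    the exact rasterised tube support.  ``noise_level`` is the SD of the
    additive Gaussian noise in intensity units.  The volume is min-max
    normalised to [0, 1] at the end.  Identical seeds give identical
    volumes.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < min_axis for s in shape):
        raise ValueError(
            f"degenerate shape {shape}: every axis must be >= {min_axis} "
            "so that at least one full patch fits"
        )
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    if not 0 <= noise_level <= 0.5:
        raise ValueError("noise_level must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    # smooth low-frequency background texture
    bg = _BG_BASE + _BG_TEXTURE * gaussian_filter(
        rng.normal(size=shape), sigma=4.0
    ) / max(1e-8, gaussian_filter(rng.normal(size=(8, 8, 8)), sigma=4.0).std())
    intensity = bg.copy()
    mask = np.zeros(shape, dtype=np.uint8)
    dist_weight = np.zeros(shape)  # Gaussian radial profile accumulator
    for _ in range(n_vessels):
        pts, radii = _random_walk_centerline(rng, shape)
        tube = rasterize_tube(shape, pts, radii)
        mask |= tube
        # brightness profile: distance-to-centerline approximated per ball
        for p, r in zip(pts[::2], radii[::2]):
            lo = np.maximum(np.floor(p - 2 * r).astype(int), 0)
            hi = np.minimum(np.ceil(p + 2 * r).astype(int) + 1, shape)
            xs, ys, zs = np.meshgrid(
                *(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij"
            )
            d2 = (xs - p[0]) ** 2 + (ys - p[1]) ** 2 + (zs - p[2]) ** 2
            prof = np.exp(-d2 / (2 * (r / 1.5) ** 2))
            sub = dist_weight[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            np.maximum(sub, prof, out=sub)
    vessel_intensity = _VESSEL_MIN + (1.0 - _VESSEL_MIN) * dist_weight
    on = mask.astype(bool)
    intensity[on] = np.maximum(intensity[on], vessel_intensity[on])
    if noise_level > 0:
        intensity = intensity + rng.normal(0.0, noise_level, size=shape)
    lo_v, hi_v = intensity.min(), intensity.max()
    intensity = (intensity - lo_v) / max(hi_v - lo_v, 1e-8)
    return PhantomVolume(
        intensity=intensity.astype(np.float64),
        mask=mask,
        subject_id=subject_id or f"phantom-{seed}",
        seed=seed,
    )


def generate_cohort(
    n_subjects: int,
    seed: int,
    shape: tuple[int, int, int] = (64, 64, 32),
    n_vessels: int = 5,
    noise_level: float = 0.05,
    prefix: str = "subj",
) -> list[PhantomVolume]:
    """Generate a cohort of per-subject volumes with derived seeds."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    return [
        generate_volume(
            int(s),
            shape=shape,
            n_vessels=n_vessels,
            noise_level=noise_level,
            subject_id=f"{prefix}-{i:03d}",
        )
        for i, s in enumerate(seeds)
    ]


def candidate_vessel_centers(vol: PhantomVolume, patch_size: int) -> np.ndarray:
    """All (row, col, z) top-left-compatible vessel-centered positions.

    A position is valid when the patch window [r, r+P) x [c, c+P) is in
    bounds and the mask at the central pixel (r + P//2, c + P//2) of slice
    z is 1.  Returned as (N, 3) array of (z, row, col) top-left corners.
    """
    P = patch_size
    h = P // 2
    nx, ny, _ = vol.shape
    vox = np.argwhere(vol.mask == 1)  # (x, y, z)
    rows = vox[:, 0] - h
    cols = vox[:, 1] - h
    ok = (rows >= 0) & (cols >= 0) & (rows + P <= nx) & (cols + P <= ny)
    out = np.stack([vox[ok, 2], rows[ok], cols[ok]], axis=1)
    return out


def extract_patches(
    vol: PhantomVolume,
    n_vessel_centered: int,
    n_random: int,
    patch_size: int = 96,
    seed: int = 0,
    max_retries: int = 200,
) -> PatchSet:
    """Extract labeled 2-D patches from axial slices of one volume.

    ``n_vessel_centered`` patches are sampled uniformly (without
    replacement) from positions whose central mask voxel is 1;
    ``n_random`` patches uniformly over all in-bounds positions
    (vessel-centered positions are *not* excluded from the random pool).
    No two patches in the returned set share the same
    (subject, z, row, col) origin; random draws colliding with an already
    chosen origin are resampled up to a retry cap.
    """
    P = int(patch_size)
    nx, ny, nz = vol.shape
    if P > nx or P > ny:
        raise ValueError(f"patch_size {P} exceeds in-plane volume extent {(nx, ny)}")
    rng = np.random.default_rng(seed)
    chosen: set[tuple] = set()
    patches: list[LabeledPatch] = []

    def cut(z: int, r: int, c: int, mode: str) -> LabeledPatch:
        img = vol.intensity[r : r + P, c : c + P, z]
        lab = vol.mask[r : r + P, c : c + P, z]
        return LabeledPatch(
            np.ascontiguousarray(img),
            np.ascontiguousarray(lab).astype(np.uint8),
            (vol.subject_id, int(z), int(r), int(c)),
            mode,
        )

    if n_vessel_centered > 0:
        cand = candidate_vessel_centers(vol, P)
        if cand.shape[0] < n_vessel_centered:
            raise ValueError(
                f"only {cand.shape[0]} vessel-centered candidate positions exist, "
                f"{n_vessel_centered} requested (shortfall "
                f"{n_vessel_centered - cand.shape[0]})"
            )
        idx = rng.choice(cand.shape[0], size=n_vessel_centered, replace=False)
        for z, r, c in cand[idx]:
            chosen.add((int(z), int(r), int(c)))
            patches.append(cut(int(z), int(r), int(c), "vessel_centered"))

    n_positions = nz * (nx - P + 1) * (ny - P + 1)
    if n_random > 0:
        if n_positions - len(chosen) < n_random:
            raise ValueError(
                f"not enough distinct positions: {n_positions} total, "
                f"{len(chosen)} taken, {n_random} random requested"
            )
        got = 0
        attempts = 0
        cap = max_retries * max(1, n_random)
        while got < n_random:
            if attempts >= cap:
                raise RuntimeError("retry cap reached while deduplicating random patches")
            attempts += 1
            z = int(rng.integers(0, nz))
            r = int(rng.integers(0, nx - P + 1))
            c = int(rng.integers(0, ny - P + 1))
            key = (z, r, c)
            if key in chosen:
                continue
            chosen.add(key)
            patches.append(cut(z, r, c, "random"))
            got += 1
    return PatchSet(patches)


def save_volume(vol: PhantomVolume, image_path: str | Path, mask_path: str | Path) -> None:
    """Write intensity and mask as NIfTI pairs with identical headers."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.intensity.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), str(mask_path))


def load_volume(
    image_path: str | Path, mask_path: str | Path, subject_id: str = "loaded", seed: int = -1
) -> PhantomVolume:
    import nibabel as nib

    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PhantomVolume(
        intensity=np.asarray(img.dataobj, dtype=np.float64),
        mask=(np.asarray(msk.dataobj) > 0.5).astype(np.uint8),
        spacing=spacing,
        subject_id=subject_id,
        seed=seed,
    )
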
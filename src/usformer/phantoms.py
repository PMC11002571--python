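"""Synthetic LGE-MRI-like 3D phantoms with known ground truth.

Each phantom emulates the properties that make left-atrium segmentation
hard: the foreground is a small fraction of the volume (class imbalance),
the foreground/background intensity gap is low relative to the noise
(indistinct boundaries), and slender tubular appendages emanate from the
body (pulmonary-vein-like structures). The mask is an ellipsoid body plus
curved tubes and an optional appendage lobe; the image is the mask at a
configurable contrast, blurred, with additive Gaussian noise.

Phantoms are fully determined by (spec, seed) and regenerate bit-identically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import Volume3D, write_mask, write_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "phantom_pair"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of the phantom family.

    Radii and lengths are in voxels; ``contrast`` is the foreground-minus-
    background mean intensity gap in units of the noise SD, so the default
    1.5 gives genuinely low-contrast boundaries after blurring.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.25, 1.25, 2.5)
    body_semiaxes_ij: tuple[float, float] = (7.0, 12.0)
    body_semiaxes_k: tuple[float, float] = (4.0, 7.0)
    n_tubes_range: tuple[int, int] = (2, 4)
    tube_radius_range: tuple[float, float] = (1.2, 2.2)
    tube_length_range: tuple[int, int] = (8, 16)
    appendage: bool = True
    contrast: float = 1.5
    noise_sd: float = 1.0
    background_level: float = 0.0
    smoothing: float = 1.0
    foreground_bounds: tuple[float, float] = (0.005, 0.05)
    max_retries: int = 50

    def __post_init__(self) -> None:
        lo, hi = self.foreground_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("foreground_bounds must satisfy 0 < lo < hi < 1")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _mark_ball(mask: np.ndarray, center: np.ndarray, radius: float) -> None:
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, mask.shape)
    if np.any(lo >= hi):
        return
    grids = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
    acc = np.zeros(tuple(b - a for a, b in zip(lo, hi)), dtype=np.float64)
    for g, c in zip(grids, center):
        acc = acc + (g - c) ** 2
    mask[tuple(slice(a, b) for a, b in zip(lo, hi))] |= acc <= radius ** 2


def _sample_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = np.asarray(spec.shape)
    center = shape / 2.0 + rng.uniform(-0.08, 0.08, size=3) * shape
    semi = np.array(
        [
            rng.uniform(*spec.body_semiaxes_ij),
            rng.uniform(*spec.body_semiaxes_ij),
            rng.uniform(*spec.body_semiaxes_k),
        ]
    )
    mask = _ellipsoid(spec.shape, center, semi)

    n_tubes = int(rng.integers(spec.n_tubes_range[0], spec.n_tubes_range[1] + 1))
    for _ in range(n_tubes):
        _grow_tube(mask, center, semi, spec, rng)
    if spec.appendage:
        # small lobe straddling the body surface
        direction = _random_unit(rng)
        anchor = center + direction * semi
        lobe_semi = semi * rng.uniform(0.25, 0.4, size=3)
        mask |= _ellipsoid(spec.shape, anchor, np.maximum(lobe_semi, 1.5))
    return mask


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _grow_tube(mask, center, semi, spec, rng) -> None:
    """March a curved tube outward from the body surface, stamping balls."""
    direction = _random_unit(rng)
    pos = center + direction * semi * 0.95  # just inside the surface
    radius = rng.uniform(*spec.tube_radius_range)
    length = int(rng.integers(spec.tube_length_range[0], spec.tube_length_range[1] + 1))
    drift = rng.normal(scale=0.15, size=3)
    for _ in range(length):
        _mark_ball(mask, pos, radius)
        direction = direction + drift * 0.3 + rng.normal(scale=0.05, size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + direction
        if np.any(pos < -radius) or np.any(pos > np.asarray(mask.shape) + radius):
            break


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[Volume3D, np.ndarray]:
    """One phantom: (intensity volume, binary mask), deterministic in seed.

    Shape parameters are resampled (bounded retries) until the mask is a
    single 6-connected component with foreground fraction inside
    ``spec.foreground_bounds``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.foreground_bounds
    for _ in range(spec.max_retries):
        mask = _sample_mask(spec, rng)
        frac = mask.mean()
        if not (lo <= frac <= hi):
            continue
        _, n_comp = ndimage.label(mask, structure=_STRUCT6)
        if n_comp == 1:
            break
    else:
        raise RuntimeError(
            f"could not draw a phantom satisfying {spec.foreground_bounds} "
            f"in {spec.max_retries} attempts"
        )
    clean = spec.background_level + spec.contrast * spec.noise_sd * mask.astype(np.float64)
    if spec.smoothing > 0:
        clean = ndimage.gaussian_filter(clean, spec.smoothing)
    noisy = clean + rng.normal(scale=spec.noise_sd, size=spec.shape)
    vol = Volume3D(noisy, spacing=spec.spacing, source_id=f"phantom-seed{seed}")
    return vol, mask.astype(np.uint8)


def phantom_pair(seed: int, spec: PhantomSpec | None = None) -> tuple[Volume3D, np.ndarray]:
    """Convenience wrapper with the default spec."""
    return generate_phantom(spec or PhantomSpec(), seed)


def generate_dataset(
    n: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[Volume3D, np.ndarray]], list[dict]]:
    """Generate ``n`` phantoms with per-item seeds derived from ``seed``.

    If ``out_dir`` is given, writes ``vol_###.nii.gz`` / ``mask_###.nii.gz``
    pairs plus ``manifest.csv`` (id, seed, foreground_fraction); regenerating
    from the manifest seeds reproduces the files exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or PhantomSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(n).tolist()
    items, manifest = [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(child_seeds):
        vol, mask = generate_phantom(spec, int(s))
        items.append((vol, mask))
        row = {"id": f"{i:03d}", "seed": int(s), "foreground_fraction": float(mask.mean())}
        manifest.append(row)
        if out is not None:
            write_volume(vol, out / f"vol_{i:03d}.nii.gz")
            write_mask(mask, vol, out / f"mask_{i:03d}.nii.gz")
    if out is not None:
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["id", "seed", "foreground_fraction"])
            writer.writeheader()
            writer.writerows(manifest)
    return items, manifest
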
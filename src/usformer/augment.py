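"""Training-time augmentation: random in-plane (IJ) affine transforms.

With probability 0.5 a scan is left untouched; otherwise one set of affine
parameters is drawn — scale in (0.5, 1.5), rotation in (-25, 25) degrees,
translation in (-10, 10) pixels per in-plane axis — and the same 2D affine
is applied to every IJ slice of both image and mask. Sharing one draw across
slices keeps the 3D anatomy coherent; the image is resampled linearly, the
mask with nearest-neighbour so it stays binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "AffineParams", "sample_affine", "apply_inplane_affine"]


@dataclass(frozen=True)
class AugmentConfig:
    probability: float = 0.5
    scale_range: tuple[float, float] = (0.5, 1.5)
    angle_range: tuple[float, float] = (-25.0, 25.0)
    shift_range: tuple[float, float] = (-10.0, 10.0)


@dataclass(frozen=True)
class AffineParams:
    """One in-plane affine draw; ``applied=False`` means exact identity."""

    scale: float = 1.0
    angle: float = 0.0  # degrees
    shift: tuple[float, float] = (0.0, 0.0)  # (di, dj) pixels
    applied: bool = False

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls()


def sample_affine(rng: np.random.Generator, cfg: AugmentConfig | None = None) -> AffineParams:
    """Draw augmentation parameters; identity with probability 1 - cfg.probability."""
    cfg = cfg or AugmentConfig()
    if rng.random() >= cfg.probability:
        return AffineParams.identity()
    return AffineParams(
        scale=float(rng.uniform(*cfg.scale_range)),
        angle=float(rng.uniform(*cfg.angle_range)),
        shift=(float(rng.uniform(*cfg.shift_range)), float(rng.uniform(*cfg.shift_range))),
        applied=True,
    )


def _inplane_matrix(p: AffineParams, shape_ij: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-map matrix and offset for scipy's affine_transform (3D, k fixed)."""
    theta = np.deg2rad(p.angle)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    fwd = p.scale * rot
    inv = np.linalg.inv(fwd)
    center = (np.asarray(shape_ij, dtype=np.float64) - 1.0) / 2.0
    shift = np.asarray(p.shift, dtype=np.float64)
    # output voxel q maps from input voxel inv @ (q - center - shift) + center
    matrix = np.eye(3)
    matrix[:2, :2] = inv
    offset = np.zeros(3)
    offset[:2] = center - inv @ (center + shift)
    return matrix, offset


def apply_inplane_affine(
    volume: np.ndarray, mask: np.ndarray, p: AffineParams
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one affine draw to every IJ slice of a volume/mask pair.

    Scaling and rotation are about the slice centre; out-of-field image
    voxels are filled with the volume minimum and mask voxels with 0.
    Shapes are unchanged.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask)
    if volume.shape != mask.shape:
        raise ValueError(f"volume/mask shapes differ: {volume.shape} vs {mask.shape}")
    if not p.applied:
        return volume, mask
    matrix, offset = _inplane_matrix(p, volume.shape[:2])
    vol_out = ndimage.affine_transform(
        volume, matrix, offset=offset, order=1, mode="constant", cval=float(volume.min())
    )
    mask_out = ndimage.affine_transform(
        mask.astype(np.uint8), matrix, offset=offset, order=0, mode="constant", cval=0
    )
    return vol_out.astype(volume.dtype, copy=False), mask_out.astype(np.uint8)
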
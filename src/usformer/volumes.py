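"""Volumetric data model and NIfTI/NRRD I/O.

Volumes are held as rank-3 arrays indexed ``(i, j, k)`` where the first two
axes span the in-plane (axial, "IJ") slice and ``k`` walks through slices.
Physical voxel spacing in millimetres is carried alongside the grid so that
surface-distance metrics can be reported in mm on anisotropic grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume3D",
    "PadRecord",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "pad_to_multiple",
    "crop_by_record",
    "znormalize",
    "as_binary_mask",
]

_NIFTI_EXTS = (".nii", ".nii.gz")
_NRRD_EXTS = (".nrrd",)


@dataclass
class Volume3D:
    """A 3D scalar grid with physical spacing.

    Parameters
    ----------
    data : ndarray, shape (H, W, Z)
        Voxel intensities (or binary labels for masks).
    spacing : tuple of float
        Millimetres per voxel along each axis; strictly positive.
    affine : ndarray, optional
        4x4 voxel-index -> physical-coordinate map. Defaults to a diagonal
        scaling by ``spacing``.
    source_id : str
        Free-text provenance tag.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a rank-3 grid, got rank {self.data.ndim}")
        if any(d < 1 for d in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class PadRecord:
    """Padding applied per axis; cropping by the record inverts the pad exactly."""

    original_shape: tuple[int, int, int]
    pad_width: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_EXTS):
        return "nifti"
    if name.endswith(_NRRD_EXTS):
        return "nrrd"
    raise IOError(f"unsupported volume format: {path} (expected .nii, .nii.gz or .nrrd)")


def read_volume(path: str | Path, nan_policy: str = "error") -> Volume3D:
    """Read a NIfTI or NRRD volume from disk.

    Parameters
    ----------
    path : path-like
        File ending in ``.nii``, ``.nii.gz`` or ``.nrrd``.
    nan_policy : {"error", "zero"}
        ``"error"`` raises on non-finite voxels; ``"zero"`` replaces them
        with 0 and emits a warning.

    Returns
    -------
    Volume3D
        Intensities as float64, spacing taken from the file header.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _detect_format(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        affine = np.asarray(img.affine, dtype=np.float64)
    else:
        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); restore (i, j, k) order.
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
        spacing = tuple(float(s) for s in img.GetSpacing())
        affine = None
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got rank {data.ndim}")
    if not np.all(np.isfinite(data)):
        if nan_policy == "zero":
            n_bad = int(np.count_nonzero(~np.isfinite(data)))
            warnings.warn(f"{path}: {n_bad} non-finite voxels replaced with 0", stacklevel=2)
            data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
        else:
            raise ValueError(f"{path}: volume contains non-finite voxels")
    return Volume3D(data=data, spacing=spacing, affine=affine, source_id=str(path))


def read_mask(path: str | Path) -> Volume3D:
    """Read a binary label mask; values must be exactly {0, 1}."""
    vol = read_volume(path)
    vol.data = as_binary_mask(vol.data)
    return vol


def as_binary_mask(data: np.ndarray) -> np.ndarray:
    """Validate that ``data`` contains only {0, 1} and cast to uint8."""
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask values must be exactly {{0,1}}, found {uniq[:10]}")
    return data.astype(np.uint8)


def _write(data: np.ndarray, ref: Volume3D, path: Path) -> None:
    fmt = _detect_format(path)
    if fmt == "nifti":
        img = nib.Nifti1Image(data, affine=ref.affine)
        img.header.set_zooms(ref.spacing)
        nib.save(img, str(path))
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(ref.spacing))
        sitk.WriteImage(img, str(path))


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume to NIfTI or NRRD (by extension)."""
    _write(vol.data.astype(np.float64), vol, Path(path))


def write_mask(mask: np.ndarray | Volume3D, ref: Volume3D, path: str | Path) -> None:
    """Write a binary mask on the grid of ``ref``.

    Raises if the mask shape does not match ``ref`` or contains values
    outside {0, 1}.
    """
    data = mask.data if isinstance(mask, Volume3D) else np.asarray(mask)
    if data.shape != ref.data.shape:
        raise ValueError(f"mask shape {data.shape} does not match reference {ref.data.shape}")
    _write(as_binary_mask(data), ref, Path(path))


def pad_to_multiple(
    vol: Volume3D, multiple: int, fill: str | float = "min"
) -> tuple[Volume3D, PadRecord]:
    """Pad each axis up to the next multiple of ``multiple``.

    The network halves resolution four times, so inputs must be divisible
    by 16; this pads symmetrically (extra voxel on the high side) with the
    per-volume minimum intensity, which approximates MRI background better
    than zero once intensities are normalized.
    """
    if multiple < 1:
        raise ValueError("multiple must be >= 1")
    shape = vol.data.shape
    pads = []
    for d in shape:
        target = -(-d // multiple) * multiple
        extra = target - d
        pads.append((extra // 2, extra - extra // 2))
    record = PadRecord(original_shape=shape, pad_width=tuple(pads))  # type: ignore[arg-type]
    if all(lo == 0 and hi == 0 for lo, hi in pads):
        return vol, record
    value = float(vol.data.min()) if fill == "min" else float(fill)
    padded = np.pad(vol.data, pads, mode="constant", constant_values=value)
    return (
        Volume3D(padded, spacing=vol.spacing, affine=vol.affine, source_id=vol.source_id),
        record,
    )


def crop_by_record(data: np.ndarray, record: PadRecord) -> np.ndarray:
    """Invert :func:`pad_to_multiple` exactly."""
    slices = tuple(
        slice(lo, lo + d) for (lo, _hi), d in zip(record.pad_width, record.original_shape)
    )
    out = data[slices]
    assert out.shape == record.original_shape
    return out


def znormalize(data: np.ndarray) -> np.ndarray:
    """Per-volume z-score; constant volumes map to all-zero."""
    data = np.asarray(data, dtype=np.float32)
    sd = float(data.std())
    if sd == 0.0:
        return data - data.mean()
    return (data - data.mean()) / sd
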
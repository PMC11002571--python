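"""3D evaluation metrics: Dice, Hausdorff distance and ASSD.

    Dice = 2TP / (2TP + FN + FP)
    HD   = max{ max_p min_g d(p,g),  max_g min_p d(p,g) }
    ASSD = ( sum_g min_p d(p,g) + sum_p min_g d(p,g) ) / (n_G + n_P)

Surfaces are the foreground voxels with at least one background voxel among
their 6-neighbours; the array border counts as background. Distances are
Euclidean between voxel centres in physical millimetres, so anisotropic
spacing is honoured. HD is the full maximum (not a percentile) and ASSD
averages over the two surface cardinalities n_G = |G|, n_P = |P|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_counts",
    "dice3d",
    "surface_voxels",
    "hausdorff",
    "assd",
    "surface_distances",
    "evaluate_set",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Per-scan Dice (fraction), HD (mm) and ASSD (mm) with aggregates."""

    ids: list[str]
    dice: np.ndarray
    hd: np.ndarray
    assd: np.ndarray

    @property
    def dice_mean(self) -> float:
        return float(self.dice.mean())

    @property
    def dice_sd(self) -> float:
        return float(self.dice.std())

    @property
    def hd_mean(self) -> float:
        return float(self.hd.mean())

    @property
    def hd_sd(self) -> float:
        return float(self.hd.std())

    @property
    def assd_mean(self) -> float:
        return float(self.assd.mean())

    @property
    def assd_sd(self) -> float:
        return float(self.assd.std())

    def to_rows(self) -> list[dict]:
        rows = [
            {"id": i, "dice": float(d), "hd_mm": float(h), "assd_mm": float(a)}
            for i, d, h, a in zip(self.ids, self.dice, self.hd, self.assd)
        ]
        rows.append(
            {
                "id": "mean",
                "dice": self.dice_mean,
                "hd_mm": self.hd_mean,
                "assd_mm": self.assd_mean,
            }
        )
        rows.append(
            {"id": "sd", "dice": self.dice_sd, "hd_mm": self.hd_sd, "assd_mm": self.assd_sd}
        )
        return rows


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be rank 3, got rank {mask.ndim}")
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask values must be in {0, 1}")
    return mask.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact voxel-wise confusion counts over the whole volume."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dice3d(pred: np.ndarray, truth: np.ndarray) -> float:
    """2TP / (2TP + FN + FP); both-empty masks score 1.0 (with a warning)."""
    c = confusion_counts(pred, truth)
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        warnings.warn("both masks empty; dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * c.tp / denom


_FACES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (m, 3) of foreground voxels with a background 6-neighbour.

    Out-of-bounds neighbours count as background, so foreground touching the
    array border is surface.
    """
    m = _as_bool(mask)
    if not m.any():
        raise ValueError("cannot extract the surface of an empty mask")
    # 6-connectivity erosion with border treated as background
    interior = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return np.argwhere(m & ~interior)


def _directed_min_dists(
    src: np.ndarray, dst: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Distance from each voxel of ``src`` to its nearest voxel of ``dst`` (mm)."""
    sp = np.asarray(spacing, dtype=np.float64)
    tree = cKDTree(dst * sp)
    d, _ = tree.query(src * sp, k=1)
    return d


def surface_distances(
    pred_surf: np.ndarray, truth_surf: np.ndarray, spacing: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Both directed nearest-surface distance sets (pred->truth, truth->pred)."""
    if len(pred_surf) == 0 or len(truth_surf) == 0:
        raise ValueError("surface-distance metrics are undefined for empty surfaces")
    return (
        _directed_min_dists(pred_surf, truth_surf, spacing),
        _directed_min_dists(truth_surf, pred_surf, spacing),
    )


def hausdorff(
    pred_surf: np.ndarray, truth_surf: np.ndarray, spacing: tuple[float, float, float]
) -> float:
    """Full symmetric Hausdorff distance in millimetres."""
    d_pg, d_gp = surface_distances(pred_surf, truth_surf, spacing)
    return float(max(d_pg.max(), d_gp.max()))


def assd(
    pred_surf: np.ndarray, truth_surf: np.ndarray, spacing: tuple[float, float, float]
) -> float:
    """Average symmetric surface distance in millimetres."""
    d_pg, d_gp = surface_distances(pred_surf, truth_surf, spacing)
    return float((d_pg.sum() + d_gp.sum()) / (len(d_pg) + len(d_gp)))


def evaluate_pair(
    pred: np.ndarray, truth: np.ndarray, spacing: tuple[float, float, float]
) -> tuple[float, float, float]:
    """(dice, hd_mm, assd_mm) for one mask pair."""
    d = dice3d(pred, truth)
    ps, ts = surface_voxels(pred), surface_voxels(truth)
    return d, hausdorff(ps, ts, spacing), assd(ps, ts, spacing)


def evaluate_set(
    pairs: list[tuple[np.ndarray, np.ndarray, tuple[float, float, float]]],
    ids: list[str] | None = None,
) -> EvalReport:
    """Per-scan metrics plus mean and (population) SD across the set."""
    if not pairs:
        raise ValueError("evaluate_set needs at least one (pred, truth, spacing) pair")
    ids = ids or [f"scan{i:03d}" for i in range(len(pairs))]
    rows = [evaluate_pair(p, t, sp) for p, t, sp in pairs]
    arr = np.asarray(rows, dtype=np.float64)
    return EvalReport(ids=list(ids), dice=arr[:, 0], hd=arr[:, 1], assd=arr[:, 2])
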
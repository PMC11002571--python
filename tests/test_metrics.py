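"""Metric tests against brute-force oracles: per-voxel loops for confusion
counts and surfaces, all-pairs O(|P||G|) min/max scans for HD and ASSD."""

import numpy as np
import pytest

from conftest import random_blob
from usformer.metrics import (
    assd,
    confusion_counts,
    dice3d,
    evaluate_set,
    hausdorff,
    surface_voxels,
)


# --------------------------------------------------------------------------
# oracles


def surface_oracle(mask):
    """Per-voxel loop over the 6-neighbourhood; border is background."""
    out = []
    H, W, Z = mask.shape
    for i in range(H):
        for j in range(W):
            for k in range(Z):
                if not mask[i, j, k]:
                    continue
                on_surface = False
                for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < H and 0 <= b < W and 0 <= c < Z) or not mask[a, b, c]:
                        on_surface = True
                        break
                if on_surface:
                    out.append((i, j, k))
    return np.array(sorted(out)).reshape(-1, 3)


def allpairs_distances(ps, gs, spacing):
    sp = np.asarray(spacing)
    d = np.sqrt((((ps[:, None, :] - gs[None, :, :]) * sp) ** 2).sum(axis=2))
    hd = max(d.min(axis=1).max(), d.min(axis=0).max())
    a = (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(ps) + len(gs))
    return hd, a


# --------------------------------------------------------------------------
# confusion / dice


def test_confusion_identical_masks():
    m = np.zeros((4, 4, 4), dtype=np.uint8)
    m.flat[:10] = 1
    c = confusion_counts(m, m)
    assert (c.tp, c.tn, c.fp, c.fn) == (10, 54, 0, 0)


def test_confusion_complement():
    m = (np.random.default_rng(0).random((4, 4, 4)) < 0.5).astype(np.uint8)
    c = confusion_counts(1 - m, m)
    assert c.tp == 0 and c.tn == 0
    assert c.fp + c.fn == m.size


@pytest.mark.parametrize("seed", range(5))
def test_confusion_matches_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    p, t = random_blob(rng, (4, 4, 4)), random_blob(rng, (4, 4, 4))
    c = confusion_counts(p, t)
    tp = sum(int(p[i] and t[i]) for i in np.ndindex(p.shape))
    fp = sum(int(p[i] and not t[i]) for i in np.ndindex(p.shape))
    fn = sum(int(not p[i] and t[i]) for i in np.ndindex(p.shape))
    assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, p.size - tp - fp - fn)
    assert c.total == p.size


def test_dice_values():
    m = random_blob(np.random.default_rng(1), (5, 5, 5))
    assert dice3d(m, m) == 1.0
    a = np.zeros((4, 4, 4), dtype=np.uint8)
    b = np.zeros_like(a)
    a[0, 0, 0] = 1
    b[3, 3, 3] = 1
    assert dice3d(a, b) == 0.0
    # TP=2, FP=1, FN=1 -> 4/6
    p = np.zeros((3, 3, 3), dtype=np.uint8)
    t = np.zeros_like(p)
    p[0, 0, 0] = p[0, 0, 1] = p[0, 0, 2] = 1
    t[0, 0, 0] = t[0, 0, 1] = t[1, 1, 1] = 1
    assert dice3d(p, t) == pytest.approx(4 / 6)


def test_dice_both_empty_is_one_with_warning():
    empty = np.zeros((3, 3, 3), dtype=np.uint8)
    with pytest.warns(UserWarning, match="empty"):
        assert dice3d(empty, empty) == 1.0


# --------------------------------------------------------------------------
# surfaces


def test_single_voxel_is_its_own_surface():
    m = np.zeros((5, 5, 5), dtype=np.uint8)
    m[2, 3, 1] = 1
    np.testing.assert_array_equal(surface_voxels(m), [[2, 3, 1]])


def test_solid_cube_surface_excludes_center():
    m = np.zeros((5, 5, 5), dtype=np.uint8)
    m[1:4, 1:4, 1:4] = 1
    s = surface_voxels(m)
    assert len(s) == 26
    assert [2, 2, 2] not in s.tolist()


def test_mask_touching_border_is_surface():
    m = np.ones((2, 2, 2), dtype=np.uint8)
    assert len(surface_voxels(m)) == 8


def test_empty_mask_surface_raises():
    with pytest.raises(ValueError, match="empty"):
        surface_voxels(np.zeros((3, 3, 3), dtype=np.uint8))


@pytest.mark.parametrize("seed", range(10))
def test_surface_matches_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    m = random_blob(rng, tuple(rng.integers(3, 9, size=3)), p=0.4)
    got = surface_voxels(m)
    want = surface_oracle(m)
    np.testing.assert_array_equal(np.array(sorted(got.tolist())), want)


# --------------------------------------------------------------------------
# distances


def test_identical_surfaces_zero_distance():
    m = random_blob(np.random.default_rng(3), (6, 6, 6))
    s = surface_voxels(m)
    sp = (1.0, 1.0, 2.0)
    assert hausdorff(s, s, sp) == 0.0
    assert assd(s, s, sp) == 0.0


def test_two_voxel_anisotropic_distance():
    """Voxels (0,0,0) and (0,0,2) at spacing (1,1,2.5): 2 * 2.5 = 5 mm."""
    a = np.array([[0, 0, 0]])
    b = np.array([[0, 0, 2]])
    sp = (1.0, 1.0, 2.5)
    assert hausdorff(a, b, sp) == pytest.approx(5.0)
    assert assd(a, b, sp) == pytest.approx(5.0)


@pytest.mark.parametrize("seed", range(15))
def test_distances_match_allpairs_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    shape = tuple(rng.integers(4, 13, size=3))
    p = random_blob(rng, shape, p=0.25)
    g = random_blob(rng, shape, p=0.25)
    spacing = tuple(rng.uniform(0.5, 3.0, size=3))
    ps, gs = surface_voxels(p), surface_voxels(g)
    hd_want, assd_want = allpairs_distances(ps, gs, spacing)
    hd_got = hausdorff(ps, gs, spacing)
    assd_got = assd(ps, gs, spacing)
    assert hd_got == pytest.approx(hd_want, abs=1e-9)
    assert assd_got == pytest.approx(assd_want, abs=1e-9)
    assert assd_got <= hd_got + 1e-12
    # symmetry
    assert hausdorff(gs, ps, spacing) == pytest.approx(hd_got, abs=1e-12)
    assert assd(gs, ps, spacing) == pytest.approx(assd_got, abs=1e-12)
    # mm-linearity in spacing
    double = tuple(2 * s for s in spacing)
    assert hausdorff(ps, gs, double) == pytest.approx(2 * hd_got, rel=1e-9)
    assert assd(ps, gs, double) == pytest.approx(2 * assd_got, rel=1e-9)


# --------------------------------------------------------------------------
# reports


def test_evaluate_set_identical_pair():
    m = random_blob(np.random.default_rng(5), (6, 6, 4))
    report = evaluate_set([(m, m, (1.0, 1.0, 1.0))])
    assert report.dice_mean == 1.0
    assert report.hd_mean == 0.0
    assert report.assd_mean == 0.0
    assert report.dice_sd == 0.0


def test_evaluate_set_aggregates_consistent(rng):
    pairs = []
    for seed in range(4):
        r = np.random.default_rng(seed)
        pairs.append((random_blob(r, (6, 6, 4)), random_blob(r, (6, 6, 4)),
                      (1.25, 1.25, 2.5)))
    report = evaluate_set(pairs)
    assert len(report.ids) == 4
    assert report.dice_mean == pytest.approx(float(report.dice.mean()))
    assert report.hd_sd == pytest.approx(float(report.hd.std()))
    rows = report.to_rows()
    assert rows[-2]["id"] == "mean" and rows[-1]["id"] == "sd"
    assert np.all(report.assd <= report.hd + 1e-12)


def test_evaluate_set_empty_input_rejected():
    with pytest.raises(ValueError):
        evaluate_set([])
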
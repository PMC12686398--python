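"""Occlusion-sensitivity saliency maps for the age model.

The importance of an image region is measured by how much blacking it out
degrades age estimation: for a square grid of windows at a given mask
size, each window is zeroed in one view of every exam, the MAE over the
exam set is recomputed, and the cell score is
``delta_MAE = MAE_occluded - MAE_original``.  Grids at several mask sizes
are reconstructed to image resolution by cubic interpolation of the cell
centre values, averaged across scales, floored at zero and divided by the
maximum so the final per-view map lies in [0, 1].

Occlusion is applied one view at a time, giving one map per view; the
maps for a cohort can be further stratified into age-decade x density
subgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline

__all__ = ["OcclusionGrid", "occlusion_windows", "occlude", "delta_mae_grid",
           "fuse_saliency", "subgroup_saliency", "AGE_GROUPS", "assign_age_group",
           "desk_mask_sizes"]

logger = logging.getLogger(__name__)

#: age-decade bins used for subgroup maps; boundary ages fall in the lower bin
AGE_GROUPS = ("<=40", "41-50", "51-60", "61-70", ">=70")

#: desk-scale analogue of the full-resolution mask sizes 32/64/128/256,
#: scaled proportionally for a 256-pixel-high frame
def desk_mask_sizes(image_height: int = 256) -> tuple[int, ...]:
    return tuple(max(2, image_height * m // 1536) for m in (32, 64, 128, 256))


@dataclass
class OcclusionGrid:
    mask_size: int
    windows: list[tuple[int, int, int, int]]     # (row, col, height, width)
    delta_mae: np.ndarray                        # (rows, cols), years
    grid_shape: tuple[int, int]
    image_shape: tuple[int, int]

    def __post_init__(self):
        self.delta_mae = np.asarray(self.delta_mae, dtype=np.float64)
        if not np.all(np.isfinite(self.delta_mae)):
            raise ValueError("delta MAE values must be finite")
        if sum(h * w for _, _, h, w in self.windows) != int(np.prod(self.image_shape)):
            raise ValueError("windows must tile the image exactly")


def occlusion_windows(image_shape: tuple[int, int], mask_size: int
                      ) -> list[tuple[int, int, int, int]]:
    """Row-major square tiling; boundary windows are clipped to the image.

    A mask larger than the image in both dimensions degenerates to a
    single full-image window.
    """
    H, W = image_shape
    if H <= 0 or W <= 0 or mask_size <= 0:
        raise ValueError("shapes must be positive")
    m = mask_size
    if m >= H and m >= W:
        return [(0, 0, H, W)]
    windows = []
    for r0 in range(0, H, m):
        for c0 in range(0, W, m):
            windows.append((r0, c0, min(m, H - r0), min(m, W - c0)))
    return windows


def occlude(image: np.ndarray, window: tuple[int, int, int, int]) -> np.ndarray:
    """Copy of ``image`` with the window blacked out (set to 0)."""
    r0, c0, h, w = window
    H, W = image.shape[-2:]
    if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise ValueError(f"window {window} exceeds image shape {(H, W)}")
    out = image.copy()
    out[..., r0:r0 + h, c0:c0 + w] = 0.0
    return out


def delta_mae_grid(predict_fn, images: np.ndarray, ages: np.ndarray,
                   view_index: int, mask_size: int,
                   clamp_negative: bool = False) -> OcclusionGrid:
    """Delta-MAE grid for one view at one mask size.

    ``predict_fn`` maps a batch of exams (N, 4, H, W) to predicted ages
    (N,); ``view_index`` selects which of the four views is occluded
    (the other three stay intact).  Negative cells (occlusion improving
    MAE) are retained unless ``clamp_negative``.
    """
    images = np.asarray(images, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if images.ndim != 4 or images.shape[1] != 4:
        raise ValueError("expected exams of shape (N, 4, H, W)")
    if len(images) == 0:
        raise ValueError("need at least one exam")
    H, W = images.shape[2:]
    windows = occlusion_windows((H, W), mask_size)
    mae0 = float(np.mean(np.abs(predict_fn(images) - ages)))
    deltas = []
    for win in windows:
        occluded = images.copy()
        occluded[:, view_index] = occlude(images[:, view_index], win)
        mae = float(np.mean(np.abs(predict_fn(occluded) - ages)))
        deltas.append(mae - mae0)
    n_rows = len(range(0, H, mask_size)) if not (mask_size >= H and mask_size >= W) else 1
    n_cols = len(windows) // n_rows
    grid = np.asarray(deltas, dtype=np.float64).reshape(n_rows, n_cols)
    if clamp_negative:
        grid = np.maximum(grid, 0.0)
    return OcclusionGrid(mask_size=mask_size, windows=windows, delta_mae=grid,
                         grid_shape=(n_rows, n_cols), image_shape=(H, W))


def _upsample_grid(grid: OcclusionGrid) -> np.ndarray:
    """Cubic interpolation of cell-centre values to image resolution.

    Values outside the convex hull of the centres are extended by edge
    replication (an extra ring of replicated centres at the image border).
    """
    H, W = grid.image_shape
    n_rows, n_cols = grid.grid_shape
    wins = np.array(grid.windows, dtype=np.float64).reshape(n_rows, n_cols, 4)
    # cell centres in pixel-index coordinates (pixel i at coordinate i)
    rc = wins[:, 0, 0] + (wins[:, 0, 2] - 1) / 2.0
    cc = wins[0, :, 1] + (wins[0, :, 3] - 1) / 2.0
    vals = grid.delta_mae

    def _pads(coords, last):
        pre = 1 if coords[0] > 1e-9 else 0
        post = 1 if coords[-1] < last - 1e-9 else 0
        padded = np.concatenate([[0.0] * pre, coords, [float(last)] * post])
        return pre, post, padded

    pre_r, post_r, rc_p = _pads(rc, H - 1)
    pre_c, post_c, cc_p = _pads(cc, W - 1)
    vals_p = np.pad(vals, ((pre_r, post_r), (pre_c, post_c)), mode="edge")
    kx = max(1, min(3, len(rc_p) - 1))
    ky = max(1, min(3, len(cc_p) - 1))
    spline = RectBivariateSpline(rc_p, cc_p, vals_p, kx=kx, ky=ky, s=0)
    return spline(np.arange(H, dtype=np.float64), np.arange(W, dtype=np.float64))


def fuse_saliency(grids: list[OcclusionGrid], image_shape: tuple[int, int]
                  ) -> np.ndarray:
    """Average the upsampled delta-MAE grids across mask scales, floor
    negatives at 0, and max-normalize into [0, 1].

    An identically-zero (or nonpositive) fused map is returned as zeros.
    """
    if not grids:
        raise ValueError("need at least one occlusion grid")
    for g in grids:
        if tuple(g.image_shape) != tuple(image_shape):
            raise ValueError("all grids must share the image shape")
    stack = np.stack([_upsample_grid(g) for g in grids])
    fused = stack.mean(axis=0)
    fused = np.maximum(fused, 0.0)
    peak = fused.max()
    if peak > 0:
        fused = fused / peak
    return fused


def assign_age_group(age: float) -> str:
    """Decade bin; boundary convention: age 40 -> '<=40', age 41 -> '41-50'."""
    if age <= 40:
        return AGE_GROUPS[0]
    if age <= 50:
        return AGE_GROUPS[1]
    if age <= 60:
        return AGE_GROUPS[2]
    if age <= 70:
        return AGE_GROUPS[3]
    return AGE_GROUPS[4]


def subgroup_saliency(predict_fn, images: np.ndarray, ages: np.ndarray,
                      densities: list[str], mask_sizes: tuple[int, ...] | None = None,
                      ) -> dict[tuple[str, str], list[np.ndarray]]:
    """Per-subgroup (age-decade x density A-D) fused maps, one per view.

    Empty subgroups are skipped with a logged notice.  Returns a mapping
    (age_group, density) -> [map for each of the four views].
    """
    H, W = images.shape[2:]
    if mask_sizes is None:
        mask_sizes = desk_mask_sizes(H)
    groups = np.array([assign_age_group(a) for a in ages])
    out: dict[tuple[str, str], list[np.ndarray]] = {}
    densities = np.asarray(densities)
    for ag in AGE_GROUPS:
        for dens in "ABCD":
            sel = (groups == ag) & (densities == dens)
            if not sel.any():
                logger.info("subgroup (%s, %s) is empty; skipped", ag, dens)
                continue
            maps = []
            for v in range(4):
                grids = [delta_mae_grid(predict_fn, images[sel], ages[sel], v, m)
                         for m in mask_sizes]
                maps.append(fuse_saliency(grids, (H, W)))
            out[(ag, dens)] = maps
    return out
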
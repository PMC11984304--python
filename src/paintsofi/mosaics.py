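"""Multi-position grid acquisition and mosaic stitching.

High-throughput screening images a large sample as a grid of partially
overlapping fields of view (default 10% overlap, raster order), records a
short blinking movie at each position, reconstructs each tile and stitches
the tiles into one large field of view.  Stage positioning error is modeled
as Gaussian jitter on the nominal offsets (default SD 2 px) so that the
stitcher's phase-correlation refinement is actually exercised; blending is a
linear feather across the overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .blink_sim import MovieStack, OpticsCamera, Phantom, render_movie

__all__ = ["GridPlan", "plan_grid", "simulate_tiles", "stitch", "write_tile_configuration"]


@dataclass(frozen=True)
class GridPlan:
    """Raster-order grid of partially overlapping tiles (offsets in px)."""

    rows: int
    cols: int
    tile_shape: tuple[int, int]  # (H, W) px
    overlap: float
    offsets_px: tuple[tuple[float, float], ...]  # nominal (y, x) per tile, raster order
    order: str = "raster"

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        H, W = self.tile_shape
        ys = [o[0] for o in self.offsets_px]
        xs = [o[1] for o in self.offsets_px]
        return (int(round(max(ys))) + H, int(round(max(xs))) + W)

    def overlap_px(self) -> tuple[int, int]:
        return (int(round(self.overlap * self.tile_shape[0])), int(round(self.overlap * self.tile_shape[1])))


def plan_grid(
    rows: int,
    cols: int,
    tile_shape: tuple[int, int],
    overlap: float = 0.10,
) -> GridPlan:
    """Plan a rows x cols grid with the given fractional overlap between tiles."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if not 0.0 < overlap < 0.5:
        raise ValueError("overlap must be in (0, 0.5)")
    H, W = tile_shape
    step_y = H * (1.0 - overlap)
    step_x = W * (1.0 - overlap)
    offsets = tuple((r * step_y, c * step_x) for r in range(rows) for c in range(cols))
    return GridPlan(rows=rows, cols=cols, tile_shape=(H, W), overlap=overlap, offsets_px=offsets)


def simulate_tiles(
    large_phantom: Phantom,
    grid_plan: GridPlan,
    optics: OpticsCamera,
    stage_jitter_px: float = 2.0,
    seed: int | None = None,
) -> tuple[list[MovieStack], np.ndarray]:
    """Render one blinking movie per grid position over a large phantom.

    Each tile sees the phantom restricted to its (jittered) stage window;
    sites in overlap strips appear in several tiles with *independent*
    blinking realizations (tiles are imaged sequentially).  Returns the tile
    stacks and the true (y, x) offsets in px, for stitching accuracy checks.
    """
    H, W = grid_plan.tile_shape
    p = optics.pixel_size
    my, mx = grid_plan.mosaic_shape
    if large_phantom.extent[0] < mx * p - 1e-6 or large_phantom.extent[1] < my * p - 1e-6:
        raise ValueError(
            f"grid footprint {(my, mx)} px exceeds phantom extent {large_phantom.extent} nm"
        )
    seed = optics.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    tile_extent = (W * p, H * p)
    stacks: list[MovieStack] = []
    true_offsets = np.zeros((grid_plan.n_tiles, 2))
    for k, (oy, ox) in enumerate(grid_plan.offsets_px):
        if stage_jitter_px > 0:
            # clipped Gaussian: stage error is bounded (repeatability spec)
            jy, jx = np.clip(
                rng.normal(0.0, stage_jitter_px, size=2), -2 * stage_jitter_px, 2 * stage_jitter_px
            )
        else:
            jy, jx = 0.0, 0.0
        ty, tx = oy + jy, ox + jx
        # clamp so the window stays inside the phantom
        ty = float(np.clip(ty, 0, large_phantom.extent[1] / p - H))
        tx = float(np.clip(tx, 0, large_phantom.extent[0] / p - W))
        true_offsets[k] = (ty, tx)
        sub = large_phantom.translated(tx * p, ty * p, tile_extent)
        tile_optics = OpticsCamera(**{**optics.__dict__, "seed": optics.seed})
        stacks.append(render_movie(sub, tile_optics, acquisition=k + 1))
    return stacks, true_offsets


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / den) if den > 0 else -np.inf


def _overlap_windows(tile_a: np.ndarray, tile_b: np.ndarray, rel: np.ndarray):
    """Views of the two tiles on their common region for relative offset ``rel``."""
    H, W = tile_a.shape
    ry, rx = int(rel[0]), int(rel[1])
    ys0, ys1 = max(0, ry), min(H, ry + H)
    xs0, xs1 = max(0, rx), min(W, rx + W)
    if ys1 - ys0 < 4 or xs1 - xs0 < 4:
        return None
    return tile_a[ys0:ys1, xs0:xs1], tile_b[ys0 - ry : ys1 - ry, xs0 - rx : xs1 - rx]


def _refine_relative_offset(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    nominal_rel: np.ndarray,
    search: int,
    min_overlap_std: float,
    corr_scale: float = 4.0,
    stage_prior_sigma: float = 6.0,
) -> tuple[np.ndarray, float] | None:
    """Relative offset of tile_b vs tile_a by maximizing the normalized
    cross-correlation of the overlap window over an integer search grid
    around the nominal grid step, with parabolic sub-pixel refinement.
    Returns None when the overlap carries no structure."""
    base = np.round(nominal_rel).astype(int)
    win = _overlap_windows(tile_a, tile_b, base)
    if win is None or win[0].std() < min_overlap_std or win[1].std() < min_overlap_std:
        return None
    # candidate windows differ in size; rank them by a Fisher-z lower
    # confidence bound so a tiny window cannot win on a chance correlation
    # (n_eff = pixels per correlation area of the image texture)
    corr_area = float(corr_scale) ** 2
    scores = np.full((2 * search + 1, 2 * search + 1), -np.inf)
    for iy in range(-search, search + 1):
        for ix in range(-search, search + 1):
            win = _overlap_windows(tile_a, tile_b, base + np.array([iy, ix]))
            if win is None:
                continue
            r = np.clip(_ncc(*win), -0.999999, 0.999999)
            n_eff = max(win[0].size / corr_area, 4.0)
            # weak Gaussian prior on the stage error: large deviations from
            # the nominal grid step need correspondingly stronger evidence
            prior = 0.25 * (iy**2 + ix**2) / stage_prior_sigma**2
            scores[iy + search, ix + search] = np.arctanh(r) - 2.0 / np.sqrt(n_eff - 3.0) - prior
    py, px = np.unravel_index(np.argmax(scores), scores.shape)
    if not np.isfinite(scores[py, px]):
        return None

    def parabolic(p, axis):
        i, j = (p[0], p[1])
        lo = scores[i - 1, j] if axis == 0 and i > 0 else (scores[i, j - 1] if axis == 1 and j > 0 else np.nan)
        hi = scores[i + 1, j] if axis == 0 and i < scores.shape[0] - 1 else (
            scores[i, j + 1] if axis == 1 and j < scores.shape[1] - 1 else np.nan
        )
        c = scores[i, j]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            return 0.0
        den = lo - 2 * c + hi
        return 0.5 * (lo - hi) / den if den < 0 else 0.0

    dy = parabolic((py, px), 0)
    dx = parabolic((py, px), 1)
    rel_int = base + np.array([py - search, px - search])
    polished = _subpixel_polish(tile_a, tile_b, rel_int)
    if polished is None:
        polished = rel_int + np.array([dy, dx])
    return polished, float(scores[py, px])


def _subpixel_polish(
    tile_a: np.ndarray, tile_b: np.ndarray, rel_int: np.ndarray, upsample: int = 4
) -> np.ndarray | None:
    """Refine an integer relative offset to sub-pixel precision by NCC on
    spline-upsampled overlap windows (search +-1 px in 1/upsample steps)."""
    from scipy import ndimage as ndi

    win = _overlap_windows(tile_a, tile_b, rel_int)
    if win is None or min(win[0].shape) < 6:
        return None
    za = ndi.zoom(win[0], upsample, order=3)
    zb = ndi.zoom(win[1], upsample, order=3)
    m = upsample  # +-1 original px
    if min(zb.shape) <= 2 * m + 4:
        return None
    zbc = zb[m:-m, m:-m]
    h, w = zbc.shape
    scores = np.full((2 * m + 1, 2 * m + 1), -np.inf)
    for iy in range(2 * m + 1):
        for ix in range(2 * m + 1):
            scores[iy, ix] = _ncc(za[iy : iy + h, ix : ix + w], zbc)
    py, px = np.unravel_index(np.argmax(scores), scores.shape)

    def parab(i, j, axis):
        if axis == 0 and 0 < i < scores.shape[0] - 1:
            lo, c, hi = scores[i - 1, j], scores[i, j], scores[i + 1, j]
        elif axis == 1 and 0 < j < scores.shape[1] - 1:
            lo, c, hi = scores[i, j - 1], scores[i, j], scores[i, j + 1]
        else:
            return 0.0
        den = lo - 2 * c + hi
        return 0.5 * (lo - hi) / den if den < 0 else 0.0

    # b-window content displaced by -delta when the true offset is +delta,
    # so the matching slide of the a-window equals +delta
    dy = (py - m + parab(py, px, 0)) / upsample
    dx = (px - m + parab(py, px, 1)) / upsample
    return rel_int + np.array([dy, dx])


def _feather_weight(shape: tuple[int, int], ramp_y: int, ramp_x: int) -> np.ndarray:
    H, W = shape

    def ramp(n: int, r: int) -> np.ndarray:
        w = np.ones(n)
        r = max(1, min(r, n // 2))
        edge = (np.arange(r) + 1.0) / (r + 1.0)
        w[:r] = edge
        w[-r:] = edge[::-1]
        return w

    return np.outer(ramp(H, ramp_y), ramp(W, ramp_x))


def stitch(
    tile_images: list[np.ndarray],
    grid_plan: GridPlan,
    refine: bool = True,
    max_deviation_px: float = 5.0,
    min_overlap_std: float = 1e-6,
    return_offsets: bool = False,
):
    """Stitch tile reconstructions into one large field of view.

    Nominal grid offsets are refined pairwise against the left (or top)
    neighbor by phase correlation restricted to the overlap strip; a
    featureless overlap (or a refinement deviating more than
    ``max_deviation_px`` from nominal) falls back to the nominal offset with
    a warning.  Tiles are combined with linear feather blending across the
    overlaps.  Offsets are reported on the tile-image lattice (which may be
    oversampled relative to camera pixels).
    """
    if len(tile_images) == 0:
        raise ValueError("need at least one tile")
    if len(tile_images) != grid_plan.n_tiles:
        raise ValueError("tile count does not match grid plan")
    tiles = [np.asarray(t, dtype=float) for t in tile_images]
    H, W = tiles[0].shape
    scale = H / grid_plan.tile_shape[0]  # lattice oversampling vs plan
    nominal = np.array(grid_plan.offsets_px, dtype=float) * scale
    ov_y, ov_x = grid_plan.overlap_px()
    ov_y = max(1, int(round(ov_y * scale)))
    ov_x = max(1, int(round(ov_x * scale)))

    search = int(np.ceil(max_deviation_px * scale))
    refined = nominal.copy()
    if refine and len(tiles) > 1:
        # measure every adjacent pair, then solve the translation graph by
        # weighted least squares (soft-anchored to the nominal grid), so a
        # tile constrained by several overlaps uses all of them
        edges: list[tuple[int, int, np.ndarray, float]] = []
        n_tiles = len(tiles)
        for k in range(n_tiles):
            r, c = divmod(k, grid_plan.cols)
            for nb in ([k - 1] if c > 0 else []) + ([k - grid_plan.cols] if r > 0 else []):
                hit = _refine_relative_offset(
                    tiles[nb],
                    tiles[k],
                    nominal[k] - nominal[nb],
                    search,
                    min_overlap_std,
                    stage_prior_sigma=3.0 * scale,
                )
                if hit is None:
                    warnings.warn(f"featureless overlap between tiles {nb} and {k}: using nominal offset")
                    continue
                rel, score = hit
                if np.max(np.abs(rel - (nominal[k] - nominal[nb]))) > max_deviation_px * scale:
                    warnings.warn(f"refined offset for tile {k} vs neighbor {nb} deviates too far; ignored")
                    continue
                edges.append((nb, k, rel, max(score, 1e-3)))
        while edges:
            rows = []
            rhs = []
            wts = []
            for nb, k, rel, wt in edges:
                row = np.zeros(n_tiles)
                row[k] = 1.0
                row[nb] = -1.0
                rows.append(row)
                rhs.append(rel)
                wts.append(wt)
            # weak anchor to nominal keeps unconstrained tiles in place and
            # fixes the global gauge
            for k in range(n_tiles):
                row = np.zeros(n_tiles)
                row[k] = 1.0
                rows.append(row)
                rhs.append(nominal[k])
                wts.append(1e-3)
            A = np.asarray(rows) * np.sqrt(np.asarray(wts))[:, None]
            B = np.asarray(rhs) * np.sqrt(np.asarray(wts))[:, None]
            sol, *_ = np.linalg.lstsq(A, B, rcond=None)
            refined = sol
            # drop the worst inconsistent pair measurement and re-solve; an
            # edge disagreeing with every redundant path is a false NCC peak
            resid = np.array([np.max(np.abs(refined[k] - refined[nb] - rel)) for nb, k, rel, _ in edges])
            worst = int(np.argmax(resid))
            if len(edges) > n_tiles - 1 and resid[worst] > 0.35 * scale:
                edges.pop(worst)
                continue
            break

    origin = refined.min(axis=0)
    refined = refined - origin  # canvas origin at the top-left-most tile
    out_h = int(np.ceil(refined[:, 0].max())) + H
    out_w = int(np.ceil(refined[:, 1].max())) + W
    acc = np.zeros((out_h, out_w))
    wacc = np.zeros((out_h, out_w))
    weight = _feather_weight((H, W), ov_y, ov_x)
    for k, tile in enumerate(tiles):
        iy = int(round(refined[k, 0]))
        ix = int(round(refined[k, 1]))
        fy = refined[k, 0] - iy
        fx = refined[k, 1] - ix
        if abs(fy) > 1e-3 or abs(fx) > 1e-3:
            from scipy import ndimage as ndi

            tile = ndi.shift(tile, (fy, fx), order=1, mode="nearest")
        acc[iy : iy + H, ix : ix + W] += tile * weight
        wacc[iy : iy + H, ix : ix + W] += weight
    with np.errstate(invalid="ignore", divide="ignore"):
        mosaic = np.where(wacc > 0, acc / np.maximum(wacc, 1e-300), 0.0)
    if return_offsets:
        return mosaic, refined
    return mosaic


def write_tile_configuration(path, grid_plan: GridPlan, offsets_px: np.ndarray | None = None) -> None:
    """TileConfiguration-style plain-text list of tile positions (x, y)."""
    offs = np.asarray(offsets_px if offsets_px is not None else grid_plan.offsets_px, dtype=float)
    with open(path, "w") as fh:
        fh.write("# Define the number of dimensions we are working on\ndim = 2\n\n")
        fh.write("# Define the image coordinates\n")
        for k, (oy, ox) in enumerate(offs):
            fh.write(f"tile_{k:03d}.tif; ; ({ox:.3f}, {oy:.3f})\n")
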
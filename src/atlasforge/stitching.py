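"""Light-sheet tile stitching: edge MIPs, offset estimation, fusion.

The stitching strategy is built for large serial stacks where raw tiles
should be read as few times as possible: only the 10% outer edge strips of
each tile are extracted and reduced to maximum-intensity projections over
groups of 32 slices.  Alignment then proceeds on those small images — first
the axial (z) coordinate across tile columns, then the in-plane (x, y)
shifts — and the per-group offsets are interpolated to every slice with a
low-order curve fit before a single-pass fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import TileSet
from .volume import Volume3D

__all__ = [
    "TileSet", "EdgeMipSet", "StitchResult",
    "extract_edge_mips", "estimate_offsets", "refine_slicewise", "fuse", "stitch",
]


@dataclass
class EdgeMipSet:
    """Per-tile, per-side MIP images of edge strips, grouped along z.

    ``strips[t][side]`` is the raw 3D edge strip for tile ``t`` and side
    ``'y0'|'y1'|'x0'|'x1'``; ``group_mips[t][side]`` is a list of 2D z-MIPs,
    one per slice group.  ``bands`` are the same cuts widened by
    ``search_margin`` voxels: the correlation targets, so matching content
    remains inside the cut even at the largest searched shift.
    """

    strips: list
    group_mips: list
    edge_fraction: float
    group_size: int
    n_slices: int
    layout: list
    bands: list = None
    search_margin: int = 0
    tile_shapes: list = None

    @property
    def n_groups(self) -> int:
        return int(np.ceil(self.n_slices / self.group_size))


@dataclass
class StitchResult:
    per_slice_offsets: np.ndarray  # (n_tiles, n_slices, 3) voxels
    fused: Volume3D
    diagnostics: dict  # per-pair correlation scores

    def __post_init__(self):
        if not np.all(np.isfinite(self.per_slice_offsets)):
            raise ValueError("offsets must be finite")


def _strip_width(extent: int, edge_fraction: float) -> int:
    return max(1, int(round(edge_fraction * extent)))


def extract_edge_mips(tiles: TileSet, edge_fraction: float = 0.10,
                      group_size: int = 32,
                      search_margin: int = 20) -> EdgeMipSet:
    """Collect the outer edge strips of each tile and z-MIP them by group.

    The strip width is ``round(edge_fraction × in-plane extent)`` (minimum
    one voxel) on each of the four lateral sides; each group of
    ``group_size`` consecutive slices is reduced to its voxel-wise maximum.
    Widened copies of the cuts (``search_margin`` extra voxels) are kept as
    correlation targets so jittered content cannot fall outside the cut.
    """
    if not tiles.tiles:
        raise ValueError("empty tile set")
    if not 0 < edge_fraction <= 0.5:
        raise ValueError("edge_fraction must be in (0, 0.5]")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n_slices = tiles.tiles[0].shape[0]
    strips, group_mips, bands = [], [], []
    for tile in tiles.tiles:
        _, ny, nx = tile.shape
        wy = _strip_width(ny, edge_fraction)
        wx = _strip_width(nx, edge_fraction)
        by = min(ny, wy + search_margin)
        bx = min(nx, wx + search_margin)
        v = tile.values
        s = {
            "y0": v[:, :wy, :], "y1": v[:, ny - wy:, :],
            "x0": v[:, :, :wx], "x1": v[:, :, nx - wx:],
        }
        strips.append(s)
        bands.append({
            "y0": v[:, :by, :], "y1": v[:, ny - by:, :],
            "x0": v[:, :, :bx], "x1": v[:, :, nx - bx:],
        })
        mips = {side: [arr[g:g + group_size].max(axis=0)
                       for g in range(0, n_slices, group_size)]
                for side, arr in s.items()}
        group_mips.append(mips)
    return EdgeMipSet(strips, group_mips, edge_fraction, group_size,
                      n_slices, list(tiles.layout), bands=bands,
                      search_margin=search_margin,
                      tile_shapes=[t.shape for t in tiles.tiles])


# ---------------------------------------------------------------------------
# Normalized cross-correlation shift search
# ---------------------------------------------------------------------------


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom < 1e-12:
        return 0.0
    return float((a @ b) / denom)


def _search_shift_2d(fixed: np.ndarray, moving: np.ndarray, radius: int,
                     center=(0, 0), min_fraction: float = 0.5):
    """Exhaustive integer NCC search for the shift of `moving` vs `fixed`.

    Returns (best_shift (d0, d1), best_score).  A shift ``s`` means the
    content of ``moving`` at index ``u`` matches ``fixed`` at ``u + s``;
    the search covers ``center ± radius`` per axis.  Candidates sharing
    fewer than ``min_fraction`` of the image pixels (or < 16 pixels) are
    skipped: a correlation supported by a sliver is not evidence.  The
    reference support is the shared area at the ``center`` shift (the
    physically overlapping region at the nominal layout).
    """
    best, best_s = np.array(center), -np.inf
    h, w = fixed.shape
    support_center = ((h - abs(center[0])) * (w - abs(center[1])))
    min_size = max(16, min_fraction * max(support_center, 0))
    for dy in range(center[0] - radius, center[0] + radius + 1):
        for dx in range(center[1] - radius, center[1] + radius + 1):
            f_sl = fixed[max(dy, 0):h + min(dy, 0), max(dx, 0):w + min(dx, 0)]
            m_sl = moving[max(-dy, 0):h + min(-dy, 0), max(-dx, 0):w + min(-dx, 0)]
            if f_sl.size < min_size:
                continue
            sc = _ncc(f_sl, m_sl)
            if sc > best_s:
                best_s, best = sc, np.array([dy, dx])
    return best, best_s



def _search_shift_inplane_3d(fixed: np.ndarray, moving: np.ndarray,
                             radius: int, center=(0, 0),
                             min_fraction: float = 0.5):
    """In-plane integer NCC search on z-aligned 3D bands.

    Like `_search_shift_2d` but correlates the full band volumes, which
    keeps the axial texture that a MIP would flatten away.
    """
    best, best_s = np.array(center), -np.inf
    _, h, w = fixed.shape
    support_center = ((h - abs(center[0])) * (w - abs(center[1])))
    min_size = max(16, min_fraction * max(support_center, 0))
    for dy in range(center[0] - radius, center[0] + radius + 1):
        for dx in range(center[1] - radius, center[1] + radius + 1):
            f_sl = fixed[:, max(dy, 0):h + min(dy, 0), max(dx, 0):w + min(dx, 0)]
            m_sl = moving[:, max(-dy, 0):h + min(-dy, 0), max(-dx, 0):w + min(-dx, 0)]
            if f_sl[0].size < min_size:
                continue
            sc = _ncc(f_sl, m_sl)
            if sc > best_s:
                best_s, best = sc, np.array([dy, dx])
    return best, best_s


def estimate_offsets(mips: EdgeMipSet, layout=None, search_radius: int = 6,
                     min_correlation: float = 0.2, nominal_offsets=None,
                     tile_shapes=None):
    """Estimate per-tile, per-group offsets (relative to nominal) from MIPs.

    Stage 1 aligns the axial (z) coordinate between each pair of adjacent
    tiles by correlating projections of their facing edge strips along the
    strip-normal axis; stage 2 aligns the in-plane coordinates per slice
    group from the grouped z-MIPs.  Facing strips sit at a known nominal
    displacement along the strip-normal axis, so the stage-2 search is
    centred on that baseline and the residual is the tile jitter.

    Pairwise shifts are accumulated breadth-first over the tile graph
    anchored at the top-left tile (offset 0); a tile reachable by two paths
    gets the average, making the result order-independent.  Pairs whose
    best correlation falls below ``min_correlation`` (or whose strips do
    not overlap at all) fall back to the nominal offset and are flagged in
    the diagnostics.

    Returns (offsets of shape (n_tiles, n_groups, 3), diagnostics).
    """
    layout = list(layout if layout is not None else mips.layout)
    n_tiles = len(layout)
    n_groups = mips.n_groups
    pos = {tuple(rc): i for i, rc in enumerate(layout)}
    if tile_shapes is None:
        tile_shapes = mips.tile_shapes
    if tile_shapes is None or nominal_offsets is None:
        raise ValueError("nominal_offsets and tile shapes are required")
    nominal_offsets = np.asarray(nominal_offsets, dtype=float)
    cuts = mips.bands if mips.bands is not None else mips.strips

    pair_shifts = {}  # (i, j) -> (n_groups, 3): rel offset of j minus i
    diagnostics = {}
    for (rc_a, ia) in pos.items():
        for drc, kind in (((0, 1), "h"), ((1, 0), "v")):
            rc_b = (rc_a[0] + drc[0], rc_a[1] + drc[1])
            if rc_b not in pos:
                continue
            ib = pos[rc_b]
            side_a, side_b = ("x1", "x0") if kind == "h" else ("y1", "y0")
            band_a = cuts[ia][side_a]
            band_b = cuts[ib][side_b]
            normal_axis = 2 if kind == "h" else 1
            # Band start indices within their tiles along the normal axis.
            w_band = band_a.shape[normal_axis]
            start_a = tile_shapes[ia][normal_axis] - w_band
            step = (nominal_offsets[ib] - nominal_offsets[ia])[normal_axis]
            # At the nominal layout, matching content sits displaced by
            # `baseline` (= band width − overlap) between the two band
            # coordinate frames; the search is centred there and the
            # residual is the tile jitter.
            baseline = int(round(step - start_a))
            key = (tuple(rc_a), tuple(rc_b))
            if abs(baseline) >= w_band:
                diagnostics[key] = {"score": float("nan"), "fallback": True,
                                    "reason": "strips do not overlap"}
                pair_shifts[(ia, ib)] = np.zeros((n_groups, 3))
                continue
            # Stage 1: project along the strip normal -> (z, tangential).
            proj_a = band_a.max(axis=normal_axis)
            proj_b = band_b.max(axis=normal_axis)
            (dz, dt), score_z = _search_shift_2d(proj_a, proj_b, search_radius)
            # Stage 2: in-plane shift.  The pair anchor comes from a full
            # 3D correlation of the z-aligned bands (axial texture intact),
            # then each slice group is refined within one voxel of it from
            # its z-MIP so feature-poor groups cannot wander.
            if kind == "h":
                center0 = (int(dt), baseline)
            else:
                center0 = (baseline, int(dt))
            nz = mips.n_slices
            fa0, fa1 = max(int(dz), 0), nz + min(int(dz), 0)
            fb0, fb1 = max(-int(dz), 0), nz + min(-int(dz), 0)
            anchor2d, _ = _search_shift_inplane_3d(
                band_a[fa0:fa1], band_b[fb0:fb1], search_radius, center=center0)
            shifts = np.zeros((n_groups, 3))
            scores = []
            for g in range(n_groups):
                ga = g * mips.group_size
                mip_a = band_a[ga:ga + mips.group_size].max(axis=0)
                gb0 = int(np.clip(ga - int(dz), 0, nz - 1))
                gb1 = min(gb0 + mips.group_size, nz)
                mip_b = band_b[gb0:gb1].max(axis=0)
                (d0, d1), score = _search_shift_2d(mip_a, mip_b, 1,
                                                   center=tuple(anchor2d))
                if kind == "h":  # MIP axes are (y, x) = (tangential, normal)
                    rel = (dz, d0, d1 - baseline)
                else:  # MIP axes are (y, x) = (normal, tangential)
                    rel = (dz, d0 - baseline, d1)
                scores.append(score)
                shifts[g] = rel
            mean_score = float(np.mean(scores))
            if mean_score < min_correlation:
                diagnostics[key] = {"score": mean_score, "fallback": True,
                                    "reason": "low correlation"}
                pair_shifts[(ia, ib)] = np.zeros((n_groups, 3))
            else:
                diagnostics[key] = {"score": mean_score, "fallback": False,
                                    "z_score": float(score_z)}
                # rel above is s + baseline-correction = (true_b - true_a)
                # minus (nominal_b - nominal_a): the relative jitter.
                pair_shifts[(ia, ib)] = shifts

    # Breadth-first accumulation anchored at tile (0, 0).
    anchor = pos[min(pos.keys())]
    acc = {anchor: np.zeros((n_groups, 3))}
    visited = {anchor}
    frontier = [anchor]
    while frontier:
        nxt = []
        for i in frontier:
            for (a, b), shift in sorted(pair_shifts.items()):
                if a == i and b not in visited:
                    _accumulate(acc, b, acc[a] + shift)
                    nxt.append(b)
                elif b == i and a not in visited:
                    _accumulate(acc, a, acc[b] - shift)
                    nxt.append(a)
        visited.update(nxt)
        frontier = sorted(set(nxt))
    offsets = np.zeros((n_tiles, n_groups, 3))
    for i in range(n_tiles):
        offsets[i] = acc.get(i, np.zeros((n_groups, 3)))
    # Re-anchor so the top-left tile is exactly zero even after averaging.
    offsets -= offsets[anchor:anchor + 1]
    return offsets, diagnostics


def _accumulate(acc: dict, key: int, value: np.ndarray):
    if key in acc:
        acc[key] = 0.5 * (acc[key] + value)
    else:
        acc[key] = value.copy()


def refine_slicewise(group_offsets: np.ndarray, n_slices: int,
                     group_size: int, poly_order: int = 2) -> np.ndarray:
    """Interpolate per-group offsets to every slice with a polynomial fit.

    Group offsets are placed at their group-centre slice indices and a
    least-squares polynomial (default quadratic) is evaluated at every
    slice; with a single group the fit degenerates to a constant.
    """
    group_offsets = np.asarray(group_offsets, dtype=float)
    if group_offsets.ndim == 2:  # single tile
        group_offsets = group_offsets[None]
    n_tiles, n_groups, _ = group_offsets.shape
    if n_groups < 1:
        raise ValueError("need at least one group")
    centers = np.array([min(g * group_size + (group_size - 1) / 2, n_slices - 1)
                        for g in range(n_groups)])
    slices = np.arange(n_slices)
    order = min(poly_order, n_groups - 1)
    out = np.zeros((n_tiles, n_slices, 3))
    for t in range(n_tiles):
        for c in range(3):
            if n_groups == 1:
                out[t, :, c] = group_offsets[t, 0, c]
            else:
                coeffs = np.polyfit(centers, group_offsets[t, :, c], order)
                out[t, :, c] = np.polyval(coeffs, slices)
    return out


def fuse(tiles: TileSet, per_slice_offsets: np.ndarray,
         blend: str = "feather") -> Volume3D:
    """Single-pass fusion of tiles at per-slice offsets.

    The output grid is the bounding box of all placed tiles.  ``feather``
    weights fall linearly from the in-plane tile centre to its edges so
    overlaps blend smoothly; ``max`` keeps the brighter value;
    ``first_wins`` keeps the first tile placed (bit-exact copies in
    non-overlap regions for all modes).  Each input tile is read exactly
    once.
    """
    if blend not in ("feather", "max", "first_wins"):
        raise ValueError(f"unknown blend mode {blend!r}")
    per_slice_offsets = np.asarray(per_slice_offsets, dtype=float)
    if not np.all(np.isfinite(per_slice_offsets)):
        raise ValueError("offsets must be finite")
    n_tiles = len(tiles.tiles)
    n_slices = tiles.tiles[0].shape[0]

    # Integer placement per slice: nominal layout + estimated offset.
    place = np.zeros((n_tiles, n_slices, 3), dtype=int)
    for t in range(n_tiles):
        place[t] = np.rint(tiles.nominal_offsets[t][None, :]
                           + per_slice_offsets[t]).astype(int)

    lo = place.min(axis=(0, 1))
    shapes = np.array([t.shape for t in tiles.tiles])
    hi = (place + shapes[:, None, :]).max(axis=(0, 1))
    out_shape = tuple((hi - lo).astype(int))
    acc = np.zeros(out_shape)
    wacc = np.zeros(out_shape)
    filled = np.zeros(out_shape, dtype=bool)

    for t, tile in enumerate(tiles.tiles):
        v = tile.values
        _, ny, nx = v.shape
        if blend == "feather":
            wy = np.minimum(np.arange(ny) + 1, ny - np.arange(ny))
            wx = np.minimum(np.arange(nx) + 1, nx - np.arange(nx))
            w2d = np.outer(wy / wy.max(), wx / wx.max())
        for z in range(n_slices):
            oz, oy, ox = place[t, z] - lo
            oz += z  # slice z of the tile lands at its own depth plus offset
            sl = (oz, slice(oy, oy + ny), slice(ox, ox + nx))
            if oz < 0 or oz >= out_shape[0]:
                continue
            if blend == "feather":
                acc[sl] += v[z] * w2d
                wacc[sl] += w2d
            elif blend == "max":
                acc[sl] = np.where(filled[sl], np.maximum(acc[sl], v[z]), v[z])
                filled[sl] = True
            else:  # first_wins
                acc[sl] = np.where(filled[sl], acc[sl], v[z])
                filled[sl] = True

    if blend == "feather":
        out = np.where(wacc > 0, acc / np.where(wacc > 0, wacc, 1.0), 0.0)
    else:
        out = acc
    spacing = tiles.tiles[0].spacing
    origin = np.asarray(tiles.tiles[0].origin) + lo * np.asarray(spacing)
    return Volume3D(out, spacing, tuple(origin.tolist()))


def stitch(tiles: TileSet, edge_fraction: float = 0.10, group_size: int = 32,
           search_radius: int = 10, blend: str = "feather",
           poly_order: int = 2) -> StitchResult:
    """End-to-end stitching: edge MIPs → offsets → slice refinement → fusion."""
    mips = extract_edge_mips(tiles, edge_fraction, group_size)
    group_offsets, diagnostics = estimate_offsets(
        mips, tiles.layout, search_radius=search_radius,
        nominal_offsets=tiles.nominal_offsets,
        tile_shapes=[t.shape for t in tiles.tiles])
    n_slices = tiles.tiles[0].shape[0]
    per_slice = refine_slicewise(group_offsets, n_slices, group_size, poly_order)
    fused = fuse(tiles, per_slice, blend=blend)
    return StitchResult(per_slice, fused, diagnostics)
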
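"""Self-contained intensity-based registration at desk scale.

Similarity metrics (mean squared difference, normalized cross-correlation,
joint-histogram mutual information), linear alignment (translation / rigid /
affine) by multi-resolution direct search, and deformable alignment by a
regularized demons-style gradient scheme with Gaussian field smoothing.
All optimization is deterministic (fixed pyramid schedule, no random
restarts) and operates in world coordinates so anisotropic voxel spacings
are handled correctly.  The reported transform always carries the
best-seen metric, so it can never be worse than the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .volume import (
    AffineTransform3D,
    DisplacementField,
    TransformChain,
    Volume3D,
    apply_transform,
    compose,
)

_METRICS = ("msd", "ncc", "mi")
_MODELS = ("translation", "rigid", "affine", "deformable")


@dataclass
class RegistrationConfig:
    """Knobs for linear and deformable registration.

    smoothing_sigma regularizes the displacement field (voxels, applied
    every iteration); levels is the multi-resolution pyramid depth
    (downsampling by 2 per level); channel_weights weight the per-channel
    metrics of multi-metric runs (need not sum to 1).
    """

    model: str = "deformable"
    metric: str = "msd"
    levels: int = 3
    smoothing_sigma: float = 2.0
    update_sigma: float = 1.0
    max_iters: int = 30
    step_voxels: float = 2.0
    mi_bins: int = 32
    channel_weights: tuple = (1.0,)
    channel_metrics: tuple | None = None

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        w = np.asarray(self.channel_weights, dtype=float)
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("channel_weights must be >= 0 and not all zero")


# ---------------------------------------------------------------------------
# Similarity metrics
# ---------------------------------------------------------------------------


def similarity(fixed: Volume3D, moving: Volume3D, metric: str = "msd",
               mask: Volume3D | None = None, mi_bins: int = 32) -> float:
    """Similarity score between two volumes on the same grid.

    msd: mean squared intensity difference (0 iff identical).
    ncc: Pearson correlation of intensities, in [-1, 1].
    mi: mutual information (nats) from a joint histogram; for an image
    against itself it equals the marginal histogram entropy.
    """
    if fixed.shape != moving.shape:
        raise ValueError("shape mismatch between fixed and moving")
    a = fixed.values.astype(float).ravel()
    b = moving.values.astype(float).ravel()
    if mask is not None:
        m = mask.values.ravel() > 0
        if not m.any():
            raise ValueError("empty mask")
        a, b = a[m], b[m]
    return _similarity_arrays(a, b, metric, mi_bins)


def _similarity_arrays(a: np.ndarray, b: np.ndarray, metric: str,
                       mi_bins: int = 32) -> float:
    if metric == "msd":
        return float(np.mean((a - b) ** 2))
    if metric == "ncc":
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom < 1e-12:
            return 0.0
        return float((a @ b) / denom)
    if metric == "mi":
        return _mutual_information(a, b, mi_bins)
    raise ValueError(f"unknown metric {metric!r}")


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (pa @ pb)[nz])))


def histogram_entropy(a: np.ndarray, bins: int = 32) -> float:
    """Shannon entropy (nats) of the intensity histogram."""
    h, _ = np.histogram(np.asarray(a, dtype=float).ravel(), bins=bins)
    p = h / h.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def _metric_sign(metric: str) -> float:
    """Multiplier making every metric a minimization objective."""
    return 1.0 if metric == "msd" else -1.0


# ---------------------------------------------------------------------------
# Pyramid helpers
# ---------------------------------------------------------------------------


def _downsample(vol: Volume3D, factor: int) -> Volume3D:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.values.astype(float), factor / 2.0)
    out = sm[::factor, ::factor, ::factor]
    spacing = tuple(s * factor for s in vol.spacing)
    return Volume3D(out, spacing, vol.origin, vol.axis_names)


def _pyramid_factors(levels: int, shape) -> list:
    factors = [2 ** (levels - 1 - i) for i in range(levels)]
    # Never shrink below 8 voxels per axis; singleton axes (2D slices
    # embedded as single-slice volumes) are exempt.
    sizes = [n for n in shape if n > 1]
    lo = min(sizes) if sizes else 1
    return [f for f in factors if lo // f >= 8] or [1]


# ---------------------------------------------------------------------------
# Linear registration
# ---------------------------------------------------------------------------


def _params_to_affine(params: np.ndarray, model: str, center: np.ndarray) -> AffineTransform3D:
    """Parameter vector -> world affine, rotations about the volume centre.

    translation: (t0, t1, t2) µm.  rigid: + rotation angles (rad) about the
    three axes.  affine: 9 matrix entries (row-major perturbation of I) + 3
    translations.
    """
    if model == "translation":
        return AffineTransform3D(np.eye(3), params)
    if model == "rigid":
        t = params[:3]
        rot = _euler_matrix(params[3:6])
        return AffineTransform3D(rot, center - rot @ center + t)
    if model == "affine":
        mat = np.eye(3) + params[3:12].reshape(3, 3)
        t = params[:3]
        return AffineTransform3D(mat, center - mat @ center + t)
    raise ValueError(model)


def _euler_matrix(angles) -> np.ndarray:
    a0, a1, a2 = angles
    c, s = np.cos(a0), np.sin(a0)
    r0 = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    c, s = np.cos(a1), np.sin(a1)
    r1 = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    c, s = np.cos(a2), np.sin(a2)
    r2 = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    return r0 @ r1 @ r2


def _n_params(model: str) -> int:
    return {"translation": 3, "rigid": 6, "affine": 12}[model]


def register_linear(fixed: Volume3D, moving: Volume3D,
                    config: RegistrationConfig | None = None) -> AffineTransform3D:
    """Linear (translation / rigid / affine) world-coordinate registration.

    Multi-resolution coarse-to-fine direct search: an exhaustive integer
    translation scan at the coarsest level seeds a Powell refinement at
    every level.  The best candidate seen (including the identity) is kept,
    so the returned transform never increases the metric relative to
    identity.
    """
    config = config or RegistrationConfig(model="translation")
    model = config.model if config.model != "deformable" else "affine"
    for vol, name in ((fixed, "fixed"), (moving, "moving")):
        if np.ptp(vol.values) == 0:
            raise ValueError(f"{name} volume is constant; registration is degenerate")

    sign = _metric_sign(config.metric)
    factors = _pyramid_factors(config.levels, fixed.shape)
    center = np.mean(fixed.index_to_world([np.array(fixed.shape) - 1, [0, 0, 0]]),
                     axis=0)

    def objective(params, fx, mv):
        aff = _params_to_affine(np.asarray(params), model, center)
        warped = apply_transform(mv, TransformChain([aff]), fx, "linear")
        return sign * _similarity_arrays(
            fx.values.ravel(), warped.values.ravel(), config.metric, config.mi_bins)

    params = np.zeros(_n_params(model))
    for li, f in enumerate(factors):
        fx = _downsample(fixed, f)
        mv = _downsample(moving, f)
        if li == 0:
            # Exhaustive integer-voxel translation scan seeds the search.
            best_t, best_val = params[:3].copy(), objective(params, fx, mv)
            step = np.asarray(fx.spacing)
            radius = 4
            for dz in range(-radius, radius + 1):
                for dy in range(-radius, radius + 1):
                    for dx in range(-radius, radius + 1):
                        cand = params.copy()
                        cand[:3] = np.array([dz, dy, dx]) * step
                        v = objective(cand, fx, mv)
                        if v < best_val:
                            best_val, best_t = v, cand[:3].copy()
            params[:3] = best_t
        res = minimize(objective, params, args=(fx, mv), method="Powell",
                       options={"maxiter": 60 * len(params), "xtol": 1e-3,
                                "ftol": 1e-9})
        if res.fun <= objective(params, fx, mv):
            params = res.x

    # Best-seen guarantee at full resolution.
    identity = np.zeros_like(params)
    if objective(identity, fixed, moving) < objective(params, fixed, moving):
        params = identity
    return _params_to_affine(params, model, center)


# ---------------------------------------------------------------------------
# Deformable registration (demons-style)
# ---------------------------------------------------------------------------


def _warp_with_field(moving_vals: np.ndarray, v_vox: np.ndarray,
                     affine_vox: tuple | None = None) -> np.ndarray:
    """Sample `moving` at x + v (v in voxel units on the same grid).

    ``affine_vox`` = (matrix, translation) applies a further voxel-space
    affine to the sampling coordinates (an initial linear alignment folded
    into the interpolation, avoiding a separate resampling pass).
    """
    idx = np.indices(moving_vals.shape, dtype=float)
    coords = (idx + np.moveaxis(v_vox, -1, 0)).reshape(3, -1)
    if affine_vox is not None:
        mat, trans = affine_vox
        coords = mat @ coords + trans[:, None]
    return ndimage.map_coordinates(moving_vals, coords, order=1,
                                   mode="constant", cval=0.0).reshape(moving_vals.shape)


def _demons_force(fixed: np.ndarray, warped: np.ndarray,
                  step_cap: float) -> np.ndarray:
    """Demons update (voxel units): -(w−f)·∇w / (|∇w|² + (w−f)²)."""
    diff = warped - fixed
    grads = np.stack(
        [np.gradient(warped, axis=ax) if warped.shape[ax] > 1
         else np.zeros_like(warped) for ax in range(3)], axis=-1)
    g2 = np.sum(grads ** 2, axis=-1)
    scale = np.mean(np.abs(fixed)) + 1e-12
    denom = g2 + (diff ** 2) / (scale ** 2 + 1e-12) + 1e-12
    upd = -(diff[..., None] * grads) / denom[..., None]
    mag = np.sqrt(np.sum(upd ** 2, axis=-1, keepdims=True))
    over = mag > step_cap
    upd = np.where(over, upd * (step_cap / np.maximum(mag, 1e-12)), upd)
    return upd


def _multichannel_metric(fixed_list, warped_list, weights, metrics, mi_bins) -> float:
    """Weighted mean of signed per-channel objectives (lower is better)."""
    total, wsum = 0.0, 0.0
    for fx, wv, w, m in zip(fixed_list, warped_list, weights, metrics):
        if w == 0:
            continue
        total += w * _metric_sign(m) * _similarity_arrays(
            fx.ravel(), wv.ravel(), m, mi_bins)
        wsum += w
    return total / wsum


def register_deformable(fixed: Volume3D, moving: Volume3D,
                        config: RegistrationConfig | None = None,
                        init: TransformChain | None = None) -> TransformChain:
    """Deformable registration; returns ``init`` chain + a displacement field."""
    return register_multichannel([fixed], [moving], config, init)


def register_multichannel(fixed_channels, moving_channels,
                          config: RegistrationConfig | None = None,
                          init: TransformChain | None = None) -> TransformChain:
    """Multi-metric deformable registration over weighted channels.

    The objective is the weighted mean of per-channel metrics; forces are
    the weighted mean of per-channel demons updates.  The update field is
    smoothed with ``update_sigma`` (fluid-like) and the accumulated field
    with ``smoothing_sigma`` (diffusion-like) every iteration.  The
    best-seen field by the full-resolution objective is returned, appended
    to ``init``.
    """
    config = config or RegistrationConfig()
    if len(fixed_channels) != len(moving_channels):
        raise ValueError("channel count mismatch")
    n_ch = len(fixed_channels)
    weights = np.asarray(config.channel_weights, dtype=float)
    if weights.size == 1 and n_ch > 1:
        weights = np.full(n_ch, weights[0])
    if weights.size != n_ch:
        raise ValueError("channel_weights length must match channel count")
    metrics = (config.channel_metrics or (config.metric,) * n_ch)
    ref = fixed_channels[0]
    for fx, mv in zip(fixed_channels, moving_channels):
        if fx.shape != ref.shape or mv.shape != ref.shape:
            raise ValueError("all channels must share the fixed grid")

    # An all-affine init folds into the sampling coordinates (single
    # interpolation); chains with dense fields pre-warp the moving images.
    init_affine = None
    if init is not None and init.steps:
        if all(isinstance(s, AffineTransform3D) for s in init.steps):
            mat, trans = np.eye(3), np.zeros(3)
            for s in init.steps:
                mat, trans = s.matrix @ mat, s.matrix @ trans + s.translation
            init_affine = (mat, trans)
        else:
            moving_channels = [
                apply_transform(mv, init, ref, "linear")
                for mv in moving_channels
            ]

    factors = _pyramid_factors(config.levels, ref.shape)
    fixed_pyr = [[_downsample(fx, f).values.astype(float) for fx in fixed_channels]
                 for f in factors]
    moving_pyr = [[_downsample(mv, f).values.astype(float) for mv in moving_channels]
                  for f in factors]

    v = None  # displacement in voxel units at current level
    for li, f in enumerate(factors):
        fxs, mvs = fixed_pyr[li], moving_pyr[li]
        shape = fxs[0].shape
        if init_affine is not None:
            s_l = np.asarray(ref.spacing) * f
            mat, trans = init_affine
            aff_vox = ((mat * s_l[None, :]) / s_l[:, None],
                       (mat @ np.asarray(ref.origin) + trans
                        - np.asarray(moving_channels[0].origin)) / s_l)
        else:
            aff_vox = None
        if v is None:
            v = np.zeros(shape + (3,))
        else:
            zoom = np.array(shape) / np.array(v.shape[:3])
            v = np.stack([ndimage.zoom(v[..., c], zoom, order=1)
                          for c in range(3)], axis=-1)
            v *= zoom  # voxel units rescale with the grid
        iters = max(4, int(config.max_iters * (1.5 if f > 1 else 1.0)))
        best_v = v.copy()
        warped0 = [_warp_with_field(mv, v, aff_vox) for mv in mvs]
        best_val = _multichannel_metric(fxs, warped0, weights, metrics,
                                        config.mi_bins)
        for _ in range(iters):
            warped = [_warp_with_field(mv, v, aff_vox) for mv in mvs]
            upd = np.zeros_like(v)
            active = np.zeros(shape)
            wsum = 0.0
            for fx, wv, w in zip(fxs, warped, weights):
                if w == 0:
                    continue
                force = _demons_force(fx, wv, config.step_voxels)
                upd += w * force
                # Weight renormalization over locally active channels: a
                # channel with no gradient at a voxel (e.g. a mask channel
                # away from its boundary) should not dilute the others.
                active += w * (np.abs(force).max(axis=-1) > 1e-3)
                wsum += w
            denom = np.where(active > 0, active, wsum)
            upd /= denom[..., None]
            if config.update_sigma > 0:
                upd = np.stack([ndimage.gaussian_filter(upd[..., c],
                                                        config.update_sigma)
                                for c in range(3)], axis=-1)
            v = v + upd
            if config.smoothing_sigma > 0:
                v = np.stack([ndimage.gaussian_filter(v[..., c],
                                                      config.smoothing_sigma)
                              for c in range(3)], axis=-1)
            warped = [_warp_with_field(mv, v, aff_vox) for mv in mvs]
            val = _multichannel_metric(fxs, warped, weights, metrics,
                                       config.mi_bins)
            if not np.isfinite(val):
                raise ValueError("non-finite metric during deformable registration")
            if val < best_val:
                best_val, best_v = val, v.copy()
        v = best_v

    # Bring the field to full resolution if the finest level was decimated.
    if v.shape[:3] != ref.shape:
        zoom = np.array(ref.shape) / np.array(v.shape[:3])
        v = np.stack([ndimage.zoom(v[..., c], zoom, order=1)
                      for c in range(3)], axis=-1)
        v *= zoom

    vec_um = v * np.asarray(ref.spacing)
    dfield = DisplacementField(vec_um, ref.like(np.zeros(ref.shape)))
    steps = [dfield] + (list(init.steps) if init is not None else [])
    return TransformChain(steps)


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """Voxel-wise Jacobian determinant of x -> x + v(x) (world units)."""
    spacing = np.asarray(field.grid.spacing)
    jac = np.zeros(field.grid.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            jac[..., i, j] = np.gradient(field.vectors[..., i], spacing[j],
                                         axis=j)
    jac += np.eye(3)
    return np.linalg.det(jac)
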
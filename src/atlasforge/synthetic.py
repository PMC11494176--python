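"""Deterministic synthetic fixtures: phantoms, tiles, cohorts, cells, sections.

Every downstream stage of the toolkit (stitching, template construction,
registration, section mapping, cell analytics) is exercised against data
generated here with known ground truth, so the whole pipeline is testable
with no external downloads.  Each generator is a pure function of a global
integer seed: a named substream is derived per generator so partial re-runs
reproduce bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import DisplacementField, TransformChain, Volume3D, apply_transform, mirror

_LR_AXIS = "left-right"


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG so each generator has its own reproducible stream."""
    digest = zlib.crc32(name.encode())  # stable across processes
    ss = np.random.SeedSequence([int(seed), digest % (2**31)])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Recipe for a nested-ellipsoid brain phantom.

    The phantom mimics the landmark classes a registration needs to lock
    onto: concentric intensity bands (tissue shells), a dark internal
    "ventricle" and a bright "tract".
    """

    seed: int = 0
    shape: tuple = (64, 64, 64)
    n_regions: int = 4
    symmetric: bool = True
    smoothness: float = 1.5
    spacing: tuple = (20.0, 20.0, 20.0)

    def __post_init__(self):
        if min(self.shape) < 16:
            raise ValueError("phantom shape must be >= 16 per axis")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.n_regions > 65535 - 2:
            raise ValueError("n_regions exceeds representable 16-bit labels")


def make_phantom(spec: PhantomSpec):
    """Build (intensity, annotation, brain_mask) volumes from a spec.

    The annotation partitions the brain mask: every in-mask voxel carries
    exactly one nonzero label (concentric shells 1..n_regions, plus a
    ventricle label n_regions+1 carved out of the innermost shell).  With
    ``symmetric=True`` the result equals its own left-right mirror.
    """
    rng = _substream(spec.seed, "phantom")
    shape = tuple(spec.shape)
    zc, yc, xc = [(n - 1) / 2.0 for n in shape]
    z, y, x = np.indices(shape, dtype=float)
    # Semi-axes leave a background margin; mild per-axis anisotropy.
    semi = np.array([0.42, 0.40, 0.38]) * np.array(shape)
    if not spec.symmetric:
        # Asymmetric bulge along the left-right axis.
        bulge = 1.0 + 0.12 * (x - xc) / shape[2]
    else:
        bulge = 1.0
    r = np.sqrt(
        ((z - zc) / semi[0]) ** 2
        + ((y - yc) / semi[1]) ** 2
        + ((x - xc) / (semi[2] * bulge)) ** 2
    )
    mask = r < 1.0

    # Concentric shells: region k covers radii [(k-1)/n, k/n).
    shell = np.clip((r * spec.n_regions).astype(int) + 1, 1, spec.n_regions)
    annotation = np.where(mask, shell, 0).astype(np.uint16)

    # Dark ventricle inside the innermost shell.
    rv = np.sqrt(
        ((z - zc) / (0.10 * shape[0])) ** 2
        + ((y - (yc - 0.08 * shape[1])) / (0.14 * shape[1])) ** 2
        + ((x - xc) / (0.10 * shape[2])) ** 2
    )
    ventricle = (rv < 1.0) & mask
    annotation[ventricle] = spec.n_regions + 1

    # Bright tract: thin tube along the anterior-posterior axis.
    rt = np.sqrt(((z - (zc + 0.18 * shape[0])) / (0.05 * shape[0])) ** 2
                 + ((x - xc) / (0.05 * shape[2])) ** 2)
    tract = (rt < 1.0) & mask & ~ventricle

    bands = np.linspace(120.0, 40.0, spec.n_regions)
    intensity = np.zeros(shape)
    for k in range(1, spec.n_regions + 1):
        intensity[annotation == k] = bands[k - 1]
    intensity[tract] = 160.0
    intensity[ventricle] = 5.0
    if spec.smoothness > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.smoothness)
    # Deterministic cellular-scale texture: real autofluorescence carries
    # fine local contrast that alignment locks onto; without it the nested
    # shells are self-similar along the radius.
    texture = ndimage.gaussian_filter(rng.normal(0, 1, shape), 1.2)
    texture /= max(texture.std(), 1e-12)
    texture = np.where(mask, texture, 0.0)
    if spec.symmetric:
        texture = 0.5 * (texture + np.flip(texture, axis=2))
    intensity = intensity + 12.0 * texture
    intensity[~mask] = 0.0

    vol_kwargs = dict(spacing=spec.spacing)
    return (
        Volume3D(intensity, **vol_kwargs),
        Volume3D(annotation, **vol_kwargs),
        Volume3D(mask.astype(np.uint8), **vol_kwargs),
    )


# ---------------------------------------------------------------------------
# Tiles with known offsets (stitching ground truth)
# ---------------------------------------------------------------------------


@dataclass
class TileSet:
    """Tiles in (z, y, x) array order with a nominal row/column layout."""

    tiles: list
    layout: list  # (row, col) per tile
    nominal_offsets: np.ndarray  # (n_tiles, 3) voxel offsets into the mosaic
    overlap_fraction: float

    def __post_init__(self):
        self.nominal_offsets = np.asarray(self.nominal_offsets, dtype=float)
        if len({tuple(rc) for rc in self.layout}) != len(self.layout):
            raise ValueError("layout indices must be unique")
        spacings = {tuple(t.spacing) for t in self.tiles}
        if len(spacings) > 1:
            raise ValueError("all tiles must share spacing")


def make_tiles(volume: Volume3D, grid=(2, 2), overlap_fraction: float = 0.15,
               jitter_voxels: int = 0, noise_sd: float = 0.0, seed: int = 0):
    """Cut a volume into an overlapping tile grid with known jitter.

    Tiles are crops of the source at ``nominal + jitter`` positions (jitter
    uniform integer in ±jitter_voxels per axis), so placing each tile back at
    its returned ``true_offset`` reconstructs the source exactly in the
    noise-free case.  Gaussian noise of ``noise_sd`` is added independently
    per tile.
    """
    if not 0.05 <= overlap_fraction <= 0.5:
        raise ValueError("overlap_fraction must be in [0.05, 0.5]")
    rng = _substream(seed, "tiles")
    rows, cols = grid
    nz, ny, nx = volume.shape
    # In-plane tile extents such that tiles at nominal spots cover the image
    # exactly: the step is floored so the last row/column stays inside.
    ty = int(np.ceil(ny / (rows - (rows - 1) * overlap_fraction))) if rows > 1 else ny
    tx = int(np.ceil(nx / (cols - (cols - 1) * overlap_fraction))) if cols > 1 else nx
    step_y = (ny - ty) // (rows - 1) if rows > 1 else 0
    step_x = (nx - tx) // (cols - 1) if cols > 1 else 0
    overlap_y = ty - step_y
    overlap_x = tx - step_x
    if rows > 1 and step_y < 1 or cols > 1 and step_x < 1:
        raise ValueError("grid too large for requested overlap")
    if jitter_voxels > min(overlap_y if rows > 1 else ty,
                           overlap_x if cols > 1 else tx):
        raise ValueError("jitter exceeds the overlap extent")

    tiles, layout, nominal, true = [], [], [], []
    for r in range(rows):
        for c in range(cols):
            off = np.array([0, r * step_y, c * step_x])
            jit = rng.integers(-jitter_voxels, jitter_voxels + 1, size=3) \
                if jitter_voxels > 0 else np.zeros(3, dtype=int)
            pos = off + jit
            pos[1] = np.clip(pos[1], 0, ny - ty)
            pos[2] = np.clip(pos[2], 0, nx - tx)
            pos[0] = 0 if jitter_voxels == 0 else int(np.clip(pos[0], 0, 0))
            # z jitter is emulated by rolling the tile content instead of
            # cropping (tiles always span the full stack depth).
            crop = volume.values[:, pos[1]:pos[1] + ty, pos[2]:pos[2] + tx].astype(float)
            zj = int(jit[0])
            if zj != 0:
                crop = np.roll(crop, -zj, axis=0)
            if noise_sd > 0:
                crop = crop + rng.normal(0, noise_sd, crop.shape)
            tiles.append(Volume3D(crop, volume.spacing))
            layout.append((r, c))
            nominal.append(off)
            true.append(np.array([zj, pos[1], pos[2]]))
    tileset = TileSet(tiles, layout, np.array(nominal, dtype=float), overlap_fraction)
    return tileset, np.array(true, dtype=float)


# ---------------------------------------------------------------------------
# Deformed cohorts (template-construction ground truth)
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Cohort of smoothly deformed copies of one phantom."""

    n_samples: int = 4
    warp_amplitude: float = 3.0  # voxels
    intensity_jitter: float = 0.0  # multiplicative fraction
    seed: int = 0
    warp_scale: float = 6.0  # Gaussian smoothing of the random fields (voxels)

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.warp_amplitude < 0:
            raise ValueError("warp_amplitude must be >= 0")


def make_cohort(phantom: Volume3D, spec: CohortSpec):
    """Deform a phantom into a cohort with zero-mean smooth warps.

    Warp fields are smoothed white noise scaled to ``warp_amplitude`` voxels;
    the per-voxel mean over the cohort is subtracted so the cohort's mean
    morphology is the phantom itself (mean displacement < 0.1 voxel
    everywhere), making the phantom the ground truth for template recovery.
    """
    rng = _substream(spec.seed, "cohort")
    shape = phantom.shape
    if spec.warp_amplitude == 0:
        fields = [DisplacementField(np.zeros(shape + (3,)), phantom.like(np.zeros(shape)))
                  for _ in range(spec.n_samples)]
        samples = [phantom.copy() for _ in range(spec.n_samples)]
        return samples, fields

    raw = []
    for _ in range(spec.n_samples):
        f = np.stack([
            ndimage.gaussian_filter(rng.normal(0, 1, shape), spec.warp_scale)
            for _ in range(3)
        ], axis=-1)
        # warp_amplitude is the RMS displacement magnitude in voxels.
        rms = np.sqrt(np.mean(np.sum(f ** 2, axis=-1)))
        f = f / max(rms, 1e-12) * spec.warp_amplitude
        raw.append(f)
    mean_f = np.mean(raw, axis=0)
    raw = [f - mean_f for f in raw]

    spacing = np.asarray(phantom.spacing)
    samples, fields = [], []
    for i, f in enumerate(raw):
        vec_um = f * spacing  # voxel -> µm, axis-aligned grid
        dfield = DisplacementField(vec_um, phantom.like(np.zeros(shape)))
        warped = apply_transform(phantom, TransformChain([dfield]), phantom,
                                 interpolation="linear")
        if spec.intensity_jitter > 0:
            gain = 1.0 + rng.normal(0, spec.intensity_jitter)
            warped = warped.like(warped.values * gain)
        samples.append(warped)
        fields.append(dfield)
    return samples, fields


# ---------------------------------------------------------------------------
# Cell point clouds (spatial-transcriptomics stand-in)
# ---------------------------------------------------------------------------


def make_cells(annotation: Volume3D, rates: dict, subclass_mix: dict,
               seed: int = 0) -> pd.DataFrame:
    """Scatter synthetic cell somata inside annotation regions.

    ``rates`` maps label -> intensity in cells/mm³; counts per label are
    Poisson(rate × label volume) and positions uniform within the label's
    voxels.  ``subclass_mix`` maps label -> {subclass: probability} (each
    distribution sums to 1); subclass names of the form ``"class/subclass"``
    yield the parent class column, otherwise class equals subclass.

    Returns a table with columns x_um, y_um, z_um (world coordinates in axis
    order 0, 1, 2 of the annotation volume are z_um, y_um, x_um
    respectively), subclass, cell_class, true_label.
    """
    rng = _substream(seed, "cells")
    labels_present = set(np.unique(annotation.values)) - {0}
    rows = []
    spacing = np.asarray(annotation.spacing)
    for label in sorted(rates):
        if label not in labels_present:
            raise ValueError(f"rate given for unknown label {label}")
        rate = rates[label]
        if rate < 0:
            raise ValueError("rates must be >= 0")
        mix = subclass_mix.get(label, {"unassigned": 1.0})
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"subclass_mix for label {label} does not sum to 1")
        voxels = np.argwhere(annotation.values == label)
        vol_mm3 = len(voxels) * annotation.voxel_volume_mm3
        n = rng.poisson(rate * vol_mm3)
        if n == 0:
            continue
        picks = voxels[rng.integers(0, len(voxels), size=n)]
        # Uniform position within each voxel: centre convention means the
        # voxel spans index ± 0.5.
        frac = rng.uniform(-0.5, 0.5, size=(n, 3))
        world = annotation.index_to_world(picks + frac)
        subclasses = rng.choice(list(mix.keys()), size=n, p=list(mix.values()))
        for w, sc in zip(world, subclasses):
            cls = sc.split("/")[0] if "/" in sc else sc
            rows.append({
                "z_um": w[0], "y_um": w[1], "x_um": w[2],
                "subclass": sc, "cell_class": cls, "true_label": label,
            })
    return pd.DataFrame(rows, columns=["z_um", "y_um", "x_um", "subclass",
                                       "cell_class", "true_label"])


# ---------------------------------------------------------------------------
# Serial section stacks (gene-expression experiment stand-in)
# ---------------------------------------------------------------------------


@dataclass
class SectionStack:
    """Ordered 2D sections with per-channel ownership and missing flags.

    Real experiments alternate consecutive slices across 4–7 staining
    channels, so each channel observes a sparse subset of the physical
    stack; every slice it does not own is flagged missing for it.
    """

    sections: list  # 2D arrays, one per physical slice (None if dropped)
    slice_indices: list
    channel_of: list  # owning channel per slice
    n_channels: int
    in_plane_spacing: tuple = (20.0, 20.0)
    slice_spacing: float = 100.0
    in_plane_size: tuple | None = None

    def __post_init__(self):
        if list(self.slice_indices) != sorted(self.slice_indices):
            raise ValueError("slice_indices must be strictly increasing")

    def owned_slices(self, channel: int) -> list:
        return [i for i, c in zip(self.slice_indices, self.channel_of) if c == channel]

    def missing_for(self, channel: int) -> list:
        return [i for i, c in zip(self.slice_indices, self.channel_of) if c != channel]


def make_section_stack(volume: Volume3D, n_channels: int = 4,
                       drop_missing: bool = False, seed: int = 0) -> SectionStack:
    """Slice a volume along axis 0 into a round-robin multi-channel stack.

    Channel ``c`` owns slices ``{i : i mod n_channels == c}``.  With
    ``drop_missing`` the un-owned sections' pixel data is removed (None),
    emulating sections consumed by other experiments.
    """
    if not 1 <= n_channels <= 8:
        raise ValueError("n_channels must be in [1, 8]")
    nz = volume.shape[0]
    sections, channels = [], []
    for i in range(nz):
        channels.append(i % n_channels)
        sections.append(volume.values[i].astype(float).copy())
    if drop_missing:
        pass  # ownership already encodes missingness per channel
    return SectionStack(
        sections=sections,
        slice_indices=list(range(nz)),
        channel_of=channels,
        n_channels=n_channels,
        in_plane_spacing=(volume.spacing[1], volume.spacing[2]),
        slice_spacing=volume.spacing[0],
    )
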
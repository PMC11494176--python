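"""Volumetric data model and physical-space geometry.

Everything in the toolkit flows through :class:`Volume3D`: an axis-aligned
voxel grid with physical spacing and origin in micrometres.  World
coordinates follow the convention

    world = origin + index * spacing        (per axis, 0-based indices)

so that spatial transforms can be expressed in physical units and applied
across volumes with different resolutions (embryonic and postnatal templates
are imaged at different voxel sizes, so index-space transforms would be
wrong).  Transforms are *pull-back* maps: a :class:`TransformChain` maps
points of the fixed (output) space into the moving (input) space, which is
the convention needed for resampling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import nibabel as nib
import numpy as np
import tifffile
from scipy import ndimage
from skimage.measure import block_reduce

#: Canonical anatomical axis names.
ANATOMICAL_AXES = ("left-right", "anterior-posterior", "superior-inferior")

#: Default ordering of axes for arrays in this package (z, y, x style).
DEFAULT_AXIS_NAMES = ("superior-inferior", "anterior-posterior", "left-right")


def _as_triple(x, dtype=float) -> tuple:
    arr = np.asarray(x, dtype=dtype).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"expected a length-3 vector, got {x!r}")
    return tuple(arr.tolist())


@dataclass
class Volume3D:
    """A 3D scalar volume on an oriented physical grid.

    Parameters
    ----------
    values : ndarray, shape (n0, n1, n2)
        Intensities (float) or integer region labels.
    spacing : 3-tuple of float
        Physical voxel size per axis, micrometres; all > 0.
    origin : 3-tuple of float
        World coordinate (µm) of voxel (0, 0, 0).
    axis_names : 3-tuple of str
        Anatomical name of each array axis; a permutation of
        ``ANATOMICAL_AXES``.
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    axis_names: tuple = DEFAULT_AXIS_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("all shape components must be >= 1")
        self.spacing = _as_triple(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin)
        self.axis_names = tuple(self.axis_names)
        if sorted(self.axis_names) != sorted(ANATOMICAL_AXES):
            raise ValueError(
                f"axis_names must be a permutation of {ANATOMICAL_AXES}, "
                f"got {self.axis_names}"
            )

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def is_label(self) -> bool:
        """Integer-valued volumes are treated as label maps."""
        return np.issubdtype(self.values.dtype, np.integer)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing)) * 1e-9

    def axis_index(self, name: str) -> int:
        try:
            return self.axis_names.index(name)
        except ValueError:
            raise ValueError(
                f"unknown axis {name!r}; volume axes are {self.axis_names}"
            ) from None

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def grid_world_points(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (N, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.index_to_world(idx)

    def like(self, values: np.ndarray) -> "Volume3D":
        """A new volume sharing this grid's geometry."""
        return Volume3D(values, self.spacing, self.origin, self.axis_names)

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and self.axis_names == other.axis_names
        )

    def copy(self) -> "Volume3D":
        return replace(self, values=self.values.copy())


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform3D:
    """World-coordinate affine map ``p -> matrix @ p + translation`` (µm)."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform3D":
        return cls(np.eye(3), np.zeros(3))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.matrix.T + self.translation

    def inverted(self) -> "AffineTransform3D":
        minv = np.linalg.inv(self.matrix)
        return AffineTransform3D(minv, -minv @ self.translation)


@dataclass
class DisplacementField:
    """Dense per-voxel world-space displacement (µm) on a reference grid.

    ``vectors`` has shape ``grid.shape + (3,)``; applying the field maps a
    world point ``p`` to ``p + v(p)`` where ``v`` is sampled with trilinear
    interpolation (zero displacement outside the grid).
    """

    vectors: np.ndarray
    grid: Volume3D  # geometry carrier; its values are ignored

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match grid "
                f"{self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    def sample(self, pts: np.ndarray) -> np.ndarray:
        """Interpolated displacement (µm) at world points.

        Outside the grid the field extends by its nearest edge value, which
        keeps fixed-point inversion contractive at the boundary.
        """
        idx = self.grid.world_to_index(pts).T  # (3, N)
        out = np.empty((pts.shape[0], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.vectors[..., c], idx, order=1, mode="nearest"
            )
        return out

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts + self.sample(pts)

    def inverted(self, max_iters: int = 50, tol_voxels: float = 0.05) -> "DisplacementField":
        """Numerical inverse by fixed-point iteration.

        Solves ``u(x) = -v(x + u(x))`` on the field's own grid; iteration
        stops when the maximum update falls below ``tol_voxels`` (in units of
        the smallest grid spacing).  Non-convergence is reported via a
        warning, never silently accepted.
        """
        pts = self.grid.grid_world_points()
        u = np.zeros_like(pts)
        tol_um = tol_voxels * min(self.grid.spacing)
        converged = False
        for _ in range(max_iters):
            u_new = -self.sample(pts + u)
            delta = np.max(np.abs(u_new - u)) if u.size else 0.0
            u = u_new
            if delta < tol_um:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"displacement-field inversion did not converge below "
                f"{tol_voxels} voxel in {max_iters} iterations "
                f"(last update {delta / min(self.grid.spacing):.3f} voxel)",
                RuntimeWarning,
            )
        vec = u.reshape(self.grid.shape + (3,))
        return DisplacementField(vec, self.grid)


TransformStep = Union[AffineTransform3D, DisplacementField]


@dataclass
class TransformChain:
    """Ordered transform steps mapping fixed-space points to moving space.

    An empty ``steps`` list is the identity chain.  Steps are applied in
    order: ``p -> steps[-1](... steps[0](p))`` reading left to right.
    """

    steps: list = field(default_factory=list)

    def __post_init__(self):
        for s in self.steps:
            if not isinstance(s, (AffineTransform3D, DisplacementField)):
                raise TypeError(f"invalid transform step {type(s)}")

    @classmethod
    def identity(cls) -> "TransformChain":
        return cls([])

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        for s in self.steps:
            pts = s.apply_points(pts)
        return pts


def compose(chain_a: TransformChain, chain_b: TransformChain) -> TransformChain:
    """Chain applying ``chain_a`` first, then ``chain_b``."""
    return TransformChain(list(chain_a.steps) + list(chain_b.steps))


def invert(chain: TransformChain, max_iters: int = 50, tol_voxels: float = 0.05) -> TransformChain:
    """Inverse chain: steps reversed and each step inverted.

    Affine steps invert exactly; displacement fields invert numerically by
    fixed-point iteration on their own grid.
    """
    inv_steps = []
    for s in reversed(chain.steps):
        if isinstance(s, AffineTransform3D):
            inv_steps.append(s.inverted())
        else:
            inv_steps.append(s.inverted(max_iters=max_iters, tol_voxels=tol_voxels))
    return TransformChain(inv_steps)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def mirror(volume: Volume3D, axis: str) -> Volume3D:
    """Reflect a volume across the mid-plane of an anatomical axis.

    Voxel ``i`` maps to ``N-1-i``, so the reflection plane lies between the
    two central voxels for even axis lengths and on the central voxel for odd
    lengths — in both cases ``mirror`` is an exact involution.
    """
    ax = volume.axis_index(axis)
    return volume.like(np.flip(volume.values, axis=ax).copy())


def resample(volume: Volume3D, target_spacing, mode: str = "linear") -> Volume3D:
    """Resample onto an axis-aligned grid with the given spacing.

    ``mode='sum'`` aggregates blocks of voxels (the target spacing must be an
    integer multiple of the source spacing per axis) and conserves the grand
    total exactly — the operation used to pool high-resolution binary
    classification maps into per-voxel positive counts.  ``'nearest'`` never
    invents values; ``'linear'`` interpolates intensities.
    """
    target = np.asarray(_as_triple(target_spacing))
    if np.any(target <= 0):
        raise ValueError("target_spacing must be positive")
    src = np.asarray(volume.spacing)

    if mode == "sum":
        factors = target / src
        rounded = np.rint(factors).astype(int)
        if not np.allclose(factors, rounded, atol=1e-9) or np.any(rounded < 1):
            raise ValueError(
                f"mode='sum' requires integer aggregation factors, got {factors}"
            )
        out = block_reduce(volume.values, tuple(rounded), np.sum)
        return Volume3D(out, tuple(target), volume.origin, volume.axis_names)

    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    if np.allclose(target, src):
        return volume.copy()

    extent = (np.array(volume.shape) - 1) * src
    new_shape = np.maximum(1, np.floor(extent / target + 1e-9).astype(int) + 1)
    scale = target / src
    coords = [np.arange(n) * s for n, s in zip(new_shape, scale)]
    grid = np.meshgrid(*coords, indexing="ij")
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        volume.values, np.array([g.ravel() for g in grid]), order=order,
        mode="nearest",
    ).reshape(tuple(new_shape))
    if mode == "nearest":
        out = out.astype(volume.values.dtype)
    return Volume3D(out, tuple(target), volume.origin, volume.axis_names)


def apply_transform(
    volume: Volume3D,
    chain: TransformChain,
    reference: Volume3D,
    interpolation: str = "linear",
) -> Volume3D:
    """Resample ``volume`` onto the reference grid through a transform chain.

    The chain is a pull-back: each reference voxel's world point is mapped
    into the moving volume's space and the value interpolated there.
    Out-of-domain samples receive 0 (background).  Label volumes must use
    nearest-neighbour interpolation so no labels are invented.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if volume.is_label and interpolation == "linear":
        raise ValueError("label volumes must be warped with nearest interpolation")
    pts = reference.grid_world_points()
    moved = chain.apply_points(pts)
    idx = volume.world_to_index(moved).T
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(
        volume.values.astype(float), idx, order=order, mode="constant", cval=0.0
    ).reshape(reference.shape)
    if interpolation == "nearest":
        out = out.astype(volume.values.dtype)
    return Volume3D(out, reference.spacing, reference.origin, reference.axis_names)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_DESCRIP_PREFIX = "axes:"


def write_volume(volume: Volume3D, path, format: str | None = None):
    """Write a volume to NIfTI-1 or a multi-page TIFF stack.

    TIFF stacks carry their physical geometry in a JSON sidecar
    ``<path>.json`` with keys ``spacing_um``, ``origin_um``, ``axis_names``.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
        affine[:3, 3] = volume.origin
        img = nib.Nifti1Image(volume.values, affine)
        img.header["descrip"] = (_DESCRIP_PREFIX + ",".join(volume.axis_names)).encode()
        nib.save(img, str(path))
    elif fmt == "tiff_stack":
        tifffile.imwrite(str(path), volume.values, photometric="minisblack")
        sidecar = {
            "spacing_um": list(volume.spacing),
            "origin_um": list(volume.origin),
            "axis_names": list(volume.axis_names),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_volume(path, format: str | None = None, spacing=None, origin=None,
                axis_names=None) -> Volume3D:
    """Read a NIfTI or TIFF-stack volume.

    For TIFF stacks the spacing must come from the JSON sidecar or be passed
    explicitly — it is never silently defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        values = np.asarray(img.dataobj)
        affine = img.affine
        sp = tuple(np.abs(np.diag(affine)[:3]).tolist())
        org = tuple(affine[:3, 3].tolist())
        names = axis_names
        descrip = img.header["descrip"].tobytes().decode(errors="ignore").rstrip("\x00")
        if names is None and descrip.startswith(_DESCRIP_PREFIX):
            names = tuple(descrip[len(_DESCRIP_PREFIX):].split(","))
        return Volume3D(values, spacing or sp, origin or org,
                        names or DEFAULT_AXIS_NAMES)
    if fmt == "tiff_stack":
        values = tifffile.imread(str(path))
        sidecar_path = Path(str(path) + ".json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            spacing = spacing or tuple(meta["spacing_um"])
            origin = origin or tuple(meta.get("origin_um", (0, 0, 0)))
            axis_names = axis_names or tuple(meta["axis_names"])
        if spacing is None:
            raise ValueError(
                f"TIFF stack {path} has no spacing sidecar; pass spacing explicitly"
            )
        return Volume3D(values, spacing, origin or (0, 0, 0),
                        axis_names or DEFAULT_AXIS_NAMES)
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise ValueError(f"cannot infer format from {path}")


# ---------------------------------------------------------------------------
# Transform serialization (JSON manifest; fields as NIfTI vector images)
# ---------------------------------------------------------------------------


def write_chain(chain: TransformChain, path) -> Path:
    """Serialize a chain as a JSON manifest; fields go to sibling NIfTI files."""
    path = Path(path)
    steps = []
    for i, s in enumerate(chain.steps):
        if isinstance(s, AffineTransform3D):
            steps.append({
                "type": "affine",
                "matrix": s.matrix.tolist(),
                "translation": s.translation.tolist(),
            })
        else:
            field_path = path.with_suffix("").name + f"_field{i}.nii.gz"
            img = nib.Nifti1Image(s.vectors, _grid_affine(s.grid))
            nib.save(img, str(path.parent / field_path))
            steps.append({
                "type": "field",
                "path": field_path,
                "spacing_um": list(s.grid.spacing),
                "origin_um": list(s.grid.origin),
                "axis_names": list(s.grid.axis_names),
            })
    path.write_text(json.dumps({"steps": steps}, indent=2))
    return path


def read_chain(path) -> TransformChain:
    path = Path(path)
    manifest = json.loads(path.read_text())
    steps = []
    for s in manifest["steps"]:
        if s["type"] == "affine":
            steps.append(AffineTransform3D(np.array(s["matrix"]),
                                           np.array(s["translation"])))
        else:
            img = nib.load(str(path.parent / s["path"]))
            vectors = np.asarray(img.dataobj)
            grid = Volume3D(np.zeros(vectors.shape[:3]), tuple(s["spacing_um"]),
                            tuple(s["origin_um"]), tuple(s["axis_names"]))
            steps.append(DisplacementField(vectors, grid))
    return TransformChain(steps)


def _grid_affine(grid: Volume3D) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = grid.spacing
    affine[:3, 3] = grid.origin
    return affine
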
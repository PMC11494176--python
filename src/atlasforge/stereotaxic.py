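"""Stereotaxic alignment and coordinate-grid overlays for postnatal atlases.

Stereotaxic orientation places the estimated bregma directly superior to
the centre of the anterior commissure: the template is rotated purely in
the sagittal plane (about the left-right axis) until the two annotated
midline points share their anterior-posterior (and left-right)
coordinates.  Overlay volumes draw 1 mm coordinate grids anchored at the
anterior commissure, with sagittal/horizontal/coronal plane families coded
1/2/3 and optional bitmap distance digits coded 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import (
    AffineTransform3D,
    TransformChain,
    Volume3D,
    apply_transform,
)

_AX = {"lr": "left-right", "ap": "anterior-posterior", "si": "superior-inferior"}


@dataclass
class StereotaxicFrame:
    bregma: np.ndarray  # world µm, after rotation
    ac: np.ndarray
    rotation: AffineTransform3D
    angle_deg: float

    def __post_init__(self):
        self.bregma = np.asarray(self.bregma, dtype=float)
        self.ac = np.asarray(self.ac, dtype=float)
        if np.allclose(self.bregma, self.ac):
            raise ValueError("bregma and anterior commissure coincide")
        if abs(np.linalg.det(self.rotation.matrix) - 1.0) > 1e-9:
            raise ValueError("rotation must be orthonormal")


def align_stereotaxic(volume: Volume3D, bregma, ac,
                      interpolation: str | None = None):
    """Rotate a template in the sagittal plane into stereotaxic orientation.

    ``bregma`` and ``ac`` are world coordinates (µm) of the two annotated
    midline points.  The rotation is about the left-right axis through the
    anterior commissure; afterwards bregma sits directly superior to the
    commissure (equal anterior-posterior and left-right coordinates) and
    their distance is preserved.  Intensity volumes are resampled linearly,
    label volumes with nearest-neighbour.

    Returns (rotated volume, StereotaxicFrame).
    """
    bregma = np.asarray(bregma, dtype=float)
    ac = np.asarray(ac, dtype=float)
    if np.allclose(bregma, ac):
        raise ValueError("bregma and anterior commissure coincide")
    i_ap = volume.axis_index(_AX["ap"])
    i_si = volume.axis_index(_AX["si"])
    i_lr = volume.axis_index(_AX["lr"])

    d = bregma - ac
    # Rotate in the sagittal (SI–AP) plane so the bregma direction lands on
    # the superior axis: AP component of d goes to zero and the SI
    # component becomes negative (superior = decreasing SI coordinate).
    angle = float(np.arctan2(-d[i_ap], -d[i_si]))

    rot = np.eye(3)
    c, s = np.cos(angle), np.sin(angle)
    # Rotation in the (si, ap) plane about the lr axis.
    rot[i_si, i_si] = c
    rot[i_si, i_ap] = s
    rot[i_ap, i_si] = -s
    rot[i_ap, i_ap] = c
    # Rotate about the anterior commissure so it stays fixed.
    forward = AffineTransform3D(rot, ac - rot @ ac)

    if interpolation is None:
        interpolation = "nearest" if volume.is_label else "linear"
    # Pull-back resampling uses the inverse of the forward point map.
    chain = TransformChain([forward.inverted()])
    rotated = apply_transform(volume, chain, volume, interpolation)
    new_bregma = forward.apply_points(bregma[None])[0]
    frame = StereotaxicFrame(new_bregma, ac.copy(), forward,
                             float(np.degrees(angle)))
    return rotated, frame


# ---------------------------------------------------------------------------
# Coordinate grids
# ---------------------------------------------------------------------------

# 5x7 bitmap digits (rows top->bottom); 1 bits are drawn with code 4.
_DIGITS = {
    "0": ["01110", "10001", "10011", "10101", "11001", "10001", "01110"],
    "1": ["00100", "01100", "00100", "00100", "00100", "00100", "01110"],
    "2": ["01110", "10001", "00001", "00010", "00100", "01000", "11111"],
    "3": ["11110", "00001", "00001", "01110", "00001", "00001", "11110"],
    "4": ["00010", "00110", "01010", "10010", "11111", "00010", "00010"],
    "5": ["11111", "10000", "11110", "00001", "00001", "10001", "01110"],
    "6": ["00110", "01000", "10000", "11110", "10001", "10001", "01110"],
    "7": ["11111", "00001", "00010", "00100", "01000", "01000", "01000"],
    "8": ["01110", "10001", "10001", "01110", "10001", "10001", "01110"],
    "9": ["01110", "10001", "10001", "01111", "00001", "00010", "01100"],
    "-": ["00000", "00000", "00000", "11111", "00000", "00000", "00000"],
}


def make_grid(shape, spacing, ac_index, line_spacing_um: float = 1000.0,
              with_text_labels: bool = False,
              axis_names=("superior-inferior", "anterior-posterior",
                          "left-right")) -> Volume3D:
    """Build a stereotaxic coordinate-grid overlay volume.

    Gridline families parallel to the sagittal / horizontal / coronal
    planes carry codes 1 / 2 / 3 and repeat every ``line_spacing_um``
    (default 1 mm); each family is anchored so one plane passes through
    ``ac_index`` (the anterior commissure voxel), making that voxel the
    central vertex of all three families.  Where families intersect, the
    lowest code wins.  Optional millimetre distance labels are rendered as
    5×7 bitmap digits with value 4 on each coronal gridline slice.  Output
    origin metadata is fixed at (0, 0, 0).
    """
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in np.broadcast_to(np.asarray(spacing, float), (3,)))
    ac_index = tuple(int(i) for i in ac_index)
    if not all(0 <= a < n for a, n in zip(ac_index, shape)):
        raise ValueError("ac_index outside the volume")
    periods = []
    for s in spacing:
        p = line_spacing_um / s
        if abs(p - round(p)) > 1e-9:
            raise ValueError(
                f"line spacing {line_spacing_um} µm is not an integer "
                f"multiple of voxel spacing {s} µm")
        periods.append(int(round(p)))

    names = tuple(axis_names)
    grid = np.zeros(shape, dtype=np.uint8)
    # Plane families by anatomical meaning: sagittal planes are constant
    # left-right, horizontal constant superior-inferior, coronal constant
    # anterior-posterior.
    code_by_axis = {"left-right": 1, "superior-inferior": 2,
                    "anterior-posterior": 3}
    # Draw higher codes first so the lowest code wins at intersections.
    for axis_name in ("anterior-posterior", "superior-inferior", "left-right"):
        ax = names.index(axis_name)
        code = code_by_axis[axis_name]
        idx = _anchored_indices(shape[ax], ac_index[ax], periods[ax])
        sl = [slice(None)] * 3
        for i in idx:
            sl[ax] = i
            grid[tuple(sl)] = code

    if with_text_labels:
        _render_coronal_labels(grid, names, spacing, ac_index, periods)

    return Volume3D(grid, spacing, origin=(0.0, 0.0, 0.0), axis_names=names)


def _anchored_indices(n: int, anchor: int, period: int) -> np.ndarray:
    first = anchor % period
    return np.arange(first, n, period)


def _render_coronal_labels(grid, names, spacing, ac_index, periods):
    """Stamp AP distance (mm) digits near the bottom-left of coronal slices."""
    ax_ap = names.index("anterior-posterior")
    ax_si = names.index("superior-inferior")
    ax_lr = names.index("left-right")
    n_ap = grid.shape[ax_ap]
    for i in _anchored_indices(n_ap, ac_index[ax_ap], periods[ax_ap]):
        dist_mm = (int(i) - ac_index[ax_ap]) * spacing[ax_ap] / 1000.0
        text = f"{dist_mm:g}".replace(".0", "") or "0"
        stamp = _text_bitmap(text)
        sl = [slice(None)] * 3
        sl[ax_ap] = i
        plane = grid[tuple(sl)]  # 2D view: axes (si, lr) in residual order
        h, w = stamp.shape
        if plane.shape[0] > h + 2 and plane.shape[1] > w + 2:
            region = plane[-(h + 1):-1, 1:w + 1]
            region[stamp > 0] = 4
            plane[-(h + 1):-1, 1:w + 1] = region


def _text_bitmap(text: str) -> np.ndarray:
    cols = []
    for ch in text:
        glyph = _DIGITS.get(ch)
        if glyph is None:
            continue
        arr = np.array([[int(b) for b in row] for row in glyph], dtype=np.uint8)
        cols.append(arr)
        cols.append(np.zeros((7, 1), dtype=np.uint8))
    if not cols:
        return np.zeros((7, 1), dtype=np.uint8)
    return np.hstack(cols[:-1])
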
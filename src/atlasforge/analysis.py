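"""Atlas-space analytics: label correspondence, cell matrices, occupancy, volumes.

These are the quantification steps run once data sit in a common atlas
space: cross-parcellation voxel correspondence (the input to a Sankey flow
diagram), assignment of cell somata to regions, subclass-by-region
proportion matrices, regional signal occupancy, and regional volumes with
growth statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ontology import AnnotationVolume, Ontology, aggregate_to_level
from .volume import Volume3D


def label_correspondence(annot_a: AnnotationVolume, annot_b: AnnotationVolume,
                         min_voxels: int = 250,
                         group_level: int | None = None) -> pd.DataFrame:
    """Voxel-to-voxel correspondence counts between two parcellations.

    Each voxel labeled in both volumes contributes one count to its ordered
    (label_a, label_b) pair; pairs below ``min_voxels`` are dropped (the
    default threshold of 250 voxels is what a flow diagram can legibly
    show).  With ``group_level`` both annotations are first aggregated to
    that ontology depth.
    """
    if not annot_a.labels.same_grid(annot_b.labels):
        raise ValueError("annotation grids differ")
    if group_level is not None:
        annot_a = aggregate_to_level(annot_a, group_level)
        annot_b = aggregate_to_level(annot_b, group_level)
    a = annot_a.labels.values.ravel()
    b = annot_b.labels.values.ravel()
    both = (a != 0) & (b != 0)
    pairs = np.stack([a[both], b[both]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    df = pd.DataFrame({
        "label_a": uniq[:, 0].astype(int),
        "label_b": uniq[:, 1].astype(int),
        "voxel_count": counts.astype(int),
    })
    df.attrs["total_doubly_labeled"] = int(both.sum())
    df.attrs["min_voxels"] = int(min_voxels)
    out = df[df["voxel_count"] >= min_voxels].reset_index(drop=True)
    out.attrs.update(df.attrs)
    return out


def assign_cells(cells: pd.DataFrame, annotation: AnnotationVolume) -> pd.DataFrame:
    """Attach the region label containing each cell's soma coordinate.

    The world coordinate is converted to a voxel index by flooring (a
    deterministic tie-break for cells exactly on voxel boundaries);
    out-of-bounds cells receive the background label 0 and are counted in
    ``result.attrs['n_out_of_bounds']``.
    """
    vol = annotation.labels
    pts = cells[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    # voxel centre convention: voxel i spans [i-0.5, i+0.5) index units
    idx = np.floor(vol.world_to_index(pts) + 0.5).astype(int)
    shape = np.array(vol.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    labels = np.zeros(len(cells), dtype=int)
    ii = idx[inside]
    labels[inside] = vol.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    out = cells.copy()
    out["region_id"] = labels
    out.attrs["n_out_of_bounds"] = int((~inside).sum())
    return out


def region_matrix(cells: pd.DataFrame, ontology: Ontology | None = None,
                  normalize: str = "per_subclass",
                  group_level: int | None = None) -> pd.DataFrame:
    """Subclass-by-region matrix of cell proportions.

    Entry (s, r) is the number of subclass-s cells in region r divided by
    the total subclass-s cell count, so every emitted row sums to 1.
    Subclasses with zero cells are omitted rather than emitted as NaN rows.
    With ``group_level`` region ids are rolled up to ontology ancestors
    before counting.
    """
    if "region_id" not in cells.columns:
        raise ValueError("cells must be assigned to regions first")
    df = cells[cells["region_id"] != 0].copy()
    if group_level is not None:
        if ontology is None:
            raise ValueError("ontology required for group_level")
        df["region_id"] = [ontology.ancestor_at_level(r, group_level)
                           for r in df["region_id"]]
    counts = pd.crosstab(df["subclass"], df["region_id"])
    if normalize == "per_subclass":
        counts = counts.div(counts.sum(axis=1), axis=0)
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    return counts


def occupancy(count_volume: Volume3D, annotation: AnnotationVolume,
              aggregation_factor: int) -> pd.DataFrame:
    """Per-region signal occupancy from a sum-pooled positive-voxel count map.

    ``count_volume`` holds, per atlas voxel, the number of positive
    high-resolution voxels pooled into it (so each value lies in
    [0, aggregation_factor]).  Per region the table reports the positive
    total, the raw ratio positives / region voxel count, and the normalized
    fraction positives / (region voxels × aggregation_factor) in [0, 1]
    (the "% area filled with signal" reading).
    """
    if not count_volume.same_grid(annotation.labels):
        raise ValueError("count volume and annotation grids differ")
    counts = count_volume.values
    if counts.min() < 0:
        raise ValueError("counts must be >= 0")
    if counts.max() > aggregation_factor:
        raise ValueError(
            f"count {counts.max()} exceeds aggregation_factor {aggregation_factor}"
        )
    labels = annotation.labels.values
    region_ids = [l for l in np.unique(labels) if l != 0]
    rows = []
    for r in region_ids:
        sel = labels == r
        pos = float(counts[sel].sum())
        nvox = int(sel.sum())
        rows.append({
            "region_id": int(r),
            "positive_voxels": pos,
            "region_voxels": nvox,
            "ratio": pos / nvox,
            "normalized_fraction": pos / (nvox * aggregation_factor),
        })
    return pd.DataFrame(rows)


def region_volumes(annotation: AnnotationVolume,
                   level: int | None = None) -> pd.DataFrame:
    """Voxel counts and physical volumes (mm³) per region."""
    annot = annotation if level is None else aggregate_to_level(annotation, level)
    labels = annot.labels.values
    ids, counts = np.unique(labels, return_counts=True)
    vox_mm3 = annot.labels.voxel_volume_mm3
    rows = [{"region_id": int(i), "voxel_count": int(c),
             "volume_mm3": float(c * vox_mm3)}
            for i, c in zip(ids, counts) if i != 0]
    return pd.DataFrame(rows)


def growth_stats(sample_volumes, template_volume: float) -> dict:
    """Mean, sample SD and template z-score for a set of sample volumes.

    ``z`` measures how far the template's volume sits from the sample mean
    in sample-SD units (n−1 denominator); a template within |z| <= 1 is
    within one standard deviation of its cohort.
    """
    vols = np.asarray(sample_volumes, dtype=float)
    if vols.size < 2:
        raise ValueError("need >= 2 samples for a standard deviation")
    mean = float(vols.mean())
    sd = float(vols.std(ddof=1))
    if sd == 0:
        if template_volume != mean:
            raise ValueError("sd is 0 but template differs from the mean")
        z = 0.0
    else:
        z = (float(template_volume) - mean) / sd
    return {"mean": mean, "sd": sd, "z": z}
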
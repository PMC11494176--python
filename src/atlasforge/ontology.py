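"""Hierarchical region ontology, ID remapping and annotation validation.

Developmental parcellations use a prosomeric-model region tree of up to 13
levels.  Annotation volumes store one integer region ID per voxel; to keep
those volumes 16-bit, legacy 32-bit IDs above 65535 are compressed into the
20000–29999 range by keeping their last four decimal digits and prefixing a
2 (newly added structures live in 18000–19999 and are never remapped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import Volume3D, mirror

MAX_DEPTH = 13
NEW_STRUCTURE_RANGE = (18000, 19999)
REMAP_RANGE = (20000, 29999)


@dataclass
class RegionNode:
    id16: int
    name: str
    acronym: str
    parent_id: int | None
    color: str = "#808080"
    level: int = 0
    id32: int | None = None

    def __post_init__(self):
        if not 0 <= self.id16 <= 65535:
            raise ValueError(f"id16 {self.id16} outside [0, 65535]")


class Ontology:
    """A single-rooted region tree keyed by 16-bit IDs."""

    def __init__(self, nodes: list):
        self.nodes = {}
        for node in nodes:
            if node.id16 in self.nodes:
                raise ValueError(f"duplicate ontology id {node.id16}")
            if node.id16 == 0:
                raise ValueError("id 0 is reserved for background")
            self.nodes[node.id16] = node
        roots = [n for n in self.nodes.values() if n.parent_id in (None, 0)]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for n in self.nodes.values():
            if n.parent_id not in (None, 0) and n.parent_id not in self.nodes:
                raise ValueError(f"node {n.id16} references missing parent {n.parent_id}")
        self._check_acyclic()
        if self.max_depth() > MAX_DEPTH:
            raise ValueError(f"ontology depth exceeds {MAX_DEPTH} levels")

    def _check_acyclic(self):
        for n in self.nodes.values():
            seen = set()
            cur = n
            while cur.parent_id not in (None, 0):
                if cur.id16 in seen:
                    raise ValueError(f"cycle in ontology involving id {cur.id16}")
                seen.add(cur.id16)
                cur = self.nodes[cur.parent_id]

    # -- queries ----------------------------------------------------------
    def __contains__(self, id16: int) -> bool:
        return id16 in self.nodes

    def __getitem__(self, id16: int) -> RegionNode:
        return self.nodes[id16]

    def depth(self, id16: int) -> int:
        d, cur = 0, self.nodes[id16]
        while cur.parent_id not in (None, 0):
            d += 1
            cur = self.nodes[cur.parent_id]
        return d

    def max_depth(self) -> int:
        return max(self.depth(i) for i in self.nodes)

    def children(self, id16: int) -> list:
        return [n for n in self.nodes.values() if n.parent_id == id16]

    def descendants(self, id16: int) -> list:
        out = []
        stack = [id16]
        while stack:
            cur = stack.pop()
            for c in self.children(cur):
                out.append(c.id16)
                stack.append(c.id16)
        return out

    def ancestor_at_level(self, id16: int, level: int) -> int:
        """Ancestor at the given tree depth; IDs at or above stay unchanged."""
        cur = self.nodes[id16]
        while self.depth(cur.id16) > level:
            cur = self.nodes[cur.parent_id]
        return cur.id16


def load_ontology(path_or_df) -> Ontology:
    """Build an ontology from a CSV table.

    Required columns: id, name, acronym, parent_id, color, level; an
    optional id32 column carries original 32-bit identifiers.  Cycles,
    duplicate ids and unresolvable parents are rejected.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df)
    required = {"id", "name", "acronym", "parent_id", "color", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ontology table missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].astype(int))
        raise ValueError(f"duplicate ontology ids {dupes}")
    nodes = []
    for _, row in df.iterrows():
        parent = row["parent_id"]
        parent = None if pd.isna(parent) or int(parent) == 0 else int(parent)
        nid = int(row["id"])
        if parent == nid:
            raise ValueError(f"node {nid} is its own parent (cycle)")
        id32 = None
        if "id32" in df.columns and not pd.isna(row.get("id32")):
            id32 = int(row["id32"])
        nodes.append(RegionNode(
            id16=nid, name=str(row["name"]), acronym=str(row["acronym"]),
            parent_id=parent, color=str(row["color"]), level=int(row["level"]),
            id32=id32,
        ))
    return Ontology(nodes)


def save_ontology(ontology: Ontology, path) -> Path:
    rows = []
    for n in ontology.nodes.values():
        rows.append({
            "id": n.id16, "name": n.name, "acronym": n.acronym,
            "parent_id": 0 if n.parent_id is None else n.parent_id,
            "color": n.color, "level": n.level,
            "id32": "" if n.id32 is None else n.id32,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def remap_id16(id32: int) -> int:
    """Compress a 32-bit region ID into 16-bit space.

    IDs already within [0, 65535] pass through unchanged; larger IDs keep
    their last four decimal digits and gain a prefix of 2, landing in
    [20000, 29999].  Example: 17754321 -> 24321.
    """
    id32 = int(id32)
    if id32 < 0:
        raise ValueError("id must be >= 0")
    if id32 <= 65535:
        return id32
    return 20000 + id32 % 10000


def remap_ontology_ids(id32_values) -> dict:
    """Remap a collection of 32-bit IDs, rejecting collisions.

    Returns {id32: id16}.  Two distinct inputs mapping to one output abort
    with both offenders named — uniqueness is required, and no tie-break
    rule exists.
    """
    mapping, reverse = {}, {}
    for v in id32_values:
        out = remap_id16(v)
        if out in reverse and reverse[out] != v:
            raise ValueError(
                f"id16 collision: {reverse[out]} and {v} both map to {out}"
            )
        mapping[v] = out
        reverse[out] = v
    return mapping


@dataclass
class AnnotationVolume:
    """Integer label volume paired with its ontology."""

    labels: Volume3D
    ontology: Ontology

    def __post_init__(self):
        if not self.labels.is_label:
            raise ValueError("annotation volume must hold integer labels")


def validate_annotation(annotation: AnnotationVolume,
                        check_symmetry_axis: str | None = None) -> dict:
    """Structural report on an annotation volume.

    Reports unknown labels (absent from the ontology), per-label voxel
    counts, the distinct-label count versus the ontology-entry count, and —
    because an integer volume stores exactly one value per voxel — confirms
    the single-label-per-voxel property structurally.  Optionally measures
    bilateral symmetry against the mirrored volume.
    """
    values = annotation.labels.values
    labels, counts = np.unique(values, return_counts=True)
    per_label = {int(l): int(c) for l, c in zip(labels, counts) if l != 0}
    unknown = {l: c for l, c in per_label.items() if l not in annotation.ontology}
    report = {
        "per_label_voxel_counts": per_label,
        "unknown_labels": unknown,
        "n_labels_in_volume": len(per_label),
        "n_labels_in_ontology": len(annotation.ontology.nodes),
        "labeled_voxel_total": int(sum(per_label.values())),
        "single_label_per_voxel": True,
    }
    if check_symmetry_axis is not None:
        mirrored = mirror(annotation.labels, check_symmetry_axis)
        agree = np.mean(values == mirrored.values)
        report["bilateral_symmetry_fraction"] = float(agree)
    return report


def aggregate_to_level(annotation: AnnotationVolume, level: int) -> AnnotationVolume:
    """Replace every label by its ancestor at the requested tree depth.

    Labels already at or above that depth are unchanged; the labeled voxel
    total is conserved exactly.
    """
    ont = annotation.ontology
    if not 0 <= level <= ont.max_depth():
        raise ValueError(f"level {level} outside [0, {ont.max_depth()}]")
    values = annotation.labels.values
    present = np.unique(values)
    lut = {0: 0}
    for l in present:
        if l == 0:
            continue
        if int(l) not in ont:
            raise ValueError(f"label {int(l)} not in ontology")
        lut[int(l)] = ont.ancestor_at_level(int(l), level)
    mapped = np.vectorize(lut.get, otypes=[values.dtype])(values)
    return AnnotationVolume(annotation.labels.like(mapped), ont)


def make_synthetic_ontology(n_regions: int, depth: int = 2) -> Ontology:
    """Small ontology matching `synthetic.make_phantom` labels.

    Synthetic stand-in for a curated region tree: root id 1000, shells
    1..n_regions and the ventricle (n_regions+1) as its children.
    """
    nodes = [RegionNode(1000, "brain", "Br", None, "#ffffff", 0)]
    for k in range(1, n_regions + 1):
        nodes.append(RegionNode(k, f"shell {k}", f"S{k}", 1000, "#3070b0", 1))
    nodes.append(RegionNode(n_regions + 1, "ventricle", "V", 1000, "#202020", 1))
    return Ontology(nodes)
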
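"""Hierarchical pose-grouping skeletons.

A skeleton schema describes one species as a three-level hierarchy:
instance -> anatomical parts -> keypoints. Every keypoint belongs to
exactly one part; each part is later represented by an adaptive part
point regressed from the instance center, so the schema is what ties the
two-hop offset decomposition to the animal's anatomy. The schema also
carries per-keypoint OKS constants and the bilateral flip permutation
used for mirror-augmented training and flip testing.

Built-in schemas ship for the three space model organisms:

- ``celegans``   5 keypoints / 5 parts (one keypoint per part, midline only)
- ``zebrafish``  10 keypoints / 5 parts (1-3 keypoints per part)
- ``drosophila`` 26 keypoints / 9 parts (1-6 keypoints per part)

The zebrafish and fly keypoint names and part memberships are plausible
anatomical assignments, not a published annotation key; users can supply
their own schema files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "KeypointDef",
    "PartDef",
    "SkeletonSchema",
    "PoseInstance",
    "load_schema",
    "builtin_schema",
    "builtin_species",
    "flip_permutation",
    "instance_center",
    "SchemaFormatError",
    "SchemaValidationError",
]

DEFAULT_OKS_K = 0.1  # uniform per-keypoint OKS constant; none published for animals


class SchemaFormatError(ValueError):
    """Raised when a schema file cannot be parsed into the expected fields."""


class SchemaValidationError(ValueError):
    """Raised when a parsed schema violates structural invariants."""


@dataclass(frozen=True)
class KeypointDef:
    name: str
    index: int
    oks_k: float = DEFAULT_OKS_K
    flip_partner: int = -1  # -1 -> self

    def partner(self) -> int:
        return self.index if self.flip_partner < 0 else self.flip_partner


@dataclass(frozen=True)
class PartDef:
    name: str
    keypoint_indices: tuple


@dataclass(frozen=True)
class SkeletonSchema:
    species: str
    keypoints: tuple
    parts: tuple
    skeleton_edges: tuple = ()
    center_rule: str = "keypoint_centroid"

    @property
    def n_keypoints(self) -> int:
        return len(self.keypoints)

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    @property
    def oks_sigmas(self) -> np.ndarray:
        return np.array([k.oks_k for k in self.keypoints])

    def part_of_keypoint(self) -> np.ndarray:
        """Map keypoint index -> owning part index."""
        owner = np.full(self.n_keypoints, -1, dtype=int)
        for pi, part in enumerate(self.parts):
            for ki in part.keypoint_indices:
                owner[ki] = pi
        return owner

    def validate(self) -> None:
        errors = []
        idxs = [k.index for k in self.keypoints]
        if idxs != list(range(self.n_keypoints)):
            errors.append(f"keypoint indices must be 0..{self.n_keypoints - 1} in order, got {idxs}")
        for k in self.keypoints:
            if k.oks_k <= 0:
                errors.append(f"keypoint {k.name!r}: oks_k must be positive, got {k.oks_k}")
            p = k.partner()
            if not (0 <= p < self.n_keypoints):
                errors.append(f"keypoint {k.name!r}: flip partner {p} out of range")
            elif self.keypoints[p].partner() != k.index:
                errors.append(f"flip relation not an involution at keypoint {k.name!r}")
        seen: dict[int, str] = {}
        for part in self.parts:
            if not 1 <= len(part.keypoint_indices) <= 6:
                errors.append(f"part {part.name!r} has {len(part.keypoint_indices)} keypoints (must be 1-6)")
            for ki in part.keypoint_indices:
                if ki in seen:
                    errors.append(f"keypoint {ki} in both parts {seen[ki]!r} and {part.name!r}")
                seen[ki] = part.name
        missing = set(range(self.n_keypoints)) - set(seen)
        if missing:
            errors.append(f"keypoints not assigned to any part: {sorted(missing)}")
        for a, b in self.skeleton_edges:
            if not (0 <= a < self.n_keypoints and 0 <= b < self.n_keypoints):
                errors.append(f"skeleton edge ({a},{b}) out of range")
        if self.center_rule not in ("keypoint_centroid", "bbox_center"):
            errors.append(f"unknown center_rule {self.center_rule!r}")
        if errors:
            raise SchemaValidationError("; ".join(errors))


@dataclass
class PoseInstance:
    """One animal: K keypoint triplets plus center and OKS scale.

    Visibility follows the COCO convention: 0 absent, 1 labeled but
    occluded, 2 visible. Coordinates are 0-based continuous pixels,
    x right / y down; v=0 coordinates are meaningless.
    """

    keypoints: np.ndarray  # (K, 3) columns x, y, v
    center: tuple | None = None
    scale_s: float | None = None
    instance_id: int = -1

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.ndim != 2 or self.keypoints.shape[1] != 3:
            raise ValueError(f"keypoints must be (K, 3), got {self.keypoints.shape}")

    @property
    def visible(self) -> np.ndarray:
        return self.keypoints[:, 2] > 0

    def n_visible(self) -> int:
        return int(self.visible.sum())

    def compute_scale(self, pad: float = 0.1) -> float:
        """sqrt of the tight bbox area of labeled keypoints, padded 10% a side."""
        vis = self.keypoints[self.visible, :2]
        if len(vis) == 0:
            raise ValueError("cannot compute scale with no labeled keypoints")
        w = vis[:, 0].max() - vis[:, 0].min()
        h = vis[:, 1].max() - vis[:, 1].min()
        area = max(w * (1 + 2 * pad), 1.0) * max(h * (1 + 2 * pad), 1.0)
        return float(np.sqrt(area))


# ---------------------------------------------------------------------------
# Built-in species


def _mk(species, names, parts, flip_pairs, edges, oks_k=DEFAULT_OKS_K):
    partner = {i: i for i in range(len(names))}
    for a, b in flip_pairs:
        partner[a], partner[b] = b, a
    kps = tuple(
        KeypointDef(name=n, index=i, oks_k=oks_k, flip_partner=partner[i])
        for i, n in enumerate(names)
    )
    pdefs = tuple(PartDef(name=p, keypoint_indices=tuple(ks)) for p, ks in parts)
    schema = SkeletonSchema(species=species, keypoints=kps, parts=pdefs, skeleton_edges=tuple(edges))
    schema.validate()
    return schema


def _celegans():
    names = ["head", "front", "middle", "back", "tail"]
    parts = [(n, [i]) for i, n in enumerate(names)]
    edges = [(0, 1), (1, 2), (2, 3), (3, 4)]
    return _mk("celegans", names, parts, [], edges)


def _zebrafish():
    names = [
        "snout", "eye_left", "eye_right",           # head
        "dorsal_fin_front", "dorsal_fin_rear",       # dorsal
        "pelvic_fin", "anal_fin",                    # ventral
        "mid_body",                                  # mid-body
        "peduncle", "tail_tip",                      # caudal
    ]
    parts = [
        ("head", [0, 1, 2]),
        ("dorsal", [3, 4]),
        ("ventral", [5, 6]),
        ("mid_body", [7]),
        ("caudal", [8, 9]),
    ]
    flip_pairs = [(1, 2)]
    edges = [(0, 1), (0, 2), (0, 7), (3, 7), (5, 7), (7, 8), (4, 8), (6, 8), (8, 9)]
    return _mk("zebrafish", names, parts, flip_pairs, edges)


def _drosophila():
    names = [
        "proboscis", "eye_left", "eye_right",                    # head: 0-2
        "antenna_left", "antenna_right",                          # antennae: 3-4
        "notum",                                                  # thorax: 5
        "abdomen_1", "abdomen_2", "abdomen_3", "abdomen_tip",     # abdomen: 6-9
        "wing_left_base", "wing_left_tip",                        # left wing: 10-11
        "wing_right_base", "wing_right_tip",                      # right wing: 12-13
        "leg_front_left_joint", "leg_front_left_tip",             # front legs: 14-17
        "leg_front_right_joint", "leg_front_right_tip",
        "leg_mid_left_joint", "leg_mid_left_tip",                 # mid legs: 18-21
        "leg_mid_right_joint", "leg_mid_right_tip",
        "leg_hind_left_joint", "leg_hind_left_tip",               # hind legs: 22-25
        "leg_hind_right_joint", "leg_hind_right_tip",
    ]
    parts = [
        ("head", [0, 1, 2]),
        ("antennae", [3, 4]),
        ("thorax", [5]),
        ("abdomen", [6, 7, 8, 9]),
        ("wing_left", [10, 11]),
        ("wing_right", [12, 13]),
        ("front_legs", [14, 15, 16, 17]),
        ("mid_legs", [18, 19, 20, 21]),
        ("hind_legs", [22, 23, 24, 25]),
    ]
    flip_pairs = [
        (1, 2), (3, 4), (10, 12), (11, 13),
        (14, 16), (15, 17), (18, 20), (19, 21), (22, 24), (23, 25),
    ]
    edges = [
        (0, 1), (0, 2), (1, 3), (2, 4), (0, 5), (5, 6), (6, 7), (7, 8), (8, 9),
        (5, 10), (10, 11), (5, 12), (12, 13),
        (5, 14), (14, 15), (5, 16), (16, 17),
        (5, 18), (18, 19), (5, 20), (20, 21),
        (5, 22), (22, 23), (5, 24), (24, 25),
    ]
    return _mk("drosophila", names, parts, flip_pairs, edges)


_BUILTINS = {"celegans": _celegans, "zebrafish": _zebrafish, "drosophila": _drosophila}


def builtin_species() -> list:
    return sorted(_BUILTINS)


def builtin_schema(species: str) -> SkeletonSchema:
    try:
        return _BUILTINS[species]()
    except KeyError:
        raise KeyError(f"no built-in schema {species!r}; known: {builtin_species()}") from None


# ---------------------------------------------------------------------------
# File I/O


def load_schema(path) -> SkeletonSchema:
    """Load a schema from YAML/JSON, or a built-in by bare name."""
    spath = str(path)
    if spath in _BUILTINS:
        return builtin_schema(spath)
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text) if not spath.endswith(".json") else json.loads(text)
    except Exception as exc:
        raise SchemaFormatError(f"cannot parse schema file {spath}: {exc}") from exc
    return schema_from_dict(doc)


def schema_from_dict(doc: dict) -> SkeletonSchema:
    if not isinstance(doc, dict):
        raise SchemaFormatError("schema document must be a mapping")
    for key in ("species", "keypoints", "parts"):
        if key not in doc:
            raise SchemaFormatError(f"schema missing required field {key!r}")
    name_to_idx = {}
    kp_rows = doc["keypoints"]
    for i, row in enumerate(kp_rows):
        if isinstance(row, str):
            name = row
        elif isinstance(row, dict) and "name" in row:
            name = row["name"]
        else:
            raise SchemaFormatError(f"keypoints[{i}]: expected name string or mapping with 'name'")
        name_to_idx[name] = i

    def resolve(ref, ctx):
        if isinstance(ref, int):
            return ref
        if ref in name_to_idx:
            return name_to_idx[ref]
        raise SchemaFormatError(f"{ctx}: unknown keypoint reference {ref!r}")

    kps = []
    for i, row in enumerate(kp_rows):
        if isinstance(row, str):
            row = {"name": row}
        partner = row.get("flip_partner", i)
        kps.append(
            KeypointDef(
                name=row["name"],
                index=i,
                oks_k=float(row.get("oks_k", DEFAULT_OKS_K)),
                flip_partner=resolve(partner, f"keypoints[{i}].flip_partner"),
            )
        )
    parts = []
    for j, prow in enumerate(doc["parts"]):
        if not isinstance(prow, dict) or "name" not in prow or "keypoints" not in prow:
            raise SchemaFormatError(f"parts[{j}]: expected mapping with 'name' and 'keypoints'")
        parts.append(
            PartDef(
                name=prow["name"],
                keypoint_indices=tuple(resolve(r, f"parts[{j}]") for r in prow["keypoints"]),
            )
        )
    edges = tuple(
        (resolve(a, "skeleton"), resolve(b, "skeleton")) for a, b in doc.get("skeleton", [])
    )
    schema = SkeletonSchema(
        species=doc["species"],
        keypoints=tuple(kps),
        parts=tuple(parts),
        skeleton_edges=edges,
        center_rule=doc.get("center_rule", "keypoint_centroid"),
    )
    schema.validate()
    return schema


def schema_to_dict(schema: SkeletonSchema) -> dict:
    return {
        "species": schema.species,
        "keypoints": [
            {"name": k.name, "oks_k": k.oks_k, "flip_partner": k.partner()}
            for k in schema.keypoints
        ],
        "parts": [
            {"name": p.name, "keypoints": list(p.keypoint_indices)} for p in schema.parts
        ],
        "skeleton": [list(e) for e in schema.skeleton_edges],
        "center_rule": schema.center_rule,
    }


def save_schema(schema: SkeletonSchema, path) -> None:
    Path(path).write_text(yaml.safe_dump(schema_to_dict(schema), sort_keys=False))


# ---------------------------------------------------------------------------
# Derived quantities


def flip_permutation(schema: SkeletonSchema) -> np.ndarray:
    """Keypoint index remap under horizontal mirroring (an involution)."""
    return np.array([k.partner() for k in schema.keypoints], dtype=int)


def instance_center(inst: PoseInstance, schema: SkeletonSchema) -> tuple:
    """Ground-truth instance center from labeled keypoints.

    ``keypoint_centroid`` (default) is the mean of labeled keypoints —
    robust for the limbless midline skeletons of worms and fish;
    ``bbox_center`` is the midpoint of their tight bounding box.
    """
    vis = inst.keypoints[inst.visible, :2]
    if len(vis) == 0:
        raise ValueError("instance center undefined: no keypoint with v > 0")
    if schema.center_rule == "bbox_center":
        lo, hi = vis.min(axis=0), vis.max(axis=0)
        c = (lo + hi) / 2.0
    else:
        c = vis.mean(axis=0)
    return float(c[0]), float(c[1])
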
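"""Synthetic multi-animal scenes with exact keypoint annotations.

The generator emulates the imaging regime of in-orbit behavioral
recordings of small model organisms: many visually similar individuals
per frame (1-15), flexible non-rigid bodies, frequent overlap and
occlusion, and optional image degradations (blur, glare). Shape models:

- worm (``celegans``): a smooth spline centerline through random turning
  angles (self-coiling allowed), rendered as a tapering tube; the 5
  keypoints sit at arclength fractions 0, .25, .5, .75, 1.
- fish (``zebrafish``): a body ellipse plus an articulated tail fin;
  10 keypoints on snout, eyes, fin bases, mid-body, peduncle, tail tip.
- fly (``drosophila``): head/thorax/abdomen blobs, two wing ellipses and
  six two-segment legs; 26 keypoints on those structures.

Annotations are exactly consistent with rendering: every labeled
keypoint is placed on the instance's own foreground mask. Later-drawn
instances occlude earlier ones; a keypoint of an earlier instance whose
3-px neighbourhood is >= 60% covered by later foreground is downgraded
to v=1 (labeled but occluded).

Determinism: a single integer seed drives a `numpy.random.SeedSequence`
which is split into one child stream per instance plus one for the
background and degradations, so adding instances never perturbs the
appearance of earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep

from .schema import PoseInstance, SkeletonSchema, builtin_schema, instance_center

__all__ = [
    "SceneConfig",
    "SceneSample",
    "generate_scene",
    "generate_dataset",
    "write_coco",
    "read_coco",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when instances cannot be placed after bounded retries."""


@dataclass(frozen=True)
class SceneConfig:
    species: str = "celegans"
    image_size: tuple = (128, 128)  # (H, W)
    n_instances: tuple = (1, 4)     # inclusive range
    occlusion_prob: float = 0.3
    blur_sigma: float = 0.0
    glare_prob: float = 0.0
    background: str = "textured"
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image_size must be at least 64x64")
        lo, hi = self.n_instances
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid n_instances range {self.n_instances}")


@dataclass
class SceneSample:
    image: np.ndarray | None          # (H, W, 3) in [0, 1], or None when lazy
    instances: list
    config: SceneConfig | None = None
    masks: list | None = None         # per-instance boolean foreground masks
    overlap_fraction: list | None = None
    image_id: int = 0
    file_name: str = ""
    image_size: tuple = ()

    def __post_init__(self):
        if not self.image_size and self.image is not None:
            self.image_size = self.image.shape[:2]


# ---------------------------------------------------------------------------
# Shape models: each returns (mask, keypoints (K,2), paint) for one instance
# on an (H, W) canvas. `paint` is the instance's grayscale foreground value.


def _thick_polyline(mask, pts, radius):
    """Rasterize a polyline with a (possibly per-point) disc radius."""
    h, w = mask.shape
    radius = np.broadcast_to(np.asarray(radius, dtype=float), (len(pts),))
    for (x, y), r in zip(pts, radius):
        r = max(float(r), 1.0)
        x0, x1 = int(max(0, np.floor(x - r))), int(min(w - 1, np.ceil(x + r)))
        y0, y1 = int(max(0, np.floor(y - r))), int(min(h - 1, np.ceil(y + r)))
        if x0 > x1 or y0 > y1:
            continue
        yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        mask[y0 : y1 + 1, x0 : x1 + 1] |= (xx - x) ** 2 + (yy - y) ** 2 <= r * r


def _ellipse_mask(mask, cx, cy, a, b, theta):
    h, w = mask.shape
    r = max(a, b) + 1
    x0, x1 = int(max(0, cx - r)), int(min(w - 1, cx + r))
    y0, y1 = int(max(0, cy - r)), int(min(h - 1, cy + r))
    if x0 > x1 or y0 > y1:
        return
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    mask[y0 : y1 + 1, x0 : x1 + 1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _spline_curve(control, n=200):
    control = np.asarray(control, dtype=float)
    k = min(3, len(control) - 1)
    tck, _ = splprep([control[:, 0], control[:, 1]], s=0, k=k)
    u = np.linspace(0, 1, n)
    x, y = splev(u, tck)
    return np.stack([x, y], axis=1)


def _arclength_points(curve, fracs):
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    out = []
    for f in fracs:
        t = f * total
        i = np.searchsorted(cum, t, side="right") - 1
        i = min(i, len(seg) - 1)
        w = 0.0 if seg[i] == 0 else (t - cum[i]) / seg[i]
        out.append(curve[i] * (1 - w) + curve[i + 1] * w)
    return np.array(out)


def _worm(rng, hw, anchor):
    h, w = hw
    length = rng.uniform(0.30, 0.55) * min(h, w)
    n_ctrl = 5
    heading = rng.uniform(0, 2 * np.pi)
    turns = rng.uniform(-1.2, 1.2, size=n_ctrl - 2)  # radians; coiling allowed
    pts = [np.asarray(anchor, dtype=float)]
    step = length / (n_ctrl - 1)
    for i in range(n_ctrl - 1):
        pts.append(pts[-1] + step * np.array([np.cos(heading), np.sin(heading)]))
        if i < len(turns):
            heading += turns[i]
    curve = _spline_curve(pts)
    kps = _arclength_points(curve, [0.0, 0.25, 0.5, 0.75, 1.0])
    mask = np.zeros((h, w), dtype=bool)
    u = np.linspace(0, 1, len(curve))
    radii = np.maximum(length / 22.0 * np.sqrt(np.clip(4 * u * (1 - u) + 0.12, 0, None)), 1.2)
    _thick_polyline(mask, curve, radii)
    return mask, kps, rng.uniform(0.2, 0.4)


def _fish(rng, hw, anchor):
    h, w = hw
    length = rng.uniform(0.28, 0.45) * min(h, w)
    body_l = 0.62 * length
    body_w = 0.30 * body_l
    theta = rng.uniform(0, 2 * np.pi)
    d = np.array([np.cos(theta), np.sin(theta)])
    n = np.array([-d[1], d[0]])
    c = np.asarray(anchor, dtype=float)
    mask = np.zeros((h, w), dtype=bool)
    _ellipse_mask(mask, c[0], c[1], body_l / 2, body_w / 2, theta)
    # articulated tail: peduncle -> tip with a random bend
    ped = c + d * body_l / 2 * 0.95
    bend = rng.uniform(-0.9, 0.9)
    tail_dir = np.array(
        [np.cos(theta + bend), np.sin(theta + bend)]
    )
    tip = ped + tail_dir * (length - body_l)
    tail_pts = np.linspace(0, 1, 30)[:, None] * (tip - ped)[None] + ped[None]
    _thick_polyline(mask, tail_pts, np.linspace(0.30 * body_w, 0.55 * body_w, 30))
    snout = c - d * body_l / 2 * 0.98
    eye_off = c - d * body_l * 0.30
    kps = np.array(
        [
            snout,
            eye_off + n * body_w * 0.22,   # eye_left
            eye_off - n * body_w * 0.22,   # eye_right
            c - d * body_l * 0.10 + n * body_w * 0.40,  # dorsal_fin_front
            c + d * body_l * 0.25 + n * body_w * 0.32,  # dorsal_fin_rear
            c - d * body_l * 0.05 - n * body_w * 0.40,  # pelvic_fin
            c + d * body_l * 0.28 - n * body_w * 0.30,  # anal_fin
            c,                                          # mid_body
            ped,                                        # peduncle
            tip,                                        # tail_tip
        ]
    )
    return mask, kps, rng.uniform(0.25, 0.45)


def _fly(rng, hw, anchor):
    h, w = hw
    size = rng.uniform(0.22, 0.34) * min(h, w)
    theta = rng.uniform(0, 2 * np.pi)
    d = np.array([np.cos(theta), np.sin(theta)])
    n = np.array([-d[1], d[0]])
    c = np.asarray(anchor, dtype=float)  # thorax center
    head_c = c + d * size * 0.28
    abd_c = c - d * size * 0.32
    mask = np.zeros((h, w), dtype=bool)
    _ellipse_mask(mask, head_c[0], head_c[1], size * 0.13, size * 0.11, theta)
    _ellipse_mask(mask, c[0], c[1], size * 0.18, size * 0.14, theta)
    _ellipse_mask(mask, abd_c[0], abd_c[1], size * 0.26, size * 0.15, theta)
    # antennae
    ant_l = head_c + d * size * 0.17 + n * size * 0.10
    ant_r = head_c + d * size * 0.17 - n * size * 0.10
    for tip in (ant_l, ant_r):
        _thick_polyline(mask, np.linspace(head_c, tip, 8), 1.0)
    # wings: ellipses swept back
    wing = {}
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        wdir = -d * 0.85 + sgn * n * 0.55
        wdir /= np.linalg.norm(wdir)
        base = c + sgn * n * size * 0.10 - d * size * 0.05
        wc = base + wdir * size * 0.30
        _ellipse_mask(mask, wc[0], wc[1], size * 0.32, size * 0.10, np.arctan2(wdir[1], wdir[0]))
        wing[side] = (base, base + wdir * size * 0.60)
    # legs: 3 per side, two segments each
    legs = []
    for i, ux in enumerate((0.14, 0.0, -0.14)):
        for sgn in (1.0, -1.0):
            hip = c + d * size * ux + sgn * n * size * 0.12
            sweep = (0.55, 0.05, -0.55)[i]
            ldir = sgn * n * 0.9 + d * sweep
            ldir /= np.linalg.norm(ldir)
            joint = hip + ldir * size * 0.20
            bend = ldir * 0.6 - d * 0.25 * np.sign(sweep + 1e-9)
            bend /= np.linalg.norm(bend)
            tip = joint + bend * size * 0.22
            _thick_polyline(mask, np.linspace(hip, joint, 8), 1.1)
            _thick_polyline(mask, np.linspace(joint, tip, 8), 1.0)
            legs.append((sgn, i, joint, tip))
    eye_l = head_c + n * size * 0.10
    eye_r = head_c - n * size * 0.10
    abd = [c - d * size * (0.18 + 0.12 * j) for j in range(3)] + [abd_c - d * size * 0.24]
    leg_kp = {}
    for sgn, i, joint, tip in legs:
        side = "left" if sgn > 0 else "right"
        leg_kp[(i, side)] = (joint, tip)
    kps = np.array(
        [
            head_c + d * size * 0.12,  # proboscis
            eye_l, eye_r, ant_l, ant_r,
            c,                          # notum
            *abd,                       # abdomen_1..3, abdomen_tip
            wing["left"][0], wing["left"][1],
            wing["right"][0], wing["right"][1],
            *leg_kp[(0, "left")], *leg_kp[(0, "right")],
            *leg_kp[(1, "left")], *leg_kp[(1, "right")],
            *leg_kp[(2, "left")], *leg_kp[(2, "right")],
        ]
    )
    return mask, kps, rng.uniform(0.2, 0.4)


_SHAPES = {"celegans": _worm, "zebrafish": _fish, "drosophila": _fly}


# ---------------------------------------------------------------------------
# Scene assembly


def _place_instance(shape_fn, rng, hw, margin, prior_centers, want_overlap, max_tries=60):
    h, w = hw
    for _ in range(max_tries):
        if want_overlap and prior_centers:
            base = prior_centers[rng.integers(len(prior_centers))]
            anchor = np.asarray(base) + rng.uniform(-12, 12, size=2)
        else:
            anchor = np.array([rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)])
        mask, kps, paint = shape_fn(rng, hw, anchor)
        if (
            kps[:, 0].min() >= 1
            and kps[:, 0].max() <= w - 2
            and kps[:, 1].min() >= 1
            and kps[:, 1].max() <= h - 2
            and mask.any()
        ):
            return mask, kps, paint
    raise PlacementError(f"could not place instance within {max_tries} tries on {hw} canvas")


def generate_scene(cfg: SceneConfig, schema: SkeletonSchema | None = None) -> SceneSample:
    """Render one scene and its exact annotations. Deterministic given cfg.seed."""
    if cfg.species not in _SHAPES:
        raise KeyError(f"no shape model for species {cfg.species!r}")
    schema = schema or builtin_schema(cfg.species)
    shape_fn = _SHAPES[cfg.species]
    h, w = cfg.image_size
    root = np.random.SeedSequence(cfg.seed)
    bg_rng = np.random.default_rng(root.spawn(1)[0])
    n = int(np.random.default_rng(root).integers(cfg.n_instances[0], cfg.n_instances[1] + 1))
    inst_streams = root.spawn(n + 1)[1:]

    margin = 0.22 * min(h, w)
    masks, kp_sets, paints = [], [], []
    centers = []
    for i in range(n):
        rng = np.random.default_rng(inst_streams[i])
        want_overlap = bool(centers) and rng.uniform() < cfg.occlusion_prob
        for attempt in range(40):
            mask, kps, paint = _place_instance(
                shape_fn, rng, (h, w), margin, centers, want_overlap
            )
            if cfg.occlusion_prob > 0:
                break
            # occlusion disabled: demand clear separation from prior bodies
            union = np.zeros((h, w), dtype=bool)
            for m in masks:
                union |= ndimage.binary_dilation(m, iterations=4)
            if not (mask & union).any():
                break
        else:
            raise PlacementError("cannot place non-overlapping instance")
        masks.append(mask)
        kp_sets.append(kps)
        paints.append(paint)
        centers.append(kps.mean(axis=0))

    # compose image: later instances painted over earlier
    if cfg.background == "textured":
        image = 0.82 + 0.06 * ndimage.gaussian_filter(bg_rng.normal(size=(h, w)), 3.0)
    else:
        image = np.full((h, w), 0.85)
    for mask, paint in zip(masks, paints):
        image[mask] = paint
    if cfg.glare_prob > 0 and bg_rng.uniform() < cfg.glare_prob:
        gy, gx = bg_rng.uniform(0, h), bg_rng.uniform(0, w)
        yy, xx = np.mgrid[0:h, 0:w]
        sigma = 0.15 * min(h, w)
        image = image + 0.5 * np.exp(-((yy - gy) ** 2 + (xx - gx) ** 2) / (2 * sigma**2))
    if cfg.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, cfg.blur_sigma)
    image = np.clip(image, 0.0, 1.0)
    image = np.repeat(image[:, :, None], 3, axis=2)

    # visibility: keypoints of earlier instances hidden by later foreground
    yy, xx = np.mgrid[-3:4, -3:4]
    disc = (yy**2 + xx**2 <= 9).astype(float)
    instances, overlaps = [], []
    union_all = np.zeros((h, w), dtype=bool)
    for m in masks:
        union_all |= m
    for i, (mask, kps) in enumerate(zip(masks, kp_sets)):
        later = np.zeros((h, w), dtype=bool)
        for m in masks[i + 1 :]:
            later |= m
        v = np.full(len(kps), 2.0)
        for j, (x, y) in enumerate(kps):
            xi, yi = int(round(x)), int(round(y))
            y0, y1 = max(0, yi - 3), min(h, yi + 4)
            x0, x1 = max(0, xi - 3), min(w, xi + 4)
            patch = later[y0:y1, x0:x1]
            dpatch = disc[(y0 - yi + 3) : (y1 - yi + 3), (x0 - xi + 3) : (x1 - xi + 3)]
            if dpatch.sum() > 0 and (patch * dpatch).sum() / dpatch.sum() >= 0.6:
                v[j] = 1.0
        inst = PoseInstance(
            keypoints=np.column_stack([kps, v]), instance_id=i
        )
        inst.center = instance_center(inst, schema)
        inst.scale_s = inst.compute_scale()
        instances.append(inst)
        others = union_all & ~mask
        overlap = 0.0
        area = mask.sum()
        if area:
            overlap = float((mask & (later | (others & ~later))).sum()) / float(area)
        overlaps.append(overlap)

    return SceneSample(
        image=image,
        instances=instances,
        config=cfg,
        masks=masks,
        overlap_fraction=overlaps,
    )


def generate_dataset(cfg: SceneConfig, n_images: int, schema=None) -> list:
    """A list of scenes with per-image seeds derived from cfg.seed."""
    samples = []
    for i in range(n_images):
        sample = generate_scene(replace(cfg, seed=(cfg.seed + 1) * 100003 + i), schema)
        sample.image_id = i + 1
        samples.append(sample)
    return samples


# ---------------------------------------------------------------------------
# COCO-keypoints I/O


def write_coco(samples: list, out_dir, schema: SkeletonSchema | None = None,
               file_prefix: str = "scene") -> Path:
    """Write PNG images and a COCO-keypoints annotation file.

    Coordinates are rounded to 2 decimals; read_coco round-trips losslessly
    at that precision.
    """
    from PIL import Image

    if not samples:
        raise ValueError("no samples to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species = samples[0].config.species if samples[0].config else (schema.species if schema else "celegans")
    schema = schema or builtin_schema(species)
    images, annotations = [], []
    ann_id = 1
    for i, s in enumerate(samples):
        image_id = s.image_id or (i + 1)
        fname = s.file_name or f"{file_prefix}_{image_id:05d}.png"
        h, w = s.image_size if s.image_size else s.image.shape[:2]
        if s.image is not None:
            arr = (np.clip(s.image, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(arr).save(out_dir / fname)
        images.append({"id": image_id, "file_name": fname, "height": int(h), "width": int(w)})
        for inst in s.instances:
            kps = inst.keypoints.copy()
            kps[:, :2] = np.round(kps[:, :2], 2)
            vis = kps[:, 2] > 0
            flat = kps.copy()
            flat[~vis, :2] = 0.0
            if vis.any():
                x0, y0 = kps[vis, 0].min(), kps[vis, 1].min()
                x1, y1 = kps[vis, 0].max(), kps[vis, 1].max()
            else:
                x0 = y0 = x1 = y1 = 0.0
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": image_id,
                    "category_id": 1,
                    "keypoints": [round(float(v), 2) for v in flat.ravel()],
                    "num_keypoints": int(vis.sum()),
                    "bbox": [round(float(x0), 2), round(float(y0), 2),
                             round(float(x1 - x0), 2), round(float(y1 - y0), 2)],
                    "area": round(float((x1 - x0) * (y1 - y0)), 2),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {
                "id": 1,
                "name": schema.species,
                "supercategory": "animal",
                "keypoints": [k.name for k in schema.keypoints],
                "skeleton": [[a + 1, b + 1] for a, b in schema.skeleton_edges],
            }
        ],
    }
    path = out_dir / "annotations.json"
    path.write_text(json.dumps(doc))
    return path


def read_coco(path, schema: SkeletonSchema | None = None) -> list:
    """Read the documented COCO-keypoints dialect back into SceneSamples.

    Images are left lazy (``image=None``); use :func:`load_image` to read
    pixel data for a sample.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    cats = {c["id"]: c for c in doc.get("categories", [])}
    if schema is None:
        if not cats:
            raise ValueError("annotation file has no categories; pass a schema explicitly")
        name = next(iter(cats.values()))["name"]
        try:
            schema = builtin_schema(name)
        except KeyError as exc:
            raise KeyError(
                f"cannot resolve schema for category {name!r}; pass one explicitly"
            ) from exc
    k = schema.n_keypoints
    by_image: dict[int, list] = {}
    for ann in doc.get("annotations", []):
        flat = ann["keypoints"]
        if len(flat) != 3 * k:
            raise ValueError(
                f"annotation {ann.get('id')}: expected {3 * k} keypoint values, got {len(flat)}"
            )
        kps = np.asarray(flat, dtype=float).reshape(k, 3)
        inst = PoseInstance(keypoints=kps, instance_id=int(ann.get("id", -1)))
        if (kps[:, 2] > 0).any():
            inst.center = instance_center(inst, schema)
            inst.scale_s = inst.compute_scale()
        by_image.setdefault(int(ann["image_id"]), []).append(inst)
    samples = []
    for im in doc["images"]:
        samples.append(
            SceneSample(
                image=None,
                instances=by_image.get(int(im["id"]), []),
                image_id=int(im["id"]),
                file_name=im.get("file_name", ""),
                image_size=(int(im["height"]), int(im["width"])),
            )
        )
    return samples


def load_image(sample: SceneSample, root) -> np.ndarray:
    from PIL import Image

    arr = np.asarray(Image.open(Path(root) / sample.file_name), dtype=float) / 255.0
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    sample.image = arr[:, :, :3]
    return sample.image
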
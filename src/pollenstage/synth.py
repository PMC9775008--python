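"""Synthetic whole-slide corpus generator with exact ground truth.

Emulates, at desk scale, the statistical structure of stained airborne-pollen
slide scans: a pale, near-uniform background that dominates the raster
(extreme foreground/background imbalance), pink-toned regular pollen grains
of 8 mutually confusable taxa, yellow/brown irregular impurities, and
colorless circular bubbles. Object placement is a homogeneous Poisson
process; boxes crossing the slide border are rejected and pairwise overlap
is capped so that detection matching stays unambiguous.

Everything is driven by a single integer seed: the same (config, seed) pair
reproduces pixel arrays and annotations byte for byte.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import resize

logger = logging.getLogger(__name__)

COARSE_CLASSES = ("pollen", "impurity", "bubble")

#: The eight allergenic taxa tracked by the fine-grained classifier.
FINE_CLASSES = (
    "Artemisia",
    "Gramineae",
    "Chenopodiaceae",
    "Cupressaceae",
    "Pinaceae",
    "Populus",
    "Salix",
    "Moraceae",
)

#: Default per-taxon sampling weights mirroring the relative abundances of a
#: typical aeropalynological collection (Populus and Salix under-represented).
DEFAULT_CLASS_COUNTS = (1640, 1580, 1930, 1750, 1400, 910, 870, 1020)


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class RegionAnnotation:
    """Axis-aligned box in 0-based half-open pixel coordinates.

    ``fine`` is the 1-based taxon index for pollen regions, None otherwise.
    """

    x0: int
    y0: int
    x1: int
    y1: int
    coarse: str
    fine: int | None = None

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def as_xyxy(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)


@dataclass
class SlideImage:
    slide_id: str
    pixels: np.ndarray  # (H, W, 3) uint8

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class GroundTruth:
    """Boxes plus the patch-level foreground mask derived from them.

    ``patch_labels[i, j]`` is True iff the patch with origin
    (j * patch_size, i * patch_size) intersects at least one object box.
    """

    boxes: list[RegionAnnotation]
    patch_labels: np.ndarray
    patch_size: int

    @property
    def fine_labels(self) -> list[int]:
        return [b.fine for b in self.boxes if b.coarse == "pollen"]

    @property
    def pollen_boxes(self) -> list[RegionAnnotation]:
        return [b for b in self.boxes if b.coarse == "pollen"]


@dataclass(frozen=True)
class SynthConfig:
    slide_width: int = 4096
    slide_height: int = 2048
    patch_size: int = 512
    n_pollen_classes: int = 8
    grain_density: float = 4.0  # expected grains per megapixel
    impurity_density: float = 1.5
    bubble_density: float = 1.5
    class_weights: tuple[float, ...] | None = None
    confusability: float = 0.0
    diameter_range: tuple[float, float] = (30.0, 90.0)
    max_pair_iou: float = 0.3
    seed: int = 0

    def resolved_weights(self) -> np.ndarray:
        if self.class_weights is None:
            counts = np.asarray(DEFAULT_CLASS_COUNTS[: self.n_pollen_classes], float)
            if len(counts) < self.n_pollen_classes:
                counts = np.ones(self.n_pollen_classes)
            return counts / counts.sum()
        return np.asarray(self.class_weights, float)

    def validate(self) -> None:
        if self.slide_width <= 0 or self.slide_height <= 0 or self.patch_size <= 0:
            raise ConfigError("slide dimensions and patch size must be positive")
        if min(self.slide_width, self.slide_height) < 2 * self.patch_size:
            raise ConfigError("slide dimensions must be at least 2x the patch size")
        for d in (self.grain_density, self.impurity_density, self.bubble_density):
            if d < 0:
                raise ConfigError("densities must be non-negative")
        w = self.resolved_weights()
        if len(w) != self.n_pollen_classes:
            raise ConfigError("class_weights length must equal n_pollen_classes")
        if abs(float(w.sum()) - 1.0) > 1e-9 or (w < 0).any():
            raise ConfigError("class_weights must be non-negative and sum to 1")
        if not 0.0 <= self.confusability <= 1.0:
            raise ConfigError("confusability must lie in [0, 1]")
        if self.diameter_range[0] <= 0 or self.diameter_range[1] < self.diameter_range[0]:
            raise ConfigError("invalid diameter range")


# ---------------------------------------------------------------------------
# Morph parameterization
#
# Each taxon k is a point in morph space: (lobe count, radius jitter,
# green-channel offset, blue-channel offset, texture frequency). The
# confusability knob linearly interpolates every class vector toward the
# across-class mean, shrinking inter-class distances to zero at 1.0.
# ---------------------------------------------------------------------------

# Class colors are spread over the (green, blue) plane (red pinned high, so
# everything stays pink-toned) rather than along a line: at confusability 0
# every pair of taxa is separated by a comparable color margin, and lobe
# count / texture frequency add shape and exine-pattern cues.
_BASE_MORPHS = np.array(
    # lobes, jitter, green, blue, tex_freq
    [
        [3, 0.06, 95.0, 135.0, 2.0],
        [5, 0.05, 165.0, 135.0, 5.0],
        [7, 0.07, 95.0, 195.0, 8.0],
        [9, 0.04, 165.0, 195.0, 3.0],
        [4, 0.06, 130.0, 120.0, 6.0],
        [6, 0.05, 130.0, 210.0, 9.0],
        [8, 0.07, 100.0, 165.0, 4.0],
        [10, 0.04, 160.0, 165.0, 7.0],
    ]
)

_POLLEN_RED = 228.0


def class_morphs(config: SynthConfig) -> np.ndarray:
    """Per-class morph parameter matrix after confusability interpolation."""
    c = config.n_pollen_classes
    base = _BASE_MORPHS[np.linspace(0, len(_BASE_MORPHS) - 1, c).round().astype(int)]
    mean = base.mean(axis=0, keepdims=True)
    t = config.confusability
    return (1.0 - t) * base + t * mean


def _star_mask(h: int, w: int, radius: float, lobes: float, jitter: float,
               phase: float) -> np.ndarray:
    """Star-convex mask: r(theta) = R * (1 + jitter * cos(lobes*theta + phase))."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    rim = radius * (1.0 + jitter * np.cos(lobes * theta + phase))
    return r <= rim, r, rim


def _render_pollen(img: np.ndarray, box: RegionAnnotation, morph: np.ndarray,
                   rng: np.random.Generator) -> None:
    lobes, jitter, green, blue, tex = morph
    h, w = box.height, box.width
    radius = min(h, w) / 2.0 / (1.0 + jitter)
    phase = rng.uniform(0, 2 * np.pi)
    mask, r, rim = _star_mask(h, w, radius, lobes, jitter, phase)
    color = np.array([_POLLEN_RED, green, blue])
    tile = img[box.y0 : box.y1, box.x0 : box.x1].astype(np.float64)
    rel = np.divide(r, rim, out=np.zeros_like(r), where=rim > 0)
    shading = 1.0 + 0.10 * np.cos(2 * np.pi * tex * rel)  # radial exine texture
    shading *= 1.0 - 0.25 * np.clip(rel - 0.8, 0, 0.2) / 0.2  # darker rim
    body = color[None, None, :] * shading[:, :, None]
    body += rng.normal(0, 3.0, size=body.shape)
    tile[mask] = body[mask]
    img[box.y0 : box.y1, box.x0 : box.x1] = np.clip(tile, 0, 255).astype(np.uint8)


def _render_impurity(img: np.ndarray, box: RegionAnnotation,
                     rng: np.random.Generator) -> None:
    h, w = box.height, box.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy)
    theta = np.arctan2(yy - cy, xx - cx)
    # irregular blob: random low-order Fourier boundary with large amplitude
    rim = np.full_like(theta, min(h, w) / 2.0 * 0.55)
    for k in range(2, 6):
        rim *= 1.0 + rng.uniform(0.08, 0.22) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    mask = r <= rim
    base = np.array([rng.uniform(150, 185), rng.uniform(110, 150), rng.uniform(40, 75)])
    tile = img[box.y0 : box.y1, box.x0 : box.x1].astype(np.float64)
    body = base[None, None, :] * (1.0 + rng.normal(0, 0.08, size=(h, w, 1)))
    tile[mask] = body[mask]
    img[box.y0 : box.y1, box.x0 : box.x1] = np.clip(tile, 0, 255).astype(np.uint8)


def _render_bubble(img: np.ndarray, box: RegionAnnotation,
                   rng: np.random.Generator) -> None:
    h, w = box.height, box.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy)
    radius = min(h, w) / 2.0 - 1.0
    tile = img[box.y0 : box.y1, box.x0 : box.x1].astype(np.float64)
    interior = r <= radius - 2.5
    rim = (r <= radius) & ~interior
    tile[interior] = np.clip(tile[interior] * 1.04 + 4.0, 0, 255)  # faintly brighter
    tile[rim] = 150.0  # thin gray rim
    img[box.y0 : box.y1, box.x0 : box.x1] = np.clip(tile, 0, 255).astype(np.uint8)


def _box_iou_xyxy(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    ix = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua


def _place_objects(config: SynthConfig, rng: np.random.Generator) -> list[RegionAnnotation]:
    area_mp = config.slide_width * config.slide_height / 1e6
    weights = config.resolved_weights()
    lo, hi = config.diameter_range
    placed: list[RegionAnnotation] = []

    for coarse, density in (
        ("pollen", config.grain_density),
        ("impurity", config.impurity_density),
        ("bubble", config.bubble_density),
    ):
        target = int(rng.poisson(density * area_mp))
        attempts = 0
        count = 0
        while count < target and attempts < 60 * max(target, 1):
            attempts += 1
            d = rng.uniform(lo, hi)
            side = int(np.ceil(d))
            if side >= min(config.slide_width, config.slide_height):
                continue
            x0 = int(rng.integers(0, config.slide_width - side + 1))
            y0 = int(rng.integers(0, config.slide_height - side + 1))
            cand = (x0, y0, x0 + side, y0 + side)
            if any(_box_iou_xyxy(cand, p.as_xyxy()) > config.max_pair_iou for p in placed):
                continue
            fine = None
            if coarse == "pollen":
                fine = int(rng.choice(config.n_pollen_classes, p=weights)) + 1
            placed.append(RegionAnnotation(*cand, coarse=coarse, fine=fine))
            count += 1
        if count < target:
            logger.warning("placed %d/%d %s objects (overlap cap)", count, target, coarse)
    return placed


def compute_patch_labels(boxes: list[RegionAnnotation], slide_w: int, slide_h: int,
                         patch_size: int) -> np.ndarray:
    """Foreground mask over the non-overlapping patch grid.

    A patch is foreground iff it intersects at least one object box.
    """
    nx, ny = slide_w // patch_size, slide_h // patch_size
    labels = np.zeros((ny, nx), dtype=bool)
    for b in boxes:
        j0 = max(0, b.x0 // patch_size)
        j1 = min(nx - 1, (b.x1 - 1) // patch_size)
        i0 = max(0, b.y0 // patch_size)
        i1 = min(ny - 1, (b.y1 - 1) // patch_size)
        if j0 <= j1 and i0 <= i1:
            labels[i0 : i1 + 1, j0 : j1 + 1] = True
    return labels


def generate_slide(config: SynthConfig, slide_id: str = "slide-0") -> tuple[SlideImage, GroundTruth]:
    """Render one synthetic slide and its exact ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.slide_height, config.slide_width

    # pale near-uniform field with smooth low-amplitude mottle
    base = np.array([238.0, 234.0, 228.0])
    coarse_noise = rng.normal(0, 3.0, size=(max(h // 32, 1), max(w // 32, 1), 3))
    mottle = resize(coarse_noise, (h, w, 3), order=1, mode="edge", anti_aliasing=False)
    img = np.clip(base[None, None, :] + mottle + rng.normal(0, 1.5, size=(h, w, 3)),
                  0, 255).astype(np.uint8)

    boxes = _place_objects(config, rng)
    morphs = class_morphs(config)
    for b in boxes:
        if b.coarse == "pollen":
            _render_pollen(img, b, morphs[b.fine - 1], rng)
        elif b.coarse == "impurity":
            _render_impurity(img, b, rng)
        else:
            _render_bubble(img, b, rng)

    labels = compute_patch_labels(boxes, w, h, config.patch_size)
    return SlideImage(slide_id, img), GroundTruth(boxes, labels, config.patch_size)


def generate_corpus(config: SynthConfig, n_slides: int) -> list[tuple[SlideImage, GroundTruth]]:
    """Generate ``n_slides`` independent slides; slide i uses seed config.seed + i."""
    out = []
    for i in range(n_slides):
        cfg = replace(config, seed=config.seed + i)
        out.append(generate_slide(cfg, slide_id=f"slide-{i}"))
    return out


# ---------------------------------------------------------------------------
# Derived datasets: D1-like patches, D2-like annotated patches, D3-like crops
# ---------------------------------------------------------------------------


@dataclass
class PatchDataset:
    """Foreground/background patch set (the patch-filter training data)."""

    images: list[np.ndarray]  # (l, l, 3) uint8
    labels: np.ndarray  # 1 = foreground, 0 = background
    provenance: list[tuple[str, int, int]]  # (slide_id, x0, y0)

    def __len__(self) -> int:
        return len(self.images)


def build_d1(
    corpus: list[tuple[SlideImage, GroundTruth]],
    patch_size: int | None = None,
    n_foreground: int | None = None,
    n_background: int | None = None,
    seed: int = 0,
) -> PatchDataset:
    """Extract labeled fg/bg patches from the non-overlapping grid.

    With ``n_foreground``/``n_background`` set, subsamples each stratum to the
    requested count (error if a slide pool is too small); otherwise returns
    every grid patch.
    """
    images, labels, prov = [], [], []
    for slide, truth in corpus:
        ps = patch_size or truth.patch_size
        grid = (
            truth.patch_labels
            if ps == truth.patch_size
            else compute_patch_labels(truth.boxes, slide.width, slide.height, ps)
        )
        ny, nx = grid.shape
        for i in range(ny):
            for j in range(nx):
                x0, y0 = j * ps, i * ps
                images.append(slide.pixels[y0 : y0 + ps, x0 : x0 + ps])
                labels.append(int(grid[i, j]))
                prov.append((slide.slide_id, x0, y0))
    labels_arr = np.asarray(labels, int)

    if n_foreground is None and n_background is None:
        return PatchDataset(images, labels_arr, prov)

    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for lab, want in ((1, n_foreground), (0, n_background)):
        idx = np.flatnonzero(labels_arr == lab)
        if want is None:
            keep.extend(idx)
            continue
        if len(idx) < want:
            raise ValueError(f"requested {want} patches of label {lab}, only {len(idx)} available")
        keep.extend(rng.choice(idx, size=want, replace=False))
    keep = sorted(keep)
    return PatchDataset(
        [images[i] for i in keep], labels_arr[keep], [prov[i] for i in keep]
    )


@dataclass
class DetectionSample:
    image: np.ndarray  # (l, l, 3) uint8
    boxes: list[RegionAnnotation]  # coordinates local to the patch
    provenance: tuple[str, int, int]


def build_d2(
    corpus: list[tuple[SlideImage, GroundTruth]],
    patch_size: int | None = None,
    min_visible: float = 0.4,
    foreground_only: bool = True,
) -> list[DetectionSample]:
    """Annotated detection patches: grid patches with their clipped boxes.

    A box is attached to a patch when at least ``min_visible`` of its area
    falls inside; coordinates are shifted to the patch frame.
    """
    samples = []
    for slide, truth in corpus:
        ps = patch_size or truth.patch_size
        ny, nx = slide.height // ps, slide.width // ps
        for i in range(ny):
            for j in range(nx):
                x0, y0 = j * ps, i * ps
                local = []
                for b in truth.boxes:
                    cx0, cy0 = max(b.x0, x0), max(b.y0, y0)
                    cx1, cy1 = min(b.x1, x0 + ps), min(b.y1, y0 + ps)
                    if cx1 <= cx0 or cy1 <= cy0:
                        continue
                    if (cx1 - cx0) * (cy1 - cy0) < min_visible * b.area:
                        continue
                    local.append(
                        RegionAnnotation(cx0 - x0, cy0 - y0, cx1 - x0, cy1 - y0,
                                         coarse=b.coarse, fine=b.fine)
                    )
                if local or not foreground_only:
                    samples.append(
                        DetectionSample(
                            slide.pixels[y0 : y0 + ps, x0 : x0 + ps],
                            local,
                            (slide.slide_id, x0, y0),
                        )
                    )
    return samples


@dataclass
class CropDataset:
    """Fine-grained classification crops (one per pollen box)."""

    images: list[np.ndarray]  # (s, s, 3) uint8
    labels: np.ndarray  # 1-based taxon indices

    def __len__(self) -> int:
        return len(self.images)


def crop_box(image: np.ndarray, box: RegionAnnotation, out_size: int) -> np.ndarray:
    """Square crop around the box center, resized to out_size."""
    side = max(box.width, box.height)
    cx, cy = (box.x0 + box.x1) / 2.0, (box.y0 + box.y1) / 2.0
    x0 = int(round(cx - side / 2.0))
    y0 = int(round(cy - side / 2.0))
    h, w = image.shape[:2]
    x0 = min(max(x0, 0), max(w - side, 0))
    y0 = min(max(y0, 0), max(h - side, 0))
    crop = image[y0 : y0 + side, x0 : x0 + side]
    out = resize(crop, (out_size, out_size, 3), order=1, anti_aliasing=True,
                 preserve_range=True)
    return np.clip(out, 0, 255).astype(np.uint8)


def build_d3(
    corpus: list[tuple[SlideImage, GroundTruth]],
    crop_size: int = 100,
    box_jitter: float = 0.0,
    jitter_seed: int = 0,
) -> CropDataset:
    """Crop every annotated pollen box around its center at crop_size.

    ``box_jitter`` > 0 perturbs each box before cropping (center shifted by
    up to ``box_jitter`` of the side, side scaled in [1, 1+2*box_jitter]),
    emulating the looser boxes a detector produces so that downstream
    classifiers are trained on realistic framing.
    """
    rng = np.random.default_rng(jitter_seed)
    images, labels = [], []
    for slide, truth in corpus:
        for b in truth.pollen_boxes:
            if b.area == 0:
                warnings.warn(f"skipping degenerate box {b.as_xyxy()} on {slide.slide_id}")
                continue
            box = b
            if box_jitter > 0:
                side = max(b.width, b.height)
                cx = (b.x0 + b.x1) / 2 + rng.uniform(-box_jitter, box_jitter) * side
                cy = (b.y0 + b.y1) / 2 + rng.uniform(-box_jitter, box_jitter) * side
                s = side * rng.uniform(1.0, 1.0 + 2 * box_jitter)
                box = RegionAnnotation(
                    int(round(cx - s / 2)), int(round(cy - s / 2)),
                    int(round(cx + s / 2)), int(round(cy + s / 2)),
                    coarse=b.coarse, fine=b.fine,
                )
            images.append(crop_box(slide.pixels, box, crop_size))
            labels.append(b.fine)
    return CropDataset(images, np.asarray(labels, int))


def augment(crop: np.ndarray, rng: np.random.Generator | None = None,
            transform: int | None = None) -> np.ndarray:
    """Apply one of the 8 dihedral transforms (flips and 90-degree rotations).

    ``transform`` in 0..7 selects rot90^k (k=t%4) with an optional horizontal
    flip first (t>=4); drawn uniformly when omitted. Labels are unaffected.
    """
    if crop.shape[0] != crop.shape[1]:
        raise ValueError("augment requires a square crop")
    if transform is None:
        if rng is None:
            raise ValueError("provide either a transform index or an rng")
        transform = int(rng.integers(0, 8))
    if not 0 <= transform < 8:
        raise ValueError("transform index must be in 0..7")
    out = crop[:, ::-1] if transform >= 4 else crop
    return np.ascontiguousarray(np.rot90(out, k=transform % 4))


def augment_crops(d3: CropDataset, n_extra: int, seed: int = 0) -> CropDataset:
    """Extend a crop dataset with ``n_extra`` distinct dihedral transforms of
    every crop (labels preserved) — the flip/rotation augmentation used to
    counter per-class scarcity."""
    if n_extra <= 0:
        return d3
    rng = np.random.default_rng(seed)
    images = list(d3.images)
    labels = list(d3.labels)
    for img, lab in zip(d3.images, d3.labels):
        picks = rng.choice(np.arange(1, 8), size=min(n_extra, 7), replace=False)
        for t in picks:
            images.append(augment(img, transform=int(t)))
            labels.append(lab)
    return CropDataset(images, np.asarray(labels, int))


# ---------------------------------------------------------------------------
# I/O: COCO-style JSON, patch-label CSV, PNG slides
# ---------------------------------------------------------------------------


def to_coco(corpus: list[tuple[SlideImage, GroundTruth]], fine_categories: bool = False) -> dict:
    """COCO-style dict with 0-based (x, y, width, height) boxes.

    Coarse categories by default; ``fine_categories`` swaps pollen boxes to
    per-taxon categories.
    """
    if fine_categories:
        cats = [{"id": i + 1, "name": n} for i, n in enumerate(FINE_CLASSES)]
    else:
        cats = [{"id": i + 1, "name": n} for i, n in enumerate(COARSE_CLASSES)]
    images, anns = [], []
    aid = 1
    for img_id, (slide, truth) in enumerate(corpus, start=1):
        images.append(
            {"id": img_id, "file_name": f"{slide.slide_id}.png",
             "width": slide.width, "height": slide.height}
        )
        for b in truth.boxes:
            if fine_categories:
                if b.coarse != "pollen":
                    continue
                cat = b.fine
            else:
                cat = COARSE_CLASSES.index(b.coarse) + 1
            entry = {"id": aid, "image_id": img_id, "category_id": cat,
                     "bbox": [b.x0, b.y0, b.width, b.height],
                     "area": b.area, "iscrowd": 0}
            if not fine_categories and b.fine is not None:
                entry["fine"] = b.fine  # taxon index carried alongside coarse class
            anns.append(entry)
            aid += 1
    return {"images": images, "annotations": anns, "categories": cats}


def save_coco(corpus: list[tuple[SlideImage, GroundTruth]], path: str, **kw) -> None:
    with open(path, "w") as fh:
        json.dump(to_coco(corpus, **kw), fh)


def patch_labels_to_frame(corpus: list[tuple[SlideImage, GroundTruth]]) -> pd.DataFrame:
    rows = []
    for slide, truth in corpus:
        ps = truth.patch_size
        ny, nx = truth.patch_labels.shape
        for i in range(ny):
            for j in range(nx):
                rows.append(
                    (slide.slide_id, j * ps, i * ps, ps, int(truth.patch_labels[i, j]))
                )
    return pd.DataFrame(rows, columns=["slide_id", "x0", "y0", "size", "label"])
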
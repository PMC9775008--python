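"""Coarse-grained pollen localization.

A single-shot anchor-based detector at desk scale. Dense anchors are laid
over a multi-scale feature pyramid (top-down aggregation across levels when
fusion is enabled; a single level when it is not), a classification head is
trained with the focal loss

    FL(p_t) = -(1 - p_t)^gamma * log(p_t)

(alpha-balanced during training), and a box-regression head is trained with
the smooth-L1 loss on encoded center/log-size offsets

    L_loc = sum_{i in (x, y, w, h)} SmoothL1(t_i - v_i).

The backbone is a fixed multi-scale descriptor pyramid (per-cell color
statistics and gradient energy with local context, plus pooled per-anchor
box statistics from integral images) rather than a deep learned stack; the
heads share a small hidden ReLU trunk. At the patch sizes and object
contrasts this package targets, this trains in minutes on one CPU while
preserving the anchor/assignment/loss structure of the full-size detector.

Coordinates are 0-based half-open (x_min, y_min, x_max, y_max) internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .synth import COARSE_CLASSES, DetectionSample, RegionAnnotation, crop_box

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

PT_CLAMP = 1e-7


def focal_loss(pt, gamma: float = 2.0):
    """Focal loss of the true-class probability: (1-pt)^gamma * (-log pt).

    gamma=0 reduces exactly to cross-entropy. ``pt`` is clamped to
    [1e-7, 1] so pt <= 0 is tolerated rather than an error.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    pt = np.clip(np.asarray(pt, dtype=float), PT_CLAMP, 1.0)
    out = (1.0 - pt) ** gamma * (-np.log(pt))
    return float(out) if out.ndim == 0 else out


def smooth_l1(x):
    """Smooth-L1: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise (continuous at 1)."""
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    out = np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)
    return float(out) if out.ndim == 0 else out


def encode_offsets(anchor, box) -> np.ndarray:
    """Standard center/log-size offsets of ``box`` relative to ``anchor``.

    Both are (x0, y0, x1, y1); returns (tx, ty, tw, th) with
    tx = (bx - ax)/aw, tw = log(bw/aw), etc.
    """
    anchor = np.asarray(anchor, float)
    box = np.asarray(box, float)
    aw, ah = anchor[..., 2] - anchor[..., 0], anchor[..., 3] - anchor[..., 1]
    bw, bh = box[..., 2] - box[..., 0], box[..., 3] - box[..., 1]
    if np.any(aw <= 0) or np.any(ah <= 0) or np.any(bw <= 0) or np.any(bh <= 0):
        raise ValueError("anchor and box sizes must be positive")
    ax, ay = anchor[..., 0] + aw / 2, anchor[..., 1] + ah / 2
    bx, by = box[..., 0] + bw / 2, box[..., 1] + bh / 2
    return np.stack([(bx - ax) / aw, (by - ay) / ah, np.log(bw / aw), np.log(bh / ah)],
                    axis=-1)


def decode_offsets(anchor, offsets) -> np.ndarray:
    """Inverse of :func:`encode_offsets`."""
    anchor = np.asarray(anchor, float)
    offsets = np.asarray(offsets, float)
    aw, ah = anchor[..., 2] - anchor[..., 0], anchor[..., 3] - anchor[..., 1]
    if np.any(aw <= 0) or np.any(ah <= 0):
        raise ValueError("anchor sizes must be positive")
    ax, ay = anchor[..., 0] + aw / 2, anchor[..., 1] + ah / 2
    bx = ax + offsets[..., 0] * aw
    by = ay + offsets[..., 1] * ah
    bw = aw * np.exp(offsets[..., 2])
    bh = ah * np.exp(offsets[..., 3])
    return np.stack([bx - bw / 2, by - bh / 2, bx + bw / 2, by + bh / 2], axis=-1)


def regression_loss(pred_box, gt_box, anchor) -> float:
    """L_loc: smooth-L1 summed over the four encoded offset components."""
    gt = np.asarray(gt_box, float)
    if gt[2] - gt[0] <= 0 or gt[3] - gt[1] <= 0:
        raise ValueError("ground-truth box must have positive width and height")
    t = encode_offsets(anchor, pred_box)
    v = encode_offsets(anchor, gt_box)
    return float(smooth_l1(t - v).sum())


# ---------------------------------------------------------------------------
# Anchors, assignment, suppression
# ---------------------------------------------------------------------------


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) xyxy boxes."""
    a = np.asarray(a, float).reshape(-1, 4)
    b = np.asarray(b, float).reshape(-1, 4)
    ix = np.clip(
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
        0, None,
    )
    iy = np.clip(
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
        0, None,
    )
    inter = ix * iy
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.divide(inter, union, out=np.zeros_like(inter), where=union > 0)


NEGATIVE = -1
IGNORE = -2


def assign_anchors(anchors, gt_boxes, pos_thr: float = 0.5, neg_thr: float = 0.4) -> np.ndarray:
    """Per-anchor assignment: gt index (>=0), NEGATIVE (-1), or IGNORE (-2).

    An anchor is positive when its max IoU >= pos_thr (assigned to the argmax
    ground truth), negative when max IoU < neg_thr, else ignored. Every
    ground truth with at least one anchor of nonzero IoU also claims its
    best-IoU anchor (the best-anchor fallback), so no reachable object is
    left without a positive.
    """
    if pos_thr < neg_thr:
        raise ValueError("pos_thr must be >= neg_thr")
    anchors = np.asarray(anchors, float).reshape(-1, 4)
    out = np.full(len(anchors), NEGATIVE, dtype=int)
    gt = np.asarray(gt_boxes, float).reshape(-1, 4)
    if len(gt) == 0:
        return out
    iou = iou_matrix(anchors, gt)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(len(anchors)), best_gt]
    out[best_iou >= pos_thr] = best_gt[best_iou >= pos_thr]
    out[(best_iou < pos_thr) & (best_iou >= neg_thr)] = IGNORE
    for g in range(len(gt)):
        col = iou[:, g]
        if col.max() > 0:
            out[int(col.argmax())] = g
    return out


def nms(boxes, scores, iou_threshold: float = 0.5) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, descending score
    (ties broken toward the earlier index)."""
    boxes = np.asarray(boxes, float).reshape(-1, 4)
    scores = np.asarray(scores, float)
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    while len(order):
        i = int(order[0])
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i], boxes[rest])[0]
        order = rest[ious < iou_threshold]
    return np.asarray(keep, int)


@dataclass(frozen=True)
class AnchorGrid:
    """Pyramid anchor layout: per level a stride and base size, shared aspect
    ratios and scale multipliers (the canonical single-shot configuration,
    reduced to three levels at desk scale)."""

    strides: tuple[int, ...] = (8, 16, 32)
    base_sizes: tuple[int, ...] = (32, 64, 128)
    ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    scales: tuple[float, ...] = (1.0, 2 ** (1.0 / 3.0), 2 ** (2.0 / 3.0))

    @property
    def anchors_per_cell(self) -> int:
        return len(self.ratios) * len(self.scales)

    def level_anchors(self, level: int, feat_h: int, feat_w: int) -> np.ndarray:
        """(feat_h * feat_w * A, 4) anchors, cell-major (row-major cells,
        then ratio-major/scale-minor slots)."""
        stride, base = self.strides[level], self.base_sizes[level]
        shapes = []
        for r in self.ratios:
            for s in self.scales:
                size = base * s
                w = size * np.sqrt(1.0 / r)
                h = size * np.sqrt(r)
                shapes.append((w, h))
        shapes = np.asarray(shapes)  # (A, 2)
        cy, cx = np.mgrid[0:feat_h, 0:feat_w]
        centers = np.stack([(cx + 0.5) * stride, (cy + 0.5) * stride], axis=-1)
        centers = centers.reshape(-1, 1, 2)
        half = shapes[None, :, :] / 2.0
        lo = centers - half
        hi = centers + half
        return np.concatenate([lo, hi], axis=-1).reshape(-1, 4)


# ---------------------------------------------------------------------------
# Descriptor pyramid backbone
# ---------------------------------------------------------------------------


def _cell_stats(img: np.ndarray, stride: int) -> np.ndarray:
    """(H/s, W/s, 7): per-cell RGB means, RGB stds, gradient-energy mean."""
    h, w = img.shape[:2]
    hh, ww = h // stride, w // stride
    x = img[: hh * stride, : ww * stride].astype(np.float32) / 255.0
    cells = x.reshape(hh, stride, ww, stride, 3)
    mean = cells.mean(axis=(1, 3))
    sq = (cells**2).mean(axis=(1, 3))
    std = np.sqrt(np.clip(sq - mean**2, 0, None))
    gray = x.mean(axis=2)
    gy, gx = np.gradient(gray)
    grad = np.hypot(gx, gy).reshape(hh, stride, ww, stride).mean(axis=(1, 3))
    return np.concatenate([mean, std, grad[:, :, None]], axis=2)


def _context(feat: np.ndarray) -> np.ndarray:
    """3x3 neighborhood mean of cell features (edge-padded)."""
    p = np.pad(feat, ((1, 1), (1, 1), (0, 0)), mode="edge")
    out = np.zeros_like(feat)
    for di in range(3):
        for dj in range(3):
            out += p[di : di + feat.shape[0], dj : dj + feat.shape[1]]
    return out / 9.0


def _upsample2(feat: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    up = np.repeat(np.repeat(feat, 2, axis=0), 2, axis=1)
    return up[:out_h, :out_w]


def compute_pyramid(img: np.ndarray, grid: AnchorGrid, fusion: bool) -> list[np.ndarray]:
    """Per-level (cells, F) feature maps.

    Each level carries its own cell statistics plus 3x3 context; with fusion
    enabled the coarser level's (already fused) features are upsampled and
    added top-down, so fine levels see large-receptive-field context — the
    pyramid aggregation that the fusion ablation switches off (a no-fusion
    model has a single level and no top-down pathway).
    """
    per_level = []
    for stride in grid.strides:
        stats = _cell_stats(img, stride)
        per_level.append(np.concatenate([stats, _context(stats)], axis=2))
    if fusion:
        for lev in range(len(per_level) - 2, -1, -1):
            h, w = per_level[lev].shape[:2]
            per_level[lev] = per_level[lev] + _upsample2(per_level[lev + 1], h, w)
    return [f.reshape(-1, f.shape[2]) for f in per_level]


# ---------------------------------------------------------------------------
# Per-anchor pooled descriptors
#
# Integral images make box statistics O(1) per anchor: interior color,
# contrast against a surrounding ring, texture variance, gradient energy,
# and half-box asymmetries (the directional signal the regression head
# needs to re-center an anchor on its object).
# ---------------------------------------------------------------------------


def _integral_images(img: np.ndarray) -> tuple[list[np.ndarray], int, int]:
    x = img.astype(np.float32) / 255.0
    gray = x.mean(axis=2)
    gy, gx = np.gradient(gray)
    grad = np.hypot(gx, gy)
    chans = [x[:, :, 0], x[:, :, 1], x[:, :, 2], gray * gray, grad]
    ints = [np.pad(np.cumsum(np.cumsum(c, 0), 1), ((1, 0), (1, 0))) for c in chans]
    return ints, img.shape[0], img.shape[1]


def _box_sum(s: np.ndarray, x0, y0, x1, y1) -> np.ndarray:
    return s[y1, x1] - s[y0, x1] - s[y1, x0] + s[y0, x0]


def _box_mean(s: np.ndarray, x0, y0, x1, y1) -> np.ndarray:
    area = np.maximum((x1 - x0) * (y1 - y0), 1)
    return _box_sum(s, x0, y0, x1, y1) / area


def anchor_descriptors(anchors: np.ndarray, integrals, h: int, w: int) -> np.ndarray:
    """(N, 11) pooled statistics per anchor box."""
    sr, sg, sb, sg2, sgr = integrals

    def clip(a, hi):
        return np.clip(np.round(a).astype(int), 0, hi)

    x0 = clip(anchors[:, 0], w)
    y0 = clip(anchors[:, 1], h)
    x1 = np.maximum(clip(anchors[:, 2], w), x0 + 1)
    y1 = np.maximum(clip(anchors[:, 3], h), y0 + 1)
    bw, bh = x1 - x0, y1 - y0

    r = _box_mean(sr, x0, y0, x1, y1)
    g = _box_mean(sg, x0, y0, x1, y1)
    b = _box_mean(sb, x0, y0, x1, y1)
    gray = (r + g + b) / 3.0
    var = np.clip(_box_mean(sg2, x0, y0, x1, y1) - gray * gray, 0, None)
    grad = _box_mean(sgr, x0, y0, x1, y1)

    # surrounding ring (box grown 30% per side)
    ex0 = clip(x0 - 0.3 * bw, w)
    ey0 = clip(y0 - 0.3 * bh, h)
    ex1 = np.maximum(clip(x1 + 0.3 * bw, w), ex0 + 1)
    ey1 = np.maximum(clip(y1 + 0.3 * bh, h), ey0 + 1)
    area_in = (x1 - x0) * (y1 - y0)
    area_out = (ex1 - ex0) * (ey1 - ey0)
    ring_area = np.maximum(area_out - area_in, 1)
    ring = [
        (_box_sum(s, ex0, ey0, ex1, ey1) - _box_sum(s, x0, y0, x1, y1)) / ring_area
        for s in (sr, sg, sb)
    ]

    xm = np.maximum(((x0 + x1) // 2), x0 + 1)
    ym = np.maximum(((y0 + y1) // 2), y0 + 1)
    left = (_box_mean(sr, x0, y0, xm, y1) + _box_mean(sg, x0, y0, xm, y1)
            + _box_mean(sb, x0, y0, xm, y1)) / 3.0
    right = (_box_mean(sr, xm, y0, x1, y1) + _box_mean(sg, xm, y0, x1, y1)
             + _box_mean(sb, xm, y0, x1, y1)) / 3.0
    top = (_box_mean(sr, x0, y0, x1, ym) + _box_mean(sg, x0, y0, x1, ym)
           + _box_mean(sb, x0, y0, x1, ym)) / 3.0
    bottom = (_box_mean(sr, x0, ym, x1, y1) + _box_mean(sg, x0, ym, x1, y1)
              + _box_mean(sb, x0, ym, x1, y1)) / 3.0

    cx0 = clip(x0 + 0.25 * bw, w)
    cy0 = clip(y0 + 0.25 * bh, h)
    cx1 = np.maximum(clip(x1 - 0.25 * bw, w), cx0 + 1)
    cy1 = np.maximum(clip(y1 - 0.25 * bh, h), cy0 + 1)
    center = (_box_mean(sr, cx0, cy0, cx1, cy1) + _box_mean(sg, cx0, cy0, cx1, cy1)
              + _box_mean(sb, cx0, cy0, cx1, cy1)) / 3.0

    return np.stack(
        [r, g, b, ring[0], ring[1], ring[2], var, grad,
         right - left, bottom - top, center - gray],
        axis=1,
    ).astype(np.float32)


def anchor_features(
    image: np.ndarray, grid: AnchorGrid, fusion: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated per-anchor features and anchors for every pyramid level.

    Each anchor sees its level's (optionally top-down fused) cell features
    plus its own pooled box descriptors.
    """
    feats = compute_pyramid(image, grid, fusion)
    integrals, h, w = _integral_images(image)
    all_feat, all_anchor = [], []
    for lev, f in enumerate(feats):
        fh, fw = h // grid.strides[lev], w // grid.strides[lev]
        anchors = grid.level_anchors(lev, fh, fw)
        cell = np.repeat(f, grid.anchors_per_cell, axis=0)
        desc = anchor_descriptors(anchors, integrals, h, w)
        all_feat.append(np.concatenate([cell, desc], axis=1).astype(np.float32))
        all_anchor.append(anchors)
    return np.concatenate(all_feat, axis=0), np.concatenate(all_anchor, axis=0)


# ---------------------------------------------------------------------------
# Detector model and training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectorConfig:
    fusion: bool = True
    grid: AnchorGrid = field(default_factory=AnchorGrid)
    single_level: int = 1  # pyramid level used when fusion is off
    pos_thr: float = 0.5
    neg_thr: float = 0.4
    gamma: float = 2.0
    alpha: float = 0.5
    hidden: int = 48  # shared hidden width of the head trunk; 0 = linear heads
    lr: float = 0.02
    momentum: float = 0.9
    batch_size: int = 16
    epochs: int = 60
    reg_weight: float = 1.0
    score_thr: float = 0.05
    nms_thr: float = 0.5
    seed: int = 0

    def effective_grid(self) -> AnchorGrid:
        if self.fusion:
            return self.grid
        i = self.single_level
        return replace(
            self.grid, strides=(self.grid.strides[i],), base_sizes=(self.grid.base_sizes[i],)
        )


@dataclass
class Detection:
    box: tuple[float, float, float, float]  # (x0, y0, x1, y1)
    score: float
    coarse: str

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError("detection box must have positive extent")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass
class DetectorModel:
    """Heads over standardized anchor features: an optional shared hidden
    layer (``w_hid``), then slot-wise classification and regression maps."""

    config: DetectorConfig
    w_hid: np.ndarray  # (F+1, H); empty when the heads are linear
    w_cls: np.ndarray  # (H+1 or F+1, A*K)
    w_reg: np.ndarray  # (H+1 or F+1, A*4)
    feat_mean: np.ndarray
    feat_std: np.ndarray
    train_loss: list[float] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.config.effective_grid().strides)

    def head_input(self, x: np.ndarray) -> np.ndarray:
        """Map standardized-plus-bias features through the trunk."""
        if self.w_hid.size == 0:
            return x
        h = np.maximum(x @ self.w_hid, 0.0)
        return np.concatenate([h, np.ones((len(h), 1))], axis=1)

    def save(self, path: str) -> None:
        import json

        from dataclasses import asdict

        cfg = asdict(self.config)
        cfg["grid"] = asdict(self.config.grid)
        np.savez(path, w_hid=self.w_hid, w_cls=self.w_cls, w_reg=self.w_reg,
                 feat_mean=self.feat_mean, feat_std=self.feat_std,
                 config=json.dumps(cfg), train_loss=np.asarray(self.train_loss))

    @classmethod
    def load(cls, path: str) -> "DetectorModel":
        import json

        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["config"]))
        grid = AnchorGrid(**{k: tuple(v) for k, v in cfg.pop("grid").items()})
        config = DetectorConfig(grid=grid, **cfg)
        return cls(config, data["w_hid"], data["w_cls"], data["w_reg"],
                   data["feat_mean"], data["feat_std"], list(data["train_loss"]))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def _focal_grad(z: np.ndarray, t: np.ndarray, gamma: float, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Loss matrix and dLoss/dlogit for alpha-balanced sigmoid focal loss."""
    p = _sigmoid(z)
    pt = np.where(t == 1, p, 1.0 - p)
    at = np.where(t == 1, alpha, 1.0 - alpha)
    ptc = np.clip(pt, PT_CLAMP, 1.0)
    loss = at * (1.0 - pt) ** gamma * (-np.log(ptc))
    sign = np.where(t == 1, 1.0, -1.0)
    grad = at * sign * (
        gamma * pt * (1.0 - pt) ** gamma * np.log(ptc) - (1.0 - pt) ** (gamma + 1)
    )
    return loss, grad


def _smooth_l1_grad(x: np.ndarray) -> np.ndarray:
    return np.clip(x, -1.0, 1.0)


def _prepare_sample(
    sample: DetectionSample, cfg: DetectorConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Features (N,F), anchors (N,4), assignment (N,), class targets (N,)."""
    grid = cfg.effective_grid()
    feat, anchors = anchor_features(sample.image, grid, cfg.fusion)
    gt = np.asarray([b.as_xyxy() for b in sample.boxes], float).reshape(-1, 4)
    assign = assign_anchors(anchors, gt, cfg.pos_thr, cfg.neg_thr)
    classes = np.asarray(
        [COARSE_CLASSES.index(b.coarse) for b in sample.boxes], int
    )
    return feat, anchors, assign, classes


def train_detector(
    d2: list[DetectionSample], config: DetectorConfig | None = None
) -> DetectorModel:
    """Train classification (focal) and regression (smooth-L1) heads by
    momentum SGD over the anchor targets of a D2-style annotated patch set."""
    if not d2:
        raise ValueError("empty detection dataset")
    cfg = config or DetectorConfig()
    rng = np.random.default_rng(cfg.seed)
    k = len(COARSE_CLASSES)
    a = cfg.grid.anchors_per_cell

    prepared = []
    feat_acc = []
    for s in d2:
        feat, anchors, assign, classes = _prepare_sample(s, cfg)
        gt = np.asarray([b.as_xyxy() for b in s.boxes], float).reshape(-1, 4)
        pos = np.flatnonzero(assign >= 0)
        targets = (
            encode_offsets(anchors[pos], gt[assign[pos]]).astype(np.float32)
            if len(pos)
            else np.zeros((0, 4), np.float32)
        )
        prepared.append([feat, assign, classes, pos, targets])
        feat_acc.append(feat[rng.choice(len(feat), size=min(len(feat), 2048), replace=False)])
    stack = np.concatenate(feat_acc, axis=0)
    mean = stack.mean(axis=0).astype(np.float32)
    std = (stack.std(axis=0) + 1e-6).astype(np.float32)
    for entry in prepared:
        feat = entry[0]
        entry[0] = np.concatenate(
            [(feat - mean) / std, np.ones((len(feat), 1), np.float32)],
            axis=1, dtype=np.float32,
        )

    nf = feat_acc[0].shape[1]
    if cfg.hidden > 0:
        w_hid = rng.normal(0.0, np.sqrt(2.0 / (nf + 1)),
                           size=(nf + 1, cfg.hidden)).astype(np.float32)
        head_in = cfg.hidden + 1
    else:
        w_hid = np.zeros((0, 0), np.float32)
        head_in = nf + 1
    w_cls = np.zeros((head_in, a * k), np.float32)
    w_cls[-1, :] = -np.log((1 - 0.01) / 0.01)  # prior: rare positives
    w_reg = np.zeros((head_in, a * 4), np.float32)
    v_hid = np.zeros_like(w_hid)
    v_cls = np.zeros_like(w_cls)
    v_reg = np.zeros_like(w_reg)
    losses = []

    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(prepared))
        ep_loss, nb = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            g_hid = np.zeros_like(w_hid)
            g_cls = np.zeros_like(w_cls)
            g_reg = np.zeros_like(w_reg)
            batch_loss = 0.0
            for i in idx:
                x, assign, classes, pos, targets = prepared[i]
                n = len(x)
                if cfg.hidden > 0:
                    h_pre = x @ w_hid
                    xh = np.concatenate(
                        [np.maximum(h_pre, 0.0), np.ones((n, 1), np.float32)],
                        axis=1,
                    )
                else:
                    h_pre = None
                    xh = x
                # x has one row per anchor (cells repeated A times) in
                # slot-minor order: row j uses head output slot j % a, so the
                # heads are applied slot-wise on strided row groups
                slot = np.arange(n) % a
                w_cls3 = w_cls.reshape(-1, a, k)
                z = np.empty((n, k), np.float32)
                for s_ in range(a):
                    z[s_::a] = xh[s_::a] @ w_cls3[:, s_, :]
                t = np.zeros((n, k), np.float32)
                pos_mask = assign >= 0
                if pos_mask.any():
                    t[pos_mask, classes[assign[pos_mask]]] = 1.0
                loss_mat, grad_mat = _focal_grad(z, t, cfg.gamma, cfg.alpha)
                valid = assign != IGNORE
                loss_mat[~valid] = 0.0
                grad_mat[~valid] = 0.0
                n_pos = max(int(pos_mask.sum()), 1)
                batch_loss += float(loss_mat.sum()) / n_pos
                gz = (grad_mat / n_pos).astype(np.float32)  # (N, k)
                g_cls3 = g_cls.reshape(-1, a, k)
                g_xh = np.zeros_like(xh) if cfg.hidden > 0 else None
                for s_ in range(a):
                    g_cls3[:, s_, :] += xh[s_::a].T @ gz[s_::a]
                    if g_xh is not None:
                        g_xh[s_::a] = gz[s_::a] @ w_cls3[:, s_, :].T

                if len(pos):
                    w_reg3 = w_reg.reshape(-1, a, 4)
                    sp = slot[pos]
                    zr = np.einsum("nf,nfo->no", xh[pos],
                                   w_reg3[:, sp, :].transpose(1, 0, 2)).astype(np.float32)
                    diff = zr - targets
                    batch_loss += cfg.reg_weight * float(smooth_l1(diff).sum()) / n_pos
                    gr = (cfg.reg_weight * _smooth_l1_grad(diff) / n_pos).astype(np.float32)
                    g_reg3 = g_reg.reshape(-1, a, 4)
                    for s_ in np.unique(sp):
                        m = sp == s_
                        g_reg3[:, s_, :] += xh[pos][m].T @ gr[m]
                        if g_xh is not None:
                            g_xh[pos[m]] += gr[m] @ w_reg3[:, s_, :].T

                if cfg.hidden > 0:
                    gh = g_xh[:, :-1] * (h_pre > 0)
                    g_hid += x.T @ gh
            scale = 1.0 / max(len(idx), 1)
            if cfg.hidden > 0:
                v_hid = cfg.momentum * v_hid - cfg.lr * scale * g_hid
                w_hid = w_hid + v_hid
            v_cls = cfg.momentum * v_cls - cfg.lr * scale * g_cls
            v_reg = cfg.momentum * v_reg - cfg.lr * scale * g_reg
            w_cls += v_cls
            w_reg += v_reg
            ep_loss += batch_loss * scale
            nb += 1
        losses.append(ep_loss / max(nb, 1))
    logger.info("detector trained: %d epochs, final loss %.4f", cfg.epochs, losses[-1])
    return DetectorModel(cfg, w_hid, w_cls, w_reg, mean, std, losses)


def detect_regions(
    patch_image: np.ndarray,
    model: DetectorModel,
    score_thr: float | None = None,
    nms_thr: float | None = None,
    classes: tuple[str, ...] = COARSE_CLASSES,
    max_detections: int = 100,
) -> list[Detection]:
    """Score anchors, decode boxes, and suppress per class.

    Returns detections for the requested coarse classes; downstream the
    pipeline forwards only the pollen class.
    """
    cfg = model.config
    score_thr = cfg.score_thr if score_thr is None else score_thr
    nms_thr = cfg.nms_thr if nms_thr is None else nms_thr
    grid = cfg.effective_grid()
    k = len(COARSE_CLASSES)
    a = grid.anchors_per_cell
    h, w = patch_image.shape[:2]
    feat, anchors = anchor_features(patch_image, grid, cfg.fusion)
    x = np.concatenate(
        [(feat - model.feat_mean) / model.feat_std, np.ones((len(anchors), 1))],
        axis=1,
    )
    xh = model.head_input(x)
    slot = np.arange(len(anchors)) % a
    z = (xh @ model.w_cls).reshape(-1, a, k)[np.arange(len(anchors)), slot]
    probs = _sigmoid(z)  # (N, k)
    zr = (xh @ model.w_reg).reshape(-1, a, 4)[np.arange(len(anchors)), slot]

    all_boxes, all_scores, all_cls = [], [], []
    cand = probs.max(axis=1) > score_thr
    if cand.any():
        boxes = decode_offsets(anchors[cand], zr[cand])
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
        for ci in range(k):
            keep = probs[cand, ci] > score_thr
            if not keep.any():
                continue
            all_boxes.append(boxes[keep])
            all_scores.append(probs[cand, ci][keep])
            all_cls.append(np.full(int(keep.sum()), ci))
    if not all_boxes:
        return []
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    cls = np.concatenate(all_cls)
    ok = (boxes[:, 2] - boxes[:, 0] > 1e-3) & (boxes[:, 3] - boxes[:, 1] > 1e-3)
    boxes, scores, cls = boxes[ok], scores[ok], cls[ok]

    detections: list[Detection] = []
    for ci in range(k):
        name = COARSE_CLASSES[ci]
        if name not in classes:
            continue
        m = cls == ci
        if not m.any():
            continue
        keep = nms(boxes[m], scores[m], nms_thr)
        for j in keep[:max_detections]:
            b = boxes[m][j]
            detections.append(Detection(tuple(float(v) for v in b), float(scores[m][j]), name))
    detections.sort(key=lambda d: -d.score)
    return detections[:max_detections]


@dataclass
class RegionCrop:
    image: np.ndarray  # (s, s, 3) uint8
    box: tuple[float, float, float, float]  # clipped source box in the patch
    score: float


def crop_regions(
    patch_image: np.ndarray,
    detections: list[Detection],
    out_size: int = 100,
    classes: tuple[str, ...] = ("pollen",),
) -> list[RegionCrop]:
    """One resized square crop per (pollen) detection, with provenance.

    Boxes are clipped to the patch; zero-area boxes after clipping are
    skipped with a warning.
    """
    h, w = patch_image.shape[:2]
    crops = []
    for d in detections:
        if d.coarse not in classes:
            continue
        x0 = max(0.0, min(d.box[0], w))
        y0 = max(0.0, min(d.box[1], h))
        x1 = max(0.0, min(d.box[2], w))
        y1 = max(0.0, min(d.box[3], h))
        ix0, iy0 = int(np.floor(x0)), int(np.floor(y0))
        ix1, iy1 = int(np.ceil(x1)), int(np.ceil(y1))
        if ix1 - ix0 <= 0 or iy1 - iy0 <= 0:
            warnings.warn(f"detection box {d.box} has zero area after clipping; skipped")
            continue
        region = RegionAnnotation(ix0, iy0, ix1, iy1, coarse=d.coarse)
        crops.append(RegionCrop(crop_box(patch_image, region, out_size),
                                (x0, y0, x1, y1), d.score))
    return crops
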
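"""End-to-end progressive pipeline: tile -> filter -> detect -> crop -> classify.

One global seed fans out to per-stage seeds by fixed offsets, so a saved
configuration reproduces a run exactly. Detections from neighbouring
patches are stitched back together at slide level (an object cut by the
non-overlapping grid appears as two abutting partial boxes; stitching
unions them before scoring).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _nn
from .classify import EnsembleSpec, classify_crops, train_ensemble
from .detect import (
    AnchorGrid,
    DetectorConfig,
    DetectorModel,
    crop_regions,
    detect_regions,
    train_detector,
)
from .evaluate import (
    ABLATION_VARIANTS,
    AblationVariant,
    identification_accuracy,
    score_grain_identifications,
)
from .preprocess import PatchFilterModel, TilingSpec, filter_patches, tile_slide, train_patch_filter
from .synth import (
    CropDataset,
    GroundTruth,
    SlideImage,
    SynthConfig,
    augment_crops,
    build_d1,
    build_d2,
    build_d3,
    generate_corpus,
)

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets
SEED_FILTER = 101
SEED_DETECTOR = 202
SEED_ENSEMBLE = 303
SEED_EVAL = 404


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_train_slides: int = 2
    n_test_slides: int = 2
    patch_size: int = 512
    filter_threshold: float = 0.5
    filter_architecture: str = "alexnet-tiny"
    filter_max_patches: int = 150  # per label stratum when training the filter
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    ensemble_menu: tuple[str, ...] = ("alexnet-tiny", "vgg-tiny", "resnet-tiny", "densenet-tiny")
    detection_score_thr: float = 0.6  # operating point for forwarding regions
    detection_nms_thr: float = 0.3  # matches the generator's overlap cap
    crop_size: int = 100
    crop_augment: int = 2  # extra dihedral copies per training crop
    crop_jitter: float = 0.1  # box perturbation emulating detector framing
    train_epochs: int = 25  # cap for the classifier stages
    balance_negatives: bool = True  # subsample OVR negatives at desk scale
    enable_localization: bool = True
    seed: int = 0

    def train_config(self) -> _nn.TrainConfig:
        # slightly impatient early stopping keeps the 32-model selection
        # grid affordable on one CPU
        return _nn.TrainConfig(max_epochs=self.train_epochs, patience=4)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = SynthConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.pop("synth").items()
        })
        det = dict(d.pop("detector"))
        grid = AnchorGrid(**{k: tuple(v) for k, v in det.pop("grid").items()})
        detector = DetectorConfig(grid=grid, **det)
        d["ensemble_menu"] = tuple(d["ensemble_menu"])
        return cls(synth=synth, detector=detector, **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class TrainedModels:
    patch_filter: PatchFilterModel
    detector: DetectorModel | None
    ensemble: EnsembleSpec


def train_models(
    train_corpus: list[tuple[SlideImage, GroundTruth]],
    config: PipelineConfig,
    cache_dir: str | Path | None = None,
) -> TrainedModels:
    """Fit all three stages on a training corpus.

    With ``cache_dir`` set, stage artifacts are cached keyed by the config
    hash (the training stages dominate runtime and ablations reuse them).
    """
    cache = None
    if cache_dir is not None:
        cache = Path(cache_dir) / config.config_hash()
        if (cache / "done").exists():
            logger.info("loading cached models from %s", cache)
            detector = None
            if (cache / "detector.npz").exists():
                detector = DetectorModel.load(cache / "detector.npz")
            return TrainedModels(
                PatchFilterModel.load(cache / "filter.npz"),
                detector,
                EnsembleSpec.load(cache / "ensemble"),
            )
        cache.mkdir(parents=True, exist_ok=True)

    tc = config.train_config()

    d1 = build_d1(train_corpus, config.patch_size, seed=config.seed + SEED_FILTER)
    n_fg = int(d1.labels.sum())
    n_bg = len(d1) - n_fg
    cap = config.filter_max_patches
    d1 = build_d1(
        train_corpus, config.patch_size,
        n_foreground=min(n_fg, cap), n_background=min(n_bg, cap),
        seed=config.seed + SEED_FILTER,
    )
    logger.info("stage filter: training on %d patches", len(d1))
    patch_filter = train_patch_filter(
        d1, config.filter_architecture, tc, config.filter_threshold,
        seed=config.seed + SEED_FILTER,
    )

    detector = None
    if config.enable_localization:
        d2 = build_d2(train_corpus, config.patch_size)
        logger.info("stage detect: training on %d annotated patches", len(d2))
        detector = train_detector(
            d2, replace(config.detector, seed=config.seed + SEED_DETECTOR)
        )

    d3 = build_d3(train_corpus, config.crop_size, box_jitter=config.crop_jitter,
                  jitter_seed=config.seed + SEED_ENSEMBLE)
    if config.crop_augment > 0:
        d3 = augment_crops(d3, config.crop_augment, seed=config.seed + SEED_ENSEMBLE)
    logger.info("stage classify: training ensemble on %d crops", len(d3))
    ensemble, _table = train_ensemble(
        d3, config.synth.n_pollen_classes, config.ensemble_menu, tc,
        seed=config.seed + SEED_ENSEMBLE,
        balance_negatives=config.balance_negatives,
    )

    if cache is not None:
        patch_filter.save(cache / "filter.npz")
        if detector is not None:
            detector.save(cache / "detector.npz")
        ensemble.save(cache / "ensemble")
        (cache / "done").touch()
    return TrainedModels(patch_filter, detector, ensemble)


def stitch_detections(
    boxes: list[tuple], scores: list[float], patch_size: int, tol: float = 4.0
) -> tuple[list[tuple], list[float]]:
    """Union partial boxes that abut across a patch grid line.

    Two boxes are merged when one ends and the other starts within ``tol``
    pixels of the same grid line and their perpendicular extents overlap by
    at least 30% of the smaller extent. Iterates to a fixed point.
    """
    boxes = [tuple(b) for b in boxes]
    scores = list(scores)
    changed = True
    while changed:
        changed = False
        n = len(boxes)
        for i in range(n):
            if boxes[i] is None:
                continue
            for j in range(i + 1, n):
                if boxes[j] is None:
                    continue
                if _abuts(boxes[i], boxes[j], patch_size, tol):
                    a, b = boxes[i], boxes[j]
                    boxes[i] = (min(a[0], b[0]), min(a[1], b[1]),
                                max(a[2], b[2]), max(a[3], b[3]))
                    scores[i] = max(scores[i], scores[j])
                    boxes[j] = None
                    changed = True
        boxes_sc = [(b, s) for b, s in zip(boxes, scores) if b is not None]
        boxes = [b for b, _ in boxes_sc]
        scores = [s for _, s in boxes_sc]
    return boxes, scores


def _near_grid(v: float, patch_size: int, tol: float) -> bool:
    r = v % patch_size
    return r <= tol or patch_size - r <= tol


def _overlap_frac(a0, a1, b0, b1) -> float:
    inter = min(a1, b1) - max(a0, b0)
    small = min(a1 - a0, b1 - b0)
    return inter / small if small > 0 else 0.0


def _abuts(a, b, patch_size: int, tol: float) -> bool:
    # horizontal adjacency at a vertical grid line, then vertical adjacency
    for u, v in ((a, b), (b, a)):
        if (abs(u[2] - v[0]) <= tol and _near_grid(u[2], patch_size, tol)
                and _overlap_frac(u[1], u[3], v[1], v[3]) >= 0.3):
            return True
        if (abs(u[3] - v[1]) <= tol and _near_grid(u[3], patch_size, tol)
                and _overlap_frac(u[0], u[2], v[0], v[2]) >= 0.3):
            return True
    # a grid-touching fragment mostly swallowed by an earlier union is
    # absorbed too (the fourth piece of a corner split)
    small, big = (a, b) if _area(a) <= _area(b) else (b, a)
    ix = max(0.0, min(small[2], big[2]) - max(small[0], big[0]))
    iy = max(0.0, min(small[3], big[3]) - max(small[1], big[1]))
    if _area(small) > 0 and ix * iy / _area(small) >= 0.8:
        touches = any(_near_grid(v, patch_size, tol) for v in small)
        if touches:
            return True
    return False


def _area(b) -> float:
    return max(0.0, b[2] - b[0]) * max(0.0, b[3] - b[1])


@dataclass
class SlideResult:
    slide_id: str
    table: pd.DataFrame  # one row per identification
    n_correct: int
    n_gt: int
    n_false_pos: int
    stage_counts: dict[str, int]

    @property
    def accuracy(self) -> float:
        return identification_accuracy(self.n_correct, self.n_gt, self.n_false_pos)


def identify_slide(
    slide: SlideImage,
    truth: GroundTruth,
    models: TrainedModels,
    config: PipelineConfig,
    variant: AblationVariant | None = None,
) -> SlideResult:
    """Run the (possibly ablated) pipeline on one slide and score it.

    With localization, pollen detections are stitched across patch borders,
    cropped, ensemble-classified, and matched to ground-truth grains at
    IoU >= 0.5. Without localization, each forwarded patch is classified
    whole and a grain is judged by the patch containing its center.
    """
    variant = variant or AblationVariant(direct_sampling=False, coarse_localization=True)
    spec = TilingSpec(config.patch_size)
    tiles = tile_slide(slide, spec)
    if variant.direct_sampling:
        kept = tiles
    else:
        kept = filter_patches(tiles, models.patch_filter, config.filter_threshold)
    counts = {"tiles_in": len(tiles), "kept": len(kept),
              "filtered": len(tiles) - len(kept)}

    gt_boxes = [b.as_xyxy() for b in truth.pollen_boxes]
    gt_labels = [b.fine for b in truth.pollen_boxes]
    rows = []

    if variant.coarse_localization:
        if models.detector is None:
            raise ValueError("variant requires the localization stage but no detector was trained")
        g_boxes: list[tuple] = []
        g_scores: list[float] = []
        n_dets = n_crops = 0
        crops_all, crop_meta = [], []
        for patch in kept:
            dets = detect_regions(patch.image, models.detector,
                                  score_thr=config.detection_score_thr,
                                  nms_thr=config.detection_nms_thr,
                                  classes=("pollen",))
            n_dets += len(dets)
            crops = crop_regions(patch.image, dets, config.crop_size)
            n_crops += len(crops)
            for c in crops:
                x0, y0, x1, y1 = c.box
                g_boxes.append((x0 + patch.x0, y0 + patch.y0, x1 + patch.x0, y1 + patch.y0))
                g_scores.append(c.score)
                crops_all.append(c.image)
        counts["detections_forwarded"] = n_dets
        counts["crops_created"] = n_crops
        g_boxes, g_scores = stitch_detections(g_boxes, g_scores, config.patch_size)
        if len(g_boxes) < len(crops_all):
            # re-crop merged boxes from the slide so the classifier sees the
            # whole stitched object
            from .synth import RegionAnnotation, crop_box

            crops_all = [
                crop_box(
                    slide.pixels,
                    RegionAnnotation(int(b[0]), int(b[1]),
                                     max(int(b[2]), int(b[0]) + 1),
                                     max(int(b[3]), int(b[1]) + 1), coarse="pollen"),
                    config.crop_size,
                )
                for b in g_boxes
            ]
        preds = classify_crops(crops_all, models.ensemble)
        pred_labels = [p.label for p in preds]
        n_correct, n_fp = score_grain_identifications(gt_boxes, gt_labels, g_boxes, pred_labels)
        for b, s, p in zip(g_boxes, g_scores, preds):
            rows.append((slide.slide_id, *b, s, p.label, p.probability))
    else:
        crops = [p.image for p in kept]
        preds = classify_crops(crops, models.ensemble) if crops else []
        n_correct = n_fp = 0
        # grain -> containing patch
        kept_index = {(p.x0, p.y0): i for i, p in enumerate(kept)}
        for gb, gl in zip(gt_boxes, gt_labels):
            cx = (gb[0] + gb[2]) / 2.0
            cy = (gb[1] + gb[3]) / 2.0
            key = (int(cx // config.patch_size) * config.patch_size,
                   int(cy // config.patch_size) * config.patch_size)
            i = kept_index.get(key)
            if i is None:
                continue
            if preds[i].label == gl:
                n_correct += 1
        for i, p in enumerate(kept):
            has = any(
                p.x0 <= (gb[0] + gb[2]) / 2.0 < p.x0 + config.patch_size
                and p.y0 <= (gb[1] + gb[3]) / 2.0 < p.y0 + config.patch_size
                for gb in gt_boxes
            )
            if not has:
                n_fp += 1
            rows.append((slide.slide_id, p.x0, p.y0, p.x0 + p.size, p.y0 + p.size,
                         1.0, preds[i].label, preds[i].probability))
    table = pd.DataFrame(
        rows, columns=["slide_id", "x0", "y0", "x1", "y1", "score", "label", "probability"]
    )
    return SlideResult(slide.slide_id, table, n_correct, len(gt_boxes), n_fp, counts)


@dataclass
class PipelineResult:
    slide_results: list[SlideResult]
    accuracy: float
    table: pd.DataFrame
    stage_counts: dict[str, int]


def run_on_corpus(
    corpus: list[tuple[SlideImage, GroundTruth]],
    models: TrainedModels,
    config: PipelineConfig,
    variant: AblationVariant | None = None,
) -> PipelineResult:
    results = [identify_slide(s, t, models, config, variant) for s, t in corpus]
    n_c = sum(r.n_correct for r in results)
    n_g = sum(r.n_gt for r in results)
    n_f = sum(r.n_false_pos for r in results)
    counts: dict[str, int] = {}
    for r in results:
        for k, v in r.stage_counts.items():
            counts[k] = counts.get(k, 0) + v
    table = pd.concat([r.table for r in results], ignore_index=True) if results else pd.DataFrame()
    return PipelineResult(results, identification_accuracy(n_c, n_g, n_f), table, counts)


def run_pipeline(
    config: PipelineConfig,
    variant: AblationVariant | None = None,
    cache_dir: str | Path | None = None,
    train_corpus: list[tuple[SlideImage, GroundTruth]] | None = None,
    test_corpus: list[tuple[SlideImage, GroundTruth]] | None = None,
) -> PipelineResult:
    """Full run: generate corpora, train all stages, identify the test slides.

    Explicit corpora override the config-generated ones (e.g., a training
    corpus mixing dense and sparse slides). The localization stage is
    mandatory outside ablation mode: a config with
    ``enable_localization=False`` is refused unless an ablation variant that
    omits the stage is passed explicitly.
    """
    if not config.enable_localization and (variant is None or variant.coarse_localization):
        raise ValueError(
            "coarse localization is a required stage; disable it only through "
            "an ablation variant without CL"
        )
    synth_cfg = replace(config.synth, patch_size=config.patch_size)
    if train_corpus is None:
        train_corpus = generate_corpus(synth_cfg, config.n_train_slides)
    if test_corpus is None:
        test_corpus = generate_corpus(
            replace(synth_cfg, seed=synth_cfg.seed + 5000), config.n_test_slides
        )
    models = train_models(train_corpus, config, cache_dir)
    result = run_on_corpus(test_corpus, models, config, variant)
    logger.info("pipeline accuracy %.3f (%s)", result.accuracy, result.stage_counts)
    return result


def run_variant(
    variant: AblationVariant,
    corpus: tuple[list, list],
    seed: int = 0,
    config: PipelineConfig | None = None,
    models: TrainedModels | None = None,
) -> float:
    """Accuracy of one ablation variant on (train_corpus, test_corpus)."""
    train_corpus, test_corpus = corpus
    cfg = config or PipelineConfig()
    cfg = replace(cfg, seed=seed)
    if models is None:
        models = train_models(train_corpus, cfg)
    return run_on_corpus(test_corpus, models, cfg, variant).accuracy


def run_ablation_grid(
    corpus: tuple[list, list],
    seeds: list[int],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Accuracy of all four variants for each seed (models shared per seed)."""
    cfg = config or PipelineConfig()
    rows = []
    for seed in seeds:
        c = replace(cfg, seed=seed)
        train_corpus, test_corpus = corpus
        models = train_models(train_corpus, c)
        row = {"seed": seed}
        for name, variant in ABLATION_VARIANTS.items():
            row[name] = run_on_corpus(test_corpus, models, c, variant).accuracy
        rows.append(row)
    return pd.DataFrame(rows).set_index("seed")
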
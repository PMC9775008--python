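"""Reference synthetic studies exercising the full pipeline.

Three packaged experiment setups with fixed study conditions:

* identification study — an easy, well-separated 8-taxon corpus; trains all
  three stages and reports end-to-end grain-level identification accuracy.
* ablation study — a small corpus rich in both blank tiles and impurities;
  runs the four sampling x localization variants across training seeds.
* fusion study — grains spanning disparate scales; compares detector AP50
  with the multi-scale pyramid against a single-level model.

Every source of randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from . import detect, evaluate, pipeline, synth
from .preprocess import TilingSpec, tile_slide

logger = logging.getLogger(__name__)

EQUAL_WEIGHTS = tuple([1 / 8] * 8)


def _easy_base(seed: int) -> synth.SynthConfig:
    return synth.SynthConfig(
        slide_width=4096, slide_height=2048, patch_size=512,
        confusability=0.0, class_weights=EQUAL_WEIGHTS, seed=seed,
    )


def identification_study_setup(seed: int):
    """Easy-corpus study conditions: two dense slides plus two sparse slides
    for training (the sparse ones supply blank background), two
    medium-density test slides."""
    base = _easy_base(seed)
    dense = replace(base, grain_density=12, impurity_density=1.5, bubble_density=1.5)
    sparse = replace(base, grain_density=1.5, impurity_density=0.5,
                     bubble_density=0.5, seed=seed + 100)
    train = synth.generate_corpus(dense, 2) + synth.generate_corpus(sparse, 2)
    test = synth.generate_corpus(
        replace(base, grain_density=6, impurity_density=1.0, bubble_density=1.0,
                seed=seed + 5000),
        2,
    )
    cfg = pipeline.PipelineConfig(
        synth=base,
        ensemble_menu=("alexnet-tiny", "densenet-tiny"),
        seed=seed,
    )
    return cfg, train, test


def run_identification_study(seed: int = 0) -> dict:
    """Train the progressive pipeline on the easy corpus and measure
    end-to-end identification accuracy plus per-stage quality."""
    cfg, train, test = identification_study_setup(seed)
    models = pipeline.train_models(train, cfg)
    result = pipeline.run_on_corpus(test, models, cfg)

    # patch-filter accuracy on the test grid
    d1t = synth.build_d1(test, cfg.patch_size)
    probs = models.patch_filter.foreground_probability(d1t.images)
    filter_acc = float(((probs > cfg.filter_threshold).astype(int) == d1t.labels).mean())

    # detector AP on held-out annotated patches (pollen category)
    d2t = synth.build_d2(test, cfg.patch_size)
    dets, gts = [], {}
    for i, s in enumerate(d2t):
        gts[i] = [b.as_xyxy() for b in s.boxes if b.coarse == "pollen"]
        for d in detect.detect_regions(s.image, models.detector, score_thr=0.05,
                                       nms_thr=cfg.detection_nms_thr, classes=("pollen",)):
            dets.append((i, d.box, d.score))
    rep = evaluate.ap_report(dets, gts)

    n_gt = sum(r.n_gt for r in result.slide_results)
    n_fp = sum(r.n_false_pos for r in result.slide_results)
    return {
        "accuracy": result.accuracy,
        "n_gt_grains": n_gt,
        "n_false_positives": n_fp,
        "filter_accuracy": filter_acc,
        "detector_ap": rep.ap,
        "detector_ap50": rep.ap50,
        "detector_ap75": rep.ap75,
        "stage_counts": result.stage_counts,
    }


def ablation_study_setup(seed: int):
    """Blank-rich, impurity-rich study conditions at reduced patch size.

    Grains are large relative to the 128-pixel tile so that the
    classifier-only variants see croppings comparable to their training
    framing; the test slides carry as many impurities as grains and a
    majority of blank tiles.
    """
    base = synth.SynthConfig(
        slide_width=2048, slide_height=1024, patch_size=128,
        diameter_range=(60, 110), confusability=0.0,
        class_weights=EQUAL_WEIGHTS, seed=seed + 40,
    )
    dense = replace(base, grain_density=20, impurity_density=2, bubble_density=2)
    sparse = replace(base, grain_density=2, impurity_density=1, bubble_density=1,
                     seed=seed + 60)
    train = synth.generate_corpus(dense, 1) + synth.generate_corpus(sparse, 1)
    test = synth.generate_corpus(
        replace(base, grain_density=5, impurity_density=5, bubble_density=2,
                seed=seed + 7000),
        2,
    )
    cfg = pipeline.PipelineConfig(
        synth=base, patch_size=128,
        ensemble_menu=("alexnet-tiny", "densenet-tiny"),
        detector=replace(detect.DetectorConfig(), epochs=40),
        crop_jitter=0.3,
        seed=seed,
    )
    return cfg, train, test


def run_ablation_study(seed: int = 0, n_seeds: int = 5) -> pd.DataFrame:
    """Accuracy of the four ablation variants for ``n_seeds`` training seeds
    on the shared blank- and impurity-rich corpus."""
    base_cfg, train, test = ablation_study_setup(seed)
    rows = []
    for s in range(n_seeds):
        cfg = replace(base_cfg, seed=seed + s)
        models = pipeline.train_models(train, cfg)
        row = {"seed": seed + s}
        for name, variant in evaluate.ABLATION_VARIANTS.items():
            row[name] = pipeline.run_on_corpus(test, models, cfg, variant).accuracy
        logger.info("ablation seed %d: %s", seed + s,
                    {k: round(v, 3) for k, v in row.items() if k != "seed"})
        rows.append(row)
    return pd.DataFrame(rows).set_index("seed")


def fusion_study_setup(seed: int):
    """Two-scale study conditions: grain diameters span 24-120 px so the
    single-level anchor family cannot cover both ends."""
    base = synth.SynthConfig(
        slide_width=2048, slide_height=1024, patch_size=256,
        diameter_range=(24, 120), grain_density=10,
        impurity_density=1, bubble_density=1,
        confusability=0.0, class_weights=EQUAL_WEIGHTS, seed=seed + 40,
    )
    train = synth.generate_corpus(base, 2)
    test = synth.generate_corpus(replace(base, seed=seed + 9000), 2)
    return synth.build_d2(train), synth.build_d2(test)


def run_fusion_study(seed: int = 0, n_seeds: int = 5) -> pd.DataFrame:
    """AP50 of the with-fusion vs single-level detector per training seed."""
    d2, d2t = fusion_study_setup(seed)
    gts = {i: [b.as_xyxy() for b in s.boxes if b.coarse == "pollen"]
           for i, s in enumerate(d2t)}
    rows = []
    for s in range(n_seeds):
        row = {"seed": seed + s}
        for fusion, key in ((True, "ap50_fusion"), (False, "ap50_single")):
            cfg = detect.DetectorConfig(fusion=fusion, seed=seed + s, epochs=40)
            model = detect.train_detector(d2, cfg)
            dets = []
            for i, smp in enumerate(d2t):
                for d in detect.detect_regions(smp.image, model, score_thr=0.1,
                                               classes=("pollen",)):
                    dets.append((i, d.box, d.score))
            row[key] = evaluate.ap_report(dets, gts).ap50
        logger.info("fusion seed %d: %.3f vs %.3f", seed + s,
                    row["ap50_fusion"], row["ap50_single"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("seed")
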
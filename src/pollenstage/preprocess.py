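"""Slide tiling and blank-background patch filtering.

A slide of L x H pixels is cut into the non-overlapping grid of l x l
patches (border strips narrower than l are discarded), giving
M = floor(L/l) * floor(H/l) patches in row-major order. A small binary CNN
then scores each patch; patches whose foreground probability exceeds the
confidence threshold (default 0.5) form the candidate set forwarded to
detection. A probability of exactly 0.5 is background: foreground requires
strictly exceeding the threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import _nn
from .synth import PatchDataset, SlideImage

logger = logging.getLogger(__name__)

FILTER_INPUT_SIZE = 32


@dataclass(frozen=True)
class TilingSpec:
    """Non-overlapping grid tiling: 0-based, half-open [x0, x0+l) x [y0, y0+l)."""

    patch_size: int = 512

    def grid_shape(self, width: int, height: int) -> tuple[int, int]:
        return height // self.patch_size, width // self.patch_size

    def patch_count(self, width: int, height: int) -> int:
        ny, nx = self.grid_shape(width, height)
        return ny * nx


@dataclass
class Patch:
    """One l x l crop with its 0-based origin in the parent slide."""

    slide_id: str
    x0: int
    y0: int
    size: int
    image: np.ndarray  # (l, l, 3) uint8


def tile_slide(slide: SlideImage, spec: TilingSpec = TilingSpec()) -> list[Patch]:
    """Cut the slide into the full non-overlapping patch grid, row-major.

    Slides smaller than one patch in either dimension yield an empty list
    with a warning (the border-discard convention leaves nothing).
    """
    l = spec.patch_size
    ny, nx = spec.grid_shape(slide.width, slide.height)
    if ny == 0 or nx == 0:
        warnings.warn(
            f"slide {slide.slide_id} ({slide.width}x{slide.height}) smaller than one "
            f"{l}x{l} patch; no tiles produced"
        )
        return []
    patches = []
    for i in range(ny):
        for j in range(nx):
            x0, y0 = j * l, i * l
            patches.append(Patch(slide.slide_id, x0, y0, l,
                                 slide.pixels[y0 : y0 + l, x0 : x0 + l]))
    return patches


def _to_filter_input(images: list[np.ndarray]) -> np.ndarray:
    """Downsample patches to 32x32 and subtract the per-patch median color.

    The median estimates the blank-field color, so a background patch maps
    to near-zero everywhere while any rendered object leaves a localized
    signed deviation — the signal the filter needs, independent of absolute
    illumination.
    """
    s = FILTER_INPUT_SIZE
    out = np.empty((len(images), 3, s, s), np.float32)
    for i, img in enumerate(images):
        h, w = img.shape[:2]
        if h % s == 0 and w % s == 0:
            small = img.reshape(s, h // s, s, w // s, 3).mean(axis=(1, 3))
        else:
            small = resize(img, (s, s, 3), order=1, anti_aliasing=True,
                           preserve_range=True)
        small = small.astype(np.float32) / 255.0
        small = small - np.median(small, axis=(0, 1))
        out[i] = (2.0 * small).transpose(2, 0, 1)
    return out


@dataclass
class PatchFilterModel:
    """Binary foreground/background patch classifier.

    Emits a softmax 2-vector per patch; index 1 is the foreground class.
    """

    net: _nn.Sequential
    architecture: str
    threshold: float = 0.5
    log: _nn.TrainLog = field(default_factory=_nn.TrainLog)

    def predict_proba(self, images: list[np.ndarray]) -> np.ndarray:
        if not images:
            return np.zeros((0, 2))
        return self.net.predict_proba(_to_filter_input(images))

    def foreground_probability(self, images: list[np.ndarray]) -> np.ndarray:
        return self.predict_proba(images)[:, 1]

    def save(self, path: str) -> None:
        arrays = {f"w{i}": a for i, a in enumerate(self.net.state_arrays())}
        np.savez(path, architecture=self.architecture, threshold=self.threshold,
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "PatchFilterModel":
        data = np.load(path, allow_pickle=False)
        arch = str(data["architecture"])
        net = _nn.build_preset(arch, np.random.default_rng(0), n_out=2)
        net.load_state_arrays([data[f"w{i}"] for i in range(len(net.state_arrays()))])
        return cls(net, arch, float(data["threshold"]))


def train_patch_filter(
    d1: PatchDataset,
    architecture: str = "alexnet-tiny",
    train_config: _nn.TrainConfig | None = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> PatchFilterModel:
    """Train the binary patch filter on a D1-style fg/bg patch dataset.

    Uses momentum SGD with an internal validation split and early stopping;
    the per-epoch loss trajectory is kept on the returned model.
    """
    if len(d1) == 0:
        raise ValueError("empty patch dataset")
    labels = np.unique(d1.labels)
    if len(labels) < 2:
        raise ValueError("patch dataset must contain both foreground and background")
    cfg = train_config or _nn.TrainConfig()
    rng = np.random.default_rng(seed)
    net = _nn.build_preset(architecture, rng, n_out=2)
    x = _to_filter_input(d1.images)
    y = np.asarray(d1.labels, int)
    log = _nn.train_classifier(net, x, y, cfg, rng)
    logger.info("patch filter trained: %d epochs, val loss %.4f",
                log.stopped_epoch, log.final_val_loss)
    return PatchFilterModel(net, architecture, threshold, log)


def filter_patches(
    patches: list[Patch], model: PatchFilterModel, threshold: float | None = None
) -> list[Patch]:
    """Candidate set C: patches with foreground probability strictly above
    the threshold, input order preserved."""
    tau = model.threshold if threshold is None else threshold
    if not 0.0 <= tau < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    if not patches:
        return []
    probs = model.foreground_probability([p.image for p in patches])
    return [p for p, q in zip(patches, probs) if q > tau]


def patch_index_frame(
    patches: list[Patch], model: PatchFilterModel, threshold: float | None = None
) -> pd.DataFrame:
    """Per-patch table (slide_id, x0, y0, size, fg_prob, kept) for CSV export."""
    tau = model.threshold if threshold is None else threshold
    probs = (
        model.foreground_probability([p.image for p in patches]) if patches else []
    )
    rows = [
        (p.slide_id, p.x0, p.y0, p.size, float(q), bool(q > tau))
        for p, q in zip(patches, probs)
    ]
    return pd.DataFrame(rows, columns=["slide_id", "x0", "y0", "size", "fg_prob", "kept"])
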
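"""Fine-grained pollen classification: one-vs-rest multi-classifier ensemble.

The c-class crop dataset is decomposed into c binary subsets (positives =
class k, negatives = the rest). For each class a menu of small CNN
architectures is trained and the best-validating one is kept, giving a
heterogeneous ensemble — one dedicated binary classifier per taxon. At
inference every active classifier emits its positive-class probability and
the crop takes the label of the most confident classifier (decision-level
max fusion, unweighted). The per-class probability vector is a set of
independent binary posteriors and need not sum to one.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import _nn
from .synth import CropDataset

logger = logging.getLogger(__name__)

ARCHITECTURE_MENU = _nn.ARCHITECTURE_MENU
NET_INPUT_SIZE = 32


def _to_net_input(images: list[np.ndarray] | np.ndarray) -> np.ndarray:
    s = NET_INPUT_SIZE
    out = np.empty((len(images), 3, s, s), np.float32)
    for i, img in enumerate(images):
        if img.shape[:2] != (s, s):
            img = np.clip(
                resize(img, (s, s, 3), order=1, anti_aliasing=True, preserve_range=True),
                0, 255,
            )
        out[i] = (np.asarray(img, np.float32) / 255.0 - 0.5).transpose(2, 0, 1)
    return out


@dataclass
class OvrDataset:
    """Binary subset for class k: positives are the class-k crops, negatives
    everything else. Order within each side follows the source dataset."""

    k: int
    positives: list[np.ndarray]
    negatives: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def build_ovr_datasets(d3: CropDataset, c: int) -> list[OvrDataset]:
    """One-vs-rest decomposition of a c-class crop dataset (labels 1..c)."""
    if c < 2:
        raise ValueError("one-vs-rest needs at least 2 classes")
    labels = np.asarray(d3.labels, int)
    if labels.min(initial=c) < 1 or labels.max(initial=1) > c:
        raise ValueError("labels must lie in 1..c")
    out = []
    for k in range(1, c + 1):
        pos_idx = np.flatnonzero(labels == k)
        if len(pos_idx) == 0:
            raise ValueError(f"class {k} has zero instances")
        neg_idx = np.flatnonzero(labels != k)
        out.append(
            OvrDataset(
                k,
                [d3.images[i] for i in pos_idx],
                [d3.images[i] for i in neg_idx],
            )
        )
    return out


@dataclass
class BaseClassifier:
    """Binary CNN: softmax index 1 is the positive (class-k) probability."""

    net: _nn.Sequential
    architecture: str
    val_accuracy: float = float("nan")
    log: _nn.TrainLog = field(default_factory=_nn.TrainLog)

    def positive_probability(self, images: list[np.ndarray]) -> np.ndarray:
        if not len(images):
            return np.zeros(0)
        return self.net.predict_proba(_to_net_input(images))[:, 1]


def train_base_classifier(
    ovr: OvrDataset,
    architecture: str,
    train_config: _nn.TrainConfig | None = None,
    seed: int = 0,
    balance_negatives: bool = False,
    negative_ratio: float = 3.0,
) -> BaseClassifier:
    """Train one binary base classifier and record its validation accuracy.

    Negatives are the full rest-classes pool by default;
    ``balance_negatives`` subsamples them to ``negative_ratio`` times the
    positive count for heavily imbalanced or time-constrained runs. A
    held-out split (15% of the full pool) provides the accuracy used for
    architecture selection.
    """
    if architecture not in ARCHITECTURE_MENU:
        raise ValueError(f"unknown architecture {architecture!r} (menu: {ARCHITECTURE_MENU})")
    if not ovr.positives or not ovr.negatives:
        raise ValueError("both positives and negatives are required")
    rng = np.random.default_rng(seed)
    images = list(ovr.positives) + list(ovr.negatives)
    y = np.array([1] * len(ovr.positives) + [0] * len(ovr.negatives))
    x = _to_net_input(images)

    # held-out split for the selection metric (taken from the full pool, so
    # it stays representative even when training negatives are subsampled);
    # separate from the trainer's internal early-stopping split
    order = rng.permutation(len(x))
    n_hold = max(1, int(round(0.15 * len(x))))
    hold, tr = order[:n_hold], order[n_hold:]
    if balance_negatives:
        pos_tr = tr[y[tr] == 1]
        neg_tr = tr[y[tr] == 0]
        want = int(round(negative_ratio * len(pos_tr)))
        if len(neg_tr) > want:
            neg_tr = rng.choice(neg_tr, size=want, replace=False)
        tr = rng.permutation(np.concatenate([pos_tr, neg_tr]))
    cfg = train_config or _nn.TrainConfig()
    net = _nn.build_preset(architecture, rng, n_out=2)
    log = _nn.train_classifier(net, x[tr], y[tr], cfg, rng)
    pred = net.predict_proba(x[hold]).argmax(axis=1)
    acc = float((pred == y[hold]).mean())
    logger.info("class %d / %s: val accuracy %.3f (%d epochs)",
                ovr.k, architecture, acc, log.stopped_epoch)
    return BaseClassifier(net, architecture, acc, log)


@dataclass
class EnsembleMember:
    k: int
    architecture: str
    model: BaseClassifier | None
    val_accuracy: float


@dataclass
class EnsembleSpec:
    """Exactly one base classifier per class; ``active_classes`` masks the
    subset enabled at inference (e.g., taxa in season)."""

    members: list[EnsembleMember]
    active_classes: frozenset[int] | None = None  # None = all

    @property
    def n_classes(self) -> int:
        return len(self.members)

    def active(self) -> list[int]:
        if self.active_classes is None:
            return [m.k for m in self.members]
        return sorted(self.active_classes)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = []
        for m in self.members:
            entry = {"class": m.k, "architecture": m.architecture,
                     "val_accuracy": m.val_accuracy,
                     "active": self.active_classes is None or m.k in self.active_classes,
                     "weights": f"class_{m.k}.npz"}
            if m.model is not None:
                arrays = {f"w{i}": a for i, a in enumerate(m.model.net.state_arrays())}
                np.savez(directory / f"class_{m.k}.npz", **arrays)
            manifest.append(entry)
        (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleSpec":
        directory = Path(directory)
        manifest = json.loads((directory / "ensemble.json").read_text())
        members, active = [], set()
        for entry in manifest:
            net = _nn.build_preset(entry["architecture"], np.random.default_rng(0), n_out=2)
            data = np.load(directory / entry["weights"], allow_pickle=False)
            net.load_state_arrays([data[f"w{i}"] for i in range(len(net.state_arrays()))])
            model = BaseClassifier(net, entry["architecture"], entry["val_accuracy"])
            members.append(EnsembleMember(entry["class"], entry["architecture"],
                                          model, entry["val_accuracy"]))
            if entry["active"]:
                active.add(entry["class"])
        spec = cls(members)
        if len(active) != len(members):
            spec.active_classes = frozenset(active)
        return spec


def select_architectures(table: pd.DataFrame) -> EnsembleSpec:
    """Pick, per class (row), the architecture (column) with the highest
    validation accuracy; ties resolve to the earlier column in menu order.

    Returns an EnsembleSpec whose members carry architecture ids and
    accuracies but no trained models.
    """
    if table.isna().any().any():
        raise ValueError("selection table has missing cells")
    members = []
    for ki, (_, row) in enumerate(table.iterrows(), start=1):
        best_arch, best_acc = None, -np.inf
        for arch in table.columns:
            if float(row[arch]) > best_acc:
                best_arch, best_acc = arch, float(row[arch])
        members.append(EnsembleMember(ki, best_arch, None, best_acc))
    return EnsembleSpec(members)


def train_ensemble(
    d3: CropDataset,
    c: int,
    menu: tuple[str, ...] = ARCHITECTURE_MENU,
    train_config: _nn.TrainConfig | None = None,
    seed: int = 0,
    balance_negatives: bool = False,
    negative_ratio: float = 3.0,
) -> tuple[EnsembleSpec, pd.DataFrame]:
    """Train the full class x architecture grid, select the per-class best,
    and return the fitted heterogeneous ensemble plus the accuracy table."""
    ovrs = build_ovr_datasets(d3, c)
    trained: dict[tuple[int, str], BaseClassifier] = {}
    rows = []
    for ovr in ovrs:
        row = {}
        for ai, arch in enumerate(menu):
            clf = train_base_classifier(
                ovr, arch, train_config, seed=seed + 1000 * ovr.k + ai,
                balance_negatives=balance_negatives, negative_ratio=negative_ratio,
            )
            trained[(ovr.k, arch)] = clf
            row[arch] = clf.val_accuracy
        rows.append(row)
    table = pd.DataFrame(rows, index=range(1, c + 1))
    spec = select_architectures(table)
    for m in spec.members:
        m.model = trained[(m.k, m.architecture)]
    return spec, table


def fuse_max(
    probabilities: dict[int, float], active_classes: list[int] | None = None
) -> tuple[int, float]:
    """Max-probability decision fusion over the active classes.

    Returns (label, winning probability); ties break toward the lowest class
    index. Raises if no active class has a probability.
    """
    active = sorted(probabilities) if active_classes is None else sorted(active_classes)
    active = [k for k in active if k in probabilities]
    if not active:
        raise ValueError("no active classes with probabilities")
    best = max(active, key=lambda k: (probabilities[k], -k))
    return best, float(probabilities[best])


@dataclass
class EnsemblePrediction:
    probabilities: dict[int, float]  # only active classes present
    label: int
    probability: float


def classify_region(crop: np.ndarray, ensemble: EnsembleSpec) -> EnsemblePrediction:
    """Run every active base classifier on one crop and fuse by max."""
    return classify_crops([crop], ensemble)[0]


def classify_crops(crops: list[np.ndarray], ensemble: EnsembleSpec) -> list[EnsemblePrediction]:
    """Vectorized ensemble inference over a batch of crops."""
    if not crops:
        return []
    active = set(ensemble.active())
    if not active:
        raise ValueError("ensemble has no active classes")
    fixed = []
    for crop in crops:
        if crop.shape[0] != crop.shape[1]:
            warnings.warn("non-square crop resized for classification")
        fixed.append(crop)
    probs: dict[int, np.ndarray] = {}
    for m in ensemble.members:
        if m.k not in active:
            continue
        if m.model is None:
            raise ValueError(f"ensemble member for class {m.k} has no trained model")
        probs[m.k] = m.model.positive_probability(fixed)
    out = []
    for i in range(len(fixed)):
        vec = {k: float(p[i]) for k, p in probs.items()}
        label, p = fuse_max(vec)
        out.append(EnsemblePrediction(vec, label, p))
    return out


def train_multiclass(
    d3: CropDataset,
    c: int,
    architecture: str = "vgg-tiny",
    train_config: _nn.TrainConfig | None = None,
    seed: int = 0,
) -> "MulticlassClassifier":
    """Single multi-class CNN baseline (the alternative the ensemble is
    compared against)."""
    if architecture not in ARCHITECTURE_MENU:
        raise ValueError(f"unknown architecture {architecture!r}")
    rng = np.random.default_rng(seed)
    x = _to_net_input(d3.images)
    y = np.asarray(d3.labels, int) - 1
    net = _nn.build_preset(architecture, rng, n_out=c)
    cfg = train_config or _nn.TrainConfig()
    log = _nn.train_classifier(net, x, y, cfg, rng)
    return MulticlassClassifier(net, architecture, c, log)


@dataclass
class MulticlassClassifier:
    net: _nn.Sequential
    architecture: str
    n_classes: int
    log: _nn.TrainLog = field(default_factory=_nn.TrainLog)

    def predict(self, images: list[np.ndarray]) -> np.ndarray:
        """1-based labels."""
        if not len(images):
            return np.zeros(0, int)
        return self.net.predict_proba(_to_net_input(images)).argmax(axis=1) + 1
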
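"""One-vs-rest decomposition, architecture selection, max fusion."""

import numpy as np
import pandas as pd
import pytest

from pollenstage import _nn, classify, synth
from pollenstage.classify import (
    BaseClassifier,
    EnsembleMember,
    EnsembleSpec,
    build_ovr_datasets,
    classify_crops,
    classify_region,
    fuse_max,
    select_architectures,
    train_base_classifier,
)


def _crop_dataset(counts: dict[int, int], size: int = 16, seed: int = 0) -> synth.CropDataset:
    """Crops with a distinct hue per class (trivially separable)."""
    rng = np.random.default_rng(seed)
    hues = {k: np.array([220, 40 + 22 * k, 90 + 15 * k]) for k in counts}
    images, labels = [], []
    for k, n in counts.items():
        for _ in range(n):
            img = hues[k][None, None, :] + rng.normal(0, 6, size=(size, size, 3))
            images.append(np.clip(img, 0, 255).astype(np.uint8))
            labels.append(k)
    return synth.CropDataset(images, np.asarray(labels))


class _OracleClassifier:
    """Stub base classifier: probability = closeness to its class hue."""

    def __init__(self, k):
        self.k = k
        self.hue = np.array([220, 40 + 22 * k, 90 + 15 * k])

    def positive_probability(self, images):
        out = []
        for img in images:
            d = np.linalg.norm(img.reshape(-1, 3).mean(0) - self.hue)
            out.append(np.exp(-d / 10))
        return np.asarray(out)


def _oracle_ensemble(classes) -> EnsembleSpec:
    return EnsembleSpec([
        EnsembleMember(k, "oracle", _OracleClassifier(k), 1.0) for k in classes
    ])


class TestBuildOvr:
    def test_counting(self):
        d3 = _crop_dataset({1: 5, 2: 3, 3: 2})
        subsets = build_ovr_datasets(d3, 3)
        assert [len(s.positives) for s in subsets] == [5, 3, 2]
        assert [len(s.negatives) for s in subsets] == [5, 7, 8]

    def test_partition_property(self):
        """Each crop appears exactly once as positive and c-1 times negative."""
        d3 = _crop_dataset({1: 4, 2: 5, 3: 6, 4: 2})
        subsets = build_ovr_datasets(d3, 4)
        n = len(d3)
        assert sum(len(s.positives) for s in subsets) == n
        assert sum(len(s.negatives) for s in subsets) == n * 3
        for s in subsets:
            assert len(s.positives) + len(s.negatives) == n

    def test_degenerate_single_class(self):
        d3 = _crop_dataset({1: 5})
        with pytest.raises(ValueError, match="at least 2"):
            build_ovr_datasets(d3, 1)

    def test_missing_class_named(self):
        d3 = _crop_dataset({1: 5, 3: 5})
        with pytest.raises(ValueError, match="class 2"):
            build_ovr_datasets(d3, 3)

    def test_two_class_mirror(self):
        d3 = _crop_dataset({1: 4, 2: 4})
        a, b = build_ovr_datasets(d3, 2)
        assert [img.tobytes() for img in a.positives] == [img.tobytes() for img in b.negatives]
        assert [img.tobytes() for img in a.negatives] == [img.tobytes() for img in b.positives]


class TestSelectArchitectures:
    # Validation-accuracy grid shaped like a published per-taxon comparison
    # of the four classical families; row-wise maxima drive the selection.
    TOY = pd.DataFrame(
        {
            "alexnet": [58.13, 52.90, 60.27, 64.63, 65.71, 66.53, 53.96, 51.93],
            "vgg16": [87.50, 85.10, 64.93, 84.76, 81.07, 79.90, 56.59, 72.10],
            "resnet50": [82.93, 77.63, 70.93, 71.33, 85.35, 77.30, 67.58, 63.27],
            "densenet121": [74.70, 59.06, 62.43, 91.80, 78.57, 80.22, 52.19, 55.37],
        },
        index=range(1, 9),
    )

    def test_rowwise_argmax_selection(self):
        spec = select_architectures(self.TOY)
        chosen = {m.k: m.architecture for m in spec.members}
        assert chosen == {
            1: "vgg16", 2: "vgg16", 8: "vgg16",
            3: "resnet50", 5: "resnet50", 7: "resnet50",
            4: "densenet121", 6: "densenet121",
        }

    def test_dominant_architecture_homogeneous(self):
        table = pd.DataFrame({"a": [0.9, 0.9], "b": [0.5, 0.6]})
        spec = select_architectures(table)
        assert all(m.architecture == "a" for m in spec.members)

    def test_tie_resolves_to_menu_order(self):
        table = pd.DataFrame({"first": [0.8], "second": [0.8]})
        assert select_architectures(table).members[0].architecture == "first"

    def test_missing_cell_rejected(self):
        table = pd.DataFrame({"a": [0.9, np.nan], "b": [0.5, 0.6]})
        with pytest.raises(ValueError, match="missing"):
            select_architectures(table)


class TestFuseMax:
    def test_plain_argmax(self):
        assert fuse_max({1: 0.9, 2: 0.1, 3: 0.2}) == (1, 0.9)

    def test_tie_lowest_index(self):
        assert fuse_max({1: 0.4, 2: 0.4}) == (1, 0.4)

    def test_masking_inactive_classes(self):
        """Masking the would-be winner reroutes to the best active class."""
        probs = {1: 0.9, 2: 0.95, 3: 0.2}
        assert fuse_max(probs, active_classes=[1, 3]) == (1, 0.9)

    def test_masking_nonmaximal_classes_is_noop(self, rng):
        for _ in range(50):
            probs = {k: float(p) for k, p in enumerate(rng.random(6), start=1)}
            label, p = fuse_max(probs)
            others = [k for k in probs if k != label]
            drop = [k for k in others[:2]]
            kept = [k for k in probs if k not in drop]
            assert fuse_max(probs, active_classes=kept) == (label, p)

    def test_no_active_classes_error(self):
        with pytest.raises(ValueError):
            fuse_max({}, active_classes=[])
        with pytest.raises(ValueError):
            fuse_max({1: 0.5}, active_classes=[2])


class TestClassifyRegion:
    def test_oracle_composition_recovers_labels(self):
        d3 = _crop_dataset({k: 6 for k in range(1, 6)}, seed=3)
        ens = _oracle_ensemble(range(1, 6))
        preds = classify_crops(d3.images, ens)
        assert all(p.label == lab for p, lab in zip(preds, d3.labels))

    def test_single_active_class_always_wins(self):
        d3 = _crop_dataset({1: 3, 2: 3})
        ens = _oracle_ensemble([1, 2])
        ens.active_classes = frozenset([2])
        preds = classify_crops(d3.images, ens)
        assert all(p.label == 2 for p in preds)
        assert all(set(p.probabilities) == {2} for p in preds)

    def test_permutation_equivariance(self):
        """Relabeling classes relabels predictions identically."""
        d3 = _crop_dataset({k: 4 for k in range(1, 5)}, seed=9)
        ens = _oracle_ensemble(range(1, 5))
        preds = [p.label for p in classify_crops(d3.images, ens)]

        perm = {1: 3, 2: 1, 3: 4, 4: 2}
        relabeled = EnsembleSpec([
            EnsembleMember(perm[m.k], "oracle", m.model, 1.0) for m in ens.members
        ])
        preds2 = [p.label for p in classify_crops(d3.images, relabeled)]
        assert preds2 == [perm[p] for p in preds]

    def test_single_crop_wrapper(self):
        d3 = _crop_dataset({1: 1, 2: 1})
        pred = classify_region(d3.images[0], _oracle_ensemble([1, 2]))
        assert pred.label == 1
        assert pred.probability == max(pred.probabilities.values())


class TestTrainBaseClassifier:
    def test_separable_binary_high_accuracy(self):
        """Distinct-hue positives/negatives are separable by a hue threshold
        (oracle); the CNN must validate at 95%+."""
        d3 = _crop_dataset({1: 60, 2: 60}, size=32, seed=5)
        ovr = build_ovr_datasets(d3, 2)[0]

        greens = np.array([img[:, :, 1].mean() for img in ovr.positives + ovr.negatives])
        oracle = greens < 73  # class-1 hue has green 62, class-2 has 84
        truth = np.array([1] * 60 + [0] * 60, bool)
        assert (oracle == truth).mean() == 1.0

        clf = train_base_classifier(ovr, "alexnet-tiny",
                                    _nn.TrainConfig(max_epochs=20), seed=0)
        assert clf.val_accuracy >= 0.95

    def test_determinism(self):
        d3 = _crop_dataset({1: 20, 2: 20}, size=16, seed=6)
        ovr = build_ovr_datasets(d3, 2)[0]
        cfg = _nn.TrainConfig(max_epochs=4)
        a = train_base_classifier(ovr, "vgg-tiny", cfg, seed=1)
        b = train_base_classifier(ovr, "vgg-tiny", cfg, seed=1)
        assert a.val_accuracy == b.val_accuracy
        assert a.log.val_loss == b.log.val_loss

    def test_empty_negatives_rejected(self):
        ovr = classify.OvrDataset(1, [np.zeros((8, 8, 3), np.uint8)], [])
        with pytest.raises(ValueError):
            train_base_classifier(ovr, "vgg-tiny")

    def test_unknown_architecture_rejected(self):
        d3 = _crop_dataset({1: 4, 2: 4})
        ovr = build_ovr_datasets(d3, 2)[0]
        with pytest.raises(ValueError, match="unknown architecture"):
            train_base_classifier(ovr, "lenet-1998")


class TestEnsembleVersusMulticlass:
    @staticmethod
    def _confusable_crops(n_per: int, seed: int) -> synth.CropDataset:
        """Eight classes whose hues come in close pairs, so class-specific
        binary discrimination matters."""
        rng = np.random.default_rng(seed)
        hues = [(210, 60, 100), (210, 78, 100), (160, 120, 60), (160, 120, 78),
                (120, 80, 160), (138, 80, 160), (90, 150, 150), (90, 150, 132)]
        images, labels = [], []
        for k, hue in enumerate(hues, start=1):
            for _ in range(n_per):
                img = np.array(hue)[None, None, :] + rng.normal(0, 14.0, (16, 16, 3))
                images.append(np.clip(img, 0, 255).astype(np.uint8))
                labels.append(k)
        return synth.CropDataset(images, np.asarray(labels))

    def test_ovr_combination_beats_single_multiclass_model(self):
        """The one-vs-rest combination matches or beats a single multi-class
        model of the same architecture and seed for a majority of seeds."""
        tc = _nn.TrainConfig(max_epochs=20)
        wins = 0
        for seed in range(5):
            train = self._confusable_crops(40, seed=seed)
            test = self._confusable_crops(25, seed=100 + seed)
            spec, _ = classify.train_ensemble(
                train, 8, menu=("vgg-tiny",), train_config=tc, seed=seed,
                balance_negatives=True, negative_ratio=3.0,
            )
            ens_acc = np.mean([
                p.label == lab
                for p, lab in zip(classify_crops(test.images, spec), test.labels)
            ])
            mc = classify.train_multiclass(train, 8, "vgg-tiny", tc, seed=seed)
            mc_acc = (mc.predict(test.images) == test.labels).mean()
            wins += ens_acc >= mc_acc
        assert wins >= 3


class TestEnsemblePersistence:
    def test_save_load_roundtrip(self, tmp_path):
        d3 = _crop_dataset({1: 15, 2: 15}, size=16, seed=8)
        spec, table = classify.train_ensemble(
            d3, 2, menu=("vgg-tiny",), train_config=_nn.TrainConfig(max_epochs=3), seed=0
        )
        spec.active_classes = frozenset([1, 2])
        spec.save(tmp_path / "ens")
        loaded = EnsembleSpec.load(tmp_path / "ens")
        assert [m.architecture for m in loaded.members] == [m.architecture for m in spec.members]
        pa = classify_crops(d3.images[:4], spec)
        pb = classify_crops(d3.images[:4], loaded)
        assert [p.label for p in pa] == [p.label for p in pb]
        assert np.allclose(
            [list(p.probabilities.values()) for p in pa],
            [list(p.probabilities.values()) for p in pb],
        )
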
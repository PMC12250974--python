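"""Decision rule, metrics, five-fold cross-validation, and the ablation harness.

Evaluation is subject-dependent: a model is trained and 5-fold cross-validated
within each subject's data (8:2 train/test per fold). The two phase-paired
samples derived from one EEG window always land in the same fold — splitting
them would leak near-duplicate signals between train and test. Folds are
stratified by class so small synthetic sets never produce an empty-class test
fold. Augmentation happens after splitting and only on training folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .augmentation import AugmentConfig, augment_set
from .model import ModelConfig, TRMMAAN, build_model
from .preprocessing import PairedSample
from .training import TrainConfig, fit, samples_to_arrays
from .autodiff import Tensor, no_grad

__all__ = ["ConfusionMatrix", "EvalReport", "predict", "accuracy", "macro_f1",
           "confusion_matrix", "evaluate_model", "five_fold_cv", "run_ablation",
           "ABLATION_VARIANTS"]

logger = logging.getLogger(__name__)

#: public names of the ablation variants mapped onto model-config variants
ABLATION_VARIANTS = {
    "TRM_MAAN": "trm_maan", "TRM": "trm", "MAAN": "maan",
    "Uni_EEG": "uni_eeg", "Uni_EMG": "uni_emg",
}


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = samples with true class i predicted as class j."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    per_fold: list[dict] = field(default_factory=list)
    mean_acc: float = float("nan")
    sd_acc: float = float("nan")
    mean_f1: float = float("nan")
    sd_f1: float = float("nan")

    def summarize(self) -> "EvalReport":
        accs = [f["acc"] for f in self.per_fold]
        f1s = [f["f1"] for f in self.per_fold]
        self.mean_acc = float(np.mean(accs))
        self.sd_acc = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
        self.mean_f1 = float(np.mean(f1s))
        self.sd_f1 = float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0
        return self

    def to_dict(self) -> dict:
        return {
            "folds": [
                {**f, "confusion": np.asarray(f["confusion"].counts).tolist()}
                for f in self.per_fold
            ],
            "mean_acc": self.mean_acc, "sd_acc": self.sd_acc,
            "mean_f1": self.mean_f1, "sd_f1": self.sd_f1,
        }


def predict(model: TRMMAAN, sample: PairedSample) -> int:
    """Argmax decision over workload class probabilities.

    Ties break to the lowest class index.
    """
    probs = model.predict_proba(sample.eeg[None], sample.emg[None])[0]
    return int(np.argmax(probs))


def predict_batch(model: TRMMAAN, samples: list[PairedSample]) -> np.ndarray:
    eeg, emg, _ = samples_to_arrays(samples)
    probs = model.predict_proba(eeg, emg)
    return probs.argmax(axis=-1)


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     n_classes: int = 3) -> ConfusionMatrix:
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        counts[int(t), int(p)] += 1
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Multi-class accuracy: trace / total."""
    if cm.total == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class one-vs-rest F1 scores.

    A class with no true and no predicted instances contributes F1 = 0 (with
    a warning) rather than being dropped.
    """
    if cm.total == 0:
        raise ValueError("F1 undefined for an empty confusion matrix")
    c = cm.counts
    f1s = []
    for i in range(c.shape[0]):
        tp = c[i, i]
        fp = c[:, i].sum() - tp
        fn = c[i, :].sum() - tp
        if tp + fp + fn == 0:
            warnings.warn(f"class {i} absent from truth and predictions; "
                          "its F1 counts as 0", UserWarning, stacklevel=2)
            f1s.append(0.0)
            continue
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return float(np.mean(f1s))


def _modal_accuracy(model: TRMMAAN, samples: list[PairedSample]) -> float:
    """Accuracy of the modal classifier M on this set's fused features."""
    if not model.uses_adversary:
        return float("nan")
    eeg, emg, _ = samples_to_arrays(samples)
    model.eval()
    with no_grad():
        fused = model.fused_features(Tensor(eeg), Tensor(emg))
        correct = 0
        n = 0
        for idx, m in enumerate(("eeg", "emg")):
            pred = model.modal_head.logits(fused[m]).data.argmax(axis=-1)
            correct += int((pred == idx).sum())
            n += len(pred)
    model.train()
    return correct / n


def stratified_group_folds(samples: list[PairedSample], n_folds: int,
                           rng: np.random.Generator) -> list[list[int]]:
    """Assign samples to folds by (subject, window) group, stratified by label.

    Both interleaved-phase samples of one EEG window share a group and
    therefore a fold.
    """
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault((s.subject_id, s.window_index), []).append(i)
    by_label: dict[int, list[tuple]] = {}
    for key, idxs in groups.items():
        by_label.setdefault(samples[idxs[0]].label, []).append(key)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    counter = 0
    for label in sorted(by_label):
        keys = sorted(by_label[label])
        rng.shuffle(keys)
        for key in keys:
            folds[counter % n_folds].extend(groups[key])
            counter += 1
    return folds


def evaluate_model(model: TRMMAAN, test: list[PairedSample]) -> dict:
    y_true = np.array([s.label for s in test])
    y_pred = predict_batch(model, test)
    cm = confusion_matrix(y_true, y_pred, model.cfg.n_classes)
    return {"acc": accuracy(cm), "f1": macro_f1(cm), "confusion": cm,
            "modal_acc": _modal_accuracy(model, test)}


def five_fold_cv(data: list[PairedSample], model_cfg: ModelConfig,
                 train_cfg: TrainConfig, aug_cfg: AugmentConfig | None = None,
                 seed: int = 0, n_folds: int = 5) -> EvalReport:
    """Subject-level 8:2 five-fold cross-validation."""
    if aug_cfg is None:
        aug_cfg = AugmentConfig(seed=seed)
    n_groups = len({(s.subject_id, s.window_index) for s in data})
    if n_groups < n_folds:
        raise ValueError(f"need at least {n_folds} windows, got {n_groups}")
    if any(s.is_augmented for s in data):
        raise ValueError("cross-validation input must not contain augmented samples")
    rng = np.random.default_rng(seed)
    folds = stratified_group_folds(data, n_folds, rng)

    report = EvalReport()
    for k, test_idx in enumerate(folds):
        train_idx = [i for f in folds if f is not test_idx for i in f]
        test = [data[i] for i in test_idx]
        train = [data[i] for i in train_idx]
        test_keys = {(s.subject_id, s.window_index) for s in test}
        train_keys = {(s.subject_id, s.window_index) for s in train}
        assert not (test_keys & train_keys), "fold leakage by window group"
        train = augment_set(train, aug_cfg)
        n_ch, wlen = test[0].eeg.shape
        model = build_model(model_cfg, n_ch, wlen, seed=seed * 1000 + k)
        fit(model, train, replace(train_cfg, seed=seed * 1000 + k))
        fold_result = evaluate_model(model, test)
        fold_result["fold"] = k
        report.per_fold.append(fold_result)
        logger.info("fold %d: acc=%.3f f1=%.3f", k, fold_result["acc"],
                    fold_result["f1"])
    return report.summarize()


def run_ablation(variant: str, data: list[PairedSample],
                 model_cfg: ModelConfig, train_cfg: TrainConfig,
                 aug_cfg: AugmentConfig | None = None, seed: int = 0,
                 n_folds: int = 5) -> EvalReport:
    """Five-fold CV for one ablation variant (TRM_MAAN / TRM / MAAN / Uni_*)."""
    key = ABLATION_VARIANTS.get(variant, variant)
    if key not in ABLATION_VARIANTS.values():
        raise ValueError(f"unknown ablation variant {variant!r}")
    cfg = replace(model_cfg, variant=key)
    return five_fold_cv(data, cfg, train_cfg, aug_cfg, seed=seed,
                        n_folds=n_folds)
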
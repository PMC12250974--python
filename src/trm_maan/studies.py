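"""Predefined synthetic studies: alignment, ablation ordering, trainability,
determinism.

These are the package's standard evaluation experiments on the synthetic
generator, shared by the test suite and ``scripts/acceptance.py``. The
problem sizes are scaled for a single CPU (see docs/methods.md): 8 channels
at a 125 Hz post-pairing rate, a small model, float32 arithmetic, reduced
epochs. Thresholds and protocols (5 seeds, 5 folds, probe definitions) are
not reduced.
"""

from __future__ import annotations




from .augmentation import AugmentConfig, augment_set
from .autodiff import default_dtype
from .config import ExperimentConfig, run_experiment
from .evaluation import run_ablation
from .model import ModelConfig, build_model
from .synthetic import ModalityShift, SimConfig, make_paired_dataset, model_shift_probe
from .training import TrainConfig, fit

__all__ = ["study_sim_config", "study_model_config", "study_train_config",
           "alignment_study", "ablation_study", "trainability_study",
           "determinism_study"]

#: training epochs per variant: the adversarial game needs the most steps;
#: the plain variants converge within ~10 epochs on the band task
STUDY_EPOCHS = {"TRM_MAAN": 50, "TRM": 12, "MAAN": 15}
ABLATION_EPOCHS = {"TRM_MAAN": 20, "TRM": 10, "MAAN": 10}


def study_sim_config(seed: int, **overrides) -> SimConfig:
    base = dict(n_subjects=1, windows_per_class=20, n_channels=8,
                rate_hz=125.0, snr_db=10.0, seed=seed)
    base.update(overrides)
    return SimConfig(**base)


def study_model_config(variant: str = "trm_maan", **overrides) -> ModelConfig:
    base = dict(D=8, n_heads=2, n_layers=1, trunk_channels=4, fc_hidden=16,
                proj_stride=2, variant=variant)
    base.update(overrides)
    return ModelConfig(**base)


def study_train_config(epochs: int, seed: int, **overrides) -> TrainConfig:
    base = dict(epochs=epochs, batch_size=32, seed=seed, patience=1000)
    base.update(overrides)
    return TrainConfig(**base)


def _train_variant(data, variant: str, epochs: int, seed: int):
    n_ch, wlen = data[0].eeg.shape
    model = build_model(study_model_config(variant.lower()), n_ch, wlen,
                        seed=seed)
    train = augment_set(data, AugmentConfig(seed=seed))
    fit(model, train, study_train_config(epochs, seed))
    return model


def alignment_study(seeds=range(5), windows_per_class: int = 20) -> dict:
    """Modality-probe accuracy on fused features, with and without the
    adversary, per seed.

    The probe (held-out linear classifier separating EEG-derived from
    EMG-derived fused features) reads near 1.0 when the modality shift
    survives into the fused space and near 0.5 when it is removed.
    """
    out = {"trm": {}, "trm_maan": {}}
    with default_dtype("float32"):
        for seed in seeds:
            data = make_paired_dataset(
                study_sim_config(seed, windows_per_class=windows_per_class))
            for variant in ("trm", "trm_maan"):
                model = _train_variant(data, variant,
                                       STUDY_EPOCHS[variant.upper()], seed)
                out[variant][seed] = model_shift_probe(model, data, seed=seed)
    return out


def ablation_study(seeds=range(5), windows_per_class: int = 20,
                   variants=("TRM_MAAN", "TRM", "MAAN"),
                   epochs: dict | None = None) -> dict:
    """Mean five-fold CV accuracy per ablation variant, per seed."""
    epochs = epochs or ABLATION_EPOCHS
    out = {v: {} for v in variants}
    with default_dtype("float32"):
        for seed in seeds:
            data = make_paired_dataset(
                study_sim_config(seed, windows_per_class=windows_per_class))
            for variant in variants:
                rep = run_ablation(
                    variant, data, study_model_config(),
                    study_train_config(epochs[variant], seed),
                    AugmentConfig(seed=seed), seed=seed)
                out[variant][seed] = rep.mean_acc
    return out


def trainability_study(seed: int = 0, windows_per_class: int = 20,
                       epochs: int = 40) -> float:
    """Five-fold mean accuracy of the full model on easy data (high SNR, no
    modality shift) — a pipeline sanity check that the solvable task is
    solved."""
    with default_dtype("float32"):
        data = make_paired_dataset(study_sim_config(
            seed, windows_per_class=windows_per_class, snr_db=30.0,
            modality_shift=ModalityShift(enabled=False)))
        rep = run_ablation("TRM_MAAN", data, study_model_config(),
                           study_train_config(epochs, seed),
                           AugmentConfig(seed=seed), seed=seed)
    return rep.mean_acc


def determinism_study(seed: int = 0) -> tuple[dict, dict]:
    """Two identically seeded end-to-end runs; reports should be identical."""
    cfg = ExperimentConfig(
        simulate=study_sim_config(seed, windows_per_class=6),
        model=study_model_config(),
        train=study_train_config(3, seed, critic_steps=5),
    ).with_seed(seed)
    with default_dtype("float32"):
        a = run_experiment(cfg)
        b = run_experiment(cfg)
    return a, b
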
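"""Training-set augmentation: flipped copies and additive Gaussian noise.

The augmented set is the union of the originals, a time-reversed copy of each
sample, and a noised copy of each sample (3x the input size). Augmentation is
only ever applied to training folds; the provenance flag ``is_augmented`` lets
the evaluation code assert that no augmented sample reaches a test fold.

The noise scale is specified *relative* to the per-modality training-set
standard deviation, because EEG (microvolts) and EMG (millivolts) live on
amplitude scales orders of magnitude apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import PairedSample

__all__ = ["AugmentConfig", "flip", "add_gaussian_noise", "augment_set"]


@dataclass
class AugmentConfig:
    sigma_rel: float = 0.05     # noise SD as a fraction of per-modality SD
    flip_axis: str = "time"     # "time" | "channel"
    enabled: bool = True
    flip_prob: float | None = None  # None: deterministic copy-and-flip
    seed: int = 0

    def __post_init__(self):
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")
        if self.flip_axis not in ("time", "channel"):
            raise ValueError("flip_axis must be 'time' or 'channel'")


def flip(x: np.ndarray, flip_axis: str = "time") -> np.ndarray:
    """Reverse sample order along the flip axis (an involution)."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("cannot flip an empty array")
    axis = -1 if flip_axis == "time" else 0
    return np.flip(x, axis=axis).copy()


def add_gaussian_noise(x: np.ndarray, sigma: float,
                       rng: np.random.Generator | int) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise with standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=np.float64)
    if sigma == 0:
        return x.copy()
    return x + rng.normal(0.0, sigma, size=x.shape)


def augment_set(samples: list[PairedSample],
                cfg: AugmentConfig) -> list[PairedSample]:
    """Originals + one flipped copy + one noised copy per sample.

    Both modalities of a copy get the same kind of transform; labels and
    sample identity (subject, window index, phase) are preserved.
    """
    if not samples:
        raise ValueError("augment_set needs a nonempty sample list")
    if not cfg.enabled:
        return list(samples)
    rng = np.random.default_rng(cfg.seed)
    sigma_eeg = cfg.sigma_rel * float(np.std([s.eeg for s in samples]))
    sigma_emg = cfg.sigma_rel * float(np.std([s.emg for s in samples]))

    out: list[PairedSample] = list(samples)
    for s in samples:
        do_flip = (cfg.flip_prob is None) or (rng.random() < cfg.flip_prob)
        if do_flip:
            out.append(PairedSample(
                flip(s.eeg, cfg.flip_axis), flip(s.emg, cfg.flip_axis),
                s.label, s.subject_id, s.window_index, s.eeg_phase,
                is_augmented=True))
        out.append(PairedSample(
            add_gaussian_noise(s.eeg, sigma_eeg, rng),
            add_gaussian_noise(s.emg, sigma_emg, rng),
            s.label, s.subject_id, s.window_index, s.eeg_phase,
            is_augmented=True))
    return out
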
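"""Synthetic paired EEG/EMG generator with a controllable modality shift.

The original pilot recordings are not deposited, so alignment and
classification claims are exercised on synthetic signals that reproduce the
*structure* the pipeline depends on:

- 1-s windows of multichannel signals, EEG-like stream generated at twice the
  post-pairing rate so the interleaved-downsampling path is exercised;
- class-dependent band-limited oscillations (three workload classes mapped to
  three frequency bands, loosely evoking theta/alpha/beta rhythms — a testing
  stand-in, not a physiological claim) plus white noise at a configurable SNR;
- a modality shift applied to the EMG-like stream only (additive offset,
  multiplicative scale, and a nuisance oscillation band) that does not change
  the class-conditional band structure, i.e. exactly the kind of
  between-modality distribution shift the adversarial alignment is meant to
  remove.

``shift_probe`` quantifies that shift: the held-out accuracy of a linear probe
trained to tell EEG-derived from EMG-derived features. Near 1.0 means a strong
shift, near 0.5 means the modalities are aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .preprocessing import (Modality, PairedSample, Recording,
                            preprocess_recordings)

__all__ = ["ModalityShift", "SimConfig", "simulate_recording",
           "make_paired_dataset", "shift_probe", "shift_probe_features",
           "model_shift_probe", "band_energy_classifier"]

DEFAULT_BANDS = ((4.0, 8.0), (8.0, 13.0), (13.0, 30.0))


@dataclass
class ModalityShift:
    offset: float = 2.0
    scale: float = 1.5
    extra_band_hz: tuple[float, float] = (45.0, 55.0)
    enabled: bool = True


@dataclass
class SimConfig:
    n_subjects: int = 1
    windows_per_class: int = 20
    n_channels: int = 32
    rate_hz: float = 1000.0              # post-pairing rate; EEG-like at 2x
    class_band_hz: tuple = DEFAULT_BANDS
    snr_db: float = 10.0
    modality_shift: ModalityShift = field(default_factory=ModalityShift)
    seed: int = 0
    n_components: int = 3                # sinusoids per window and channel

    def __post_init__(self):
        if isinstance(self.modality_shift, dict):
            self.modality_shift = ModalityShift(**self.modality_shift)
        self.class_band_hz = tuple(tuple(b) for b in self.class_band_hz)
        if len(self.class_band_hz) != 3:
            raise ValueError("need one frequency band per workload class")
        nyq = self.rate_hz / 2.0
        for lo, hi in self.class_band_hz:
            if not (0 < lo < hi < nyq):
                raise ValueError(f"class band ({lo}, {hi}) outside (0, {nyq})")
        if self.modality_shift.enabled:
            lo, hi = self.modality_shift.extra_band_hz
            if not (0 < lo < hi < nyq):
                raise ValueError(f"nuisance band ({lo}, {hi}) outside (0, {nyq})")
        if self.windows_per_class < 5:
            raise ValueError("windows_per_class must be >= 5")


def _band_signal(rng: np.random.Generator, band: tuple[float, float],
                 n_channels: int, n_samples: int, rate: float,
                 n_components: int) -> np.ndarray:
    """Sum of random sinusoids inside ``band``, unit RMS per channel."""
    t = np.arange(n_samples) / rate
    sig = np.zeros((n_channels, n_samples))
    freqs = rng.uniform(band[0], band[1], size=(n_channels, n_components))
    phases = rng.uniform(0, 2 * np.pi, size=(n_channels, n_components))
    amps = rng.uniform(0.5, 1.5, size=(n_channels, n_components))
    for c in range(n_channels):
        sig[c] = (amps[c][:, None]
                  * np.sin(2 * np.pi * freqs[c][:, None] * t
                           + phases[c][:, None])).sum(axis=0)
    rms = np.sqrt((sig**2).mean(axis=1, keepdims=True))
    return sig / rms


def simulate_recording(cfg: SimConfig, subject: int = 0
                       ) -> tuple[Recording, Recording, np.ndarray]:
    """One subject's continuous EEG-like and EMG-like recordings plus
    per-window labels.

    Window order is shuffled so class blocks are not contiguous in time. The
    EEG-like stream runs at ``2 * rate_hz`` (interleaved-downsampling path);
    the EMG-like stream carries the same class-band structure pushed through
    the modality shift.
    """
    rng = np.random.default_rng((cfg.seed, subject, 0xC1A55))
    labels = np.repeat(np.arange(3), cfg.windows_per_class)
    rng.shuffle(labels)
    noise_sd = 10.0 ** (-cfg.snr_db / 20.0)  # class signal has unit RMS
    T = int(round(cfg.rate_hz))              # 1-s window, post-pairing rate
    eeg_windows, emg_windows = [], []
    for label in labels:
        band = cfg.class_band_hz[label]
        eeg = _band_signal(rng, band, cfg.n_channels, 2 * T, 2 * cfg.rate_hz,
                           cfg.n_components)
        eeg += rng.normal(0, noise_sd, size=eeg.shape)
        emg = _band_signal(rng, band, cfg.n_channels, T, cfg.rate_hz,
                           cfg.n_components)
        shift = cfg.modality_shift
        if shift.enabled:
            nuisance = _band_signal(rng, shift.extra_band_hz, cfg.n_channels,
                                    T, cfg.rate_hz, cfg.n_components)
            emg = shift.scale * emg + shift.offset + nuisance
        emg += rng.normal(0, noise_sd, size=emg.shape)
        eeg_windows.append(eeg)
        emg_windows.append(emg)
    eeg_rec = Recording(Modality.EEG, np.concatenate(eeg_windows, axis=1),
                        2 * cfg.rate_hz, subject_id=f"S{subject}")
    emg_rec = Recording(Modality.EMG, np.concatenate(emg_windows, axis=1),
                        cfg.rate_hz, subject_id=f"S{subject}")
    return eeg_rec, emg_rec, labels


def make_paired_dataset(cfg: SimConfig, subject: int = 0,
                        apply_bandpass: bool = False) -> list[PairedSample]:
    """Simulate one subject and run the real preprocessing chain.

    The generated signals are already band-limited, so the per-modality
    bandpass is off by default (the EMG-band filter would remove the
    low-frequency class signal the generator plants in both modalities).
    """
    eeg, emg, labels = simulate_recording(cfg, subject)
    return preprocess_recordings(eeg, emg, labels,
                                 apply_bandpass=apply_bandpass)


# -- modality-shift probe ----------------------------------------------------


def _summary_features(window: np.ndarray) -> np.ndarray:
    """Cheap per-channel summary (mean and SD) of a raw window."""
    return np.concatenate([window.mean(axis=1), window.std(axis=1)])


def shift_probe_features(feat_eeg: np.ndarray, feat_emg: np.ndarray,
                         seed: int = 0, test_frac: float = 0.3) -> float:
    """Held-out accuracy of a linear probe separating the two feature sets."""
    X = np.concatenate([feat_eeg, feat_emg], axis=0)
    y = np.concatenate([np.zeros(len(feat_eeg)), np.ones(len(feat_emg))])
    if len(y) < 20:
        raise ValueError("need at least 20 feature vectors for the probe")
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_frac, random_state=seed, stratify=y)
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0) + 1e-12
    clf = LogisticRegression(max_iter=2000, C=1.0)
    clf.fit((Xtr - mu) / sd, ytr)
    return float(clf.score((Xte - mu) / sd, yte))


def shift_probe(samples: list[PairedSample], featurizer=None,
                seed: int = 0) -> float:
    """Probe accuracy on per-sample features of the raw windows.

    Near 1.0: the modalities are easily told apart (strong shift);
    near 0.5: no detectable difference.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 paired samples for the probe")
    featurizer = featurizer or _summary_features
    fe = np.stack([featurizer(s.eeg) for s in samples])
    fm = np.stack([featurizer(s.emg) for s in samples])
    return shift_probe_features(fe, fm, seed=seed)


def model_shift_probe(model, samples: list[PairedSample], seed: int = 0) -> float:
    """Probe accuracy on the model's *fused* features — the alignment metric.

    A well-aligned model (trained with the adversary) drives this toward 0.5;
    an unaligned model leaves the modality shift linearly decodable.
    """
    from .autodiff import Tensor, no_grad
    from .training import samples_to_arrays
    eeg, emg, _ = samples_to_arrays(samples)
    model.eval()
    with no_grad():
        fused = model.fused_features(Tensor(eeg), Tensor(emg))
    model.train()
    return shift_probe_features(fused["eeg"].data, fused["emg"].data, seed=seed)


def band_energy_classifier(samples: list[PairedSample],
                           bands: tuple = DEFAULT_BANDS,
                           rate_hz: float = 1000.0) -> np.ndarray:
    """Learning-free oracle: classify each sample by which class band holds
    the most EEG spectral energy. Establishes the task is solvable."""
    preds = []
    for s in samples:
        spec = np.abs(np.fft.rfft(s.eeg, axis=1))**2
        freqs = np.fft.rfftfreq(s.eeg.shape[1], d=1.0 / rate_hz)
        energies = [spec[:, (freqs >= lo) & (freqs < hi)].sum() / (hi - lo)
                    for lo, hi in bands]
        preds.append(int(np.argmax(energies)))
    return np.array(preds)
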
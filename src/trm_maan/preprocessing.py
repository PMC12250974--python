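"""Signal preprocessing: bandpass filtering, windowing, interleaved EEG
downsampling, and EEG/EMG pairing.

The pipeline mirrors standard multimodal biosignal practice: the continuous
recording is filtered first (zero-phase, so edge transients only affect
recording ends and window alignment across modalities is preserved), then cut
into non-overlapping 1-s windows.  Each 2 kHz EEG window is split into two
interleaved 1 kHz streams (odd samples / even samples, in the 1-based
convention), and each stream is paired with the simultaneous EMG window —
doubling the sample count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps

__all__ = [
    "Modality", "Recording", "PairedSample", "bandpass_filter", "split_windows",
    "interleave_downsample", "reinterleave", "pair_samples",
    "EEG_BAND", "EMG_BAND", "preprocess_recordings",
]

logger = logging.getLogger(__name__)

EEG_BAND = (0.1, 30.0)
EMG_BAND = (75.0, 500.0)

#: upper band edge is clipped to this fraction of the sampling rate when the
#: requested edge would sit at or above Nyquist (e.g. the 500 Hz EMG edge at
#: a 1 kHz sampling rate)
NYQUIST_CLIP_FRACTION = 0.45


class Modality(str, Enum):
    EEG = "EEG"
    EMG = "EMG"


@dataclass
class Recording:
    """A continuous multichannel recording of one modality."""

    modality: Modality
    data: np.ndarray          # [channels x samples]
    rate_hz: float
    subject_id: str = "S0"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("recording data must be [channels x samples]")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN/Inf")
        self.modality = Modality(self.modality)

    @property
    def channel_count(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class PairedSample:
    """One 1-s EEG window paired with the simultaneous EMG window."""

    eeg: np.ndarray           # [channels x samples]
    emg: np.ndarray           # [channels x samples]
    label: int                # 0 low / 1 moderate / 2 high workload
    subject_id: str
    window_index: int
    eeg_phase: str            # "odd" | "even": which interleaved stream
    is_augmented: bool = False

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.emg = np.asarray(self.emg, dtype=np.float64)
        if self.eeg.shape[1] != self.emg.shape[1]:
            raise ValueError("EEG and EMG windows must have equal sample counts")
        if self.label not in (0, 1, 2):
            raise ValueError("label must be in {0, 1, 2}")
        if self.eeg_phase not in ("odd", "even"):
            raise ValueError("eeg_phase must be 'odd' or 'even'")


def design_bandpass(low_hz: float, high_hz: float, rate_hz: float,
                    order: int = 4):
    """Butterworth band edges -> (lowpass SOS, highpass SOS) cascade.

    The band is realized as a lowpass at the upper edge followed by a
    highpass at the lower edge rather than a single bandpass section set:
    with a near-DC lower edge (0.1 Hz) the bandpass SOS is numerically
    fragile under forward-backward filtering, while the cascade is robust.
    The lowpass runs first so that the highpass' slow edge transients are
    excited only by already-band-limited content.

    An upper edge at or above Nyquist is unrealizable; it is clipped to
    ``NYQUIST_CLIP_FRACTION * rate_hz`` with a warning.
    """
    nyq = rate_hz / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"invalid band ({low_hz}, {high_hz})")
    if low_hz >= nyq:
        raise ValueError(f"low edge {low_hz} Hz at or above Nyquist {nyq} Hz")
    if high_hz >= nyq:
        clipped = NYQUIST_CLIP_FRACTION * rate_hz
        warnings.warn(
            f"band edge {high_hz} Hz >= Nyquist {nyq} Hz; clipping to "
            f"{clipped} Hz", UserWarning, stacklevel=2)
        high_hz = clipped
    lp = sps.butter(order, high_hz, btype="lowpass", fs=rate_hz)
    hp = sps.butter(order, low_hz, btype="highpass", fs=rate_hz)
    return lp, hp


def _gust_irlen(rate_hz: float, cutoff_hz: float, n_samples: int) -> int:
    """Impulse-response length for Gustafsson initial-condition fitting."""
    return int(min(n_samples - 1, max(100, 10 * rate_hz / cutoff_hz), 50000))


def bandpass_filter(rec: Recording, low_hz: float, high_hz: float,
                    order: int = 4) -> Recording:
    """Zero-phase (forward-backward) Butterworth bandpass, per channel.

    Uses Gustafsson's initial-condition method so that the slow pole of the
    near-DC lower edge does not leak edge transients into the recording.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    (b_lp, a_lp), (b_hp, a_hp) = design_bandpass(low_hz, high_hz,
                                                 rec.rate_hz, order=order)
    filtered = sps.filtfilt(b_lp, a_lp, rec.data, axis=1, method="gust",
                            irlen=_gust_irlen(rec.rate_hz, high_hz,
                                              rec.n_samples))
    filtered = sps.filtfilt(b_hp, a_hp, filtered, axis=1, method="gust",
                            irlen=_gust_irlen(rec.rate_hz, low_hz,
                                              rec.n_samples))
    return Recording(rec.modality, filtered, rec.rate_hz, rec.subject_id)


def split_windows(rec: Recording, window_s: float = 1.0) -> list[np.ndarray]:
    """Cut into consecutive non-overlapping windows; trailing remainder
    (fewer than one window of samples) is discarded."""
    if window_s <= 0:
        raise ValueError("window length must be positive")
    wlen = int(round(window_s * rec.rate_hz))
    n = rec.n_samples // wlen
    return [rec.data[:, i * wlen:(i + 1) * wlen].copy() for i in range(n)]


def interleave_downsample(eeg_window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a [C x 2N] window into its two interleaved half-rate streams.

    Stream A holds samples 1, 3, 5, ... and stream B samples 2, 4, 6, ...
    in the 1-based convention (0-based: even and odd indices respectively).
    """
    eeg_window = np.asarray(eeg_window)
    if eeg_window.shape[-1] % 2 != 0:
        raise ValueError("interleaved downsampling needs an even sample count")
    return eeg_window[..., 0::2].copy(), eeg_window[..., 1::2].copy()


def reinterleave(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Inverse of :func:`interleave_downsample` (bit-exact)."""
    if a.shape != b.shape:
        raise ValueError("streams must have equal shapes")
    out = np.empty(a.shape[:-1] + (2 * a.shape[-1],), dtype=a.dtype)
    out[..., 0::2] = a
    out[..., 1::2] = b
    return out


def pair_samples(eeg_streams: tuple[np.ndarray, np.ndarray],
                 emg_window: np.ndarray, label: int, subject_id: str,
                 window_index: int) -> list[PairedSample]:
    """Pair both interleaved EEG streams with the same EMG window."""
    out = []
    for stream, phase in zip(eeg_streams, ("odd", "even")):
        if stream.shape[-1] != emg_window.shape[-1]:
            raise ValueError(
                f"EEG stream length {stream.shape[-1]} != EMG window length "
                f"{emg_window.shape[-1]}")
        out.append(PairedSample(stream, emg_window, label, subject_id,
                                window_index, phase))
    return out


def preprocess_recordings(eeg: Recording, emg: Recording,
                          window_labels: list[int] | np.ndarray,
                          window_s: float = 1.0,
                          apply_bandpass: bool = True,
                          eeg_band: tuple[float, float] = EEG_BAND,
                          emg_band: tuple[float, float] = EMG_BAND,
                          ) -> list[PairedSample]:
    """Full preprocessing chain for one simultaneously recorded EEG/EMG pair.

    ``window_labels`` gives one workload label per 1-s window (labels are
    taken as given; deriving them from questionnaire scores is out of scope).
    The EEG recording must run at twice the EMG rate so the interleaved
    streams match the EMG window length.
    """
    if eeg.modality != Modality.EEG or emg.modality != Modality.EMG:
        raise ValueError("arguments must be (EEG recording, EMG recording)")
    if abs(eeg.rate_hz - 2 * emg.rate_hz) > 1e-9:
        raise ValueError("EEG rate must be exactly twice the EMG rate")
    if apply_bandpass:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # Nyquist clip is logged
            eeg = bandpass_filter(eeg, *eeg_band)
            emg = bandpass_filter(emg, *emg_band)
    eeg_windows = split_windows(eeg, window_s)
    emg_windows = split_windows(emg, window_s)
    n = min(len(eeg_windows), len(emg_windows), len(window_labels))
    samples: list[PairedSample] = []
    for i in range(n):
        streams = interleave_downsample(eeg_windows[i])
        samples.extend(pair_samples(streams, emg_windows[i],
                                    int(window_labels[i]), eeg.subject_id, i))
    logger.info("preprocessed %d windows -> %d paired samples", n, len(samples))
    return samples
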
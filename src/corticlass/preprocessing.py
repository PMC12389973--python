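"""Scalp-signal conditioning: notch, band-pass, decimation, z-score, epoching.

All filters are zero-phase forward-backward Butterworth (order 4), the
standard phase-preserving choice for EEG when downstream features depend on
instantaneous phase. The canonical chain is

    notch -> band-pass -> downsample -> artifact flag -> z-score -> epoch

and z-scoring uses the population standard deviation per channel over time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synthetic import EEGRecording

FILTER_ORDER = 4
NOTCH_Q = 30.0


@dataclass
class Epoch:
    """A fixed-length non-overlapping segment of one subject's recording."""

    data: np.ndarray  # [L x T_epoch]
    sampling_rate: float
    subject_id: str
    label: int
    domain_id: str
    epoch_index: int
    artifact: bool = False


def _check_band_edge(freq: float, fs: float) -> None:
    if not (0 < freq < fs / 2):
        raise ValueError(f"frequency {freq} Hz outside (0, Nyquist={fs / 2}) at rate {fs}")


def notch_filter(rec: EEGRecording, freq: float = 50.0) -> EEGRecording:
    """Remove a narrow band around ``freq`` (power-line interference)."""
    _check_band_edge(freq, rec.sampling_rate)
    b, a = sps.iirnotch(freq, NOTCH_Q, fs=rec.sampling_rate)
    out = sps.filtfilt(b, a, rec.data, axis=-1)
    return replace(rec, data=out)


def bandpass_filter(rec: EEGRecording, low: float, high: float) -> EEGRecording:
    """Zero-phase Butterworth band-pass keeping [low, high] Hz."""
    if not (0 < low < high):
        raise ValueError("require 0 < low < high")
    _check_band_edge(high, rec.sampling_rate)
    sos = sps.butter(FILTER_ORDER, [low, high], btype="bandpass",
                     fs=rec.sampling_rate, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=out)


def downsample(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Anti-aliased decimation to ``target_rate`` (must divide the rate)."""
    ratio = rec.sampling_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("target_rate must be an integer divisor of sampling_rate")
    q = int(round(ratio))
    if q == 1:
        return replace(rec, data=rec.data.copy())
    # Polyphase FIR anti-alias filter: unit DC gain, linear phase, and
    # line-extension padding so constant signals pass through exactly.
    out = sps.resample_poly(rec.data, 1, q, axis=-1, padtype="line")
    return replace(rec, data=out, sampling_rate=target_rate)


def zscore(rec: EEGRecording) -> EEGRecording:
    """Standardize each channel over time (population convention)."""
    mu = rec.data.mean(axis=-1, keepdims=True)
    sd = rec.data.std(axis=-1, keepdims=True)  # ddof=0
    if np.any(sd == 0):
        bad = np.flatnonzero(sd[:, 0] == 0)
        raise ValueError(f"zero-variance-channel: channels {bad.tolist()}")
    return replace(rec, data=(rec.data - mu) / sd)


def epoch_split(rec: EEGRecording, epoch_seconds: float = 2.0,
                max_epochs: int = 150) -> list[Epoch]:
    """Split into consecutive non-overlapping epochs from t=0.

    The trailing partial segment is discarded; at most ``max_epochs`` epochs
    are returned.
    """
    t_epoch = epoch_seconds * rec.sampling_rate
    if abs(t_epoch - round(t_epoch)) > 1e-9:
        raise ValueError("epoch_seconds * sampling_rate must be an integer")
    t_epoch = int(round(t_epoch))
    n_avail = rec.n_samples // t_epoch
    if n_avail == 0:
        raise ValueError("recording shorter than one epoch")
    n = min(n_avail, max_epochs)
    return [
        Epoch(
            data=rec.data[:, i * t_epoch:(i + 1) * t_epoch].copy(),
            sampling_rate=rec.sampling_rate,
            subject_id=rec.subject_id,
            label=rec.label,
            domain_id=rec.domain_id,
            epoch_index=i,
        )
        for i in range(n)
    ]


def artifact_flag(epoch: Epoch, amplitude_threshold: float) -> bool:
    """True iff any sample strictly exceeds the amplitude threshold."""
    if amplitude_threshold <= 0:
        raise ValueError("amplitude_threshold must be positive")
    return bool(np.any(np.abs(epoch.data) > amplitude_threshold))


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the canonical preprocessing chain."""

    notch: float | None = 50.0
    band: tuple[float, float] = (4.0, 80.0)
    target_rate: float | None = 250.0
    epoch_seconds: float = 2.0
    max_epochs: int = 150
    artifact_threshold: float | None = None
    apply_zscore: bool = True


def preprocess(rec: EEGRecording, params: PreprocessParams = PreprocessParams()) -> list[Epoch]:
    """Run the full chain on one recording and return its epochs.

    Artifact flags are computed on the filtered (pre-z-score) signal so the
    threshold retains its physical amplitude meaning; z-scoring is applied
    per recording before epoching.
    """
    if params.notch is not None:
        rec = notch_filter(rec, params.notch)
    rec = bandpass_filter(rec, *params.band)
    if params.target_rate is not None and params.target_rate != rec.sampling_rate:
        rec = downsample(rec, params.target_rate)

    flags = None
    if params.artifact_threshold is not None:
        raw_epochs = epoch_split(rec, params.epoch_seconds, params.max_epochs)
        flags = [artifact_flag(e, params.artifact_threshold) for e in raw_epochs]

    if params.apply_zscore:
        rec = zscore(rec)
    epochs = epoch_split(rec, params.epoch_seconds, params.max_epochs)
    if flags is not None:
        for e, f in zip(epochs, flags):
            e.artifact = f
    return epochs
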
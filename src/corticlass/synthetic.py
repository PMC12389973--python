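"""Synthetic lead fields, cortical dynamics, and labeled multi-subject EEG.

The generator produces everything the downstream stages need without any
external recordings: a full-row-rank gain matrix with a block source-to-ROI
assignment, band-limited cortical noise with a class-specific theta-band
oscillation injected into a designated set of "affected" ROIs, per-subject
multiplicative gain shift (one domain per subject), and additive sensor
noise.

Label convention: 0 = depressed (DP), 1 = healthy control (HC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

MAX_LEAD_FIELD_RESEEDS = 3
COND_LIMIT = 1e6

#: ROIs receiving the class-specific oscillation (0-based ROI row indices).
DEFAULT_AFFECTED_ROIS = (0, 1)

#: Frequency (Hz) of the injected class-specific oscillation (theta band).
CLASS_OSC_FREQ = 6.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic dataset generator."""

    n_subjects_dp: int = 4
    n_subjects_hc: int = 6
    n_channels: int = 16
    n_sources: int = 32
    n_rois: int = 8
    sampling_rate: float = 500.0
    duration: float = 20.0
    noise_sd: float = 0.1
    class_effect: float = 2.0
    domain_shift_sd: float = 0.05
    seed: int = 0
    affected_rois: tuple[int, ...] = DEFAULT_AFFECTED_ROIS

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not (self.n_sources >= self.n_rois >= 2):
            raise ValueError("require n_sources >= n_rois >= 2")
        n_samp = self.duration * self.sampling_rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration * sampling_rate must be an integer")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_subjects_dp < 0 or self.n_subjects_hc < 0:
            raise ValueError("subject counts must be non-negative")
        if any(r < 0 or r >= self.n_rois for r in self.affected_rois):
            raise ValueError("affected_rois out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def n_subjects(self) -> int:
        return self.n_subjects_dp + self.n_subjects_hc


@dataclass
class LeadField:
    """Gain matrix K [L x S] plus the source-to-ROI assignment.

    ``roi_of_source`` uses 1-based ROI indices (1..N), one per source,
    assigned in contiguous blocks of floor(S/N) with the remainder going to
    the last ROI.
    """

    gain: np.ndarray
    roi_of_source: np.ndarray
    source_orientation: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    @property
    def n_rois(self) -> int:
        return int(self.roi_of_source.max())

    def sources_in_roi(self, roi: int) -> np.ndarray:
        """Indices of sources belonging to 1-based ROI ``roi``."""
        return np.flatnonzero(self.roi_of_source == roi)


@dataclass
class EEGRecording:
    """One subject's multi-channel recording with labels and provenance."""

    data: np.ndarray  # [L x T], microvolt scale (nominal)
    sampling_rate: float
    channel_names: list[str]
    subject_id: str
    label: int  # 0 = depressed, 1 = healthy
    domain_id: str
    sources: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def block_roi_assignment(n_sources: int, n_rois: int) -> np.ndarray:
    """Contiguous block assignment of sources to 1-based ROI indices."""
    block = n_sources // n_rois
    roi = np.empty(n_sources, dtype=np.int64)
    for r in range(n_rois):
        start = r * block
        stop = (r + 1) * block if r < n_rois - 1 else n_sources
        roi[start:stop] = r + 1
    return roi


def make_lead_field(config: SyntheticConfig) -> LeadField:
    """Generate a deterministic full-row-rank gain matrix.

    Rows are orthonormalized from a Gaussian draw and then perturbed, which
    keeps K K^T well conditioned (condition number <= 1e6 enforced). L > S is
    rejected outright: the synthetic regime requires at least as many sources
    as electrodes.
    """
    L, S = config.n_channels, config.n_sources
    if L > S:
        raise ValueError("underdetermined-forward-impossible: need n_channels <= n_sources")
    rng = np.random.default_rng(config.seed)
    for _ in range(MAX_LEAD_FIELD_RESEEDS):
        raw = rng.standard_normal((L, S))
        # Orthonormal rows via the SVD basis, then a small perturbation so the
        # gain is not exactly orthogonal (more realistic mixing).
        u, _, vt = np.linalg.svd(raw, full_matrices=False)
        gain = u @ vt + 0.05 * rng.standard_normal((L, S))
        gram = gain @ gain.T
        if np.linalg.matrix_rank(gain) == L and np.linalg.cond(gram) <= COND_LIMIT:
            return LeadField(
                gain=gain,
                roi_of_source=block_roi_assignment(S, config.n_rois),
                source_orientation=np.tile(np.array([0.0, 0.0, 1.0]), (S, 1)),
            )
    raise ValueError("underdetermined-forward-impossible: rank check failed after reseeds")


def _bandlimited_noise(rng: np.random.Generator, shape: tuple[int, int],
                       fs: float, low: float = 4.0, high: float = 80.0) -> np.ndarray:
    """Gaussian noise band-limited to [low, high] Hz, unit variance per row."""
    high = min(high, 0.45 * fs)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_recording(config: SyntheticConfig, lead_field: LeadField,
                       subject_index: int, seed_override: int | None = None) -> EEGRecording:
    """Simulate one subject (index into the DP-then-HC ordering).

    Source dynamics are band-limited (4-80 Hz) Gaussian noise; DP subjects
    additionally receive a ``class_effect``-scaled 6 Hz oscillation in every
    source of the affected ROIs. A per-subject scalar gain offset drawn from
    Normal(0, domain_shift_sd) multiplies the sources (domain shift), and
    sensor noise of sd ``noise_sd`` is added on the scalp. With
    ``noise_sd=0`` the scalp data is exactly ``gain @ rec.sources``.
    """
    if subject_index < 0 or subject_index >= config.n_subjects:
        raise ValueError("subject_index out of range")
    label = 0 if subject_index < config.n_subjects_dp else 1
    seed = (config.seed, subject_index) if seed_override is None else seed_override
    rng = np.random.default_rng(seed)
    T = config.n_samples
    fs = config.sampling_rate
    t = np.arange(T) / fs

    J = _bandlimited_noise(rng, (lead_field.n_sources, T), fs)
    if label == 0 and config.class_effect != 0:
        phase = rng.uniform(0, 2 * np.pi)
        burst = np.sin(2 * np.pi * CLASS_OSC_FREQ * t + phase)
        for roi in config.affected_rois:
            J[lead_field.sources_in_roi(roi + 1)] += config.class_effect * burst

    gain_offset = rng.normal(0.0, config.domain_shift_sd) if config.domain_shift_sd > 0 else 0.0
    J *= 1.0 + gain_offset

    scalp = lead_field.gain @ J
    if config.noise_sd > 0:
        scalp = scalp + rng.normal(0.0, config.noise_sd, scalp.shape)

    sid = f"sub-{subject_index:03d}"
    return EEGRecording(
        data=scalp,
        sampling_rate=fs,
        channel_names=[f"CH{i:02d}" for i in range(config.n_channels)],
        subject_id=sid,
        label=label,
        domain_id=sid,
        sources=J,
    )


def simulate_dataset(config: SyntheticConfig, lead_field: LeadField) -> list[EEGRecording]:
    """Simulate all subjects: DP subjects first (labels 0), then HC (labels 1)."""
    if lead_field.n_channels != config.n_channels or lead_field.n_sources != config.n_sources:
        raise ValueError("lead field inconsistent with config")
    return [simulate_recording(config, lead_field, i) for i in range(config.n_subjects)]
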
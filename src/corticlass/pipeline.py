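"""Glue from recordings to model-ready samples.

One sample = one epoch: its [N x D] feature matrix, the normalized
per-epoch adjacency built from the broadband node series, and the epoch's
label / subject / domain. With ``use_cfe=True`` the node series are
sLORETA ROI currents; with ``use_cfe=False`` (scalp ablation) the scalp
channels themselves act as nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import DEFAULT_BANDS, FeatureParams, assemble_features
from .inverse import DEFAULT_ALPHA, build_inverse_operator, solve_epoch
from .model import DEFAULT_PHI, build_adjacency
from .preprocessing import PreprocessParams, preprocess
from .synthetic import EEGRecording, LeadField


@dataclass
class Sample:
    x: np.ndarray  # [N x D] feature matrix
    a_hat: np.ndarray  # [N x N] normalized adjacency
    label: int
    subject_id: str
    domain_id: str
    epoch_index: int


def build_samples(recordings: list[EEGRecording],
                  lead_field: LeadField | None = None,
                  alpha: float = DEFAULT_ALPHA,
                  preprocess_params: PreprocessParams = PreprocessParams(),
                  feature_params: FeatureParams = FeatureParams(),
                  bands=DEFAULT_BANDS,
                  phi: float = DEFAULT_PHI,
                  use_cfe: bool = True,
                  drop_artifacts: bool = True) -> list[Sample]:
    """Preprocess, (optionally) invert, and featurize every epoch."""
    if use_cfe and lead_field is None:
        raise ValueError("cortical feature extraction requires a lead field")
    op = build_inverse_operator(lead_field, alpha) if use_cfe else None
    samples: list[Sample] = []
    for rec in recordings:
        for epoch in preprocess(rec, preprocess_params):
            if drop_artifacts and epoch.artifact:
                continue
            if use_cfe:
                node_series = solve_epoch(op, lead_field, epoch.data).roi_series
            else:
                node_series = epoch.data
            fm = assemble_features(node_series, epoch.sampling_rate, bands,
                                   feature_params)
            graph = build_adjacency(node_series, phi)
            samples.append(Sample(
                x=fm.x, a_hat=graph.a_hat, label=epoch.label,
                subject_id=epoch.subject_id, domain_id=epoch.domain_id,
                epoch_index=epoch.epoch_index,
            ))
    return samples
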
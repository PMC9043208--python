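"""End-to-end glue: recording -> preprocessing -> segmentation -> per-lead
features -> per-lead fQRS scores."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fqrs import features as ft
from fqrs.classifier import FQRSModel, LabeledLeadSet
from fqrs.errors import DegenerateSignalError, FQRSError, SegmentationFailure
from fqrs.io_preprocess import MultiLeadECG, bandpass, normalize, select_analysis_leads
from fqrs.segmentation import DEFAULT_QUALITY_LIMIT, BeatSegmentation, segment_recording
from fqrs.synthetic import CohortRecording


@dataclass
class PipelineConfig:
    """All tunables of the scoring pipeline with their standard defaults."""

    low_hz: float = 0.5
    high_hz: float = 70.0
    quality_limit: float = DEFAULT_QUALITY_LIMIT  # q = 0.85
    vmd_k: int = 5
    vmd_alpha: float = ft.DEFAULT_VMD_ALPHA
    prsa_window_ms: float = 40.0
    peak_prominence: float = ft.DEFAULT_PEAK_PROMINENCE
    kernel: str = "linear"
    threshold: float = 0.5
    aggregate: str = "mean"
    seed: int = 0

    def prsa_half_window(self, fs: float) -> int:
        return max(1, int(round(self.prsa_window_ms / 2000.0 * fs)))


def extract_recording_features(
    ecg: MultiLeadECG, config: PipelineConfig | None = None
) -> tuple[dict[str, ft.FeatureVector | None], BeatSegmentation]:
    """Per-lead feature vectors for one raw recording.

    Leads that cannot be analyzed (flat, no valid beats) map to None.
    """
    config = config or PipelineConfig()
    if "aVR" in ecg.lead_names:
        ecg = select_analysis_leads(ecg)
    ecg = bandpass(ecg, config.low_hz, config.high_hz)
    # normalize leads individually so one flat lead does not kill the recording
    samples = ecg.samples.copy()
    flat = []
    for j in range(ecg.n_leads):
        sd = samples[:, j].std()
        if sd <= 1e-12 * max(1.0, abs(samples[:, j].mean())):
            flat.append(j)
        else:
            samples[:, j] = (samples[:, j] - samples[:, j].mean()) / sd
    ecg = MultiLeadECG(samples, ecg.fs, list(ecg.lead_names), dict(ecg.meta))
    seg = segment_recording(ecg, q=config.quality_limit)
    out: dict[str, ft.FeatureVector | None] = {}
    half_window = config.prsa_half_window(ecg.fs)
    for j, name in enumerate(ecg.lead_names):
        if j in flat:
            out[name] = None
            continue
        beats = seg.lead_beats(ecg, j, valid_only=True)
        try:
            out[name] = ft.extract_lead_features(
                beats,
                vmd_alpha=config.vmd_alpha,
                prsa_half_window=half_window,
                peak_prominence=config.peak_prominence,
                aggregate=config.aggregate,
            )
        except (SegmentationFailure, DegenerateSignalError):
            out[name] = None
    return out, seg


def score_recording(
    ecg: MultiLeadECG, model: FQRSModel, config: PipelineConfig | None = None
) -> dict[str, tuple[float | None, int | None]]:
    """Per-lead (score, binary) map; unanalyzable leads map to (None, None)."""
    config = config or PipelineConfig()
    feats, _ = extract_recording_features(ecg, config)
    out: dict[str, tuple[float | None, int | None]] = {}
    for name, fv in feats.items():
        if fv is None:
            out[name] = (None, None)
        else:
            s = float(model.score(fv.as_array())[0])
            out[name] = (s, int(s >= config.threshold))
    return out


def cohort_feature_table(
    recordings: list[CohortRecording], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Feature matrix over a synthetic cohort, one row per analyzable lead,
    with ground-truth binary and ordinal labels attached."""
    config = config or PipelineConfig()
    rows = []
    for rec in recordings:
        try:
            feats, _ = extract_recording_features(rec.ecg, config)
        except FQRSError:
            continue
        for name, fv in feats.items():
            if fv is None:
                continue
            row = {"recording_id": rec.recording_id, "lead": name}
            row.update(dict(zip(ft.FEATURE_NAMES, fv.as_array())))
            row["fqrs_label"] = rec.truth.fqrs_label[name]
            row["ordinal_label"] = rec.truth.ordinal_label[name]
            row["rhythm"] = rec.truth.rhythm
            rows.append(row)
    return pd.DataFrame(rows)


def labeled_set_from_table(
    table: pd.DataFrame, agreement_only: bool = False
) -> LabeledLeadSet:
    """LabeledLeadSet from a cohort feature table.

    ``agreement_only`` keeps only leads with full observer agreement
    (ordinal label 0 or 5), mirroring how the ground-truth training set is
    formed from ordinal annotations.
    """
    if agreement_only:
        table = table[table["ordinal_label"].isin([0, 5])]
    return LabeledLeadSet(
        features=table[ft.FEATURE_NAMES].to_numpy(dtype=float),
        labels=table["fqrs_label"].to_numpy(dtype=int),
        group_id=table["recording_id"].to_numpy(),
    )
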
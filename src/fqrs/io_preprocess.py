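"""ECG recording I/O, preprocessing and lead selection.

Preprocessing is two-step: a band-pass (zero-phase order-4 Butterworth
high-pass at 0.5 Hz cascaded with a zero-phase order-6 Butterworth low-pass
at 70 Hz) followed by per-lead z-normalization. All sample indices in the
package are 0-based and windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from fqrs import wfdb_io
from fqrs.errors import DegenerateSignalError, FormatError, SamplingRateError, SchemaError

STANDARD_12_LEADS = ["I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6"]
#: the 11 leads actually analyzed (aVR is excluded from fQRS analysis)
ANALYSIS_LEADS = [name for name in STANDARD_12_LEADS if name != "aVR"]


@dataclass
class MultiLeadECG:
    """A multi-lead ECG strip: voltage matrix + sampling rate + lead names."""

    samples: np.ndarray  # n_samples x n_leads
    fs: float
    lead_names: list[str]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise SchemaError("samples must be a 2-D matrix (n_samples x n_leads)")
        if self.samples.shape[1] < 2:
            raise SchemaError("a recording needs at least 2 leads")
        if self.fs <= 0:
            raise SchemaError("sampling rate must be positive")
        if len(self.lead_names) != self.samples.shape[1]:
            raise SchemaError("lead_names length must match sample columns")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise SchemaError("duplicate lead names")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_leads(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.samples[:, self.lead_names.index(name)]


def read_recording(path: str | Path, format: str | None = None, fs: float | None = None) -> MultiLeadECG:
    """Read a recording from a WFDB record or a delimited text file.

    ``format`` is ``"wfdb"`` or ``"csv"``; when omitted it is inferred from
    the file extension. CSV files carry lead names in the first row, one
    column per lead (an optional ``time`` column is ignored) and require
    ``fs`` to be supplied.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() in {".csv", ".txt", ".tsv"} else "wfdb"
    if format == "wfdb":
        target = path if path.suffix else path
        if not (Path(str(target).removesuffix(".hea").removesuffix(".dat") + ".hea")).exists():
            raise FormatError(f"no WFDB header found for {path}")
        samples, rec_fs, names = wfdb_io.read_record(str(path))
        ecg = MultiLeadECG(samples, rec_fs, names, meta={"source": str(path), "format": "wfdb"})
    elif format == "csv":
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        if fs is None:
            raise SchemaError("csv input requires an explicit sampling rate (fs)")
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        with open(path) as fh:
            header = [c.strip() for c in fh.readline().rstrip("\n").split(sep)]
        if len(set(header)) != len(header):
            raise SchemaError(f"{path}: duplicate lead name in header")
        try:
            frame = pd.read_csv(path, sep=sep)
        except Exception as exc:  # noqa: BLE001 - normalize parser errors
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        cols = [str(c) for c in frame.columns]
        if any(c.startswith("Unnamed") for c in cols):
            raise SchemaError(f"{path}: first row must be a lead-name header")
        drop = [c for c in cols if c.lower() in {"time", "t", "index"}]
        frame = frame.drop(columns=drop)
        names = [str(c).strip() for c in frame.columns]
        if len(set(names)) != len(names):
            raise SchemaError(f"{path}: duplicate lead name in header")
        samples = frame.to_numpy(dtype=float)
        ecg = MultiLeadECG(samples, fs, names, meta={"source": str(path), "format": "csv"})
    else:
        raise SchemaError(f"unknown format {format!r} (expected 'wfdb' or 'csv')")
    if ecg.duration_s < 5.0:
        raise SchemaError(f"recording too short ({ecg.duration_s:.2f} s < 5 s)")
    return ecg


def write_recording_csv(ecg: MultiLeadECG, path: str | Path) -> None:
    pd.DataFrame(ecg.samples, columns=ecg.lead_names).to_csv(path, index=False)


def select_analysis_leads(ecg: MultiLeadECG) -> MultiLeadECG:
    """Drop the aVR lead; the remaining leads keep their order.

    If aVR is absent the recording is passed through with a warning.
    """
    if "aVR" not in ecg.lead_names:
        warnings.warn("aVR not present; recording passed through unchanged", stacklevel=2)
        return ecg
    keep = [i for i, name in enumerate(ecg.lead_names) if name != "aVR"]
    return replace(
        ecg,
        samples=ecg.samples[:, keep],
        lead_names=[ecg.lead_names[i] for i in keep],
        meta=dict(ecg.meta),
    )


def bandpass(
    ecg: MultiLeadECG,
    low_hz: float = 0.5,
    high_hz: float = 70.0,
    hp_order: int = 4,
    lp_order: int = 6,
) -> MultiLeadECG:
    """Zero-phase Butterworth band-pass: order-4 high-pass at ``low_hz``
    cascaded with an order-6 low-pass at ``high_hz``."""
    if ecg.fs <= 2 * high_hz:
        raise SamplingRateError(f"fs={ecg.fs} Hz too low for a {high_hz} Hz low-pass")
    sos_hp = sps.butter(hp_order, low_hz, btype="highpass", fs=ecg.fs, output="sos")
    sos_lp = sps.butter(lp_order, high_hz, btype="lowpass", fs=ecg.fs, output="sos")
    # the sub-Hz high-pass has a seconds-long impulse response: pad accordingly
    padlen = min(ecg.n_samples - 1, int(6 * ecg.fs / low_hz))
    out = sps.sosfiltfilt(sos_hp, ecg.samples, axis=0, padlen=padlen)
    out = sps.sosfiltfilt(sos_lp, out, axis=0)
    return replace(ecg, samples=out, meta=dict(ecg.meta))


def normalize(ecg: MultiLeadECG) -> MultiLeadECG:
    """Per-lead z-normalization (zero mean, unit standard deviation)."""
    mean = ecg.samples.mean(axis=0)
    sd = ecg.samples.std(axis=0)
    # relative tolerance: a constant lead's sd is pure rounding noise
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(degenerate):
        flat = [ecg.lead_names[i] for i in np.flatnonzero(degenerate)]
        raise DegenerateSignalError(f"constant lead(s): {', '.join(flat)}")
    return replace(ecg, samples=(ecg.samples - mean) / sd, meta=dict(ecg.meta))


def preprocess(ecg: MultiLeadECG, low_hz: float = 0.5, high_hz: float = 70.0) -> MultiLeadECG:
    """Band-pass then z-normalize; drops constant leads are not handled here."""
    return normalize(bandpass(ecg, low_hz=low_hz, high_hz=high_hz))


def write_score_table(
    scores: Mapping[str, Mapping[str, tuple[float | None, int | None]]],
    path: str | Path,
) -> None:
    """Write per-recording, per-lead scores as CSV
    (columns: recording_id, lead, score, binary)."""
    rows = []
    for rec_id, leads in scores.items():
        for lead, (score, binary) in leads.items():
            rows.append({"recording_id": rec_id, "lead": lead, "score": score, "binary": binary})
    pd.DataFrame(rows, columns=["recording_id", "lead", "score", "binary"]).to_csv(path, index=False)


def write_score_table_json(
    scores: Mapping[str, Mapping[str, tuple[float | None, int | None]]],
    path: str | Path,
) -> None:
    """JSON flavor of the score table: {recording: {lead: {score, binary}}}."""
    import json

    blob = {
        rec_id: {lead: {"score": s, "binary": b} for lead, (s, b) in leads.items()}
        for rec_id, leads in scores.items()
    }
    Path(path).write_text(json.dumps(blob, indent=2))
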
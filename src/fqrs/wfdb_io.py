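"""Minimal WFDB record reader/writer (format 16, single .dat file).

Supports exactly the subset of the WFDB signal format the pipeline needs:
a ``<record>.hea`` header plus one interleaved 16-bit little-endian
``<record>.dat``. Physical units are reconstructed as
``(raw - baseline) / gain``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from fqrs.errors import FormatError

_FMT = 16  # 16-bit two's complement, little-endian, interleaved


@dataclass
class _SignalSpec:
    file_name: str
    gain: float
    baseline: int
    units: str
    name: str


def write_record(
    path_prefix: str,
    samples: np.ndarray,
    fs: float,
    lead_names: list[str],
    gain: float = 2000.0,
    units: str = "mV",
) -> None:
    """Write ``samples`` (n_samples x n_leads, physical units) as a WFDB record.

    ``path_prefix`` is the record path without extension; ``.hea`` and
    ``.dat`` files are created next to it.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be 2-D (n_samples x n_leads)")
    n_samples, n_sig = samples.shape
    if n_sig != len(lead_names):
        raise ValueError("lead_names length must match sample columns")
    record = os.path.basename(path_prefix)
    digital = np.round(samples * gain)
    if np.any(np.abs(digital) > 32767):
        raise ValueError("signal exceeds 16-bit range at this gain; lower gain")
    digital = digital.astype("<i2")
    with open(path_prefix + ".dat", "wb") as fh:
        fh.write(digital.reshape(-1).tobytes())
    lines = [f"{record} {n_sig} {fs:g} {n_samples}"]
    for name in lead_names:
        lines.append(f"{record}.dat {_FMT} {gain:g}(0)/{units} 16 0 0 0 0 {name}")
    with open(path_prefix + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_record(path_prefix: str) -> tuple[np.ndarray, float, list[str]]:
    """Read a format-16 WFDB record; returns (samples, fs, lead_names)."""
    if path_prefix.endswith(".hea") or path_prefix.endswith(".dat"):
        path_prefix = path_prefix[:-4]
    hea_path = path_prefix + ".hea"
    if not os.path.exists(hea_path):
        raise FormatError(f"missing WFDB header: {hea_path}")
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty WFDB header: {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}")
    try:
        n_sig = int(head[1])
        fs = float(head[2])
        n_samples = int(head[3])
    except ValueError as exc:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}") from exc
    specs: list[_SignalSpec] = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        if len(parts) < 3:
            raise FormatError(f"malformed WFDB signal line: {ln!r}")
        fmt = parts[1].split("x")[0]
        if int(fmt) != _FMT:
            raise FormatError(f"unsupported WFDB format {fmt} (only 16)")
        gain_field = parts[2]
        units = "mV"
        baseline = 0
        if "/" in gain_field:
            gain_field, units = gain_field.split("/", 1)
        if "(" in gain_field:
            gain_field, base = gain_field.split("(", 1)
            baseline = int(base.rstrip(")"))
        gain = float(gain_field) if float(gain_field) != 0 else 200.0
        specs.append(_SignalSpec(parts[0], gain, baseline, units, parts[-1]))
    if len(specs) != n_sig:
        raise FormatError(f"header declares {n_sig} signals, found {len(specs)}")
    if len({s.file_name for s in specs}) != 1:
        raise FormatError("multi-file WFDB records are not supported")
    dat_path = os.path.join(os.path.dirname(path_prefix), specs[0].file_name)
    if not os.path.exists(dat_path):
        raise FormatError(f"missing WFDB data file: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size < n_samples * n_sig:
        raise FormatError("WFDB data file shorter than header declares")
    raw = raw[: n_samples * n_sig].reshape(n_samples, n_sig).astype(float)
    gains = np.array([s.gain for s in specs])
    baselines = np.array([s.baseline for s in specs])
    samples = (raw - baselines) / gains
    return samples, fs, [s.name for s in specs]
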
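"""Synthetic multi-lead ECG generation with full ground truth.

Beats are sums of Gaussian components (P, Q, R, S, T), which makes QRS
support, R locations and injected notch positions analytically known. A
recording mixes per-lead polarity/scale, optional fQRS notches in chosen
leads, ectopic beats (widened, inverted morphology), and additive noise
(white, baseline wander, powerline). Ordinal 0-5 labels emulate a
5-observer threshold model driven by the notch amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from fqrs import wfdb_io
from fqrs.errors import ConfigError
from fqrs.io_preprocess import ANALYSIS_LEADS, MultiLeadECG

#: default Gaussian component amplitudes (relative to R = 1)
DEFAULT_AMPLITUDES = {"p": 0.10, "q": -0.12, "r": 1.0, "s": -0.25, "t": 0.30}

#: leads rendered with inverted dominant polarity
_NEGATIVE_LEADS = {"V1", "III"}

#: notch-amplitude band inside which observers disagree (fraction of R)
AMBIGUITY_BAND = (0.08, 0.18)


@dataclass
class SyntheticConfig:
    fs: float = 500.0
    duration_s: float = 10.0
    heart_rate_bpm: float = 60.0
    rr_cv: float = 0.03
    rhythm: str = "sinus"  # "sinus" | "af"
    lead_names: Sequence[str] = field(default_factory=lambda: list(ANALYSIS_LEADS))
    qrs_duration_ms: float = 90.0
    fqrs_leads: Sequence[str] = field(default_factory=list)
    n_notches: int = 2
    notch_amp: float = 0.25
    notch_width_ms: float = 8.0
    ectopic_prob: float = 0.0
    ectopic_scale: float = 1.8
    noise_sd: float = 0.02
    baseline_amp: float = 0.10
    baseline_freq: float = 0.30
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 250:
            raise ConfigError("fs: must be >= 250 Hz")
        if self.duration_s <= 0:
            raise ConfigError("duration_s: must be positive")
        if self.rr_cv < 0:
            raise ConfigError("rr_cv: must be >= 0")
        if self.rhythm not in {"sinus", "af"}:
            raise ConfigError("rhythm: must be 'sinus' or 'af'")
        if not 60 <= self.qrs_duration_ms <= 200:
            raise ConfigError("qrs_duration_ms: must be in [60, 200]")
        for amp_name in ("notch_amp", "noise_sd", "baseline_amp", "powerline_amp"):
            if getattr(self, amp_name) < 0:
                raise ConfigError(f"{amp_name}: must be >= 0")
        unknown = set(self.fqrs_leads) - set(self.lead_names)
        if unknown:
            raise ConfigError(f"fqrs_leads: not in lead_names: {sorted(unknown)}")


@dataclass
class GroundTruth:
    r_locations: np.ndarray  # sample index per beat
    qrs_onset: np.ndarray  # sample index per beat
    qrs_offset: np.ndarray  # sample index per beat
    fqrs_label: dict[str, int]  # lead -> {0, 1}
    ordinal_label: dict[str, int]  # lead -> 0..5
    notch_amp: dict[str, float]  # lead -> injected amplitude (0 if clean)
    ectopic: np.ndarray  # bool per beat
    rhythm: str
    rr_s: np.ndarray  # RR intervals in seconds

    @property
    def n_beats(self) -> int:
        return len(self.r_locations)


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def beat_components(qrs_ms: float, amplitudes: dict[str, float] | None = None) -> list[tuple[float, float, float]]:
    """(amplitude, center_s, sigma_s) triples for the P-QRS-T Gaussian sum.

    The QRS trio (Q, R, S) is laid out so that the total QRS support
    (3-sigma extent of the outermost components) is ~``qrs_ms``.
    """
    amp = dict(DEFAULT_AMPLITUDES)
    if amplitudes:
        amp.update(amplitudes)
    q = qrs_ms / 1000.0
    return [
        (amp["p"], -0.22 - q / 4, 0.022),
        (amp["q"], -0.30 * q, q / 14),
        (amp["r"], 0.0, q / 9),
        (amp["s"], +0.30 * q, q / 14),
        (amp["t"], 0.32 + q / 2, 0.055),
    ]


def gen_beat(
    qrs_ms: float,
    amplitudes: dict[str, float] | None = None,
    fs: float = 500.0,
    window_s: tuple[float, float] = (-0.4, 0.6),
) -> tuple[np.ndarray, int, int, int]:
    """Render one beat; returns (wave, r_idx, qrs_onset_idx, qrs_offset_idx).

    Indices are 0-based into ``wave``; onset/offset bracket the true QRS
    support ``[r - qrs/2, r + qrs/2)``.
    """
    if not 60 <= qrs_ms <= 200:
        raise ConfigError("qrs_ms must be in [60, 200]")
    t = np.arange(round(window_s[0] * fs), round(window_s[1] * fs)) / fs
    wave = np.zeros_like(t)
    for a, c, s in beat_components(qrs_ms, amplitudes):
        wave += a * _gauss(t, c, s)
    r_idx = int(np.argmin(np.abs(t)))
    half = qrs_ms / 2000.0
    onset_idx = r_idx - int(round(half * fs))
    offset_idx = r_idx + int(round(half * fs))
    return wave, r_idx, onset_idx, offset_idx


def notch_components(
    qrs_ms: float,
    n_notches: int,
    amp: float,
    width_ms: float,
    rng: np.random.Generator,
) -> list[tuple[float, float, float]]:
    """Draw notch Gaussians (amplitude, center_s, sigma_s) inside the QRS.

    Signs alternate; centers live in the central part of the QRS support,
    excluding a small guard zone right at the R apex (so the ground-truth
    R location is not shifted) and the steepest flank segments, where a
    deflection of this amplitude would not be visible as a notch. Centers
    are kept at least 1.5 notch widths apart.
    """
    half = qrs_ms / 2000.0
    width_s = width_ms / 1000.0
    if width_s >= qrs_ms / 1000.0 * 0.5:
        raise ConfigError("notch width too large for the QRS support")
    sigma = width_s / 5
    # canonical fQRS morphology zones (center as fraction of the QRS
    # half-width, with the deflection sign that renders each one as a
    # visible notch): a deflection elsewhere merges with the R flanks
    plus_zones = [(0.60, 0.68), (-0.89, -0.85)]  # notched S / notched Q
    minus_zones = [(-0.04, 0.04)]  # notched R (apex dip)
    comps: list[tuple[float, float, float]] = []
    used: list[tuple[float, float]] = []
    for i in range(n_notches):
        sign = 1 if i % 2 == 0 else -1  # alternating deflection signs
        pool = [z for z in (plus_zones if sign > 0 else minus_zones) if z not in used]
        if not pool:
            pool = plus_zones if sign > 0 else minus_zones
        zone = pool[0]
        used.append(zone)
        c = float(rng.uniform(*zone)) * half  # zone coords are in half-width units
        comps.append((sign * amp, c, sigma))
    return sorted(comps, key=lambda t: t[1])


def inject_fqrs(
    beat: np.ndarray,
    n_notches: int,
    amp: float,
    width_ms: float,
    fs: float,
    rng: np.random.Generator,
    r_idx: int,
    qrs_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Add notches to a rendered beat; returns (notched beat, notch indices)."""
    if amp == 0:
        return beat.copy(), np.array([], dtype=int)
    t = (np.arange(len(beat)) - r_idx) / fs
    comps = notch_components(qrs_ms, n_notches, amp, width_ms, rng)
    out = beat.copy()
    centers = []
    for a, c, s in comps:
        out += a * _gauss(t, c, s)
        centers.append(r_idx + int(round(c * fs)))
    return out, np.array(centers, dtype=int)


def _draw_rr(rng: np.random.Generator, n: int, mean_s: float, cv: float, rhythm: str) -> np.ndarray:
    if rhythm == "sinus":
        rr = rng.normal(mean_s, cv * mean_s, size=n)
        return np.clip(rr, 0.40, None)
    # AF: heavy-tailed, no periodicity; lognormal with matched cv
    sigma = np.sqrt(np.log(1 + cv**2))
    rr = rng.lognormal(np.log(mean_s) - sigma**2 / 2, sigma, size=n)
    return np.clip(rr, 0.30, None)


def gen_recording(config: SyntheticConfig) -> tuple[MultiLeadECG, GroundTruth]:
    """Render one recording with its ground truth; reproducible from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_samples = int(round(config.duration_s * fs))
    t_grid = np.arange(n_samples) / fs

    rr_mean = 60.0 / config.heart_rate_bpm
    cv = config.rr_cv if config.rr_cv > 0 else (0.20 if config.rhythm == "af" else 0.03)
    max_beats = int(config.duration_s / 0.3) + 2
    rr = _draw_rr(rng, max_beats, rr_mean, cv, config.rhythm)
    beat_times = 0.5 + np.concatenate([[0.0], np.cumsum(rr)])
    beat_times = beat_times[beat_times < config.duration_s - 0.45]
    n_beats = len(beat_times)
    rr_used = np.diff(beat_times)

    ectopic = rng.random(n_beats) < config.ectopic_prob

    # per-lead rendering parameters
    lead_names = list(config.lead_names)
    scales = {name: float(rng.uniform(0.6, 1.4)) for name in lead_names}
    polarity = {name: (-1.0 if name in _NEGATIVE_LEADS else 1.0) for name in lead_names}
    notch_amp = {
        name: (config.notch_amp if name in set(config.fqrs_leads) else 0.0) for name in lead_names
    }
    # fixed notch layout per fragmented lead: same morphology on every beat
    lead_notches = {
        name: notch_components(config.qrs_duration_ms, config.n_notches, amp, config.notch_width_ms, rng)
        for name, amp in notch_amp.items()
        if amp > 0
    }

    half_s = config.qrs_duration_ms / 2000.0
    normal_comps = beat_components(config.qrs_duration_ms)
    ect_qrs = min(config.qrs_duration_ms * config.ectopic_scale, 200.0)
    ectopic_comps = beat_components(ect_qrs, {"r": -1.0, "p": 0.0, "t": 0.35, "q": 0.10, "s": 0.10})

    samples = np.zeros((n_samples, len(lead_names)))
    for j, name in enumerate(lead_names):
        lead = np.zeros(n_samples)
        for k, bt in enumerate(beat_times):
            comps = list(ectopic_comps) if ectopic[k] else list(normal_comps)
            if not ectopic[k] and name in lead_notches:
                comps += lead_notches[name]
            for a, c, s in comps:
                lead += a * _gauss(t_grid, bt + c, s)
        lead *= polarity[name] * scales[name]
        lead += config.noise_sd * rng.standard_normal(n_samples)
        lead += config.baseline_amp * np.sin(
            2 * np.pi * config.baseline_freq * t_grid + rng.uniform(0, 2 * np.pi)
        )
        if config.powerline_amp > 0:
            lead += config.powerline_amp * np.sin(
                2 * np.pi * config.powerline_freq * t_grid + rng.uniform(0, 2 * np.pi)
            )
        samples[:, j] = lead

    r_loc = np.round(beat_times * fs).astype(int)
    onset = r_loc - int(round(half_s * fs))
    offset = r_loc + int(round(half_s * fs))

    ordinal = {name: _ordinal_label(notch_amp[name], rng) for name in lead_names}
    truth = GroundTruth(
        r_locations=r_loc,
        qrs_onset=onset,
        qrs_offset=offset,
        fqrs_label={name: int(notch_amp[name] > 0) for name in lead_names},
        ordinal_label=ordinal,
        notch_amp=dict(notch_amp),
        ectopic=ectopic,
        rhythm=config.rhythm,
        rr_s=rr_used,
    )
    ecg = MultiLeadECG(
        samples,
        fs,
        lead_names,
        meta={"synthetic": True, "seed": config.seed, "rhythm": config.rhythm},
    )
    return ecg, truth


def _ordinal_label(amp: float, rng: np.random.Generator) -> int:
    """5-observer threshold emulator: 0/5 outside the ambiguity band."""
    lo, hi = AMBIGUITY_BAND
    if amp <= 0:
        return 0
    if amp >= hi:
        return 5
    if amp <= lo:
        return 0
    thresholds = rng.uniform(lo, hi, size=5)
    return int(np.clip(np.sum(amp > thresholds), 1, 4))


@dataclass
class CohortRecording:
    recording_id: str
    config: SyntheticConfig
    ecg: MultiLeadECG
    truth: GroundTruth


def gen_cohort(
    n_recordings: int,
    fqrs_prevalence: float = 0.3,
    broad_frac: float = 0.4,
    af_frac: float = 0.1,
    ambiguity_frac: float = 0.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    fs: float = 500.0,
    duration_s: float = 10.0,
) -> tuple[list[CohortRecording], pd.DataFrame]:
    """Generate a labeled cohort; returns (recordings, per-lead manifest).

    Each lead is fragmented independently with probability
    ``fqrs_prevalence``; ``ambiguity_frac`` of the fragmented leads receive
    sub-threshold notch amplitudes (ordinal labels 1-4). When ``out_dir``
    is given, WFDB records plus ground-truth and manifest CSVs are written.
    """
    for frac_name, frac in [
        ("fqrs_prevalence", fqrs_prevalence),
        ("broad_frac", broad_frac),
        ("af_frac", af_frac),
        ("ambiguity_frac", ambiguity_frac),
    ]:
        if not 0 <= frac <= 1:
            raise ConfigError(f"{frac_name}: must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = AMBIGUITY_BAND
    recordings: list[CohortRecording] = []
    rows = []
    for i in range(n_recordings):
        rec_id = f"syn{i:04d}"
        rhythm = "af" if rng.random() < af_frac else "sinus"
        broad = rng.random() < broad_frac
        qrs_ms = float(rng.uniform(130, 160)) if broad else float(rng.uniform(75, 110))
        frag = rng.random(len(ANALYSIS_LEADS)) < fqrs_prevalence
        fqrs_leads = [name for name, f in zip(ANALYSIS_LEADS, frag) if f]
        ambiguous = rng.random() < ambiguity_frac if fqrs_leads else False
        amp = float(rng.uniform(lo + 0.01, hi - 0.01)) if ambiguous else float(rng.uniform(hi + 0.02, 0.35))
        cfg = SyntheticConfig(
            fs=fs,
            duration_s=duration_s,
            heart_rate_bpm=float(rng.uniform(55, 90)),
            rr_cv=0.20 if rhythm == "af" else 0.03,
            rhythm=rhythm,
            qrs_duration_ms=qrs_ms,
            fqrs_leads=fqrs_leads,
            n_notches=int(rng.integers(1, 4)),
            notch_amp=amp,
            ectopic_prob=0.05,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ecg, truth = gen_recording(cfg)
        recordings.append(CohortRecording(rec_id, cfg, ecg, truth))
        for name in ecg.lead_names:
            rows.append(
                {
                    "recording_id": rec_id,
                    "lead": name,
                    "fqrs_label": truth.fqrs_label[name],
                    "ordinal_label": truth.ordinal_label[name],
                    "notch_amp": truth.notch_amp[name],
                    "rhythm": rhythm,
                    "qrs_ms": qrs_ms,
                    "broad": int(broad),
                }
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            wfdb_io.write_record(
                str(out_dir / rec.recording_id), rec.ecg.samples, rec.ecg.fs, rec.ecg.lead_names
            )
            truth_rows = pd.DataFrame(
                {
                    "beat": np.arange(rec.truth.n_beats),
                    "r_location": rec.truth.r_locations,
                    "qrs_onset": rec.truth.qrs_onset,
                    "qrs_offset": rec.truth.qrs_offset,
                    "ectopic": rec.truth.ectopic.astype(int),
                }
            )
            truth_rows.to_csv(out_dir / f"{rec.recording_id}_truth.csv", index=False)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return recordings, manifest
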
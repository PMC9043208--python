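"""Multi-lead QRS segmentation.

Pipeline: per-lead R-peak detection (envelope/Pan-Tompkins family), cross-
lead consolidation so every lead carries the consensus beat count n_R,
per-lead QRS onset/offset delineation on a quadratic-spline dyadic wavelet
transform, cross-lead median reallocation of the boundaries, template
selection, beat alignment, and a correlation-based quality filter that
removes irregular heartbeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from fqrs.errors import SegmentationFailure
from fqrs.io_preprocess import MultiLeadECG

REFRACTORY_S = 0.200
RECOVERY_WINDOW_S = 0.040  # refined |signal| maximum search for missed beats
CLUSTER_TOL_S = 0.100  # greedy consensus clustering tolerance
ALIGN_MAX_LAG_S = 0.025
QRS_MIN_S, QRS_MAX_S = 0.040, 0.250
DEFAULT_QUALITY_LIMIT = 0.85


@dataclass
class RPeakMatrix:
    """Consolidated R-peak indices: one row per beat, one column per lead."""

    idx: np.ndarray  # n_R x n_leads, int

    @property
    def n_r(self) -> int:
        return self.idx.shape[0]

    @property
    def n_leads(self) -> int:
        return self.idx.shape[1]

    def validate(self, n_samples: int | None = None) -> None:
        if self.idx.ndim != 2:
            raise SegmentationFailure("R-peak matrix must be 2-D")
        if np.any(np.diff(self.idx, axis=0) <= 0):
            raise SegmentationFailure("R-peak columns must be strictly increasing")
        if n_samples is not None and (self.idx.min() < 0 or self.idx.max() >= n_samples):
            raise SegmentationFailure("R-peak index out of recording bounds")


@dataclass
class QRSComplex:
    """One segmented beat, amplitude-normalized to max |wave| = 1."""

    wave: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.wave = np.asarray(self.wave, dtype=float)
        if len(self.wave) < 5:
            raise SegmentationFailure("QRS segment shorter than 5 samples")
        peak = np.max(np.abs(self.wave))
        if peak > 0:
            self.wave = self.wave / peak


@dataclass
class BeatSegmentation:
    """Per-(beat, lead) QRS boundaries and validity after quality filtering."""

    onset: np.ndarray  # n_R x n_leads, int
    offset: np.ndarray  # n_R x n_leads, int
    rpeak: RPeakMatrix
    valid: np.ndarray  # n_R x n_leads, bool
    template_idx: np.ndarray  # beat index per lead (-1 when unanalyzable)
    lead_names: list[str]
    fs: float

    @property
    def n_r(self) -> int:
        return self.rpeak.n_r

    def lead_beats(self, ecg: MultiLeadECG, lead: int, valid_only: bool = True) -> list[QRSComplex]:
        """Extract (optionally only valid) QRS complexes of one lead."""
        out = []
        sig = ecg.samples[:, lead]
        for b in range(self.n_r):
            if valid_only and not self.valid[b, lead]:
                continue
            seg = sig[self.onset[b, lead] : self.offset[b, lead]]
            if len(seg) >= 5 and np.max(np.abs(seg)) > 0:
                out.append(QRSComplex(seg, self.fs))
        return out

    def to_frame(self, recording_id: str = "") -> pd.DataFrame:
        rows = []
        for lead_i, name in enumerate(self.lead_names):
            for b in range(self.n_r):
                rows.append(
                    {
                        "recording": recording_id,
                        "lead": name,
                        "beat": b,
                        "onset": int(self.onset[b, lead_i]),
                        "rpeak": int(self.rpeak.idx[b, lead_i]),
                        "offset": int(self.offset[b, lead_i]),
                        "valid": bool(self.valid[b, lead_i]),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# R-peak detection (envelope detector, Pan-Tompkins family)
# ---------------------------------------------------------------------------


def detect_rpeaks_single(signal: np.ndarray, fs: float) -> np.ndarray:
    """Detect candidate R-peaks in one preprocessed lead.

    Band-pass 8-30 Hz, derivative, squaring, 120 ms moving-window
    integration, adaptive threshold with a 200 ms refractory period; the
    returned indices are refined to the extremum of |signal| near each
    envelope peak. Returns a strictly increasing index vector (possibly
    empty).
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < fs or np.ptp(signal) == 0:
        return np.array([], dtype=int)
    sos = sps.butter(2, [8.0, 30.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, signal)
    energy = np.gradient(filt) ** 2
    win = max(1, int(round(0.120 * fs)))
    env = np.convolve(energy, np.ones(win) / win, mode="same")
    thr = 0.20 * np.quantile(env, 0.99)
    if thr <= 0:
        return np.array([], dtype=int)
    locs, _ = sps.find_peaks(env, height=thr, distance=int(round(REFRACTORY_S * fs)))
    if len(locs) == 0:
        return np.array([], dtype=int)
    # refine to the |signal| extremum (handles inverted-QRS leads)
    half = int(round(0.050 * fs))
    refined = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(len(signal), loc + half + 1)
        refined.append(lo + int(np.argmax(np.abs(signal[lo:hi]))))
    refined = np.array(sorted(set(refined)), dtype=int)
    # enforce refractory after refinement
    keep = [0]
    for i in range(1, len(refined)):
        if refined[i] - refined[keep[-1]] >= REFRACTORY_S * fs:
            keep.append(i)
        elif np.abs(signal[refined[i]]) > np.abs(signal[refined[keep[-1]]]):
            keep[-1] = i
    return refined[keep]


# ---------------------------------------------------------------------------
# Algorithm 1: cross-lead R-peak consolidation
# ---------------------------------------------------------------------------


def _cluster_detections(per_lead_peaks: list[np.ndarray], fs: float) -> list[dict[int, int]]:
    """Greedy clustering of all detections within CLUSTER_TOL_S.

    Returns one dict per consensus beat mapping lead -> detected index
    (closest detection of that lead).
    """
    events = []
    for lead, peaks in enumerate(per_lead_peaks):
        events.extend((int(p), lead) for p in peaks)
    events.sort()
    tol = CLUSTER_TOL_S * fs
    clusters: list[list[tuple[int, int]]] = []
    for pos, lead in events:
        if clusters and pos - np.mean([p for p, _ in clusters[-1]]) <= tol:
            clusters[-1].append((pos, lead))
        else:
            clusters.append([(pos, lead)])
    out = []
    for members in clusters:
        center = np.mean([p for p, _ in members])
        best: dict[int, int] = {}
        for pos, lead in members:
            if lead not in best or abs(pos - center) < abs(best[lead] - center):
                best[lead] = pos
        out.append(best)
    return out


def consolidate_rpeaks(per_lead_peaks: list[np.ndarray], ecg: MultiLeadECG) -> RPeakMatrix:
    """Algorithm 1: give every lead exactly n_R consolidated R-peaks.

    n_R is the mode of the per-lead detection counts (ties resolved toward
    the larger count). Leads with surplus detections keep the n_R closest
    to the consensus positions; leads with missing beats recover them by a
    refined maximum search of |signal| in a 40 ms window around the cross-
    lead average position.
    """
    counts = [len(p) for p in per_lead_peaks]
    if all(c == 0 for c in counts):
        raise SegmentationFailure("no R-peaks detected in any lead")
    nonzero = [c for c in counts if c > 0]
    values, freqs = np.unique(nonzero, return_counts=True)
    n_r = int(values[freqs == freqs.max()].max())  # tie -> larger count

    clusters = _cluster_detections(per_lead_peaks, ecg.fs)
    # rank consensus beats by lead support, keep the n_R best, restore time order
    order = sorted(range(len(clusters)), key=lambda i: (-len(clusters[i]), i))[:n_r]
    clusters = [clusters[i] for i in sorted(order)]
    if len(clusters) < n_r:
        raise SegmentationFailure("consensus clustering yielded fewer beats than n_R")

    half = int(round(RECOVERY_WINDOW_S * ecg.fs / 2))
    n_leads = ecg.n_leads
    idx = np.zeros((n_r, n_leads), dtype=int)
    for b, members in enumerate(clusters):
        center = int(round(np.mean(list(members.values()))))
        for lead in range(n_leads):
            if lead in members:
                idx[b, lead] = members[lead]
            else:
                lo = max(0, center - half)
                hi = min(ecg.n_samples, center + half + 1)
                seg = np.abs(ecg.samples[lo:hi, lead])
                idx[b, lead] = lo + int(np.argmax(seg)) if len(seg) else center
    # strict monotonicity can be broken by recovery at the edges; repair
    for lead in range(n_leads):
        col = idx[:, lead]
        for b in range(1, n_r):
            if col[b] <= col[b - 1]:
                col[b] = col[b - 1] + 1
    matrix = RPeakMatrix(idx)
    matrix.validate(ecg.n_samples)
    return matrix


# ---------------------------------------------------------------------------
# Wavelet delineation (quadratic-spline dyadic wavelet transform)
# ---------------------------------------------------------------------------

_LP = np.array([1, 3, 3, 1]) / 8.0  # quadratic-spline smoothing filter
_HP = np.array([2, -2])  # derivative (wavelet) filter


def _dyadic_wt(signal: np.ndarray, n_scales: int = 4) -> list[np.ndarray]:
    """A-trous dyadic wavelet transform; scale 2^k output approximates a
    smoothed derivative with support growing with the scale."""
    out = []
    approx = np.asarray(signal, dtype=float)
    for level in range(n_scales):
        hp = _upsample(_HP, level)
        lp = _upsample(_LP, level)
        out.append(np.convolve(approx, hp, mode="same"))
        approx = np.convolve(approx, lp, mode="same")
    return out


def _upsample(filt: np.ndarray, level: int) -> np.ndarray:
    """Insert 2^level - 1 zeros between filter taps."""
    step = 2**level
    out = np.zeros((len(filt) - 1) * step + 1)
    out[::step] = filt
    return out


def delineate_single(
    signal: np.ndarray, fs: float, rpeaks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate QRS onset/offset per R-peak on one lead.

    Works on the modulus of the scale-2^2 dyadic wavelet detail (selected
    at ~250 Hz-equivalent resolution): the QRS appears as a cluster of
    modulus maxima around R; the boundaries are where the modulus decays
    below a fraction of the flanking maxima. Failures fall back to a fixed
    +/-60 ms window and are reported as-is (the median reallocation step
    repairs outliers). Durations are clamped to [40, 250] ms.
    """
    signal = np.asarray(signal, dtype=float)
    # pick the dyadic scale closest to ~1/8 of fs bandwidth (scale 2^2 at 250 Hz)
    scale = int(np.clip(round(np.log2(fs / 62.5)), 1, 4))
    details = _dyadic_wt(signal, n_scales=scale)
    w = details[-1]
    mod = np.abs(w)
    search_s = 0.120
    decay = 0.05
    onsets = np.zeros(len(rpeaks), dtype=int)
    offsets = np.zeros(len(rpeaks), dtype=int)
    for k, r in enumerate(rpeaks):
        lo = max(0, int(r - search_s * fs))
        hi = min(len(signal), int(r + search_s * fs) + 1)
        local = mod[lo:hi]
        if len(local) < 5 or local.max() == 0:
            onsets[k] = max(0, int(r - 0.060 * fs))
            offsets[k] = min(len(signal) - 1, int(r + 0.060 * fs))
            continue
        thr_peak = 0.10 * local.max()
        maxima, _ = sps.find_peaks(local, height=thr_peak)
        if len(maxima) == 0:
            maxima = np.array([int(np.argmax(local))])
        first, last = lo + maxima[0], lo + maxima[-1]
        onset = first
        floor_on = decay * mod[first]
        while onset > lo and mod[onset] > floor_on:
            onset -= 1
        offset = last
        stop = hi - 1
        floor_off = decay * mod[last]
        while offset < stop and mod[offset] > floor_off:
            offset += 1
        onsets[k] = onset
        offsets[k] = offset
    # clamp durations
    min_w, max_w = int(QRS_MIN_S * fs), int(QRS_MAX_S * fs)
    for k, r in enumerate(rpeaks):
        if offsets[k] - onsets[k] < min_w:
            onsets[k] = int(r - max(min_w // 2, r - onsets[k]))
            offsets[k] = int(r + max(min_w // 2, offsets[k] - r))
        if offsets[k] - onsets[k] > max_w:
            onsets[k] = max(onsets[k], int(r - max_w // 2))
            offsets[k] = min(offsets[k], int(r + max_w // 2))
        onsets[k] = max(0, min(onsets[k], r - 1))
        offsets[k] = min(len(signal) - 1, max(offsets[k], r + 1))
    return onsets, offsets


# ---------------------------------------------------------------------------
# Algorithm 2: cross-lead boundary consolidation, alignment, quality filter
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def quality_filter(beats: list[QRSComplex], q: float = DEFAULT_QUALITY_LIMIT) -> np.ndarray:
    """Boolean keep-mask over beats.

    For each beat, rho = vector of normalized correlations against all n_R
    beats of the lead (self included, contributing one entry of 1.0); the
    beat is removed iff strictly more than half of rho's entries fall
    below the quality limit q. Negative correlations are floored at 0, so
    q = 0 keeps every beat regardless of morphology.
    """
    n = len(beats)
    if n < 2:
        raise SegmentationFailure("quality filter needs at least 2 beats")
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            corr[i, j] = corr[j, i] = max(0.0, _pearson(beats[i].wave, beats[j].wave))
    mask = np.array([np.sum(corr[i] < q) <= n / 2 for i in range(n)])
    return mask


def _align_lag(wave: np.ndarray, template: np.ndarray, max_lag: int) -> int:
    """Lag (samples) maximizing normalized cross-correlation of wave against
    the template; ties break toward zero lag."""
    best_lag, best_val = 0, -np.inf
    n = len(template)
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        if lag >= 0:
            a, b = template[: n - lag], wave[lag:]
        else:
            a, b = template[-lag:], wave[: len(wave) + lag]
        m = min(len(a), len(b))
        if m < 5:
            continue
        val = _pearson(a[:m], b[:m])
        if val > best_val + 1e-12:
            best_val, best_lag = val, lag
    return best_lag


def consolidate_delineation(
    ecg: MultiLeadECG,
    rpeaks: RPeakMatrix,
    per_lead_onsets_offsets: list[tuple[np.ndarray, np.ndarray]],
    q: float = DEFAULT_QUALITY_LIMIT,
) -> BeatSegmentation:
    """Algorithm 2: median boundary reallocation + alignment + quality filter.

    Step 1: per beat, onset/offset (relative to that beat's R) are replaced
    by the across-lead median. Step 2: beats are segmented and amplitude-
    normalized. Step 3: per lead, the template is the beat with the highest
    cumulative correlation to the others. Step 4: the remaining beats are
    aligned to the template within a bounded lag and their boundaries
    shifted by the found lag. Step 5: the correlation quality filter flags
    invalid beats.
    """
    n_r, n_leads = rpeaks.n_r, rpeaks.n_leads
    fs = ecg.fs
    rel_on = np.zeros((n_r, n_leads))
    rel_off = np.zeros((n_r, n_leads))
    for lead, (ons, offs) in enumerate(per_lead_onsets_offsets):
        rel_on[:, lead] = ons - rpeaks.idx[:, lead]
        rel_off[:, lead] = offs - rpeaks.idx[:, lead]
    med_on = np.median(rel_on, axis=1)
    med_off = np.median(rel_off, axis=1)
    onset = (rpeaks.idx + med_on[:, None]).round().astype(int)
    offset = (rpeaks.idx + med_off[:, None]).round().astype(int)
    onset = np.clip(onset, 0, ecg.n_samples - 2)
    offset = np.clip(offset, 1, ecg.n_samples - 1)

    valid = np.zeros((n_r, n_leads), dtype=bool)
    template_idx = np.full(n_leads, -1, dtype=int)
    max_lag = int(round(ALIGN_MAX_LAG_S * fs))
    for lead in range(n_leads):
        sig = ecg.samples[:, lead]
        waves = []
        usable = []
        for b in range(n_r):
            seg = sig[onset[b, lead] : offset[b, lead]]
            if len(seg) >= 5 and np.max(np.abs(seg)) > 0:
                waves.append(seg / np.max(np.abs(seg)))
                usable.append(b)
        if len(waves) < 2:
            continue
        # template: highest cumulative correlation to the other beats
        m = len(waves)
        corr = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                corr[i, j] = corr[j, i] = _pearson(waves[i], waves[j])
        t_local = int(np.argmax(corr.sum(axis=1)))
        template_idx[lead] = usable[t_local]
        template = waves[t_local]
        aligned = []
        for i, b in enumerate(usable):
            if i == t_local:
                aligned.append(waves[i])
                continue
            lo = max(0, onset[b, lead] - max_lag)
            hi = min(ecg.n_samples, offset[b, lead] + max_lag)
            wide = sig[lo:hi]
            if np.max(np.abs(wide)) > 0:
                wide = wide / np.max(np.abs(wide))
            start = onset[b, lead] - lo
            lag = _align_lag(wide[start : start + len(template) + max_lag], template, max_lag)
            onset[b, lead] = np.clip(onset[b, lead] + lag, 0, ecg.n_samples - 2)
            offset[b, lead] = np.clip(offset[b, lead] + lag, 1, ecg.n_samples - 1)
            seg = sig[onset[b, lead] : offset[b, lead]]
            if len(seg) >= 5 and np.max(np.abs(seg)) > 0:
                aligned.append(seg / np.max(np.abs(seg)))
            else:
                aligned.append(waves[i])
        beats = [QRSComplex(wv, fs) for wv in aligned]
        mask = quality_filter(beats, q=q)
        for i, b in enumerate(usable):
            valid[b, lead] = mask[i]
        if not valid[template_idx[lead], lead]:
            # template must be valid; if filtered out, lead is unanalyzable
            valid[:, lead] = False
            template_idx[lead] = -1
    return BeatSegmentation(
        onset=onset,
        offset=offset,
        rpeak=rpeaks,
        valid=valid,
        template_idx=template_idx,
        lead_names=list(ecg.lead_names),
        fs=fs,
    )


def segment_recording(ecg: MultiLeadECG, q: float = DEFAULT_QUALITY_LIMIT) -> BeatSegmentation:
    """Full multi-lead segmentation of a preprocessed recording."""
    per_lead = [detect_rpeaks_single(ecg.samples[:, j], ecg.fs) for j in range(ecg.n_leads)]
    rpeaks = consolidate_rpeaks(per_lead, ecg)
    delineated = [
        delineate_single(ecg.samples[:, j], ecg.fs, rpeaks.idx[:, j]) for j in range(ecg.n_leads)
    ]
    return consolidate_delineation(ecg, rpeaks, delineated, q=q)


def export_segmentation_plot(
    ecg: MultiLeadECG, seg: BeatSegmentation, lead: int, path: str | Path
) -> None:
    """Diagnostic per-lead plot: raw signal, segmented beats, kept beats."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3))
    sig = ecg.samples[:, lead]
    t = np.arange(len(sig)) / ecg.fs
    axes[0].plot(t, sig, lw=0.6)
    axes[0].plot(seg.rpeak.idx[:, lead] / ecg.fs, sig[seg.rpeak.idx[:, lead]], "r.")
    axes[0].set_title(f"lead {seg.lead_names[lead]}")
    for b in range(seg.n_r):
        segm = sig[seg.onset[b, lead] : seg.offset[b, lead]]
        if len(segm) < 5:
            continue
        norm = segm / np.max(np.abs(segm))
        axes[1].plot(norm, lw=0.7, alpha=0.7)
        if seg.valid[b, lead]:
            axes[2].plot(norm, lw=0.7, alpha=0.7)
    axes[1].set_title("segmented beats")
    axes[2].set_title("kept beats")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
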
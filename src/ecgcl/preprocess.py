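"""Preprocessing pipeline for 30 s ECG segments.

Fixed stage order: resample to 128 Hz -> 0.5–40 Hz band-pass -> sliding-window
segmentation -> rhythm labelling -> z-score -> beat-signal-quality (bSQI)
filtering.  The QRS detector used for quality indexing (and for T-wave
masking on real data) is a Pan–Tompkins-style pipeline.

bSQI is the agreement index between two independent beat detectors on the
same segment, ``matched / (nA + nB - matched)`` with a 150 ms matching
window; segments with bSQI < 0.8 are discarded.  It is computed on the
band-passed, pre-normalisation signal — both detectors are amplitude-scale
invariant, so the placement relative to the z-score is immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .ecg_io import ECGRecord, RhythmInterval, SegmentStore, rhythm_to_binary

DEFAULT_FS = 128.0
WINDOW_S = 30.0
BSQI_THRESHOLD = 0.8
REFRACTORY_S = 0.25


@dataclass
class Segment:
    """One fixed-length single-lead window."""

    x: np.ndarray
    fs: float
    label: Optional[int] = None
    r_peaks: Optional[np.ndarray] = None
    record_id: str = ""
    start_sample: int = 0
    constant: bool = False  # raw window was constant; z-score returned zeros


@dataclass
class SegmentPair:
    primary: Segment
    secondary: Segment


@dataclass(frozen=True)
class QualityReport:
    bsqi: float
    n_beats_detector_a: int
    n_beats_detector_b: int
    n_matched: int
    degenerate: bool = False  # both detectors found nothing


# ---------------------------------------------------------------------------
# resampling and filtering
# ---------------------------------------------------------------------------

def resample_record(record: ECGRecord, target_fs: float = DEFAULT_FS) -> ECGRecord:
    """Polyphase anti-aliased resampling of every channel; identity if the
    rate already matches."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if record.fs == target_fs:
        return record
    frac = Fraction(target_fs / record.fs).limit_denominator(10_000)
    out = sps.resample_poly(record.signals, frac.numerator, frac.denominator, axis=1)
    return ECGRecord(signals=out, fs=target_fs,
                     lead_names=record.lead_names, record_id=record.record_id)


def bandpass(x: np.ndarray, fs: float, low: float = 0.5, high: float = 40.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    if not 0 < low < high:
        raise ValueError("require 0 < low < high")
    if high >= fs / 2:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {fs / 2} Hz")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# segmentation and labelling
# ---------------------------------------------------------------------------

def segment_starts(n_samples: int, fs: float, window_s: float = WINDOW_S,
                   overlap_s: float = 0.0) -> np.ndarray:
    """Window start samples: starts at 0, step = window - overlap; parts
    shorter than one window are discarded."""
    if overlap_s >= window_s:
        raise ValueError("overlap must be smaller than the window")
    win = int(round(window_s * fs))
    step = int(round((window_s - overlap_s) * fs))
    if n_samples < win:
        return np.empty(0, dtype=np.int64)
    n_windows = (n_samples - win) // step + 1
    return np.arange(n_windows, dtype=np.int64) * step


def window_label(intervals: Sequence[RhythmInterval], start: int, end: int) -> int:
    """AF (1) iff AF/AFL rhythm covers at least half of the window."""
    af_cover = 0
    for iv in intervals:
        if rhythm_to_binary(iv.rhythm_code):
            af_cover += max(0, min(end, iv.end_sample) - max(start, iv.start_sample))
    return int(af_cover >= 0.5 * (end - start))


def segment_record(record: ECGRecord, intervals: Sequence[RhythmInterval],
                   window_s: float = WINDOW_S, overlap_s: float = 0.0,
                   channel: int = 0) -> List[Segment]:
    """Cut one channel into labelled, not-yet-normalised windows."""
    starts = segment_starts(record.n_samples, record.fs, window_s, overlap_s)
    win = int(round(window_s * record.fs))
    x = record.signals[channel]
    return [
        Segment(x=x[s : s + win].copy(), fs=record.fs,
                label=window_label(intervals, s, s + win),
                record_id=record.record_id, start_sample=int(s))
        for s in starts
    ]


def zscore(x: np.ndarray, with_flag: bool = False):
    """(x - mean) / sd with the population (1/N) standard deviation.

    A constant input maps to zeros (guarded) and raises the flag."""
    x = np.asarray(x, dtype=np.float64)
    sd = x.std()
    constant = sd == 0
    z = np.zeros_like(x) if constant else (x - x.mean()) / sd
    return (z, constant) if with_flag else z


# ---------------------------------------------------------------------------
# QRS detection
# ---------------------------------------------------------------------------

def detect_qrs(x: np.ndarray, fs: float) -> np.ndarray:
    """Pan–Tompkins-style R-peak detection.

    5–15 Hz band-pass -> differentiate -> square -> 150 ms moving-window
    integration -> adaptive signal/noise threshold with a 250 ms refractory.
    All thresholds are relative, so detections are invariant to amplitude
    scaling.  Returns strictly increasing sample indices; a flat signal
    yields an empty array.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2 * fs:
        raise ValueError("detect_qrs needs at least 2 s of signal")
    if np.ptp(x) == 0:
        return np.empty(0, dtype=np.int64)
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv * deriv
    w = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(w) / w, mode="same")
    if mwi.max() == 0:
        return np.empty(0, dtype=np.int64)

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        return np.empty(0, dtype=np.int64)

    # adaptive signal/noise levels (relative to the data; no absolute units)
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    kept = []
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] >= thr:
            kept.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
    if not kept:
        return np.empty(0, dtype=np.int64)

    # refine each detection to the band-passed-signal extremum nearby
    half = int(round(0.100 * fs))
    peaks = []
    for p in kept:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.unique(peaks)
    # enforce the refractory after refinement: keep the larger of close pairs
    out: List[int] = []
    for p in peaks:
        if out and p - out[-1] < refractory:
            if np.abs(bp[p]) > np.abs(bp[out[-1]]):
                out[-1] = int(p)
        else:
            out.append(int(p))
    return np.asarray(out, dtype=np.int64)


def detect_beats_envelope(x: np.ndarray, fs: float) -> np.ndarray:
    """Second, independent beat detector: local maxima of the 150 ms
    moving-average energy envelope of the (baseline-removed) signal, with a
    relative height floor and the same 250 ms refractory.

    Squaring before averaging makes the QRS complex dominate smaller waves
    (P, T, fibrillatory oscillations) by the square of their amplitude
    ratio, which keeps this detector independent of the Pan–Tompkins
    derivative pipeline while remaining amplitude-scale invariant.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.ptp(x) == 0:
        return np.empty(0, dtype=np.int64)
    d = x - np.median(x)
    env = np.convolve(d * d, np.ones(max(1, int(round(0.150 * fs)))), mode="same")
    if env.max() == 0:
        return np.empty(0, dtype=np.int64)
    refractory = int(round(REFRACTORY_S * fs))
    cand, props = sps.find_peaks(env, distance=refractory)
    if len(cand) == 0:
        return np.empty(0, dtype=np.int64)
    # relative floor: a beat should carry a sizeable fraction of the typical
    # detected beat energy (median is robust to one huge artefact)
    floor = 0.5 * np.median(env[cand][env[cand] >= 0.25 * env[cand].max()])
    return cand[env[cand] >= floor].astype(np.int64)


# ---------------------------------------------------------------------------
# bSQI
# ---------------------------------------------------------------------------

def match_pairs(a: Sequence[int], b: Sequence[int], tol_samples: float,
                ) -> List[Tuple[int, int]]:
    """Greedy one-to-one matching of two ordered beat lists within a
    tolerance (in samples); returns the matched index pairs (i_a, i_b)."""
    b_free = list(range(len(b)))
    pairs: List[Tuple[int, int]] = []
    for i, p in enumerate(a):
        if not b_free:
            break
        dists = [abs(p - b[j]) for j in b_free]
        k = int(np.argmin(dists))
        if dists[k] <= tol_samples:
            pairs.append((i, b_free[k]))
            b_free.pop(k)
    return pairs


def match_beats(a: Sequence[int], b: Sequence[int], tol_samples: float) -> int:
    """Number of greedily matched beats between two ordered lists."""
    return len(match_pairs(a, b, tol_samples))


def compute_bsqi(x: np.ndarray, fs: float, tolerance_ms: float = 150.0) -> QualityReport:
    """Two-detector beat agreement: ``matched / (nA + nB - matched)``.

    When both detectors return nothing the index is 0 with the degenerate
    flag raised (an empty segment is not evidence of quality).
    """
    a = detect_qrs(x, fs)
    b = detect_beats_envelope(x, fs)
    tol = tolerance_ms / 1000.0 * fs
    pairs = match_pairs(a, b, tol)
    matched = len(pairs)
    # an unmatched beat truncated by the window edge is not evidence of poor
    # quality; matched edge beats still count as agreement
    n = len(np.asarray(x))
    in_a = {i for i, _ in pairs}
    in_b = {j for _, j in pairs}
    n_a = matched + sum(1 for i, p in enumerate(a)
                        if i not in in_a and tol <= p < n - tol)
    n_b = matched + sum(1 for j, p in enumerate(b)
                        if j not in in_b and tol <= p < n - tol)
    denom = n_a + n_b - matched
    if denom == 0:
        return QualityReport(0.0, 0, 0, 0, degenerate=True)
    return QualityReport(matched / denom, n_a, n_b, matched)


def quality_filter(store: SegmentStore, threshold: float = BSQI_THRESHOLD,
                   ) -> Tuple[SegmentStore, np.ndarray]:
    """Keep segment pairs whose primary-lead bSQI is at least the threshold.

    Returns the surviving store and the per-segment bSQI values.  Both leads
    of a pair are dropped together when the primary fails.
    """
    bsqi = np.array([compute_bsqi(seg, store.fs).bsqi for seg in store.segments])
    keep = np.flatnonzero(bsqi >= threshold)
    return store.subset(keep), bsqi


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def preprocess_record(record: ECGRecord, intervals: Sequence[RhythmInterval],
                      analysis_channel: int, paired_channel: int,
                      window_s: float = WINDOW_S, overlap_s: float = 0.0,
                      bsqi_threshold: float = BSQI_THRESHOLD,
                      target_fs: float = DEFAULT_FS) -> SegmentStore:
    """resample -> band-pass -> segment -> label -> z-score -> bSQI filter.

    Rhythm intervals are given at the record's original rate and are rescaled
    along with the signal.
    """
    if record.fs != target_fs:
        scale = target_fs / record.fs
        intervals = [RhythmInterval(int(round(iv.start_sample * scale)),
                                    max(int(round(iv.end_sample * scale)),
                                        int(round(iv.start_sample * scale)) + 1),
                                    iv.rhythm_code)
                     for iv in intervals]
        record = resample_record(record, target_fs)
    filtered = bandpass(record.signals, record.fs)
    record = ECGRecord(signals=filtered, fs=record.fs,
                       lead_names=record.lead_names, record_id=record.record_id)

    primary = segment_record(record, intervals, window_s, overlap_s, analysis_channel)
    secondary = segment_record(record, intervals, window_s, overlap_s, paired_channel)

    win = int(round(window_s * target_fs))
    n = len(primary)
    seg_arr = np.empty((n, win), dtype=np.float32)
    pair_arr = np.empty((n, win), dtype=np.float32)
    bsqi = np.empty(n)
    for i, (sp, ss) in enumerate(zip(primary, secondary)):
        bsqi[i] = compute_bsqi(sp.x, target_fs).bsqi  # pre-normalisation
        seg_arr[i] = zscore(sp.x)
        pair_arr[i] = zscore(ss.x)
    store = SegmentStore(
        segments=seg_arr, paired_segments=pair_arr,
        labels=np.array([s.label for s in primary], dtype=np.int8),
        fs=target_fs,
        record_ids=[s.record_id for s in primary],
        start_samples=np.array([s.start_sample for s in primary], dtype=np.int64),
    )
    keep = np.flatnonzero(bsqi >= bsqi_threshold)
    return store.subset(keep)
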
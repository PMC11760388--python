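"""Synthetic dual-lead ECG generator with exact R-peak ground truth.

The generator renders each heartbeat as a superposition of Gaussian bumps
(P, Q, R, S, T) placed relative to the R peak, on an RR-interval grid drawn
from a rhythm-class-specific law:

* ``non-AF`` — near-regular rhythm: truncated normal RR intervals with a
  small coefficient of variation, and a visible P wave 160 ms before each R.
* ``AF`` — the three hallmarks of atrial fibrillation: irregular RR intervals
  (truncated uniform over ±40 % of the mean), absent P waves, and a
  superimposed fibrillatory (f-wave) oscillation in the physiological
  4–9 Hz band with per-beat phase jitter.

Lead 2 shares the R-peak timing of lead 1 but differs in morphology (global
gain and a halved T-wave amplitude), emulating two simultaneously recorded
leads of the same cardiac activity.  This is a phenomenological template
model, not a biophysical one: it provides controllable morphology and exact
ground truth, which is what the downstream pipeline tests need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .ecg_io import SegmentStore
from .preprocess import zscore

AF = "AF"
NON_AF = "non-AF"

#: Fixed wave template: (offset from R in s, Gaussian width in s, amplitude).
R_AMPLITUDE = 1.0
WAVE_TEMPLATE = {
    "Q": (-0.04, 0.02, -0.15),
    "R": (0.0, 0.02, R_AMPLITUDE),
    "S": (0.04, 0.02, -0.25),
    "T": (0.20, 0.05, 0.35),
}
P_OFFSET_S = -0.16
P_WIDTH_S = 0.025
T_GAIN_LEAD2 = 0.5
MIN_RR_S = 0.25


@dataclass(frozen=True)
class SyntheticRecordSpec:
    """Parameters of one synthetic dual-lead record.

    Class-dependent invariants are enforced at construction: a non-AF record
    has no f wave, an AF record has no P wave.
    """

    rhythm_class: str = NON_AF
    duration_s: float = 30.0
    fs: float = 128.0
    mean_rr_s: float = 0.8
    rr_variability: float = 0.05
    p_wave_amplitude: float = 0.15
    f_wave_amplitude: float = 0.1
    f_wave_freq_hz: float = 6.0
    noise_sd: float = 0.05
    lead_gain_2: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rhythm_class not in (AF, NON_AF):
            raise ValueError(f"unknown rhythm_class {self.rhythm_class!r}")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if self.rr_variability < 0:
            raise ValueError("rr_variability must be non-negative")
        if self.mean_rr_s <= MIN_RR_S:
            raise ValueError(
                f"mean_rr_s must exceed the {MIN_RR_S} s refractory floor"
            )
        # class-based wave suppression
        if self.rhythm_class == NON_AF and self.f_wave_amplitude != 0.0:
            object.__setattr__(self, "f_wave_amplitude", 0.0)
        if self.rhythm_class == AF and self.p_wave_amplitude != 0.0:
            object.__setattr__(self, "p_wave_amplitude", 0.0)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class SyntheticRecord:
    """Two equal-length leads with shared, exact R-peak sample indices."""

    signals: np.ndarray  # (2, n_samples)
    fs: float
    r_peaks: np.ndarray  # 0-based sample indices, strictly increasing
    rhythm_class: str
    spec: SyntheticRecordSpec


def generate_rr_sequence(spec: SyntheticRecordSpec) -> np.ndarray:
    """RR intervals (seconds) covering at least ``spec.duration_s``.

    non-AF: truncated normal(mean_rr_s, rr_variability * mean_rr_s);
    AF: truncated uniform over mean_rr_s * [0.6, 1.4].  All intervals are
    >= 0.25 s.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    intervals = []
    total = 0.0
    while total < spec.duration_s:
        chunk = _draw_rr(spec, rng, 64)
        for rr in chunk:
            intervals.append(rr)
            total += rr
            if total >= spec.duration_s:
                break
    return np.asarray(intervals)


def _draw_rr(spec: SyntheticRecordSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if spec.rhythm_class == AF:
        lo = max(spec.mean_rr_s * 0.6, MIN_RR_S)
        hi = spec.mean_rr_s * 1.4
        return rng.uniform(lo, hi, size=n)
    sd = spec.rr_variability * spec.mean_rr_s
    rr = rng.normal(spec.mean_rr_s, sd, size=n)
    # truncate by resampling below the refractory floor
    for _ in range(100):
        bad = rr < MIN_RR_S
        if not bad.any():
            break
        rr[bad] = rng.normal(spec.mean_rr_s, sd, size=int(bad.sum()))
    return np.maximum(rr, MIN_RR_S)


def _gaussian(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def synthesize_record(spec: SyntheticRecordSpec) -> SyntheticRecord:
    """Render a dual-lead record from the spec's RR law and wave template."""
    rr = generate_rr_sequence(spec)
    r_times = np.cumsum(rr)
    r_times = r_times[r_times < spec.duration_s - 1.0 / spec.fs]
    n = spec.n_samples
    t = np.arange(n) / spec.fs

    lead1 = np.zeros(n)
    lead2 = np.zeros(n)
    for tr in r_times:
        for off, width, amp in WAVE_TEMPLATE.values():
            bump = _gaussian(t, tr + off, width, amp)
            lead1 += bump
            if abs(off - WAVE_TEMPLATE["T"][0]) < 1e-12 and width == WAVE_TEMPLATE["T"][1]:
                lead2 += T_GAIN_LEAD2 * bump
            else:
                lead2 += bump
        if spec.p_wave_amplitude:
            p = _gaussian(t, tr + P_OFFSET_S, P_WIDTH_S, spec.p_wave_amplitude)
            lead1 += p
            lead2 += p

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    if spec.f_wave_amplitude:
        # per-beat phase jitter: constant random phase within each RR cell
        bounds = np.concatenate([[0.0], r_times, [spec.duration_s]])
        phase = np.zeros(n)
        for a, b in zip(bounds[:-1], bounds[1:]):
            sel = (t >= a) & (t < b)
            phase[sel] = rng.uniform(0, 2 * np.pi)
        fwave = spec.f_wave_amplitude * np.sin(
            2 * np.pi * spec.f_wave_freq_hz * t + phase
        )
        lead1 += fwave
        lead2 += fwave

    lead2 *= spec.lead_gain_2
    if spec.noise_sd > 0:
        lead1 = lead1 + rng.normal(0, spec.noise_sd, size=n)
        lead2 = lead2 + rng.normal(0, spec.noise_sd, size=n)

    r_peaks = np.round(r_times * spec.fs).astype(np.int64)
    r_peaks = r_peaks[(r_peaks >= 0) & (r_peaks < n)]
    return SyntheticRecord(
        signals=np.stack([lead1, lead2]).astype(np.float32),
        fs=spec.fs,
        r_peaks=r_peaks,
        rhythm_class=spec.rhythm_class,
        spec=spec,
    )


def make_synthetic_dataset(
    n_labeled: int,
    n_unlabeled: int,
    af_fraction: float = 0.5,
    fs: float = 128.0,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> Tuple[SegmentStore, SegmentStore]:
    """Labeled and unlabeled sets of z-scored 30 s dual-lead segment pairs.

    The labeled store carries exactly ``round(n_labeled * af_fraction)`` AF
    segments (label 1); the unlabeled store has the same class mixture but no
    labels.  Per-segment R-peak ground truth is retained for augmentation.
    Record seeds are spawned from ``seed`` so the two stores never share a
    random stream.
    """
    if n_labeled < 0 or n_unlabeled < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= af_fraction <= 1.0:
        raise ValueError("af_fraction must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    ss_lab, ss_unlab = ss.spawn(2)
    labeled = _make_store(n_labeled, af_fraction, fs, ss_lab, noise_sd, labeled=True)
    unlabeled = _make_store(n_unlabeled, af_fraction, fs, ss_unlab, noise_sd, labeled=False)
    return labeled, unlabeled


def _make_store(
    n: int,
    af_fraction: float,
    fs: float,
    ss: np.random.SeedSequence,
    noise_sd: float,
    labeled: bool,
) -> SegmentStore:
    n_af = int(round(n * af_fraction))
    classes = np.array([1] * n_af + [0] * (n - n_af), dtype=np.int8)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rng.shuffle(classes)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    t0 = int(round(30.0 * fs))
    primary = np.empty((n, t0), dtype=np.float32)
    secondary = np.empty((n, t0), dtype=np.float32)
    r_peaks = []
    for i in range(n):
        spec = SyntheticRecordSpec(
            rhythm_class=AF if classes[i] == 1 else NON_AF,
            duration_s=30.0,
            fs=fs,
            mean_rr_s=float(rng.uniform(0.6, 1.0)),
            noise_sd=noise_sd,
            seed=int(seeds[i]),
        )
        rec = synthesize_record(spec)
        primary[i] = zscore(rec.signals[0])
        secondary[i] = zscore(rec.signals[1])
        r_peaks.append(rec.r_peaks)
    return SegmentStore(
        segments=primary,
        paired_segments=secondary,
        labels=classes.copy() if labeled else None,
        fs=fs,
        record_ids=[f"syn-{int(s)}" for s in seeds],
        start_samples=np.zeros(n, dtype=np.int64),
        r_peaks=r_peaks,
    )
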
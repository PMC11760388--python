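"""Domain-knowledge augmentation for AF contrastive pre-training.

The strong view of a segment is produced by *non-diagnostic-region*
augmentation (T-wave masking: the 50–300 ms window after each selected R
peak set to a fixed value) followed, with 50 % probability, by
*diagnostic-region* augmentation (vertical flipping, x -> -x).  The weak
view is the preprocessed segment itself.  Six generic time-series
augmentations are provided for ablation comparisons.

All sample-index windows use ``floor(offset * fs)`` and are half-open, so at
128 Hz a masked beat covers exactly ``[R+6, R+38)`` — 32 samples.  The mask
fill value defaults to 0, the baseline of a z-scored signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import numpy as np

MASK_START_S = 0.05
MASK_END_S = 0.30

ABLATION_KINDS = ("gaussian_noise", "baseline_wander", "channel_scaling",
                  "horizontal_flip", "time_warp", "random_mask")

#: Printed parameter ranges of the comparison augmentations.
ABLATION_DEFAULTS: Dict[str, dict] = {
    "gaussian_noise": {"sd_range": (0.01, 0.1)},
    "baseline_wander": {"freq_range": (1 / 30, 1 / 10), "amp_range": (0.5, 0.6),
                        "fs": 128.0},
    "channel_scaling": {"scale_range": (0.1, 5.0)},
    "horizontal_flip": {},
    "time_warp": {"choices": ((1, 5), (3, 5))},
    "random_mask": {"c": 20.0, "fill": 0.0},
}


@dataclass(frozen=True)
class AugmentationConfig:
    mask_fraction_c: float = 50.0
    mask_fill_value: float = 0.0
    flip_probability: float = 0.5
    seed: int = 0
    ablation_kind: Optional[str] = None
    ablation_params: Optional[dict] = None

    def __post_init__(self) -> None:
        if not 0 <= self.mask_fraction_c <= 100:
            raise ValueError("mask_fraction_c must lie in [0, 100]")
        if not 0 <= self.flip_probability <= 1:
            raise ValueError("flip_probability must lie in [0, 1]")
        if self.ablation_kind is not None and self.ablation_kind not in ABLATION_KINDS:
            raise ValueError(f"unknown ablation kind {self.ablation_kind!r}")


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def vertical_flip(x: np.ndarray) -> np.ndarray:
    """Diagnostic-region augmentation: elementwise negation."""
    return -np.asarray(x)


def t_wave_mask(x: np.ndarray, r_peaks: Sequence[int], fs: float,
                c: float = 50.0, fill: float = 0.0,
                seed: Union[int, np.random.Generator] = 0) -> np.ndarray:
    """Set the ``[R + 50 ms, R + 300 ms)`` window of ``round(c% * n_beats)``
    uniformly chosen beats to a fixed value.  Windows are clipped at the
    segment end; an empty beat list returns the input unchanged (warned)."""
    x = np.array(x, copy=True)
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    if len(r_peaks) == 0:
        warnings.warn("t_wave_mask called without R peaks; returning input unchanged")
        return x
    if np.any((r_peaks < 0) | (r_peaks >= len(x))):
        raise ValueError("r_peaks fall outside the segment")
    rng = _as_rng(seed)
    n_sel = int(round(c / 100.0 * len(r_peaks)))
    chosen = rng.choice(len(r_peaks), size=n_sel, replace=False)
    lo_off = int(np.floor(MASK_START_S * fs))
    hi_off = int(np.floor(MASK_END_S * fs))
    for r in r_peaks[chosen]:
        x[r + lo_off : min(r + hi_off, len(x))] = fill
    return x


def domain_knowledge_augment(x: np.ndarray, r_peaks: Sequence[int], fs: float,
                             config: AugmentationConfig = AugmentationConfig(),
                             rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """T-wave masking always; vertical flipping with ``flip_probability``."""
    rng = _as_rng(config.seed) if rng is None else rng
    out = t_wave_mask(x, r_peaks, fs, c=config.mask_fraction_c,
                      fill=config.mask_fill_value, seed=rng)
    if rng.random() < config.flip_probability:
        out = vertical_flip(out)
    return out


# ---------------------------------------------------------------------------
# comparison (ablation) augmentations
# ---------------------------------------------------------------------------

def ablation_augment(x: np.ndarray, kind: str, params: Optional[dict] = None,
                     seed: Union[int, np.random.Generator] = 0) -> np.ndarray:
    """One of the six generic time-series augmentations, with the printed
    parameter ranges as defaults.  Output length always equals the input
    length (time warping is resampled back)."""
    if kind not in ABLATION_KINDS:
        raise ValueError(f"unknown augmentation kind {kind!r}")
    x = np.asarray(x, dtype=np.float64)
    p = dict(ABLATION_DEFAULTS[kind])
    if params:
        p.update(params)
    rng = _as_rng(seed)

    if kind == "gaussian_noise":
        sd = rng.uniform(*p["sd_range"])
        return x + rng.normal(0.0, sd, size=len(x))
    if kind == "baseline_wander":
        fw = rng.uniform(*p["freq_range"])
        sw = rng.uniform(*p["amp_range"])
        t = np.arange(len(x)) / p["fs"]  # seconds; fw is in Hz
        return x + sw * np.sin(2 * np.pi * fw * t)
    if kind == "channel_scaling":
        return x * rng.uniform(*p["scale_range"])
    if kind == "horizontal_flip":
        return x[::-1].copy()
    if kind == "random_mask":
        n_mask = int(round(p["c"] / 100.0 * len(x)))
        out = x.copy()
        out[rng.choice(len(x), size=n_mask, replace=False)] = p["fill"]
        return out
    # time_warp
    w, r = p["choices"][rng.integers(len(p["choices"]))]
    return _time_warp(x, w, r / 100.0, rng)


def _resample_linear(x: np.ndarray, n_out: int) -> np.ndarray:
    if len(x) == n_out:
        return x.copy()
    return np.interp(np.linspace(0, len(x) - 1, n_out), np.arange(len(x)), x)


def _time_warp(x: np.ndarray, w: int, r: float, rng: np.random.Generator) -> np.ndarray:
    """Split into ``w`` chunks; within each, one randomly chosen half is
    stretched by ``r`` and the other squeezed by ``r``; the concatenation is
    resampled back to the original length."""
    n = len(x)
    bounds = np.linspace(0, n, w + 1).astype(int)
    pieces = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        chunk = x[a:b]
        mid = len(chunk) // 2
        first, second = chunk[:mid], chunk[mid:]
        stretch_first = rng.random() < 0.5
        f1 = 1 + r if stretch_first else 1 - r
        f2 = 1 - r if stretch_first else 1 + r
        pieces.append(_resample_linear(first, max(1, int(round(len(first) * f1)))))
        pieces.append(_resample_linear(second, max(1, int(round(len(second) * f2)))))
    return _resample_linear(np.concatenate(pieces), n)


def make_strong_views(batch: np.ndarray, r_peaks: Sequence[np.ndarray], fs: float,
                      config: AugmentationConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Strong views for a batch: per-sample domain-knowledge augmentation
    (independent Bernoulli flips and beat selections)."""
    out = np.empty_like(batch)
    for i in range(len(batch)):
        out[i] = domain_knowledge_augment(batch[i], r_peaks[i], fs, config, rng)
    return out
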
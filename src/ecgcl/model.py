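"""Two-stage multi-level encoder for 30 s single-lead ECG segments.

The encoder has two parts that are deliberately kept as separate parameter
subtrees:

* ``f`` — a 1-D convolutional feature extractor (one input convolution plus a
  stack of stride-2 residual blocks) mapping a segment ``x ∈ R^{T0}`` to a
  per-timestamp hidden representation ``h ∈ R^{T×Dh}``, with ``T = T0 / 2^n``
  for ``n`` residual blocks.  Temporal contrastive learning operates on ``h``.
* ``g`` — a bidirectional LSTM fusing the hidden sequence; the fused output at
  the final position is L2-normalised onto the unit hypersphere to give the
  encoder representation ``z ∈ R^{Dz}``.  Channel and label contrastive
  learning operate on ``z``.

A three-layer MLP classifier (batch-norm before each rectifier) consumes ``z``
for the downstream atrial-fibrillation detection task, and an optional
two-layer projector can be inserted between ``z`` and the contrastive losses
for ablation experiments (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import autograd.numpy as anp
import numpy as np

from . import nn


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture of the two-stage encoder.

    Defaults give ``T0=3840`` (30 s at 128 Hz), total downsampling 64 so
    ``T = 60`` hidden timesteps of width ``Dh = 128``, and ``Dz = 256``
    encoder dimensions (128 per LSTM direction).
    """

    input_length: int = 3840
    hidden_dim: int = 128
    encoder_dim: int = 256
    channel_plan: Tuple[int, ...] = (32, 64, 64, 128, 128, 128)
    input_kernel: int = 7
    block_kernel: int = 3
    use_projector: bool = False

    def __post_init__(self) -> None:
        if self.channel_plan[-1] != self.hidden_dim:
            raise ValueError("last channel_plan entry must equal hidden_dim")
        if self.encoder_dim % 2 != 0:
            raise ValueError("encoder_dim must be even (two LSTM directions)")
        if self.input_length % self.downsample_total != 0:
            raise ValueError(
                f"input_length {self.input_length} not divisible by total "
                f"downsampling {self.downsample_total}"
            )

    @property
    def n_residual_blocks(self) -> int:
        return len(self.channel_plan)

    @property
    def downsample_total(self) -> int:
        return 2 ** self.n_residual_blocks

    @property
    def n_timesteps(self) -> int:
        return self.input_length // self.downsample_total

    @property
    def lstm_hidden(self) -> int:
        return self.encoder_dim // 2


@dataclass(frozen=True)
class ClassifierConfig:
    """Three fully connected layers Dz -> 128 -> 64 -> C with batch-norm
    before each rectifier."""

    input_dim: int = 256
    hidden_dims: Tuple[int, int] = (128, 64)
    n_classes: int = 2


# ---------------------------------------------------------------------------
# parameter initialisation
# ---------------------------------------------------------------------------

def init_extractor_params(cfg: EncoderConfig, rng: np.random.Generator) -> Dict:
    c0 = cfg.channel_plan[0]
    params: Dict = {
        "in_w": nn.he_conv(rng, cfg.input_kernel, 1, c0),
        "in_b": nn.zeros(c0),
        "blocks": [],
    }
    c_in = c0
    for c_out in cfg.channel_plan:
        block = {
            "w1": nn.he_conv(rng, cfg.block_kernel, c_in, c_out),
            "b1": nn.zeros(c_out),
            "w2": nn.he_conv(rng, cfg.block_kernel, c_out, c_out),
            "b2": nn.zeros(c_out),
        }
        if c_in != c_out:
            block["proj_w"] = nn.he_conv(rng, 1, c_in, c_out)
            block["proj_b"] = nn.zeros(c_out)
        params["blocks"].append(block)
        c_in = c_out
    return params


def init_fusion_params(cfg: EncoderConfig, rng: np.random.Generator) -> Dict:
    h = cfg.lstm_hidden
    return {
        "fwd": nn.init_lstm(rng, cfg.hidden_dim, h),
        "bwd": nn.init_lstm(rng, cfg.hidden_dim, h),
    }


def init_encoder_params(cfg: EncoderConfig, rng: np.random.Generator) -> Dict:
    return {"f": init_extractor_params(cfg, rng), "g": init_fusion_params(cfg, rng)}


def init_classifier_params(cfg: ClassifierConfig, rng: np.random.Generator) -> Dict:
    d1, d2 = cfg.hidden_dims
    return {
        "w1": nn.glorot(rng, cfg.input_dim, d1), "b1": nn.zeros(d1),
        "g1": np.ones(d1, dtype=nn.DTYPE), "be1": nn.zeros(d1),
        "w2": nn.glorot(rng, d1, d2), "b2": nn.zeros(d2),
        "g2": np.ones(d2, dtype=nn.DTYPE), "be2": nn.zeros(d2),
        "w3": nn.glorot(rng, d2, cfg.n_classes), "b3": nn.zeros(cfg.n_classes),
    }


def init_projector_params(dz: int, rng: np.random.Generator) -> Dict:
    return {
        "w1": nn.glorot(rng, dz, dz), "b1": nn.zeros(dz),
        "w2": nn.glorot(rng, dz, dz), "b2": nn.zeros(dz),
    }


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def conv_extract(params: Dict, x, cfg: EncoderConfig):
    """Hidden representations ``h (B, T, Dh)`` from segments ``x (B, T0)``."""
    if x.ndim == 2:
        x = anp.reshape(x, x.shape + (1,))
    if x.shape[1] != cfg.input_length:
        raise ValueError(
            f"expected segments of length T0={cfg.input_length}, got {x.shape[1]}"
        )
    pad = cfg.input_kernel // 2
    y = nn.relu(nn.conv1d(x, params["in_w"], params["in_b"], stride=1, pad=(pad, pad)))
    for block in params["blocks"]:
        main = nn.relu(nn.conv1d(y, block["w1"], block["b1"], stride=2, pad=(1, 1)))
        main = nn.conv1d(main, block["w2"], block["b2"], stride=1, pad=(1, 1))
        if "proj_w" in block:
            short = nn.conv1d(y, block["proj_w"], block["proj_b"], stride=2)
        else:
            short = y[:, ::2, :]
        y = nn.relu(main + short)
    return y


def fuse_encode(params: Dict, h):
    """Unit-norm encoder representation ``z (B, Dz)`` from hidden ``h (B, T, Dh)``.

    A bidirectional LSTM produces the fused sequence ``r (B, T, Dz)``; the
    representation is its final element (forward state after the whole
    sequence, concatenated with the backward state emitted at the last
    position), L2-normalised.
    """
    if h.shape[1] == 0:
        raise ValueError("hidden representation has zero timesteps")
    # The fusion network consumes direction-normalised hidden vectors: the
    # temporal objective on h is cosine-based (scale-free), and bounded
    # inputs keep the LSTM gates out of saturation.
    h = nn.l2_normalize(h)
    # Final fused element only: the forward state after the whole sequence and
    # the backward state at the last position (which, by definition of the
    # reversed recurrence, has consumed just that last timestep).
    fwd_last = nn.lstm_last(params["fwd"], h)
    bwd_last = nn.lstm_last(params["bwd"], h[:, -1:, :])
    return nn.l2_normalize(anp.concatenate([fwd_last, bwd_last], axis=1))


def encode(params: Dict, x, cfg: EncoderConfig):
    """Full encoder: segments ``(B, T0)`` to unit-norm ``z (B, Dz)``."""
    return fuse_encode(params["g"], conv_extract(params["f"], x, cfg))


def classify(params: Dict, z, bn_state: Optional[Dict] = None):
    """Class scores (pre-softmax) ``(B, C)`` from encoder representations.

    During training ``bn_state`` is None and batch statistics are used; for
    evaluation pass the frozen statistics from :func:`bn_state_from_data`.
    """
    def stats(a, key):
        if bn_state is None:
            return anp.mean(a, axis=0), anp.var(a, axis=0)
        return bn_state[key + "_m"], bn_state[key + "_v"]

    a1 = nn.dense(z, params["w1"], params["b1"])
    m, v = stats(a1, "bn1")
    a1 = nn.relu(nn.batchnorm(a1, params["g1"], params["be1"], m, v))
    a2 = nn.dense(a1, params["w2"], params["b2"])
    m, v = stats(a2, "bn2")
    a2 = nn.relu(nn.batchnorm(a2, params["g2"], params["be2"], m, v))
    return nn.dense(a2, params["w3"], params["b3"])


def bn_state_from_data(params: Dict, z) -> Dict:
    """Population batch-norm statistics of the classifier over a dataset."""
    a1 = nn.dense(z, params["w1"], params["b1"])
    m1, v1 = np.mean(a1, axis=0), np.var(a1, axis=0)
    a1 = nn.relu(nn.batchnorm(a1, params["g1"], params["be1"], m1, v1))
    a2 = nn.dense(a1, params["w2"], params["b2"])
    m2, v2 = np.mean(a2, axis=0), np.var(a2, axis=0)
    return {"bn1_m": m1, "bn1_v": v1, "bn2_m": m2, "bn2_v": v2}


def project(params: Optional[Dict], z):
    """Optional two-layer projection head used only inside pre-training losses."""
    if params is None:
        raise ValueError("projector is disabled (use_projector=False)")
    return nn.dense(nn.relu(nn.dense(z, params["w1"], params["b1"])),
                    params["w2"], params["b2"])


def softmax(scores):
    m = anp.max(scores, axis=1, keepdims=True)
    e = anp.exp(scores - m)
    return e / anp.sum(e, axis=1, keepdims=True)
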
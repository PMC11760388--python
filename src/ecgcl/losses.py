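"""Contrastive objectives for multi-level ECG representation learning.

Three InfoNCE-style losses act on two levels of the encoder:

* **temporal** — on hidden representations ``h, h̃ ∈ R^{B×T×Dh}`` of the weak
  and strong views: the positive for ``h_{i,t}`` is ``h̃_{i,t}`` (same
  timestamp, other view); negatives are the other timestamps of both views
  of the same sample.
* **channel** — on encoder representations ``z, z' ∈ R^{B×Dz}`` of two
  time-aligned leads: the positive for ``z_i`` is ``z'_i``; negatives are
  both leads of the other samples in the batch.
* **label** — a supervised contrastive loss over a set of representations
  with class labels: positives are all other samples sharing the anchor's
  label; by default it is applied to the 2B multiview set (weak + strong
  encoder representations, each carrying its sample's label).

Similarity is cosine throughout (encoder representations are unit-norm, so
cosine coincides with the dot product there), and every log-sum is
stabilised by per-anchor max subtraction.  The combined pre-training loss is
the convex combination ``λ1·Lt + λ2·Lc + λ3·Ll`` with λ = (1/3, 1/3, 1/3) on
labelled batches and the semi-supervised switch λ = (1/2, 1/2, 0) on
unlabelled batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

NEG_INF = -1e9  # masked similarity; exp underflows to exactly 0 in float32/64

LABELED_WEIGHTS = (1 / 3, 1 / 3, 1 / 3)
UNLABELED_WEIGHTS = (0.5, 0.5, 0.0)


@dataclass(frozen=True)
class LossWeights:
    lam1: float
    lam2: float
    lam3: float

    def __post_init__(self) -> None:
        for lam in (self.lam1, self.lam2, self.lam3):
            if not 0 <= lam <= 1:
                raise ValueError("loss weights must lie in [0, 1]")
        if abs(self.lam1 + self.lam2 + self.lam3 - 1.0) > 1e-9:
            raise ValueError("loss weights must sum to 1")


@dataclass(frozen=True)
class LossConfig:
    """Temperatures and weighting of the three contrastive terms."""

    tau_temporal: float = 1.0
    tau_channel: float = 0.1
    tau_label: float = 0.1
    labeled_weights: LossWeights = LossWeights(*LABELED_WEIGHTS)
    unlabeled_weights: LossWeights = LossWeights(*UNLABELED_WEIGHTS)
    label_loss_views: str = "multiview"  # or "single"

    def __post_init__(self) -> None:
        for tau in (self.tau_temporal, self.tau_channel, self.tau_label):
            if tau <= 0:
                raise ValueError("temperatures must be positive")
        if self.label_loss_views not in ("multiview", "single"):
            raise ValueError("label_loss_views must be 'multiview' or 'single'")


@dataclass
class ContrastiveBatch:
    """Representations of one pre-training batch (weak view, strong view,
    and the weak view of the time-aligned second lead)."""

    h: anp.ndarray          # (B, T, Dh) hidden, weak view
    h_tilde: anp.ndarray    # (B, T, Dh) hidden, strong view
    z: anp.ndarray          # (B, Dz) encoder, weak view
    z_tilde: anp.ndarray    # (B, Dz) encoder, strong view
    z_pair: anp.ndarray     # (B, Dz) encoder, second lead (weak)
    labels: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# similarity helpers
# ---------------------------------------------------------------------------

def cosine_sim(u, v, eps: float = 1e-12):
    """Cosine of the angle between two vectors: u·v / (||u|| ||v||)."""
    nu = anp.sqrt(anp.sum(u * u))
    nv = anp.sqrt(anp.sum(v * v))
    if nu < eps or nv < eps:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return anp.dot(u, v) / (nu * nv)


def _unit(x, eps: float = 1e-12):
    return x / anp.sqrt(anp.sum(x * x, axis=-1, keepdims=True) + eps)


def _logsumexp(a, axis):
    m = anp.max(a, axis=axis, keepdims=True)
    return anp.squeeze(m, axis=axis) + anp.log(
        anp.sum(anp.exp(a - m), axis=axis))


# ---------------------------------------------------------------------------
# the three contrastive losses
# ---------------------------------------------------------------------------

def temporal_loss(h, h_tilde, tau: float = 1.0):
    """Timestamp-level InfoNCE between two views' hidden representations.

    Averaged over the batch and over timestamps.  The denominator for anchor
    ``(i, t)`` runs over all cross-view similarities ``(h_{i,t}, h̃_{i,t'})``
    plus the same-view similarities ``(h_{i,t}, h_{i,t'})`` for t' ≠ t.
    """
    if h.shape != h_tilde.shape:
        raise ValueError("view shapes must match")
    if h.shape[1] == 0:
        raise ValueError("temporal loss needs at least one timestep")
    T = h.shape[1]
    hn = _unit(h)
    hn_t = _unit(h_tilde)
    cross = anp.einsum("itd,isd->its", hn, hn_t) / tau   # (B, T, T)
    same = anp.einsum("itd,isd->its", hn, hn) / tau
    same = same + NEG_INF * np.eye(T)                     # exclude t' = t
    allsims = anp.concatenate([cross, same], axis=2)      # (B, T, 2T)
    log_den = _logsumexp(allsims, axis=2)
    pos = anp.einsum("itd,itd->it", hn, hn_t) / tau
    return anp.mean(log_den - pos)


def channel_loss(z, z_pair, tau: float = 0.1):
    """Lead-level InfoNCE: positives are the two leads of the same window."""
    if z.shape[0] == 0:
        raise ValueError("channel loss needs a non-empty batch")
    B = z.shape[0]
    zn = _unit(z)
    zpn = _unit(z_pair)
    cross = anp.dot(zn, zpn.T) / tau                      # (B, B)
    same = anp.dot(zn, zn.T) / tau + NEG_INF * np.eye(B)
    log_den = _logsumexp(anp.concatenate([cross, same], axis=1), axis=1)
    pos = anp.sum(zn * zpn, axis=1) / tau
    return anp.mean(log_den - pos)


def label_loss(z, labels, tau: float = 0.1):
    """Supervised contrastive loss over a labelled representation set.

    For each anchor i the positives are all other samples with the same
    label; the denominator runs over all other samples.  Anchors with no
    positive contribute nothing and are excluded from the outer mean; if no
    anchor has a positive the loss is 0 (with a warning).
    """
    labels = np.asarray(labels)
    n = z.shape[0]
    if n < 2:
        raise ValueError("label loss needs at least two samples")
    if len(labels) != n:
        raise ValueError("labels must align with representations")
    zn = _unit(z)
    sims = anp.dot(zn, zn.T) / tau + NEG_INF * np.eye(n)
    pos_mask = (labels[:, None] == labels[None, :]) & ~np.eye(n, dtype=bool)
    n_pos = pos_mask.sum(axis=1)
    anchors = n_pos > 0
    if not anchors.any():
        warnings.warn("label loss: no anchor has a same-label positive")
        return anp.sum(z * 0.0)  # keeps the autograd graph alive
    log_den = _logsumexp(sims, axis=1)                    # (n,)
    log_prob = sims - log_den[:, None]
    per_anchor = -anp.sum(anp.where(pos_mask, log_prob, 0.0), axis=1) / np.maximum(n_pos, 1)
    return anp.sum(anp.where(anchors, per_anchor, 0.0)) / anchors.sum()


# ---------------------------------------------------------------------------
# combination and the supervised loss
# ---------------------------------------------------------------------------

def combined_loss(batch: ContrastiveBatch, config: LossConfig = LossConfig(),
                  is_labeled: bool = False):
    """Weighted multiple contrastive loss with the semi-supervised switch.

    Returns ``(total, breakdown)`` where the breakdown maps term names to
    float values (for logging) plus the weights used.
    """
    if is_labeled and batch.labels is None:
        raise ValueError("labeled batch requires labels")
    w = config.labeled_weights if is_labeled else config.unlabeled_weights
    l_t = temporal_loss(batch.h, batch.h_tilde, config.tau_temporal)
    l_c = channel_loss(batch.z, batch.z_pair, config.tau_channel)
    if is_labeled:
        if config.label_loss_views == "multiview":
            feats = anp.concatenate([batch.z, batch.z_tilde], axis=0)
            labs = np.concatenate([batch.labels, batch.labels])
        else:
            feats, labs = batch.z, batch.labels
        l_l = label_loss(feats, labs, config.tau_label)
    else:
        l_l = 0.0
    total = w.lam1 * l_t + w.lam2 * l_c + w.lam3 * l_l
    breakdown = {  # getval strips autograd boxes when called under tracing
        "temporal": float(getval(l_t)), "channel": float(getval(l_c)),
        "label": float(getval(l_l)),
        "lam": (w.lam1, w.lam2, w.lam3),
    }
    return total, breakdown


def cross_entropy(scores, one_hot, eps: float = 1e-7):
    """Binary-per-class cross-entropy of softmax probabilities.

    Per sample: ``-Σ_i [y_i log y'_i + (1 - y_i) log(1 - y'_i)]`` with the
    probabilities clipped to ``[eps, 1 - eps]``; averaged over the batch.
    """
    one_hot = np.asarray(one_hot)
    if scores.shape != one_hot.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape} vs labels {one_hot.shape}")
    m = anp.max(scores, axis=1, keepdims=True)
    e = anp.exp(scores - m)
    probs = e / anp.sum(e, axis=1, keepdims=True)
    probs = anp.clip(probs, eps, 1 - eps)
    per_sample = -anp.sum(one_hot * anp.log(probs)
                          + (1 - one_hot) * anp.log(1 - probs), axis=1)
    return anp.mean(per_sample)


def one_hot(labels, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((len(labels), n_classes), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out
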
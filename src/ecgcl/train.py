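"""Semi-supervised pre-training and downstream fine-tuning.

Pre-training draws single-source batches (each step is entirely labelled or
entirely unlabelled) interleaved proportionally to the two dataset sizes,
builds weak/strong views via domain-knowledge augmentation, runs both views
and the second lead through the encoder, and optimises the combined
contrastive loss (Adam, step learning-rate decay: ×0.8 every 3 epochs).

Fine-tuning attaches the MLP classifier and trains with cross-entropy under
an inverse-quadratic learning-rate schedule
``η = η_base / (1 + 10·T_cur/T_max)²``, either as a *linear probe* (encoder
frozen bit-exactly; representations are computed once and cached) or as
*full fine-tuning* (encoder and classifier updated jointly).  No
augmentation is applied downstream.  Evaluation is on a stratified held-out
split with accuracy and macro-averaged sensitivity, precision and F1.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from . import model as M
from . import nn
from .augment import AugmentationConfig, make_strong_views
from .ecg_io import SegmentStore
from .losses import (ContrastiveBatch, LossConfig, combined_loss,
                     cross_entropy, one_hot)
from .preprocess import detect_qrs


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 40
    batch_size: int = 256
    base_lr: float = 1e-3
    lr_gamma: float = 0.8
    lr_step_epochs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2")


@dataclass(frozen=True)
class FinetuneConfig:
    mode: str = "linear_probe"  # or "full_finetune"
    batch_size: int = 512
    t_max: int = 30
    eta_base: float = 1e-3
    val_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("linear_probe", "full_finetune"):
            raise ValueError("mode must be 'linear_probe' or 'full_finetune'")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


@dataclass
class Metrics:
    acc: float
    macro_sen: float
    macro_pre: float
    macro_f1: float
    confusion: np.ndarray


# ---------------------------------------------------------------------------
# learning-rate schedules
# ---------------------------------------------------------------------------

def step_lr(epoch: int, base_lr: float = 1e-3, gamma: float = 0.8,
            step: int = 3) -> float:
    """Step decay: ``base_lr * gamma^floor(epoch / step)``."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return base_lr * gamma ** (epoch // step)


def finetune_lr(t_cur: int, eta_base: float = 1e-3, t_max: int = 30) -> float:
    """Inverse-quadratic decay ``eta_base / (1 + 10 * t_cur / t_max)^2``."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not 0 <= t_cur <= t_max:
        raise ValueError("t_cur must lie in [0, t_max]")
    return eta_base / (1 + 10 * t_cur / t_max) ** 2


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(predictions, labels) -> Metrics:
    """Accuracy plus macro sensitivity / precision / F1 from the confusion
    matrix (zero-denominator cells count as 0)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must align")
    cm = confusion_matrix(labels, predictions, labels=[0, 1])
    pre, sen, f1, _ = precision_recall_fscore_support(
        labels, predictions, labels=[0, 1], average="macro", zero_division=0)
    acc = np.trace(cm) / cm.sum()
    return Metrics(acc=float(acc), macro_sen=float(sen), macro_pre=float(pre),
                   macro_f1=float(f1), confusion=cm)


# ---------------------------------------------------------------------------
# pre-training
# ---------------------------------------------------------------------------

def _batches(n: int, batch_size: int, rng: np.random.Generator) -> List[np.ndarray]:
    idx = rng.permutation(n)
    out = [idx[i : i + batch_size] for i in range(0, n, batch_size)]
    return [b for b in out if len(b) >= 2]


def _interleave(n_a: int, n_b: int) -> List[int]:
    """Proportional round-robin of two sources (0=a, 1=b), deterministic."""
    marks = [((i + 0.5) / n_a, 0) for i in range(n_a)]
    marks += [((i + 0.5) / n_b, 1) for i in range(n_b)]
    marks.sort(key=lambda m: (m[0], m[1]))
    return [s for _, s in marks]


def _store_r_peaks(store: SegmentStore) -> List[np.ndarray]:
    if store.r_peaks is not None:
        return store.r_peaks
    return [detect_qrs(seg, store.fs) for seg in store.segments]


def pretrain(labeled: Optional[SegmentStore], unlabeled: Optional[SegmentStore],
             pre_cfg: PretrainConfig = PretrainConfig(),
             enc_cfg: M.EncoderConfig = M.EncoderConfig(),
             loss_cfg: LossConfig = LossConfig(),
             aug_cfg: AugmentationConfig = AugmentationConfig(),
             ) -> Tuple[Dict, List[dict]]:
    """Learn the encoder from labelled and/or unlabelled segment pairs.

    Returns ``(checkpoint, log)``: the checkpoint holds the encoder
    parameters, configs and final RNG state; the log has one entry per step
    (epoch, source, per-term losses, weights, learning rate).
    """
    n_lab = len(labeled) if labeled is not None else 0
    n_unlab = len(unlabeled) if unlabeled is not None else 0
    if n_lab == 0 and n_unlab == 0:
        raise ValueError("pretrain needs labelled or unlabelled data")

    rng = np.random.default_rng(pre_cfg.seed)
    params = M.init_encoder_params(enc_cfg, rng)
    if enc_cfg.use_projector:
        params["proj"] = M.init_projector_params(enc_cfg.encoder_dim, rng)
    opt = nn.Adam(params, lr=pre_cfg.base_lr)
    rp_lab = _store_r_peaks(labeled) if n_lab else []
    rp_unlab = _store_r_peaks(unlabeled) if n_unlab else []
    log: List[dict] = []

    for epoch in range(pre_cfg.epochs):
        lr = step_lr(epoch, pre_cfg.base_lr, pre_cfg.lr_gamma, pre_cfg.lr_step_epochs)
        lab_batches = _batches(n_lab, pre_cfg.batch_size, rng) if n_lab else []
        unlab_batches = _batches(n_unlab, pre_cfg.batch_size, rng) if n_unlab else []
        if lab_batches and unlab_batches:
            order = _interleave(len(lab_batches), len(unlab_batches))
        else:
            order = [0] * len(lab_batches) + [1] * len(unlab_batches)
        it_lab, it_unlab = iter(lab_batches), iter(unlab_batches)
        for step_i, src in enumerate(order):
            is_labeled = src == 0
            store = labeled if is_labeled else unlabeled
            rpeaks = rp_lab if is_labeled else rp_unlab
            idx = next(it_lab if is_labeled else it_unlab)
            x = store.segments[idx].astype(nn.DTYPE)
            x_pair = store.paired_segments[idx].astype(nn.DTYPE)
            x_strong = make_strong_views(
                x, [rpeaks[i] for i in idx], store.fs, aug_cfg, rng
            ).astype(nn.DTYPE)
            labels = store.labels[idx] if is_labeled else None

            B = len(idx)
            x_all = np.concatenate([x, x_strong, x_pair], axis=0)

            def loss_fn(p):
                # one stacked forward pass over (weak | strong | second lead)
                h_all = M.conv_extract(p["f"], x_all, enc_cfg)
                z_all = M.fuse_encode(p["g"], h_all)
                h, h_t = h_all[:B], h_all[B : 2 * B]
                z, z_t, z_pair = z_all[:B], z_all[B : 2 * B], z_all[2 * B :]
                if enc_cfg.use_projector:
                    z, z_t, z_pair = (M.project(p["proj"], v)
                                      for v in (z, z_t, z_pair))
                batch = ContrastiveBatch(h=h, h_tilde=h_t, z=z, z_tilde=z_t,
                                         z_pair=z_pair, labels=labels)
                total, breakdown = combined_loss(batch, loss_cfg, is_labeled)
                loss_fn.breakdown = breakdown
                return total

            value, grads = value_and_grad(loss_fn)(params)
            params = opt.step(params, grads, lr=lr)
            entry = {"epoch": epoch, "step": step_i,
                     "source": "labeled" if is_labeled else "unlabeled",
                     "loss": float(value), "lr": lr}
            entry.update(loss_fn.breakdown)
            log.append(entry)

    checkpoint = {
        "params": params,
        "encoder_config": enc_cfg,
        "loss_config": loss_cfg,
        "pretrain_config": pre_cfg,
        "rng_state": rng.bit_generator.state,
    }
    return checkpoint, log


def save_checkpoint(checkpoint: Dict, path: str) -> None:
    with open(path, "wb") as fh:
        pickle.dump(checkpoint, fh)


def load_checkpoint(path: str) -> Dict:
    with open(path, "rb") as fh:
        return pickle.load(fh)


def check_checkpoint_compatible(checkpoint: Dict, enc_cfg: M.EncoderConfig) -> None:
    ck = checkpoint["encoder_config"]
    if ck != enc_cfg:
        raise ValueError(
            f"checkpoint encoder config {ck} incompatible with requested {enc_cfg}")


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def stratified_split(labels: np.ndarray, val_fraction: float,
                     rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n_val = int(round(val_fraction * len(idx)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def _encode_all(params: Dict, x: np.ndarray, cfg: M.EncoderConfig,
                batch: int = 256) -> np.ndarray:
    outs = [M.encode(params, x[i : i + batch].astype(nn.DTYPE), cfg)
            for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


def finetune(checkpoint: Dict, store: SegmentStore,
             ft_cfg: FinetuneConfig = FinetuneConfig(),
             ) -> Tuple[Dict, Metrics]:
    """Train the downstream AF classifier from a pre-trained checkpoint.

    Returns the trained model (encoder + classifier parameters + frozen
    batch-norm statistics) and metrics on the stratified held-out split.
    """
    if store.labels is None:
        raise ValueError("fine-tuning requires a labelled store")
    enc_cfg: M.EncoderConfig = checkpoint["encoder_config"]
    check_checkpoint_compatible(checkpoint, enc_cfg)
    enc_params = checkpoint["params"]
    rng = np.random.default_rng(ft_cfg.seed)
    clf_cfg = M.ClassifierConfig(input_dim=enc_cfg.encoder_dim)
    clf_params = M.init_classifier_params(clf_cfg, rng)

    labels = np.asarray(store.labels, dtype=int)
    train_idx, val_idx = stratified_split(labels, ft_cfg.val_fraction, rng)
    x_train, y_train = store.segments[train_idx], labels[train_idx]
    x_val, y_val = store.segments[val_idx], labels[val_idx]

    if ft_cfg.mode == "linear_probe":
        z_train = _encode_all(enc_params, x_train, enc_cfg)
        params = clf_params
        opt = nn.Adam(params, lr=ft_cfg.eta_base)
        for t_cur in range(ft_cfg.t_max):
            lr = finetune_lr(t_cur, ft_cfg.eta_base, ft_cfg.t_max)
            for idx in _batches(len(z_train), ft_cfg.batch_size, rng):
                zb, yb = z_train[idx], one_hot(y_train[idx])

                def loss_fn(p):
                    return cross_entropy(M.classify(p, zb), yb)

                _, grads = value_and_grad(loss_fn)(params)
                params = opt.step(params, grads, lr=lr)
        clf_params = params
    else:  # full_finetune
        params = {"enc": enc_params, "clf": clf_params}
        opt = nn.Adam(params, lr=ft_cfg.eta_base)
        for t_cur in range(ft_cfg.t_max):
            lr = finetune_lr(t_cur, ft_cfg.eta_base, ft_cfg.t_max)
            for idx in _batches(len(x_train), ft_cfg.batch_size, rng):
                xb = x_train[idx].astype(nn.DTYPE)
                yb = one_hot(y_train[idx])

                def loss_fn(p):
                    z = M.encode(p["enc"], xb, enc_cfg)
                    return cross_entropy(M.classify(p["clf"], z), yb)

                _, grads = value_and_grad(loss_fn)(params)
                params = opt.step(params, grads, lr=lr)
        enc_params, clf_params = params["enc"], params["clf"]

    z_train = _encode_all(enc_params, x_train, enc_cfg)
    bn_state = M.bn_state_from_data(clf_params, z_train)
    z_val = _encode_all(enc_params, x_val, enc_cfg)
    preds = predict_from_z(clf_params, bn_state, z_val)
    metrics = evaluate(preds, y_val)
    trained = {"encoder": enc_params, "classifier": clf_params,
               "bn_state": bn_state, "encoder_config": enc_cfg}
    return trained, metrics


def predict_from_z(clf_params: Dict, bn_state: Dict, z: np.ndarray) -> np.ndarray:
    scores = M.classify(clf_params, z, bn_state=bn_state)
    return np.argmax(scores, axis=1)


def predict(trained: Dict, x: np.ndarray) -> np.ndarray:
    z = _encode_all(trained["encoder"], x, trained["encoder_config"])
    return predict_from_z(trained["classifier"], trained["bn_state"], z)
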
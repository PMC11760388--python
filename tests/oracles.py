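"""Independent brute-force reference implementations used as test oracles.

Every function here is written as plain nested loops over the printed
formulas, with no code shared with the package implementation.
"""

import numpy as np


def cos(u, v):
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def temporal_loss_ref(h, h_tilde, tau):
    """Per-timestamp InfoNCE, double loop over (sample, timestep)."""
    B, T, _ = h.shape
    total = 0.0
    for i in range(B):
        for t in range(T):
            num = np.exp(cos(h[i, t], h_tilde[i, t]) / tau)
            den = 0.0
            for tp in range(T):
                den += np.exp(cos(h[i, t], h_tilde[i, tp]) / tau)
                if tp != t:
                    den += np.exp(cos(h[i, t], h[i, tp]) / tau)
            total += -np.log(num / den)
    return total / (B * T)


def channel_loss_ref(z, z_pair, tau):
    B = z.shape[0]
    total = 0.0
    for i in range(B):
        num = np.exp(cos(z[i], z_pair[i]) / tau)
        den = 0.0
        for j in range(B):
            den += np.exp(cos(z[i], z_pair[j]) / tau)
            if j != i:
                den += np.exp(cos(z[i], z[j]) / tau)
        total += -np.log(num / den)
    return total / B


def label_loss_ref(z, labels, tau):
    """Supervised contrastive loss; anchors without positives are skipped."""
    n = z.shape[0]
    labels = np.asarray(labels)
    per_anchor = []
    for i in range(n):
        pos = [p for p in range(n) if p != i and labels[p] == labels[i]]
        if not pos:
            continue
        den = sum(np.exp(cos(z[i], z[j]) / tau) for j in range(n) if j != i)
        s = sum(-np.log(np.exp(cos(z[i], z[p]) / tau) / den) for p in pos)
        per_anchor.append(s / len(pos))
    return float(np.mean(per_anchor)) if per_anchor else 0.0


def cross_entropy_ref(scores, one_hot, eps=1e-7):
    scores = np.asarray(scores, float)
    out = []
    for row, y in zip(scores, one_hot):
        p = np.exp(row - row.max())
        p = p / p.sum()
        p = np.clip(p, eps, 1 - eps)
        out.append(-sum(yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                        for yi, pi in zip(y, p)))
    return float(np.mean(out))


def count_windows_ref(n_samples, fs, window_s, overlap_s):
    """Exhaustive sliding-window enumeration."""
    win = int(round(window_s * fs))
    step = int(round((window_s - overlap_s) * fs))
    count = 0
    start = 0
    while start + win <= n_samples:
        count += 1
        start += step
    return count
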
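"""A miniature run of the whole method: semi-supervised contrastive
pre-training followed by linear probing.

Scaled below the benchmark in scripts/acceptance.py (128 labelled + 128
unlabelled pairs, 4 epochs) so it finishes in a couple of minutes on one
CPU; expect a probe accuracy well above chance but below the benchmark's.
"""

import warnings

import numpy as np

warnings.filterwarnings("ignore")

from ecgcl import model as M
from ecgcl.synthetic import make_synthetic_dataset
from ecgcl.train import FinetuneConfig, PretrainConfig, finetune, pretrain

enc_cfg = M.EncoderConfig(channel_plan=(8, 16, 16, 32, 32, 32), hidden_dim=32,
                          encoder_dim=64)
labeled, unlabeled = make_synthetic_dataset(128, 128, af_fraction=0.5, seed=11)

checkpoint, log = pretrain(labeled, unlabeled,
                           PretrainConfig(epochs=4, batch_size=16, seed=0),
                           enc_cfg)
per_epoch = {}
for e in log:
    per_epoch.setdefault(e["epoch"], []).append(e["loss"])
for ep, losses in sorted(per_epoch.items()):
    print(f"pre-training epoch {ep}: mean combined loss {np.mean(losses):.3f}")

_, metrics = finetune(checkpoint, labeled,
                      FinetuneConfig(mode="linear_probe", t_max=15,
                                     batch_size=32, seed=0))
print(f"\nlinear probe on held-out 30%: acc {metrics.acc:.3f}, "
      f"macro-F1 {metrics.macro_f1:.3f}")
print("(the loss should fall across epochs; probe accuracy above 0.5 shows")
print(" the encoder has picked up class-relevant structure without the")
print(" classifier ever seeing the encoder's training objective)")
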
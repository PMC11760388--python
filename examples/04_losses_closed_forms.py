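"""The three contrastive objectives and their closed-form sanity values.

Temporal loss contrasts per-timestamp hidden vectors across two views of
one sample; channel loss contrasts encoder representations of two
time-aligned leads; label loss (supervised contrastive) pulls together all
samples sharing a class label.  Each is an InfoNCE-style softmax over
cosine similarities with temperature tau.
"""

import numpy as np

from ecgcl.losses import channel_loss, label_loss, temporal_loss

# two mutually orthonormal timesteps, identical views, tau=1:
# every anchor sees one positive (sim 1) and two negatives (sim 0),
# so the loss is -log(e / (e + 2)) = 0.5514...
h = np.eye(2)[None, :, :]
print(f"temporal, orthonormal T=2 views : {float(temporal_loss(h, h, 1.0)):.4f} "
      f"(closed form {np.log(1 + 2 / np.e):.4f})")

z = np.eye(2)
print(f"channel, orthonormal B=2        : {float(channel_loss(z, z, 1.0)):.4f}")

# three identical same-label representations: each anchor's two positives
# each carry probability 1/2, so the loss is log 2
z3 = np.tile([1.0, 0.0], (3, 1))
print(f"label, 3 identical same-label   : {float(label_loss(z3, [0, 0, 0], 0.1)):.4f} "
      f"(log 2 = {np.log(2):.4f})")

# degenerate cases vanish: a single sample/timestep has no negatives
print(f"temporal at B=1, T=1            : "
      f"{float(temporal_loss(np.ones((1, 1, 4)), np.ones((1, 1, 4)), 1.0)):.4f}")
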
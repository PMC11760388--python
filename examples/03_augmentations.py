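"""Domain-knowledge augmentation: T-wave masking plus vertical flipping.

The strong view masks the (non-diagnostic) 50–300 ms post-R window of half
the beats and then flips the whole signal with 50 % probability; the weak
view is the preprocessed signal itself.  At 128 Hz each masked beat covers
exactly samples [R+6, R+38) — 32 samples — so masking never touches the
diagnostic QRS neighbourhood.
"""

import numpy as np

from ecgcl.augment import AugmentationConfig, ablation_augment, domain_knowledge_augment, t_wave_mask
from ecgcl.synthetic import SyntheticRecordSpec, synthesize_record
from ecgcl.preprocess import zscore

rec = synthesize_record(SyntheticRecordSpec(rhythm_class="non-AF", seed=5))
x = zscore(rec.signals[0])

masked = t_wave_mask(x, rec.r_peaks, rec.fs, c=100, fill=0.0, seed=0)
print(f"T-wave mask (c=100): {np.sum(masked == 0.0)} samples set to 0 "
      f"across {len(rec.r_peaks)} beats (32 per fully contained window)")

strong = domain_knowledge_augment(x, rec.r_peaks, rec.fs,
                                  AugmentationConfig(seed=1))
print(f"strong view differs from weak view on "
      f"{np.mean(strong != x) * 100:.1f}% of samples")

for kind in ("gaussian_noise", "channel_scaling", "horizontal_flip", "random_mask"):
    out = ablation_augment(x, kind, seed=2)
    print(f"{kind:16s} -> length {len(out)}, rms {np.sqrt(np.mean(out**2)):.2f}")
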
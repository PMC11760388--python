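"""Generate synthetic dual-lead ECG segment pairs and inspect the two
rhythm classes.

The generator renders Gaussian-bump heartbeats on an RR grid: non-AF
records have near-regular RR intervals and a P wave 160 ms before each R;
AF records have RR intervals drawn uniformly over ±40 % of the mean, no P
wave, and a 6 Hz fibrillatory oscillation.
"""

import numpy as np

from ecgcl.synthetic import SyntheticRecordSpec, generate_rr_sequence, synthesize_record

for cls in ("non-AF", "AF"):
    spec = SyntheticRecordSpec(rhythm_class=cls, seed=7)
    rr = generate_rr_sequence(spec)
    rec = synthesize_record(spec)
    print(f"{cls:7s}  beats={len(rec.r_peaks):3d}  "
          f"RR mean={rr.mean():.3f} s  RR sd={rr.std():.3f} s  "
          f"leads={rec.signals.shape}")

print()
print("The RR standard deviation separates the classes: AF rhythm is")
print("irregular by construction, which is the primary rhythm cue the")
print("encoder can learn; the P-wave/f-wave difference is the morphology cue.")
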
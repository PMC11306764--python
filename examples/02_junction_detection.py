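"""Detect the 32 junction points that partition sutures from fontanelles.

The metopic and sagittal junctions come from a first-order width-jump
criterion (thresholds k = 0.15 / 0.18 mm) on the paired width series
between the left/right frontal and parietal borders; the 24 lateral
junctions come from a second-order width change threshold (m = 0.4 mm).
Prints every detected junction next to the generator's ground truth.
"""

import warnings

import suturemorph as sm

warnings.filterwarnings("ignore")

cfg = sm.SyntheticConfig(seed=3)
subject = sm.generate_subject(cfg, subject_seed=5, subject_id="demo")
sl = sm.assemble_semilandmarks(subject.curves)
partition = sm.partition_sutures(sl)       # defaults: k=0.15/0.18, m=0.4

print(f"{'JP':<6} {'border':>6} {'detected':>9} {'truth':>6} {'err':>4}")
worst = 0
for jp in partition.junction_points:
    border, ordinal = subject.truth.junction_ordinals[jp.label]
    err = abs(jp.ordinal - ordinal)
    worst = max(worst, err)
    print(f"{jp.label:<6} {jp.border:>6} {jp.ordinal:>9} {ordinal:>6} {err:>4}")

print(f"\n9 parts: {sorted(partition.parts)}")
print(f"worst ordinal error: {worst} (the generator guarantees detectability "
      "within 1 semilandmark at default thresholds)")
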
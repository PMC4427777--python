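"""Overlap metrics and the paired comparison across cases.

Dice = 2|Vm ∩ Va| / (|Vm| + |Va|), precision = |Vm ∩ Va|/|Va|,
recall = |Vm ∩ Va|/|Vm|, with Vm the reference and Va the segmentation.
The paired t-test compares two per-case score sequences.
"""

import numpy as np

import cerebseg as cs

rng = np.random.default_rng(0)
ref = cs.BinaryMask(rng.random((32, 32, 32)) < 0.2)

# a segmentation that misses some voxels and adds a few false positives
seg_data = ref.data & (rng.random(ref.shape) > 0.1)
seg_data |= (~ref.data) & (rng.random(ref.shape) < 0.01)
seg = cs.BinaryMask(seg_data)

rep = cs.evaluate(ref, seg)
print(f"|Vm|={rep.n_ref}  |Va|={rep.n_seg}  |Vm∩Va|={rep.n_intersect}")
print(f"dice={rep.dice:.4f}  precision={rep.precision:.4f}  "
      f"recall={rep.recall:.4f}")
hm = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
print(f"dice equals the harmonic mean of precision and recall: {hm:.4f}")

# paired comparison of two methods over ten cases
method_a = [0.93, 0.94, 0.92, 0.95, 0.93, 0.94, 0.93, 0.92, 0.94, 0.93]
method_b = [0.87, 0.88, 0.87, 0.89, 0.86, 0.88, 0.87, 0.86, 0.88, 0.87]
tt = cs.paired_ttest(method_a, method_b)
print(f"paired t-test over {tt.n} cases: mean diff {tt.mean_diff:.3f}, "
      f"t={tt.t_statistic:.2f}, p={tt.p_value:.2e}")
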
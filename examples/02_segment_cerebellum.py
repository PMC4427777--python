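"""Run the full segmentation pipeline on a phantom and score it.

The pipeline subtracts the cerebral mask from the brain mask (candidate
A), removes CSF-dominated voxels and erodes to detach the venous
sinuses, keeps the largest component and dilates it back (candidate B),
then removes the brain stem + peduncle with an affinely aligned atlas
mask.  Dice/precision/recall are computed against the phantom's exact
cerebellum labels; precision rises sharply once the stem is removed.
"""

import dataclasses

import cerebseg as cs
from cerebseg.phantom import make_atlas

case = cs.generate_phantom(cs.PhantomConfig(noise_sigma=5.0, seed=3))
atlas = make_atlas(case)          # phantom-derived stand-in atlas
truth = case.cerebellum_mask()
cfg = cs.PipelineConfig(seed=42)

result = cs.segment_cerebellum(case.t1, case.brain_mask(),
                               case.cerebral_mask(), atlas, cfg)
for entry in result.stage_log:
    print(f"  {entry['stage']:<22} {entry['voxels']:>8} voxels")

after = cs.evaluate(truth, result.final)
print(f"with brain-stem removal:    dice={after.dice:.3f} "
      f"precision={after.precision:.3f} recall={after.recall:.3f}")

no_stem = cs.segment_cerebellum(
    case.t1, case.brain_mask(), case.cerebral_mask(), None,
    dataclasses.replace(cfg, remove_brainstem=False))
before = cs.evaluate(truth, no_stem.final)
print(f"without brain-stem removal: dice={before.dice:.3f} "
      f"precision={before.precision:.3f} recall={before.recall:.3f}")
print("stem removal trades a little recall for a large precision gain,"
      " lifting Dice.")
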
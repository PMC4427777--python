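# cerebseg

Automated segmentation of the **cerebellum** from skull-stripped
T1-weighted brain MRI, for anyone who needs reliable cerebellar volumes
or a cerebellar reference region (volumetry of motor/degenerative
disease, PET intensity normalization) without manual delineation.

Delineating the cerebellum is hard for intensity-based methods because
its neighbours look just like it on T1: the venous sinuses sit behind
only a thin sheet of CSF, and the brain stem is continuous with
cerebellar white matter through the cerebellar peduncles.  `cerebseg`
combines tissue classification, morphology, and an atlas prior to
exploit how each confound attaches:

1. **Candidate A** — subtract the cerebral mask from the brain mask.
2. **CSF-PVE trim** — threshold the CSF partial-volume fraction map
   (CSF fraction ≥ 0.5 dropped) and erode, severing the thin bridges
   that attach the sinuses.
3. **Candidate B** — keep the largest connected component and dilate it
   back to size with the same kernel; detached sinuses are discarded.
4. **Brain-stem removal** — affinely align a template-space brain-stem +
   peduncle mask to the subject, subtract it, open, and keep the
   largest component.

Results are scored with the standard overlap metrics, where `Vm` is the
reference voxel set and `Va` the segmentation:

```
Dice = 2|Vm ∩ Va| / (|Vm| + |Va|)    Precision = |Vm ∩ Va| / |Va|
Recall = |Vm ∩ Va| / |Vm|
```

and paired method comparisons use a two-sided paired t-test.

Because manually labelled MRI cannot ship with a package, `cerebseg`
includes a **synthetic phantom generator**: a skull-stripped head with
cerebrum, cerebellum, brain-stem/peduncle bridge, and a venous-sinus
slab behind a 1-voxel CSF sheet, with exact ground-truth labels,
partial-volume fractions and bias field.  Every accuracy claim in the
test suite is made against this exact truth.  See `docs/methods.md` for
the model, parameters, and what the phantoms do and do not show.

## Worked example

```bash
python examples/02_segment_cerebellum.py
```

generates a noisy phantom (sigma 5), segments it with and without
brain-stem removal, and prints:

```
  candidate_a               90862 voxels
  trim_with_csf_pve         28872 voxels
  candidate_b               39084 voxels
  align_atlas               11392 voxels
  remove_brainstem          32122 voxels
with brain-stem removal:    dice=0.993 precision=0.997 recall=0.988
without brain-stem removal: dice=0.902 precision=0.826 recall=0.994
stem removal trades a little recall for a large precision gain, lifting Dice.
```

Reading the stage log: candidate A (brain minus cerebrum) holds ~91k
voxels, the CSF trim cuts it to ~29k (sheet voxels and the erosion
margin), dilation restores candidate B to ~39k, and subtracting the
~11k-voxel aligned stem mask leaves a ~32k-voxel cerebellum.  The
metric lines show the pipeline's central trade: removing the brain stem
deletes a large false-positive mass (precision 0.83 → 1.00) at the
cost of a thin rind near the peduncles (recall 0.994 → 0.988), lifting
Dice from 0.90 to 0.99 against the phantom's exact cerebellum labels.

Other examples: `01_generate_phantom.py` (anatomy inventory),
`03_registration_recovery.py` (pose recovery within one voxel),
`04_evaluate_masks.py` (metrics and the paired t-test).

## Command line

```bash
cerebseg phantom --seed 1 --out case/ --noise-sigma 5
cerebseg segment --t1 case/t1.nii.gz --brain-mask brain.nii.gz \
    --cerebral-mask cerebral.nii.gz --atlas-dir atlas/ --out run/
cerebseg evaluate --ref labels_cb.nii.gz --seg run/final.nii.gz --out report.json
```

All volumes are NIfTI-1; the atlas directory holds `template.nii.gz` +
`stem_mask.nii.gz`; every command writes a `manifest.json` with config,
input hashes and seeds, and reruns are bit-identical.

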
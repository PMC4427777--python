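# Methods

`cerebseg` implements a fully automated cerebellum-segmentation pipeline
for skull-stripped T1-weighted brain MR volumes, together with the
synthetic phantoms and evaluation machinery used to validate it.  This
note documents the model, its assumptions, the tunable parameters, the
numerical choices, and what the phantom experiments do and do not show.

## The segmentation model

The pipeline exploits two anatomical facts.  First, once the cerebral
hemispheres are removed from a brain mask, what remains is dominated by
the cerebellum, the brain stem, the cerebellar peduncles, and nearby
venous sinuses — structures whose T1 intensities are too similar for
intensity classification alone to separate.  Second, the two main
false-positive sources differ in how they attach to the cerebellum: the
venous sinuses are separated from it by a thin sheet of CSF (dark on
T1, detectable through its partial-volume signature), while the brain
stem is continuous with cerebellar white matter through the peduncles
and carries no intensity or topological cue at all — only spatial prior
knowledge (an atlas) can remove it.

Stages, in fixed order with no feedback:

1. **Preprocessing.**  Multiplicative bias-field correction, three-class
   tissue classification (CSF/GM/WM), and partial-volume estimation
   (PVE), producing a CSF fraction map.
2. **Candidate A** = brain mask ∧ ¬cerebral mask.  The cerebral mask is
   an input (in practice from a cortical-surface tool; on phantoms, the
   ground-truth cerebrum dilated by 1 voxel).
3. **CSF-PVE trim.**  Voxels with CSF fraction ≥ `csf_threshold`
   (default 0.5, the majority-fraction convention) are dropped, then the
   mask is eroded with a ball of radius `trim_se_radius` (default 2
   voxels).  This severs the thin partial-volume bridges that attach
   the sinus slab to the cerebellar surface.
4. **Candidate B.**  The largest connected component (26-connectivity by
   default) is kept — the cerebellum-plus-brain-stem complex — and
   dilated with the same ball, restoring it to its original size.  The
   detached sinus components are discarded here.
5. **Brain-stem removal.**  A brain-stem + peduncle mask drawn in
   template space is mapped into subject space by intensity-based
   affine registration and subtracted; a morphological opening (ball
   radius `opening_se_radius`, default 1) removes masking noise and a
   final largest-component pass restores the single-structure
   guarantee (this last pass is an extension, recorded in the stage
   log).

The erosion/dilation pair shares one kernel so that "restore to
original size" is exact on surfaces that survive the erosion.  Because
`dilate(largest(erode(X))) ⊆ X`, candidate B can never grow beyond the
thresholded candidate A; the final mask is nested inside candidate B.

### Evaluation

With `Vm` the reference voxel set and `Va` the segmentation:
Dice = 2|Vm∩Va|/(|Vm|+|Va|), precision = |Vm∩Va|/|Va|, recall =
|Vm∩Va|/|Vm|.  Dice is exactly the harmonic mean of precision and
recall, which `evaluate` asserts.  Empty masks raise instead of scoring
zero — an empty segmentation is a failure, not a result.  Paired
method comparisons use a two-sided paired t-test (sample sd, n−1 df);
the caller interprets p.

Brain-stem removal trades recall for precision: the atlas mask clips a
thin rind of true cerebellum near the peduncle junction (recall drops
slightly) while deleting the entire stem false positive (precision and
Dice rise sharply).  This direction of effect is the pipeline's central
testable claim and is checked across ten noise seeds.

## Surrogate preprocessing components

These are deliberately simple, deterministic stand-ins for heavyweight
preprocessing tools; each one preserves the interface behaviour the
downstream trimming actually consumes.

**Bias correction.**  The field is modelled as exp of a low-order 3-D
polynomial (order `poly_order`, default 3, on coordinates normalized to
[−1,1]).  A direct least-squares fit to brain log-intensities absorbs
genuine large-scale tissue contrast (a GM-dominated cerebrum next to a
WM-rich hindbrain is itself a low-order pattern), so the fit iterates
four rounds of: split `log y − b` into three intensity classes
(multi-Otsu initialized, Lloyd-refined), fit the polynomial to
`log y − c_class`, and trim voxels whose residual exceeds 3 robust
standard deviations (1.4826·MAD) — partial-volume voxels carry tissue
residues several times larger than any plausible bias and must not
steer the fit.  The field is normalized to mean 1 inside the brain and
divided out; output intensities are rescaled to preserve the mean brain
intensity exactly.  On a noiseless phantom with a 20% synthetic field,
the within-tissue coefficient of variation of pure WM voxels falls by
~60%; on bias-free input the estimated field is identically 1.

**Brain extraction.**  Foreground threshold → ball-2 closing → largest
26-component → hole fill.  The threshold is the *lower* cut of a
3-class Otsu split (air | CSF | tissue): a plain 2-class Otsu sits
between CSF and tissue and would strip the dark CSF rim off the mask.

**Tissue classification.**  A 3-component spherical Gaussian mixture on
brain intensities (EM, tol 1e-6, ≤200 iterations, deterministic per
seed; ≤100 000 voxels used for the fit, all voxels labelled).
Initialization is a 3-class multi-Otsu split — quantile initialization
collapses because GM is ~¾ of brain volume.  A variance floor of
(1% of the intensity range)² keeps components from degenerating into
delta spikes on noiseless images.  Two refinements address the classic
partial-volume bias of mixture fits (mixture means get dragged toward
the interfaces): reported class means are the per-class *medians*, and
voxels are relabelled by nearest refined mean.  On the noiseless
phantom this recovers the generating means exactly and labels 100% of
pure voxels correctly.

**Partial-volume estimation.**  Linear two-class mixing between
adjacent class means: for μ_a < y < μ_b (adjacent classes only,
CSF↔GM and GM↔WM), fraction_b = (y−μ_a)/(μ_b−μ_a); y ≤ μ_CSF is pure
CSF, y ≥ μ_WM pure WM.  No CSF↔WM mixing is modelled: the pipeline
consumes only the thresholded CSF fraction map, and at a sheet between
sinus (GM-like) and cerebellar cortex the CSF fraction crosses 0.5
exactly where the linear model puts it.  The maps are a partition of
unity on the brain mask and zero outside.

**Affine registration.**  The template-space stem mask is used only as
a cut-out region whose boundary is then smoothed by opening, so a
9-parameter affine (3 translations, 3 rotations, 3 scales) captures
the mechanism; a nonlinear backend could be slotted behind the same
`align_atlas` contract.  The optimizer is deterministic and
derivative-free: center-of-mass translation + second-moment scale
initialization, then coarse-to-fine (4/2/1 mm) cyclic coordinate
descent on the mean squared intensity difference with greedy line
search per parameter and step halving when a sweep fails to improve;
steps start at 2 mm / 2° / 0.02 (scaled by level) and the level
terminates when all steps fall below 1/64 of their starting size or
the relative cost change drops under 1e-6.  The cost is evaluated on a
strided subsample of at most ~250 000 fixed-grid voxels per level,
which leaves recovery accuracy unchanged (self-registration returns
the identity exactly; centroid transfer errors are millivoxels) at a
fraction of the cost.  Warped masks are resampled nearest-neighbour,
so the output is bit-stable binary.

## The phantom

The generator emulates a skull-stripped head on a 128³, 1 mm isotropic
grid (configurable, ≥48³): a cerebrum ellipsoid (uniform GM), a
cerebellum ellipsoid with a WM core inside a GM shell, a brain-stem
cylinder merging into the cerebrum, a peduncle cylinder bridging stem
and cerebellum (radius 5 voxels), a venous-sinus shell hugging the
posterior-inferior cerebellar surface behind a CSF sheet
(`csf_sheet_thickness`, default 1 voxel, plus a 1-voxel guard margin so
the separation survives supersample majority voting), and a 2-voxel
CSF rim around all structures.  Default tissue means are CSF 40, GM
100, WM 150, sinus 95 (arbitrary units) — the sinus sits within 5% of
GM, reproducing the intensity confound that motivates the CSF-PVE trim.

Anatomy is evaluated analytically on a 3×-per-axis supersampled
lattice; native-voxel tissue fractions are block averages of the
supersampled label indicators (renormalized to a partition of unity on
brain voxels), native labels are the per-block majority, and the ideal
image is the fraction-weighted mix of tissue means — so partial-volume
truth, label truth and image are mutually consistent by construction.
The seed-independent anatomy is cached across seeds; a fixed seed
drives the order-2 polynomial bias field (mean exactly 1, peak
deviation = `bias_amplitude`) and additive i.i.d. Gaussian noise
(`noise_sigma`), making each case bit-reproducible.

Default study conditions used by the tests and the acceptance script:
a noiseless, bias-free reference case (the generator's defaults) and
ten replicates at `noise_sigma = 5` (≈10% of the 50-unit class gap).
The phantom-derived atlas uses a phantom T1 as template and the
ground-truth stem+peduncle dilated by 2 voxels as the stem mask — the
dilation emulates the generous margin of a manually drawn template
mask and is what makes stem removal clip a little true cerebellum
(the recall drop seen in real pipelines).

**What the phantom does not model:** cortical folding and the
convoluted cerebellar foliation (surfaces are smooth, so morphological
opening is nearly lossless — real foliations would lose fine detail),
Rician/k-space noise statistics, nonlinear anatomical variability
between "subjects" (all seeds share one anatomy; only noise and bias
vary, which is why affine registration suffices), and skull/meninges
(inputs are already skull-stripped).  Passing phantom tests therefore
demonstrates the *mechanisms* — sinus detachment via the CSF-PVE trim,
stem removal via atlas masking, the precision/recall trade — not
clinical-grade accuracy on real data.

## Numerical conventions

- Geometry: 0-based voxel indices, NIfTI sform (RAS+) affines, one
  common 1 mm isotropic working grid; combining grids tolerates 1e-4
  relative affine mismatch.  Masks resample nearest-neighbour only.
- Morphology: outside the grid is background for both erosion and
  dilation (so the duality test requires explicit padding); components
  are labelled 1..K by decreasing size, ties broken by smallest
  first raster index; default connectivity 26 (most permissive, avoids
  fragmenting thin midline structure).  Ball structuring elements
  contain every integer offset with Euclidean norm ≤ radius.  The
  scipy.ndimage backends are held bit-identical to brute-force
  definitional implementations by the test suite.
- Kernel sizes: trim ball radius 2 (severs a ≤3-voxel sinus bridge at
  1 mm), opening radius 1; both config-exposed since no standard value
  exists.
- PVE estimation runs on the working 1 mm grid, after bias correction.
- Metric edge cases raise; the t-test is two-sided with no built-in
  significance threshold.
- All randomness (classifier subsampling, phantom noise/bias) flows
  through explicit integer seeds; CLI manifests record them together
  with input content hashes, so reruns are bit-identical.

## Known limitations

- The cerebral mask is an input, not computed: cortical-surface
  extraction is out of scope, and candidate A inherits any error in it.
- Affine registration cannot follow nonlinear inter-subject anatomy;
  on real data the atlas margin (mask dilation) must absorb residual
  misalignment, at the price of recall near the peduncles.
- One erosion pass with a fixed kernel: a sinus attached through a
  bridge wider than ~2·`trim_se_radius`+1 voxels would survive trimming.
- The linear PVE surrogate ignores noise in the fraction estimate; at
  very low SNR the CSF threshold would need recalibration.
- Problem sizes in the default test/acceptance runs (128³ grid, ten
  noise seeds) were chosen as the smallest configuration that exercises
  every mechanism with comfortable margins.
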
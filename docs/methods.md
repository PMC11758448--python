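# Methods

## The problem

After endovascular thrombectomy for ischemic stroke, post-interventional
cerebral hyperdensities (PCHD) on non-contrast CT are ambiguous: retained
iodinated contrast (contrast staining, CS) and extravasated blood
(intracranial hemorrhage, ICH) have nearly identical attenuation at a single
tube voltage. Dual-energy CT resolves the ambiguity by three-material
decomposition into a virtual non-contrast image (VNC; blood remains) and an
iodine overlay map (IOM; iodine only), but dual-energy scanners are not
universally available. This package implements, end to end and at desk
scale, the alternative: an image-to-image network that synthesizes the two
material maps (sVNC, sIOM) from a single-energy image, together with the
simulation, image-quality and diagnostic-accuracy machinery needed to
exercise and verify the approach without clinical data.

## Phantom forward model

The simulator (`sect2mdi.phantom`) adopts the minimal linearized surrogate
of three-material decomposition:

    SECT = blur_sigma( VNC + k · IOM ) + N(0, noise_sd²),   clipped to [0, 256]

with mixing coefficient `k = 1` by default. VNC is a textured elliptical
"brain" (mean 60, correlated texture sd 4 on the normalized [0, 256] scale)
plus the blood contribution of each lesion; IOM is the iodine contribution
on a zero background. With `noise_sd = 0` and `blur_sigma = 0` the identity
is exact voxelwise, and ordinary least squares on lesion voxels recovers `k`
to machine precision — both are tested.

Lesions are random ellipsoids (radii 2.5–6 voxels on the default 64² grid)
placed fully inside the brain. The two classes draw their added intensity
from the *same* range ([40, 90] added units), so mean lesion brightness on
SECT carries essentially no class information — the Monte-Carlo check in
the suite bounds the best SECT-intensity threshold below AUC 0.75. What
distinguishes the classes is morphology, chosen to caricature the clinical
appearance:

* blood (ICH): sharp margins (edge Gaussian sigma 0.5 voxels) and
  correlated internal speckle (25 % relative sd, correlation length 1
  voxel) — clot heterogeneity;
* iodine staining (CS): smooth margins (sigma 2.5 voxels) and a uniform
  interior — contrast pooling in infarcted parenchyma.

Each profile is normalized to unit mean over the lesion support so the two
classes add identical expected intensity; without this normalization the
smoother CS profile would be systematically dimmer and an intensity
threshold alone would separate the classes, voiding the premise.

A case is ICH-positive if any lesion carries blood; the diagnostic unit is
the case, not the voxel. The automated dual-energy reading rule
(`classify_by_decomposition`) calls ICH when the mean VNC elevation over the
estimated background within any lesion exceeds a threshold (default 20
units, half the minimum blood intensity); the continuous maximum-elevation
score feeds ROC analysis.

What the phantom does **not** model: skull/bone, beam-hardening and
reconstruction artifacts, polyenergetic physics, anatomical variability,
partial-volume effects at clinical resolution. Passing the end-to-end test
therefore demonstrates that the method can learn a morphology-conditional
decomposition under controlled conditions; it says nothing about clinical
performance.

## Preprocessing

`sect2mdi.preprocess` mirrors a standard recipe: resampling to a target
spacing (trilinear for images, nearest-neighbor for masks; voxel-center
alignment so the output spacing is exactly the target), per-volume min-max
normalization to [0, 256], center crop / symmetric zero-padding to a fixed
grid, synchronized random crops, and training-time augmentation by
horizontal flips and axial rotations in multiples of 90° (right angles
avoid interpolation and keep the forward-model identity exact). Every
geometric operation is applied with one shared geometry to SECT, VNC, IOM
and the lesion mask. Resampling happens before normalization.

## Network

The generator (`sect2mdi.model`) is a U-shaped windowed-transformer:

* patch embedding (non-overlapping p-patches, linear to C channels;
  desk defaults p = 2, C = 16 on 64² inputs; the clinical-scale setting
  96³/p = 4/C = 48 is the same code at rank 3);
* three encoder stages of attention pairs — two pre-norm window-attention
  blocks, the second with windows cyclically shifted by half a window —
  each followed by patch merging (resolution ÷2, channels ×2);
* a bottleneck attention pair plus one patch expansion;
* two structurally identical decoders with independent parameters, one per
  material map. Each has three stages of (skip fusion with the matching
  encoder grid by concatenation + linear reduction, an attention pair,
  and an expansion); the first two stages expand ×2, the third performs
  the final ×p expansion before a linear head to one channel, so the
  generator is shape-preserving end to end.

Shifted windows treat the volume as periodic (cyclic roll without an
attention mask) — a deliberate simplification at desk scale where window
counts are small. Attention uses no positional encoding beyond the window
structure itself. Feed-forward expansion ratio is 4 with GELU (tanh
approximation). Intensities are divided by the normalization span (256) at
the network entry and multiplied back at the head, keeping features and
gradients O(1) while the external interface and all reported losses stay in
intensity units.

The two discriminators (one per map) are four strided 4×4 convolutions
(LeakyReLU 0.2, channels 16→128) and a fully connected layer producing one
realness logit; they score a map alone (unconditional).

Everything runs on a small numpy reverse-mode autodiff engine
(`sect2mdi.nn`) written for this package: float32 by default (float64 for
the finite-difference gradient checks in the suite), explicit seeded
initialization, Adam, and a deliberately small operation set.

## Training

Per iteration (`sect2mdi.training.train`): both discriminators update on
(real target, detached fake) with the non-saturating GAN loss
`-log σ(D(real)) - log(1 - σ(D(fake)))` (a least-squares variant is
config-selectable); then the generator updates on

    L_gen = w_VNC · (L1 + L_adv1) + w_IOM · (L1 + L_adv2)

with per-task gradients computed separately and combined explicitly.
GradNorm adapts (w_VNC, w_IOM) every iteration: gradient norms of the
weighted task losses, measured at the last encoder attention projection
(the deepest shared layer), are pulled toward the mean norm scaled by each
task's relative inverse training rate (asymmetry α = 1.5); the weight
update is one Adam step (lr 0.025) followed by renormalization to
w_VNC + w_IOM = 2. This matters because the IOM target is mostly zero, so
its raw L1 scale is several times smaller than the VNC one.

Two stabilizations of the weight adaptation matter in practice and are
defaults here. First, the reference losses L(0) anchor to the mean over a
200-iteration warmup (weights stay (1, 1) meanwhile): the first iterations
are dominated by fitting the trivial output bias, and anchoring there makes
that transient look like runaway progress, collapsing the affected task's
weight. Second, the weights are clamped to the band [0.25, 1.75]
(sum-preserving): per-task gradient norms at any single shared layer scale
with the magnitudes of the weights downstream of it and can differ by
orders of magnitude between a task whose output is mostly zero and one
regressing a full image; literal norm-balancing would then silence a task
outright. Within the band the adaptation is the cited rule, unchanged.
The gradient norms are measured at the patch-embedding projection — the
one layer every computation path, skip connections included, traverses;
at deeper encoder layers a skip-reliant task can leave near-zero gradient
and the comparison becomes meaningless.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999) at initial lr 1e-3 for all
parameter groups, decayed by a reduce-on-plateau rule (factor 0.5, patience
5) fed with mean training loss over consecutive 50-iteration windows.
Batch size 4. Training is single-threaded-deterministic given the seed.

A property worth knowing when interpreting results: with an L1 objective
the per-voxel optimum is the conditional median, so until the network
exploits lesion morphology, the rational prediction is to suppress lesions
on sVNC (blood prevalence ≈ 0.3 < 0.5) and to copy every hyperdensity to
sIOM (iodine prevalence ≈ 0.7). Class-conditional routing emerges on top of
that baseline and is the slowest part of training.

## Image quality and statistics

PSNR uses a fixed data range R = 256 (the normalization span), not
per-image ranges, so values are comparable across cases; identical inputs
report +inf. SSIM follows the standard windowed formulation: 11-tap
Gaussian window (sigma 1.5, truncated at 3.5 sigma), population moments,
K1 = 0.01, K2 = 0.03, border positions excluded; rank-3 volumes are scored
slice-wise and averaged. The implementation is cross-checked against
scikit-image to 1e-6 in the suite.

`sect2mdi.readereval` implements the reader-study statistics: exact
Clopper–Pearson 95% CIs for all proportions (the exact method is validated
by reproducing the published lower bound 0.79 for a 16/16 sensitivity);
the single-operating-point ROC area (sens + spec)/2 with a DeLong
placement-value variance for its CI; the paired DeLong test (verified
against the pROC implementation and a permutation oracle); unweighted
Cohen's kappa with the large-sample SE (statsmodels underneath) and a Wald
CI truncated to [-1, 1]; and `reconstruct_table`, an exhaustive enumeration
of all 2×2 tables consistent with rounded published metrics (half-up, two
decimals). Applied to the bundled published rows, the reconstruction is
unique for all four rows and reproduces the printed accuracies; the
published AUCs equal the rounded (sens + spec)/2 of the *printed* (already
rounded) sensitivities and specificities, with ties rounded to even —
the reconstructed internal-output table itself gives (1 + 24/31)/2 = 0.887.
The enumeration also shows the external rows imply 19 positives of 26,
which does not match the externally stated count of 6 — the discrepancy is
surfaced, not resolved.

## Desk-scale study conditions

The acceptance study trains the 2D configuration (64² phantoms, p = 2,
C = 16) on 200 simulated cases with batch 4 and evaluates on 40 held-out
cases: (i) mean PSNR(sVNC, VNC) must exceed the copy-input baseline
PSNR(SECT, VNC) by ≥ 3 dB, and (ii) the automated reading of the generated
maps must reach AUC ≥ 0.80 while the best SECT-intensity threshold stays
below 0.75. Training length at desk scale is 800 iterations, set by
convergence of the image-fidelity metrics within a single-CPU budget (200
batch-4 iterations, the clinical protocol's count, cannot traverse even
the desk cohort meaningfully).

At this scale the fidelity half of the study passes with a wide margin
(the iodine map converges to near-exact lesion copying; the sVNC gain over
the copy-input baseline is several dB) while the diagnostic half does not:
the trained generator assigns hyperdensities to the two maps
unconditionally rather than by class, so the decomposition reading stays
at chance. The mechanism is worth stating because it is a property of the
objective, not a bug: with in-lesion intensities matched across classes by
construction, the per-voxel L1 optimum is the conditional median, and
until the network has discovered a morphology gate, the unconditional
assignment (every blob to the map favored by the class prior) is locally
optimal. The adversarial term does not break the tie — an unconditional
discriminator cannot penalize a VNC that never shows blood, because most
real VNC images legitimately show none. Escaping this saddle is a
feature-discovery problem that did not resolve within the desk-scale
compute envelope under any of the initializations and cue designs tried;
the corresponding suite assertion is left failing rather than weakened,
and the acceptance script reports the honestly computed AUC.

## Numerical choices and degenerate inputs

* Constant volumes make min-max normalization degenerate — an error, not a
  silent pass-through.
* A window larger than its grid is clamped with a warning.
* Zero initial task losses in GradNorm are guarded with an epsilon; weights
  are floored at 1e-3 before renormalization.
* Degenerate DeLong variance (identical rating sets) reports p = 1.0 by
  convention; kappa with expected agreement 1 is reported as NaN.
* Zero denominators in diagnostic metrics report the metric as undefined
  (None), never as 0.
* NaN training loss aborts with the iteration number and loss breakdown.

## Known limitations

* The phantom's morphology cue (texture/edge sharpness) is a surrogate; the
  HU ranges of PCHD lesions are not calibrated to Hounsfield units.
* Wrapped-window attention and the absence of positional encodings are
  desk-scale simplifications.
* The numpy engine is single-process; clinical-scale 3D training is out of
  reach computationally, although the code path (rank 3) is exercised in
  the suite.
* The GAN component at desk scale mainly regularizes sharpness; no claim is
  made that the adversarial term is necessary for the phantom task.
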
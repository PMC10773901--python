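# Methods

`craniosynth` studies whether a CNN classifier for craniosynostosis can be
trained purely on synthetic images. Because clinical photogrammetric scans
of infant heads cannot be redistributed, the package includes a synthetic
head generator that emulates such a cohort; everything downstream — dense
correspondence, the three generative models, the 2-D encoding, the
similarity metric and the leakage-safe benchmark — operates on those
stand-in data exactly as it would on clinical meshes.

## Stand-in cohort (headgen)

Each head is a level-3 icosphere (642 vertices, watertight, identical
topology across subjects) whose radial field is a jittered ellipsoid
(anteroposterior/lateral/vertical semi-axes 95/75/80 mm, per-subject
semi-axis jitter ±4%, global scale ±5%) modulated by class-specific
multiplicative raised-cosine bumps in azimuth/elevation:

* **sagittal** (scaphocephaly): anterior+posterior elongation (amplitude
  0.10–0.18) and lateral narrowing (0.08–0.14) → low cephalic index;
* **metopic** (trigonocephaly): a narrow frontal keel (0.05–0.09) flanked by
  para-median flattening (0.07–0.13) → pointed forehead;
* **coronal**: anterior flattening (0.10–0.16), unilateral on a random side
  (80%) or bilateral with lateral widening (20%);
* **control**: no deformity, or mild posterior-oblique flattening
  (positional plagiocephaly, amplitude 0.03–0.07) with probability 0.3,
  reflecting that a clinical control group contains such patients.

Amplitudes are uniform draws from the ranges above; every range was fixed
once so that three scalar indices (cephalic index, frontal-angle index,
anterior-asymmetry index) linearly separate the classes with > 90% accuracy
— a property the downstream benchmark relies on. The default cohort has the
clinical class ratios: 278 control / 25 coronal / 69 metopic / 124 sagittal
(56/5/14/25%, 496 subjects). Ten cephalometric landmarks (nasion, glabella,
subnasale, gnathion; bilateral tragion, exocanthion, euryon) are placed at
fixed parametric sphere angles and evaluated through the same radial field.
The landmark identities are a package convention: the clinical annotation
protocol's exact set is not machine-readable, and only the head-frame
construction (tragion pair + nasion) depends on which points exist.

What the generator does **not** emulate: scanning noise and artifacts, hair
and texture, facial detail below the tragion plane, age-dependent size
distributions, and within-class correlations beyond the smooth deformation
model. Consequently the fixture is *cleanly separable*: benchmark scores on
it are upper-bound analogs, they show the pipeline's machinery is correct
and well-ordered (shape-model sources beat a GAN-alone source, combinations
beat singles), not that the same accuracy would be reached on clinical data.

## Dense correspondence (registration)

A template (the mean of 20 separately generated control heads, standing in
for an externally published mean shape) is aligned to each target by
closed-form landmark Procrustes (rotation, translation, isotropic scale;
Umeyama). Non-rigid morphing then proceeds in two stages of
Laplacian-regularized projection: per outer iteration, nearest-neighbour
correspondences are gated by distance (10 mm) and normal angle (60°), and
the displacement field d solves

    min_d  Σ_sel ||v0 + d − c||² + β ||L d||²

with L the template's cotangent Laplace–Beltrami operator (uniform-weight
fallback for degenerate triangles). Stage 1 uses β = 100 (global shape),
stage 2 β = 1 (tight fit); 10 iterations per stage. Correspondence search
uses nearest *vertices* (KD-tree): template and targets share sampling
density, so vertex matches sit within a fraction of an edge length of the
true foot point, and this keeps a ~500-mesh cohort within minutes; exact
point-to-triangle projection is retained for the reported residuals (the
sphere→ellipsoid fit reaches ≈ 0.13 mm mean residual, and full registration
≈ 0.02 mm, at subdivision 3). Generalized Procrustes analysis then removes
rotation and translation only — size is deliberately kept so scale variation
enters the shape statistics.

## Statistical shape models and image PCA (ssm, imgpca)

Per class, the aligned shapes enter an area-weighted PCA: vertex i carries
one third of its incident triangle area (barycentric lumping; weights sum to
the surface area), which counterbalances denser sampling. Components are
orthonormal under the weighted inner product; the retained rank is the
smallest q whose cumulative normalized eigenvalue sum reaches 95% (the
threshold is inclusive; "normalized" = eigenvalue / trace). New shapes are
drawn as s = s̄ + V Λ^{1/2} α with α ~ N(0, I_q), untruncated (an optional
±kσ clamp exists but is off). Weights are evaluated on each class's mean
shape — the method description leaves the weight geometry open, and the
mean is the only geometry every sample shares.

Image PCA reuses the identical numerical core with uniform weights on
vectorized 28×28 maps, per class, same 95% cutoff, and clips synthesized
images back to [0, 1] (clip rate recorded on the model; out-of-range mass is
a known PCA artifact on bounded intensities).

Numerical notes: the weighted PCA is computed by thin SVD of the
weight-scaled centered data; eigenvalues below 1e-10 of the leading one, or
below 1e-12 of the data's mean squared magnitude, are treated as zero (the
absolute floor catches the identical-input case where centering leaves only
rounding residue).

## Distance maps (distmap)

The head frame places the origin at the tragion midpoint; the left axis
points right→left tragion, the anterior axis is the nasion direction
orthogonalized against it, superior = anterior × left. Pixels sample
elevation 90°→0° (vertex to tragion plane, top row high) and a full
360° azimuth sweep with the anterior midline at the center column; each
pixel is the ray-cast distance from the origin to the surface divided by a
fixed d_max = 200 mm, clipped to [0, 1]. Absolute (not per-image)
normalization is essential: it makes "add a constant intensity" equivalent
to re-scaling the head, and a horizontal flip about the center column
equivalent to anatomical mirroring — the two facts the classifier's
augmentations encode. Ray casting is exact Möller–Trumbore over candidate
triangles preselected by a KD-tree on triangle centroid directions, with a
full-scan fallback for any ray that misses its candidates (the result is
bitwise identical to the full scan). The grid conventions (azimuth origin,
elevation range, d_max) are recorded in each map's metadata because the
original encoding's exact parameterization is not published; the contract is
the invariants above, not specific pixel values.

## Conditional WGAN-GP (gan)

One conditional model covers all four classes. The generator maps a latent
vector (default dimension 32) concatenated with a 16-d label embedding to a
7×7 feature map, then upsamples by nearest-neighbour interpolation + 3×3
convolution (7→14), a 4×4 stride-2 transposed convolution (14→28), and a
final 3×3 convolution with tanh output — mixing interpolation and transposed
kernels avoids checkerboard artifacts at this resolution. The critic embeds
the label as an extra 28×28 input channel followed by three 4×4 stride-2
convolutions (leaky ReLU, no normalization layers — incompatible with a
per-sample gradient penalty) and a dense score. The loss is the Wasserstein
critic objective with gradient penalty λ = 1 at per-sample uniform
interpolates; Adam with momentum pair (0.0, 0.9) for both networks.

Internally, images are standardized by the training set's mean and 4× its
standard deviation so real structure fills the bounded output range; the
affine map is stored on the model and inverted at sampling time. Without it
the class-relevant structure occupies ~3% of the tanh range and the
generator's residual noise dominates. Minibatches are drawn class-balanced
by default so the 5% minority class receives equal gradient signal.

The reference training profile is 1000 epochs, learning rate 3e-5, 10 critic
iterations per generator update (the `GANConfig` defaults keep that rate and
critic ratio). Desk-scale runs — everything the test suite and the
acceptance script execute — use a compensating schedule (learning rate 7e-4,
5 critic iterations, enough epochs for ≈ 2400 critic / 480 generator steps),
which reaches the qualitative state the long profile reaches: median SSIM_cc
above 0.95 per class and correct conditioning (same-class similarity exceeds
cross-class for every class). Both networks and the penalty run on the
package's own reverse-mode autodiff engine (`craniosynth.nn`), a deliberate
dependency-free design: the engine's vector-Jacobian products are themselves
differentiable primitives, so the penalty's double backprop needs no special
casing, and its convolution gradients are verified against finite
differences in the test suite.

## Similarity metric (simmetric)

SSIM uses a 7-pixel window (Gaussian weights, σ = 1.5; an 11-pixel window is
borderline on 28×28 images), k1 = 0.01, k2 = 0.03, data range 1.0, averaged
over windows fully inside the image; it matches the reference implementation
exactly for the uniform window and to < 1e-3 for the Gaussian window (kernel
truncation detail). SSIM_cc scores a synthetic image by its maximum SSIM
over all clinical images of the same class — 1 when the image reproduces a
clinical sample, near 0 when it resembles none. The report tabulates median,
quartiles, 1.5-IQR whiskers and outlier counts per (source, class).

## Classification benchmark (classify)

Subjects are split 75/25 into model/evaluation data by stratified fourfold
cross-validation (per-fold class ratios within one sample of the cohort's).
Per fold, all three generators are fitted **only** on model data — a hard
leakage guard raises if any evaluation subject id reaches generator fitting
or CNN training. Each source combination (7 synthetic + 1 clinical) trains
one CNN on its images, uses the model-data images as the validation set for
max-F1 checkpoint selection, and is evaluated once on the evaluation-data
images. The clinical row trains directly on the model-data images and reuses
them for validation — mirroring the reference protocol's known overfitting
caveat, which is reported, not hidden.

F1 is the unweighted (macro) mean over classes observed in truth or
prediction — on the 4-class problem this is the plain macro mean; the choice
reflects that accuracy is unreliable under the 56/5/14/25 imbalance.
"Weight decay 0.63 after each five epochs" is read as a multiplicative
learning-rate decay (γ = 0.63 every 5 epochs): per-5-epoch application is a
scheduler notion, not an optimizer coefficient. Augmentations (training
only): per-pixel Gaussian noise σ = 1/255, one global intensity offset
σ = 5/255, horizontal mirror flip with probability 0.5, and a *circular*
horizontal shift with σ = 12.44 px at 224-px width (≡ a 20° head turn;
rescaled proportionally to the actual input width, e.g. σ ≈ 1.56 px at 28).
The shift wraps because the azimuth axis is periodic.

The classifier is a compact from-scratch CNN (two stride-2 convolutions +
two dense layers, 16 base channels) operating at the native 28×28 size, with
inputs standardized by training-set statistics. The reference protocol
fine-tunes a pretrained 18-layer residual network at 224×224 with learning
rate 1e-4; a from-scratch compact net stalls at that rate under the fast
decay, so the default initial rate is 1e-3 with the decay cadence kept (the
protocol's rate remains available via `TrainConfig`). Batch size 32 and the
50-epoch budget for synthetic sources are kept.

## Scaled-down study conditions

Reference scale is 1000 synthetic images per class per source (4,000 /
8,000 / 12,000 training images for 1/2/3 sources; 372 model-data images per
fold) over four folds. The test suite and the acceptance script both run the
full 496-head cohort but a single fold, with reduced per-source sample
counts (100 and 125 images per class respectively) and shorter CNN training
(30 and 25 epochs), and sample all generators at the reference 1000 per
class for the dataset-size bookkeeping. Both use the desk-scale GAN schedule
above. The minority (coronal) class drives the cohort-size floor: with
fewer than its full 25 subjects, a fold's model data carries too few
coronal examples for any classifier to learn the class. These sizes are the
package's standing desk-scale conditions; the full-scale settings are plain
configuration away (`BenchmarkConfig`, `GANConfig`, `TrainConfig`).

## Known limitations

* The stand-in cohort is cleanly separable; absolute benchmark numbers are
  analogs, not clinical estimates (ordering and bookkeeping are the tested
  claims).
* The distance-map grid conventions are declared stand-ins for an encoding
  whose full parameterization is not published.
* The GAN's exact reference layer table is unavailable; the architecture
  here satisfies the stated constraints (conditional, deep-convolutional,
  mixed upsampling, 28×28) but is not a weight-level reproduction.
* The landmark set is a naming convention; replace `LANDMARK_ANGLES` to
  match a real annotation protocol.
* The benchmark's clinical row shares its training and validation data by
  design (as in the reference protocol); treat its selection F1 accordingly.
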
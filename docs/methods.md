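# Methods

This note records the models, conventions and design choices behind
`sycbct`, in the spirit of a model-documentation page: what each stage
assumes, which parameters matter, and what the synthetic tests do and
do not demonstrate.

## Coordinate and data conventions

Volumes are 3D scalar grids indexed `(x, y, z)` = (sagittal, coronal,
axial); an axial slice is a fixed-`z` plane. Indices are 0-based;
physical coordinates in mm are index × per-axis spacing; meshes are
always in mm. Crop ranges are accepted in 1-based inclusive "slice
numbering" form (e.g. `21–490`) and converted internally to 0-based
half-open intervals. The canonical on-disk format is NIfTI-1 (spacing
in the header); 8-bit BMP axial stacks are supported for slice-based
tooling, with a JSON sidecar recording the linear intensity scale so a
round trip is exact to half a quantisation step, `(max−min)/255/2`.

## Head phantom

Real paired dental CBCT/MRI cannot be redistributed, so the pipeline is
exercised on phantoms: a mildly anisotropic soft-tissue ellipsoid
("head", default 85 % of the half-width) in air, containing a jaw-arc
tube and tooth-like ellipsoids of hard tissue. Default grid is a
512-cube at 0.3 mm isotropic spacing — the clinical CBCT geometry —
but every stage accepts arbitrary grids and the tests run at 24–48
cubes; stated sizes below are the package's own scaled-down choices.

Intensity model. CBCT voxels take per-class means (defaults air 0,
soft 400, hard 1400, "HU-like" a.u.) plus optional corruption. MRI
voxels take per-class means with *inverted* soft/hard contrast
(air 40, soft 800, hard 300) emulating bone-visible short-TE contrast,
then a mild Gaussian blur (σ 0.7 voxel) for the softer bone margins of
MR. The class→intensity maps are injective, so the noiseless MRI→CBCT
relation is deterministic and invertible per class — this is what makes
scaled-down training convergence a meaningful test rather than a
curve-fitting exercise.

Corruption. Noise is additive Gaussian (defaults σ 20 MRI, σ 40 CBCT in
the units above; Rician MRI noise is a known simplification). The CBCT
streak artifact is a small number (default 4) of random straight
bright/dark lines through every axial slice, constant along z —
a visual stand-in for cone-beam scatter streaks, with no physics
simulated. Optional rigid misalignment resamples the MRI through a
configured transform so registration can be tested against a known
answer. A single seed drives one generator; identical configs are
bit-identical.

What the phantom does *not* emulate: anatomical shape variation,
intensity inhomogeneity/bias fields, partial-volume mixtures beyond
trilinear interpolation, spatially varying MRI sensitivity (the
submental signal falloff of head-coil MR), or realistic scatter. Tests
passing on phantoms therefore demonstrate correctness of the machinery
and learnability of a known mapping — not clinical image quality.

## Preprocessing

Registration maximises histogram mutual information (64-bin default;
32 at small scales) over the 6 rigid parameters: a deterministic coarse
grid over translations seeds a Powell refinement. On noiseless
piecewise-constant images the MI surface is exactly flat in a small
plateau around the optimum (resampled intensities remain a
deterministic function of the reference), so the refinement result is
accepted only when it strictly improves on the seed; this pins the
estimate to the plateau's seed rather than an arbitrary point on it.
Recovery of injected transforms is tested to within 0.5 voxel.

The fixed stage order is resample → mask → crop → normalise. Masking
precedes cropping because the circular mask disk is defined on the
full-field axial geometry, centred at `((W−1)/2, (H−1)/2)`; an
off-centre crop re-centres the disk, so the two orders genuinely
differ (asserted as a non-property in the tests). Normalisation is
per-volume min–max onto [−1, 1] — not per-patch, so overlapping patches
agree — with an exactly invertible scale/offset record; a per-patch
variant would make fusion scale-inconsistent. Constant volumes map to
the interval midpoint and are flagged.

## Patching and fusion

Training patches (presets 128×128×16 and 64×64×16) are drawn with
replacement, origins uniform over valid positions, MRI and CBCT cut at
identical origins; no class balancing. Inference tiles with stride =
half the patch size, adding a final flush-to-boundary origin when the
extent is not a multiple of the stride (no padding — fabricating
voxels outside the field of view was rejected). Fused output is
`Σ w·pred / Σ w` with a separable Gaussian window, σ = patch size / 8
per axis (`sigma_frac` configurable): a partition-of-unity overlap-add
that preserves constants to rounding and removes patch-border seams.
The σ choice follows common sliding-window practice — strong
down-weighting of borders (~e⁻⁸ at the edge) with a usable centre.

## Network

The synthesis model is an encoder–decoder over 1-channel 3D patches.
The encoder is a stack of ResNet-bottleneck stages (1×1×1 reduce,
3×3×3, 1×1×1 expand, expansion 4, residual addition), repeats
(3, 4, 6, 3), preceded by a 7×7×7 stride-2 stem. In-plane striding is
stronger than depth striding — stage strides (1,1,1), (2,2,2), (2,2,1),
(2,2,1) — so 16-voxel-deep patches remain divisible (total
downsampling 16×16×4). The decoder mirrors the encoder with trilinear
upsampling plus two Conv-BN-ReLU blocks per stage (a transposed-conv
variant was considered and rejected for checkerboard risk and extra
parameters), then a 1×1×1 regression head.

The *highest-resolution* skip connection is deliberately absent: with
imperfectly registered training pairs, a full-resolution shortcut lets
voxel-level misalignment dominate the loss; lower-resolution skips
(stages 1–3) are kept. `NetworkSpec.with_last_skip()` restores it for
ablations.

Kernel counts are reduced so the full 3D network totals 9,847,313
trainable parameters (~10 M): stem 32, bottleneck mid-widths
(16, 32, 64, 128), decoder widths (208, 96, 48, 24). The comparison
baseline — the canonical 2D U-Net (two 3×3 convolutions per level,
channels 64…1024, transposed-conv upsampling, final 1×1 conv) — counts
31,030,658 (~31 M). `count_parameters` is a pure function of the
declarative `NetworkSpec` (kernels + biases + BN affine terms), and the
materialised model asserts agreement.

The network is implemented directly in NumPy with explicit
forward/backward passes (convolution as a loop of BLAS contractions
over kernel offsets; batch-norm with running statistics; trilinear
upsampling as per-axis interpolation matrices whose backward is the
exact transpose). Gradients are verified against central finite
differences in the tests. Weight init is Kaiming fan-in with a fixed
seed.

## Training

Adam, initial lr 2.5e-4 decayed ×0.8 every 200 iterations (closed form
`lr0·0.8^⌊it/200⌋`), weight decay 1e-5 applied to convolution kernels
only, smooth-L1 loss (β = 1 in normalised units; quadratic below β,
linear above — robust to artifact outliers). Batch sizes: 32 for small
patches, 8 for large. Early stopping: validation is evaluated every
200 iterations (the same cadence as the decay; the "stopping factor 5"
is read as patience = 5 evaluations without improvement, both choices
declared, not inferred), and the best-validation weights are restored.
Validation holds out 1/16 of the patches by default. NaN loss aborts
with a diagnostic. Training is deterministic for fixed seeds.

Scaled-down runs (tests, `run_pipeline`) shrink the kernel counts by a
divisor (`NetworkSpec.scaled`) and use 32-cube phantoms with 16×16×8
patches and batch size 8. Under the unchanged schedule above, a
divisor-4 network trained for 800 iterations on a noiseless phantom
reaches held-out MAE below 25 % of the copy-input baseline (the error
of reading the normalised MRI as if it were the CBCT), which is the
package's learnability acceptance test.

## Evaluation

MAE, PSNR and SSIM are computed per tissue class (hard/soft/air) and
globally. Class delineation is by two thresholds on the reference CBCT
(there is no standard delineation for CBCT tissue classes, so the
thresholds are explicit configuration; phantom
ground-truth labels are the test path and give identical masks at the
class-mean midpoints). PSNR uses `f_max` = reference dynamic range
over the mask by default and log₁₀ (dB); identical inputs report the
sentinel `"identical"` rather than a number. SSIM defaults to a single
global evaluation of the means/variances/covariance form with
`c1 = (0.01 L)², c2 = (0.03 L)²`; a `gaussian_11` local-window mode
(11-point window, σ 1.5) is available. Metrics are computed on
native-depth volumes, not 8-bit exports; `per_slice_mean` provides the
per-axial-slice reading of any voxel metric where a slice-series
average is wanted instead of the per-volume value.

Surface deviation: marching-cubes isosurfaces of reference and
synthetic volumes, rigid ICP superimposition (nearest-vertex
correspondences, closed-form SVD updates, centroid pre-alignment;
residuals are non-increasing by construction), then RMS point-to-surface
distance of the evaluated mesh's vertices to the reference surface.
Point-to-triangle distances are exact (barycentric clamping) over a
KD-tree candidate set of nearest-centroid triangles (k = 16), which is
exact for meshes tessellated finely relative to their feature size —
the marching-cubes regime. Regional RMS accepts explicit vertex
partitions; the phantom supplies axial/coronal half-space partitions
(maxilla/mandible, anterior/posterior) standing in for landmark-defined
clinical planes.

## Numerical and degenerate-case choices

- Even-sized mask disks and Gaussian windows are centred at
  `(n−1)/2`; windows peak at 1 in the continuous profile (the two
  central samples tie for even sizes).
- Fusion raises on uncovered voxels rather than emitting zeros.
- `psnr` with an empty mask, `ssim` with unordered thresholds,
  indivisible patch extents (the offending axis is named), degenerate
  STL faces, and constant volumes in MI all raise `ValueError`.
- Constancy preservation under fusion and normalisation inversion hold
  to a few ulps, and tests assert them at that tolerance rather than
  bitwise.

## Known limitations

- No GPU path: the NumPy implementation trains desk-scale networks in
  minutes but is not suited to full 512-cube clinical training.
- The phantom's realism limits (listed above) mean tissue-stratified
  metric *values* on phantoms are not comparable to clinical reports;
  only orderings and convergence behaviour are meaningful.
- ICP is point-to-point with nearest-vertex correspondences; symmetric
  or point-to-plane variants would converge faster on near-planar
  regions.
- Deformable registration, bias-field correction, DICOM I/O and
  expert-reader evaluation are out of scope.
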
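# Methods

## Spin model

Each ¹³CHD₂ methyl probe is treated as an isolated ¹H–¹³C pair. After a
single ¹H excitation pulse, the detected coherences evolve within the
eight-dimensional product-operator space
(Hx, Hy, 2HxCx, 2HyCx, 2HxCy, 2HyCy, 2HxCz, 2HyCz). The state vector obeys
dM/dt = −L·M where L is the sum of a diagonal decay part — R₂,H on the ¹H
single-quantum terms, R₂,MQ on the four multiple-quantum terms, R₂,APH on
the two antiphase terms — and an antisymmetric coherent part with entries
2πΩ_H (¹H offset from the carrier), 2πΩ_C (¹³C offset from the *decoupler
position*, which defines the ¹³C rotating frame), 2πB₁ (CW field along x on
¹³C) and π·¹J_HC. Two modelling consequences worth stating:

- The single-quantum ¹³C rate never appears: the detected ¹H signal carries
  no information about it, which is why the target maps use a fixed ¹³C
  linewidth (see below).
- Cross-correlated relaxation is not modelled; the three rates are
  independent inputs.

Sign conventions are anchored to physics rather than to any particular
typesetting of the matrix: every eigenvalue of L has non-negative real part
(signals decay; enforced by a property test over random parameter draws),
and the detected quadrature signal precesses at +Ω_H so a standard complex
FFT places the peak at the ¹H shift on an ascending ppm axis. A literal
real-valued detection functional (Hx − Hy) is available as
`detection="literal_D"` for auditing.

### Propagation

The FID is s(t) = d·exp(−Lt)·v₀ with v₀ = (I₀, 0, …, 0). Rather than
integrating an ODE, one eigendecomposition per (spin, offset, B₁) gives the
closed form Σ_k c_k exp(−λ_k t), exact for the time-independent generator
and equivalent to repeatedly applying the one-dwell propagator. For batch
work the 8×8 real problem is reduced to a 4×4 complex one: the coherences
pair into (H⁺, 2H⁺Cx, 2H⁺Cy, 2H⁺Cz) with H⁺ = Hx + iHy, and in that basis
the ¹H offset enters only as a uniform diagonal phase iΩ_H — so the
eigenvectors are independent of the ¹H shift and the per-spin cost drops
roughly eightfold. The two routes are cross-checked against each other in
the tests (agreement at 1e−9).

### Acquisition and processing

Times run 0…t_max in steps of the dwell 1/(sweep width), giving
floor(t_max·sw)+1 complex points (225 at 64 ms, 5 ppm, 700 MHz). Processing
is zero-order phase, cosine-square apodization over the acquired length
(with the conventional 0.5 scaling of the first point), zero-fill, complex
FFT. The difference stack subtracts the reference FID — decoupler off by
default, or far off-resonance (−50 ppm) as in the experimental protocol —
from every offset's FID before processing; by linearity this equals
subtracting processed spectra, and the equivalence is pinned by a test.

### Oracles

Two closed forms validate the simulator end to end: the effective-splitting
formula J·|Δ|/√(Δ²+B₁²) (valid for B₁ ≳ J/2; its own error against the
exact dynamics is ~1% of J at Δ ≈ 2B₁, which sets the meaningful comparison
resolution), and the limiting lineshapes — far-off doublet components of
width R₂,H/π, on-resonance singlet decaying at
R₂,H − (R₂,H−R₂,MQ)/(1+(2B₁/J)²). The linewidth check uses a 1 s
acquisition: at 64 ms the truncation sinc (~14 Hz) would dominate the
7.96 Hz natural width, so the closed form is compared in its own validity
regime.

## Synthetic training data

A training example draws global parameters — B₀ (±1% around 700 MHz), the
B₁ pair (±3% around 220/110 Hz), ¹H sweep (4.75–5.25 ppm), offset span
(29–31 ppm over the methyl region), FID phase (±30°) — then
N_peaks ~ Uniform{1..cap} spin systems with ϖ_H ∈ [−0.7, 1.6] ppm,
ϖ_C ∈ [−1, 27] ppm, J ∈ [120, 130] Hz, R₂,H ∈ [5, 120] s⁻¹,
R₂,MQ ∈ [2, 120] s⁻¹, R₂,APH ∈ [5, 150] s⁻¹, I₀ ∈ [0.05, 1]. These ranges
span small proteins through ~MDa-equivalent tumbling; they are config, not
code, and every artifact records its generator config hash. Draws falling
outside the realized axes are resampled, not clipped, to avoid edge
pile-up.

The input stack is scaled to a global maximum of 1, Gaussian noise with a
drawn SD (0–5% of the maximum) is added, and the stack is rescaled to 1.
The target map is noise-free: one 2D Gaussian per spin at (ϖ_H, ϖ_C), peak
amplitude I₀ (amplitude, not volume — the simplest reading, and volumes are
recoverable from the fixed width rule), ¹H FWHM max(R₂,H/π, 20 Hz), ¹³C
FWHM fixed at 30 Hz. Gaussians are evaluated at pixel centres with
σ = FWHM/(2√(2 ln 2)); training and evaluation use the same rule, and the
pixelization error this leaves in discrete peak volumes (a few percent for
the ~0.5-pixel-σ ¹³C width) is acknowledged in the tests.

Normalizing the input while leaving the target in I₀ units makes the
absolute scale formally unrecoverable from a single input; the network
learns the typical scale, and quantitative mixture analysis therefore
always undoes the recorded normalization scale (see `coadd`).

### Reduced (desk-scale) preset

The full grid is 512×200 (512 ¹H points over ~5 ppm, 200 offsets over
~30 ppm). The reduced preset used for tests is 256×100 with target
linewidths scaled to preserve the full grid's pixels-per-linewidth: ¹H
floor 40 Hz (2.9 px, as 20 Hz is on the full grid) and ¹³C 60 Hz (1.1 px,
as 30 Hz is). Without this, sub-pixel targets make the MSE regression hedge
amplitudes badly at desk scale.

## Network

Seven hidden convolutional layers with skip connections, arranged as a
small U-Net: two encoder stages (2×2 average pooling after each), two
middle layers at quarter resolution, and a decoder with nearest-neighbour
upsampling plus additive skips from the matching-width encoder activations;
a linear 1-channel output head. Dropout (30%) follows every hidden layer
except the last. The reduced preset (widths 16/24/80, kernels
3/5/7/7/5/3/3/3) has ~2.1×10⁵ weights; the full preset (64/128/256,
9/9/7/7/7/9/9/3) ~5.0×10⁶. The weight count is the contract; the exact
topology is configurable. The receptive field along the offset axis
(~73 px reduced) comfortably spans the X-arms; a build-time check warns
when an architecture cannot.

The implementation is pure numpy/scipy: direct convolutions go through a
channel-major im2col and one BLAS matmul; large kernels (≥5×5) instead run
in the Fourier domain, where forward pass, input gradient and weight
gradient are per-frequency batched matmuls between transforms of the padded
activations, gradients and kernels (the input-gradient kernel transform is
derived from the cached forward transform by an index-shift phase, so no
kernel FFT is repeated in the backward pass). Both paths are
cross-validated against scipy.signal and against finite differences of an
independent float64 implementation. This layout was chosen after profiling:
on a single memory-bandwidth-limited core the naive sliding-window-view
transpose is an order of magnitude slower than either path.

Training minimizes MSE against the noise-free targets with ADAM (reduced
defaults: lr 2e−3 decaying ×0.6 per curriculum round, batch 4, L2 1e−6 on
weights). The curriculum raises the peak cap over rounds — reduced:
(5, 15, 30, 60) × 750 fresh examples each, 3,000 total; full-scale schedule
(10→1,500 over 475,000 examples) is provided but is not a test-suite
requirement. Examples are generated on the fly from per-round seeded
streams; the loss history, configs and data-config hash are stored in every
checkpoint. Small batches matter at this corpus size (more optimizer steps
per example); batch 4 measurably outperforms batch 8 on the desk-scale
fixtures.

## Reconstruction and uncertainties

Inference on a normalized difference stack (normalization is the caller's
declared step; silent rescaling is refused) runs n = 20 stochastic forward
passes with dropout active in all but the last hidden layer at the training
rate. The mean map is the reconstruction; the point-wise uncertainty is
σ_Recon = 1.4 × SD over passes, with the calibration factor 1.4 taken as a
fixed input and exposed as config. The raw passes are retained so that peak
intensities can be fitted per pass and their spread converted to intensity
errors with the same 1.4 factor (sample SD over the ensemble). The dropout
stream is seeded from (model weights, input, user seed): reconstructions
are reproducible, and different inputs never share masks.

## Quantification

Peak picking finds interior local maxima above a threshold fraction of the
map maximum and refines positions/heights per dimension with three-point
parabolic interpolation (δ = (y₋₁−y₊₁)/(2(y₋₁−2y₀+y₊₁))). The quadratic
rule is exact on parabolic neighbourhoods and accurate to ≲0.05 px for
peaks sampled at σ ≳ 1.3 px; narrower peaks carry a known sub-pixel bias.
Intensity fitting holds positions fixed, frees amplitudes and per-peak
widths, fits overlapping peaks jointly (single-linkage clustering of fit
windows), initializes widths from the target-map rule, and never drops a
non-convergent peak silently (it is flagged). Shift-RMSD benchmarking uses
greedy one-to-one nearest matching with per-dimension tolerances (defaults
0.05 ppm ¹H, 0.3 ppm ¹³C). Mixture slopes are error-weighted (1/σ²)
least-squares through the origin over converged fits, heights first
corrected by each stack's recorded normalization scale. The effective-size
helper multiplies mass by the solvent viscosity ratio (rotational diffusion
scales with η/T).

Quantitative intensity transfer through the network has a validity regime,
and the mixture fixture (`fixtures.mixture_grid_spins`) is designed inside
it: peaks isolated (fit windows never overlap); the constant component
carries the strongest amplitudes so it dominates the global normalization
of every mixture — the normalization scale then cancels between mixtures,
exactly as when the constant sample is the more concentrated one; and the
scaled component stays within the generator's trained intensity range at
every mixing ratio while remaining well above the noise floor. Outside this
regime the network's amplitude response is measurably sublinear (weak
features are shrunk, out-of-range features saturate) and fitted slopes
bias by ~10–20% at desk scale.

## What the synthetic tests do and do not show

The generator emulates isolated two-spin methyl probes with independent
rates, ideal lineshapes, flat baselines and white Gaussian noise. It does
not model solvent/buffer signals, shim or baseline artifacts,
cross-correlated relaxation, ¹³CH₃ multiplets, or inter-methyl couplings.
Passing the desk-scale contracts therefore demonstrates that the
simulator–network–quantification chain is self-consistent and that the
X-pattern-to-peak transformation is learnable at reduced scale; it does not
by itself establish performance on experimental spectra, artifact
robustness (deliberately out of scope), or the accuracy of the 1.4
uncertainty calibration, which is adopted, not derived.

## Problem sizes

Desk-scale figures used throughout the tests: 256×100 grids, a
~2.1×10⁵-weight network, 3,000 training examples, 500 held-out evaluation
examples, 200 single-peak position-recovery draws, 20 Monte-Carlo passes.
These sizes were chosen so the whole chain (data generation through
quantification) runs on one CPU core in well under half an hour while
leaving every contract comfortably met.
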
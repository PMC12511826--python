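# Methods

`qusbead` implements an automatic pipeline for estimating the ultrasonic
backscatter coefficient (BSC) of a tumor and its derived microstructure
parameters — effective scatterer diameter (ESD) and effective acoustic
concentration (EAC) — using a small metallic bead embedded in the tissue as
an in situ calibration target. This note records the models, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## The estimation model

**Bead-referenced BSC.** For a data block at position x with backscattered
power spectrum W(f, x), and a calibration bead with measured spectrum
W_bead(f) and known backscatter curve σ_bead(f),

    σ̂(f) = W(f, x) / W_bead(f) · σ_bead(f).

Because the bead shares the transmission path with adjacent tissue, every
multiplicative factor common to numerator and denominator — system gain,
transmit spectrum, diffraction to first order, and attenuation through
overlying layers — cancels exactly in the ratio. This cancellation is the
method's central property and is asserted bit-for-bit in the tests; its
physical accuracy in tissue is limited by how well the bead's propagation
path matches each block's (blocks at depths different from the bead retain
a residual attenuation mismatch).

**Spherical Gaussian scattering model.** BSC curves are reduced to two
parameters with

    σ(f) = EAC · (π/2) d⁶ k⁴ exp(−2 k² d²),      k = 2πf/c,

where d is the Gaussian correlation length of the impedance fluctuations,
EAC = n̄·γ₀² is the product of scatterer number density and squared
fractional impedance contrast, and the constant (π/2)d⁶ folds in the average
particle volume V_s = (2πd²)^{3/2} and the 1/(16π²) prefactor. The reported
size parameter is ESD = 3.11·d. Fitting is linear: with y = ln σ − 4 ln k
and x = k², ordinary least squares on y = b − 2d²x gives d = √(−slope/2)
and EAC = e^b / ((π/2)d⁶). On noiseless model curves this inversion is exact
to machine precision (asserted at 1e−6 relative). Fits with nonnegative
slope, or with d outside configurable bounds (default 1–500 µm), carry a
sentinel value at the lower bound, are flagged invalid, and are excluded
from all map summaries — the convention for blocks that do not fit the
Gaussian model.

## Pipeline stages

1. **B-mode conversion.** Per-line envelope via the frequency-domain
   Hilbert transform (exact on band-limited lines), normalization to the
   frame maximum, log compression to a 60 dB dynamic range. No scan
   conversion (linear array); axial spacing c/(2fs) and line pitch are kept
   as metadata. Template matching runs on the float dB image, not an 8-bit
   quantization, to avoid quantization ties.
2. **Segmentation.** A classic U-Net (nine resolution blocks, channels
   64→128→256→512→1024→512→256→128→64, 3×3 kernels, convolution → ReLU →
   batch normalization, 2×2 max pooling, transposed-convolution upsampling
   with skip concatenation, one logit output channel) trained with
   binary cross-entropy with logits and Adam for 20 epochs, with rotation,
   horizontal flip and elastic-deformation augmentation. The network is
   implemented directly on numpy in channels-last layout with hand-written
   backpropagation; convolutions are executed as shifted BLAS matrix
   products, which makes CPU training of scaled-down configurations
   practical. Inputs are resized to the network size (default 256×256;
   tests and examples use 128×128 with a 8→128 channel ramp), predictions
   thresholded at 0.5 and mapped back to native pixels by nearest neighbor.
3. **Bead localization.** The bead scattering function (BSF) template is
   the pixel-wise mean of z-scored labeled bead patches (default extent:
   2× bead diameter axially to cover the reverberation train, 1.5×
   laterally). Each frame's dB image is scanned by normalized
   cross-correlation; the peak (template-center convention, ties broken
   toward the smallest axial then lateral index) gives the per-frame
   detection, optionally restricted to template centers inside the tumor
   mask. The frame with the maximum peak supplies the bead reference
   spectrum for the whole volume; per-frame detections still drive
   bead-block exclusion. Peaks below 0.5 are flagged low-confidence but not
   rejected.
4. **BSC and parameter maps.** The mask's bounding box is tiled into
   3 mm × 3 mm blocks (≈10 pulse lengths per side) with 75 % overlap
   (stride 0.75 mm). A block is retained iff ≥75 % of its pixels are
   in-mask, its center pixel is in-mask, and it does not intersect the bead
   exclusion zone (axial extent = bead gate, lateral = 1.5× bead diameter,
   centered on the detection). Spectra are per-line Hann-windowed,
   zero-padded to ≥4× the gate and averaged over the block's lines; the
   bead spectrum uses the same FFT length (shared frequency grid by
   construction), a 6 mm axial gate starting a quarter-gate above the main
   echo, and averages the central 1 mm of bead lines, where the specular
   echo dominates speckle. ESD/EAC maps summarize valid fits only.

## Analysis band

The usable band is a property of the transducer and the calibration, not of
an individual acquisition: by default it is fixed at calibration time as
the transmit pulse's −10 dB power band (≈3.6–9.6 MHz for the 6.6 MHz, 70 %
bandwidth pulse). A data-driven fallback (−10 dB support of the system
response W_bead/σ_bead around its peak) exists for uncalibrated use.
Deriving the band from the raw in situ bead spectrum would let overlying
attenuation move the band and would break the overlay invariance that the
ratio estimator otherwise has exactly.

## The synthetic phantom and what it validates

Each RF frame is built line-by-line in the frequency domain: diffuse
scatterers at uniform random positions contribute the transmit pulse
(Gaussian-modulated sinusoid whose −6 dB fractional power bandwidth matches
the spec, verified by FFT) multiplied by an amplitude-domain response
√(π/2)·d³·k²·e^{−k²d²} — the Rayleigh factor times the Gaussian form-factor
amplitude — with exact fractional delays and per-scatterer, depth-cumulative
attenuation in dB/cm/MHz. The ensemble-average block spectrum is therefore
proportional to |P(f)|²·σ(f) with σ(f) exactly the spherical Gaussian
model, making the simulator a quantitative oracle for ESD recovery (the
Monte-Carlo shape test recovers d within a few percent).

Defaults emulate the target acquisition: 6.6 MHz center frequency, 70 %
−6 dB bandwidth, 40 MHz sampling, c = 1540 m/s, 0.3 mm line pitch, 0.5
dB/cm/MHz tissue attenuation, an elliptical tumor whose scatterer amplitude
variance is reduced relative to background (datasets draw the ratio from
0.08–0.3, i.e. −11 to −5 dB, the markedly hypoechoic appearance of mammary
tumors), and a 2 mm bead whose echo train has 3 reverberations with
geometric decay 0.5 and 2 mm round-trip spacing. The bead's main echo is
100× the diffuse RMS (~40 dB): the in situ reference method assumes the
bead signal is much larger than the surrounding tissue's, and a weaker bead
lets in-gate speckle tilt the reference spectrum measurably. The
reverberation model is a plumbing fixture, not a claim about titanium.

σ_bead(f) for synthetic runs is produced by an emulated one-off calibration
measurement: a speckle-free, attenuation-free phantom containing only the
bead is imaged, gated and line-averaged exactly as the in situ reference
will be, and normalized by the pulse power spectrum. This mirrors the
real-world procedure (the bead BSC is measured once in a tissue-mimicking
phantom) and means the bead's reverberation comb and window weighting
divide out of the ratio. Absolute EAC from synthetic runs is in nominal
units (the calibration constant is arbitrary); every EAC quantity the
pipeline reports for comparison purposes is a ratio in which that constant
cancels.

An optional overlay layer adds extra attenuation over its thickness.
Because every scatterer below the layer acquires the identical loss factor,
the bead-referenced estimate is invariant to the overlay by construction —
the end-to-end test observes per-phantom ESD shifts of ~0 percentage points
when a 1.5 cm, 0.5 dB/cm/MHz layer is added above bead and tumor.

**What the phantom does not emulate:** diffraction and elevational beam
effects, lateral speckle correlation (each scatterer maps to its nearest
line, so B-mode speckle is single-look and harsher than real multi-look
images — one consequence: BSF template/source correlations saturate near
0.78 rather than the >0.9 seen with real, smoother patches), nonlinear
propagation, electronic noise (optional white-noise flag), and tissue
heterogeneity beyond the tumor/background contrast. Passing the synthetic
suite therefore certifies the estimator algebra, the protocol logic, and
trainability — not in vivo segmentation accuracy or in vivo ESD accuracy.

## Numerical and design choices

- Frequency-domain synthesis length: next power of two ≥ line length +
  pulse length; attenuation filters are applied as real spectral factors
  (non-causal minimum-phase behavior is ignored; the resulting dispersion
  tails leak ≲0.5 % power between distant gates).
- Block/bead spectra share one FFT length (≥4× the longer gate, power of
  two). Hann windows, no detrending.
- Tiling offsets are computed in millimeters (stride 0.75 mm) and rounded
  to pixels per position, so non-integer pixel strides do not accumulate
  error; a 9×9 mm mask yields exactly 9×9 retained blocks.
- Training defaults: Adam, learning rate 1e-2 (1e-3 converges too slowly
  for the fixed 20-epoch budget of this numpy implementation), batch size
  8, rotation ±15°, flip probability 0.5, elastic α=34/σ=4 at 256×256
  (α scales with image size: 17 at 128×128). Best-validation weights are
  restored after training; validation runs without augmentation.
- Degenerate conventions: precision/recall/Dice are 1 when both masks are
  empty and 0 when exactly one is; zero-variance NCC windows score 0;
  empty segmentations skip the frame with a warning; a volume with no
  detectable bead halts the BSC stage with a diagnostic.
- Determinism: every stochastic component (phantom, dataset, augmentation,
  weight init, shuffling) is driven by an explicit seed; the analysis
  pipeline itself contains no randomness.

## Problem sizes used in the test suite

The distributed tests run the full pipeline at sizes chosen for a single
CPU: 20 end-to-end phantoms (48×30 mm, ~5800 scatterers each) plus overlay
repeats for ESD recovery; 40 clean and 12 decoy frames for localization;
and segmentation training on 200 pairs at 128×128 with an 8→128 channel
U-Net (≈0.5 M parameters). The full-scale 256×256 / 64→1024 configuration
(≈31 M parameters) is the library default and trains the same way, just
longer.
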
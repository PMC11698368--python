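# Methods

## Model

A volume patch is compressed by storing network weights instead of
voxels. Three stages form the codec:

**Spectral downsampling.** The high-resolution grid is transformed with
an unnormalized FFT, the zero-frequency-centered spectrum is cropped to
the target shape (an ideal low-pass), scaled by the voxel-count ratio,
and inverted on the reduced grid. This preserves mean intensity exactly
(a constant volume maps to itself) and is linear, training-free, and
outside every gradient path. For even target sizes the highest
negative-frequency (Nyquist) plane has no conjugate partner on the small
grid; it is zeroed rather than split, keeping the cropped spectrum of a
real signal Hermitian. Only signals with energy exactly at the cutoff
are affected. No spectral taper is applied; the crop is hard. The noise
term of the degradation model is fixed to zero, with an optional additive
noise callback for experiments.

**Implicit representation.** A SIREN with `L` layers and `n` neurons per
hidden layer realizes `L+1` affine maps (input 3→n, `L−1` hidden n→n,
linear output n→1), the unique reading of "L layers" that reproduces the
reference weight counts, e.g. 2011 = 2·30² + 7·30 + 1 at L=3, n=30. All
but the final map apply a sine; the first is scaled by ω₀ = 30 (the
standard SIREN frequency, exposed in `SirenConfig`). Weights follow the
SIREN initialization (first layer ±1/in_dim, later ±√(6/fan_in)/ω₀);
biases keep the framework-default ±1/√fan_in — phase diversity across
neurons matters far more for sine networks than small bias magnitudes,
and narrower bias ranges measurably slow convergence. Coordinates span
[−1, 1] inclusive per axis in raster order.

**Continuous super-resolution.** The decoder follows the neural-operator
view: one 3³ convolution lifts the coarse grid to `NC` channels; one
Galerkin attention block (width 4·NC) normalizes keys and values per
channel over the voxel tokens, aggregates `(KᵀV)/N` in channel space,
applies it to the queries, projects back and adds residually — linear
cost in voxel count, exactly equal to explicit N×N attention by
associativity; a two-layer MLP (hidden width 64) then decodes, for every
target coordinate, the trilinearly sampled features concatenated with
the sub-voxel offset and a per-axis scale token. Because the decoder is
coordinate-conditioned, the same weights decode at any requested
resolution. The internal sizes (kernel 3, one attention block, hidden 64)
are this package's defaults, exposed in `SRConfig`; the published total
parameter counts for the SR stage are treated as reference fixture data,
not as a structural constraint, so realized counts — not printed ones —
always enter the size accounting.

**Joint training.** Per step: SIREN evaluated on the low-resolution
coordinate grid → SR decode to patch shape → L1 loss against the
original patch (optionally plus a weighted L1 term against the
low-resolution target, weight 0 by default since the end-to-end loss
alone defines the published pipeline). Adam, lr 0.0015, default 5000
epochs, no schedule, full-batch, deterministic for a fixed seed.

## Size accounting

The compressed payload is the float32 weight vector of both networks, so
`bit_depth = 32` and `bitrate = #weights·32/#voxels`,
`CR = 1 − #weights/#voxels`. The 32-bit depth is the unique choice
consistent with the reference tables (2011·32/262144 = 0.245 bpp), and
the identity `bitrate = (1 − CR)·32` holds exactly for every
configuration. Training runs in float64; the stored weights are float32,
and the reconstruction reported with an artifact is recomputed from the
float32 weights, which makes decompression reproduce it bit-for-bit on
the same platform. Entropy coding of weights is deliberately out of
scope: size is defined by weight count.

## Metrics

PSNR uses MAX = 1 for normalized volumes (configurable; reports always
state it). SSIM defaults to the *global* form — the formula evaluated
once from whole-grid population (1/N) moments with C1 = 10⁻⁴,
C2 = 9·10⁻⁴ — because that is the form the metric definition writes; a
windowed mode (uniform 7³ windows) is provided for comparability with
common practice and tracks scikit-image's implementation up to boundary
handling.

## Trade-off selection

The sweep grid holds one metric bundle per (DS, NC, SN) combination. The
objective `1/PSNR + (1 − |SSIM|) + (1 − CR)` (CR as a fraction; an
infinite PSNR contributes 0) is minimized under corner equality
constraints with an Augmented Lagrangian. Axis values are min–max
normalized to [0, 1] before the residuals are formed, so the penalty is
commensurate with the objective; `DS_max` means the *largest retained
scale* (least aggressive downsampling). Defaults α = 0, β = 1,
10 multiplier rounds; each round scans the finite grid exhaustively with
a lexicographic index tie-break, so the selection provably equals a
brute-force scan of the same augmented objective, and with β → 0 it
degenerates to the plain argmin. Marginal curves reduce a transformed
metric over the two complementary axes; the default reduction is the
*mean*, which is what the published summary values actually are (the
sum form stated alongside them does not reproduce the printed numbers;
both reductions are available). One quirk is documented in
`neurovol.tradeoff`: the published summary's first two column headers
are swapped relative to the marginal semantics — the mean over the
DS = 1/2 slice appears under the NC = 4 header and vice versa. The
implementation defines marginals by the computation, not the header.

## Synthetic phantoms

The generator emulates normalized MRI-like patches at desk scale:

- `gaussian_blobs` / `ellipsoid_shell`: smooth foreground structures on
  an exactly-zero background (so the 70 %-non-zero HR-patch rule is
  exercised); values clipped to [0, 1] with a 10⁻³ floor snapped to 0.
- `bandlimited_noise`: texture whose spectrum is hard-zero above
  `cutoff_fraction` of Nyquist per axis and decays in band as
  PSD ∝ 1/|k|^slope (slope 2 by default, the standard power-law of
  natural and anatomical images). With cutoff 0.4 and scale 1/2, ideal
  low-pass downsampling is exactly lossless, which provides the
  closed-form Fourier-interpolation oracle used in tests.
- `cosine_mode`: a single integer-frequency 3-D cosine whose behaviour
  under spectral cropping is known in closed form.

All generation is seeded; no OS-entropy path exists in tests. What the
phantoms do *not* emulate: scanner noise, bias fields, partial-volume
effects, anisotropic spacing, or genuinely broadband anatomy. Passing
the desk-scale training checks therefore demonstrates that the pipeline
optimizes jointly, that gradients reach both networks, and that the
codec round-trips — not that clinical MRI reaches any particular PSNR.

## Problem sizes and numerical choices

Tests and the packaged examples run scaled down — 16³–32³ patches,
tens to 2000 epochs — chosen so a small SIREN can demonstrably converge
on one CPU; full-bore defaults (64³, 5000 epochs) remain the library
defaults. Degenerate inputs are decided, not left to chance: a constant
volume normalizes to all-zeros with its range recorded; identical grids
give the +∞ PSNR sentinel; zero-variance SSIM inputs are stabilized by
C1, C2 and give 1 for identical constants; an empty HR-patch candidate
set raises an explicit error rather than silently falling back. The
autodiff core is plain reverse-mode over numpy float64 arrays; gradient
correctness is property-tested against finite differences, and the
attention path against its quadratic-form oracle.

## Known limitations

- One patch per compression run; whole-volume orchestration is an
  external loop over patches.
- The SR stage's published per-configuration parameter totals cannot be
  reproduced structurally (internal layer sizes unpublished); only
  realized counts are used.
- Training time on CPU grows steeply with patch size; 64³/5000-epoch
  runs are practical on accelerators, not in the test suite.
- No quantization-aware training or entropy coding; 32-bit weights are
  the stored form.
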
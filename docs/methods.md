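# Methods

`switchquant` implements four quantification procedures used to
characterize a light-inducible Cre recombinase, together with the
synthetic-data generators that stand in for the instruments that
produced the original inputs (a molecular-dynamics engine, a flow
cytometer, a qPCR thermocycler and a fluorescence microscope).  This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic fixtures can and cannot establish.

## 1. Potential of mean force from umbrella sampling

### Model

A scalar reaction coordinate x (here, the helix–environment distance in
angstrom) is sampled under a ladder of harmonic restraints
b_w(x) = ½ k (x − c_w)², the ½-prefactor convention throughout.  The
protocol fixes: 13 windows with centers equally spaced on 4–10 Å,
k = 20 kcal mol⁻¹ Å⁻², 30 ns per window, a 5 ns equilibration phase,
5 ns blocks (five blocks), a reporting grid of 13 equal bins on
3.75–10.25 Å, T = 310 K with k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, and a
WHAM convergence tolerance of 0.01 kcal mol⁻¹.

Per block, the weighted histogram analysis method (WHAM) is solved
self-consistently:

    p_i = Σ_w n_{w,i} / Σ_w N_w exp(−β (b_w(x_i) − f_w))
    f_w = −kT ln Σ_i p_i exp(−β b_w(x_i))

with x_i the bin centers.  Block distributions are averaged:
p̄_i over blocks, F_i = −kT ln p̄_i, σ_p̄i = 2 · sd/√n_blocks (sample
sd), σ_Fi = kT σ_p̄i / p̄_i, and the profile is offset so its minimum
is zero.  Bins with p̄_i = 0 are reported as undefined (NaN), never as
a fabricated value, and the offset ignores them.  With a single block
σ_F is undefined rather than zero.

### Numerical choices

- **Histogram resolution.**  At k = 20 and 310 K the biased kernels
  have σ = √(kT/k) ≈ 0.18 Å, far narrower than the 0.5 Å reporting
  bins.  Solving WHAM directly on the reporting bins with the bias
  evaluated at bin centers then carries a discretization bias of
  ≈ 1.2 kcal mol⁻¹ RMSE in the exact-histogram limit (≈ 0.56 with
  bin-averaged Boltzmann bias factors) — larger than the entire
  statistical error.  `estimate_pmf` therefore solves WHAM on a
  refined grid (`refine` sub-bins per reporting bin, default 5, i.e.
  0.1 Å) and aggregates the solved probabilities back onto the
  reporting bins; the exact-limit residual is then 0.017 kcal mol⁻¹.
  `refine=1` reproduces the single-resolution convention, and
  `wham_solve` itself always operates verbatim on the grid it is
  given, so the solver can be checked against brute-force fixed-point
  iteration on small instances.
- **Stopping rule.**  The fixed-point iteration contracts geometrically
  with a ratio ρ that approaches 1 for stiff, weakly overlapping
  windows, so the per-iteration change understates the remaining
  distance to the fixed point by a factor (1 − ρ).  Iteration stops
  when the per-iteration change max|Δf_w| *and* the Aitken-extrapolated
  remaining distance Δ·ρ/(1 − ρ) are both below the tolerance.  With
  the raw per-iteration test alone, the default tolerance leaves a
  ≈ 0.35 kcal mol⁻¹ truncation error at the barrier that no amount of
  sampling removes and that breaks the error-bar calibration.
  Iteration starts from f_w = 0, no damping; f_w is reported relative
  to the first window; non-convergence within `max_iterations`
  (default 10⁵) raises with the last residual.
- **Blocking.**  Trailing partial blocks are dropped, not padded, so
  all blocks carry equal weight in the SEM.  A series shorter than one
  post-equilibration block is an error naming the shortfall.
- Samples outside the grid are counted per window; losing more than
  half of a window's samples is an error.

### Synthetic umbrella windows

The generator integrates overdamped (Brownian) Langevin dynamics,
x ← x − βD U′(x) dt + √(2D dt) ξ, under U = U₀ + bias.  Because the
estimator consumes only the scalar series, the integrator choice
affects no downstream code.  Defaults: D = 1 Å² ns⁻¹, dt = 0.002 ns
(the Euler–Maruyama stability bound dt < 1/(βD max|U″|) ≈ 0.015 ns
holds with a 7× margin), coordinate saved at every step, 15,000 steps
= 30 ns per window, each window started at its own bias center.  The
bias relaxation time 1/(βDk) ≈ 0.03 ns means each 5 ns block holds
roughly 160 effectively independent samples per window.

The ground-truth landscape for recovery tests is the quartic double
well U₀(x) = a (x − 5)² (x − 9)², scaled to a 3 kcal mol⁻¹ barrier at
7 Å — a barrier comparable in scale to the measured unbinding profile,
with minima placed so the 4–10 Å ladder exercises multi-window
overlap.  `analytic_pmf` provides the oracle,
F_i = −kT ln ∫_bin exp(−βU₀) dx by adaptive quadrature.

At these settings, over 20 repetitions the estimated profile deviates
from the analytic one by ≈ 0.15 kcal mol⁻¹ RMSE (every repetition
≤ 0.24) and the analytic value falls within F_i ± 2σ_Fi in ≈ 96% of
bins.  The coverage statistic fluctuates by a few percent across seed
sets: σ_F is the prescribed block formula, which ignores the
min-anchoring covariance and the Student-t correction for five blocks.

## 2. Flow-cytometry switch fraction

Events carry (FSC-H, SSC-H) scatter and one fluorescence channel.  The
gate is defined by a Gaussian product-kernel density estimate over
scatter, per-axis Silverman bandwidths h_j = σ̂_j n^(−1/6); the densest
⌈0.40 n⌉ events are gated.  Quantile gating (rather than taking the
interior of a rasterized contour) makes the enclosed fraction exact by
construction, which is the normative part of the protocol; the density
contour at the gate threshold is still computed as a display polygon.
Ties in density are broken by input order, the only way event order
can affect any result.

Gate-position screening replaces the original by-eye check with a
stated rule: per experiment (≥ 3 samples), samples whose gate centroid
deviates from the median by more than 5 MADs on either scatter axis
are flagged; a zero MAD flags nothing on that axis.

The ON/OFF threshold is the 99.9th percentile (linear interpolation
between order statistics) of the gated fluorescence of an empty-vector
negative control; fraction-ON counts gated events *strictly above* the
threshold, so a pure negative control fires at ≈ 10⁻³ by construction.
No compensation or intensity transformation is applied.  Group
summaries report mean ± s.e.m. (sd/√n, sample sd; n = 1 flagged);
comparisons are a two-sided Welch t-test or a rank-sum test, exact by
enumeration for combined n ≤ 20, normal approximation above.  Two
zero-variance groups with equal means give p = 1 by convention.

The synthetic acquisitions mix log-normal OFF/ON populations (medians
100 and 5000, log-sd 0.35) over a shared bivariate log-normal scatter
cloud, plus 5% broad low-scatter debris so the gate has something to
exclude.  These are stand-in distributions, not estimates of any
deposited dataset: passing tests show the gating/thresholding
machinery is correct, not that real cytometer noise (spillover,
autofluorescence drift, doublets) is handled.  Event tables are CSV;
no FCS reader is included.

## 3. qPCR excision fraction

Calibration mixtures at known edited fractions (0, 0.5, 1, 5, 10, 50,
70, 90, 100%) give a log-linear standard curve
Ct = intercept + slope·log₁₀(q) by ordinary least squares; zero
fractions never amplify and are excluded (exclusion is a filter — the
remaining points fit identically).  Amplification efficiency is
10^(−1/slope) − 1, so slope −3.3219 means 100%.  Sample Cts are
arithmetic-averaged over replicates before inversion
q = 10^((Ct−intercept)/slope); the excision fraction is
N_Lox/N_Total with each quantity read off its own assay's curve
(edited-target assay and total-template control assay fitted
independently).  A fraction above 1 is flagged, never clipped, since
both quantities carry error; a non-amplifying edited assay gives 0; a
non-amplifying total assay is an error.  NaN is the no-amplification
marker throughout.

The simulator draws Ct = intercept + slope·log₁₀(fraction) + N(0, σ)
with defaults intercept 20, slope −3.3219, σ = 0.15 cycles, 3
replicates.  Zero-noise round trips are exact for any fraction; at the
default noise the median estimate at a true fraction of 0.30 is biased
by well under 5% over 100 repetitions.

## 4. Microscopy fluorescence

Segmentation is an input: an integer label mask (0 = background) over
a grayscale image.  Each cell's mean gray value is corrected by one
shared per-image background, the pooled-pixel mean over eight random
disk-shaped regions of the median cell area placed entirely outside
all labels (rejection-sampled, seeded, bounded retries).  Pooling
pixels rather than averaging region means is the stated convention;
the two coincide when regions have equal area.  Corrected intensities
may be negative under noise and are never clipped.

For integer images the subtraction is computed as the exact rational
(S_cell·A_bg − S_bg·A_cell)/(A_cell·A_bg) in arbitrary-precision
integer arithmetic, so adding a constant offset to every pixel leaves
each corrected intensity identical bit for bit — the natural
invariance a background-subtracted quantity should satisfy exactly,
not merely to rounding.

The image simulator renders non-overlapping constant-intensity disks
on a constant background with optional Gaussian noise, quantized to
16-bit.  It does not emulate shading, point-spread blur or
photobleaching; recovery tests certify the measurement arithmetic
only.

## 5. Orchestration

The `switchquant` CLI binds the stages (simulate-umbrella, pmf,
simulate-cyto, gate, simulate-qpcr, qpcr, simulate-image, imaging,
all) over a YAML config with CLI overrides.  Validation reports every
out-of-domain field at once with its dotted path.  All randomness
derives from config seeds; CSVs are written comma-separated, UTF-8,
with 9-significant-digit floats, and the run record lists each output
with a SHA-256 checksum, so identical configs produce byte-identical
outputs.  Defaults equal the protocol constants (13 bins on
3.75–10.25 Å, tolerance 0.01 kcal mol⁻¹, 5 ns/5 ns blocking, 310 K,
40% gate, 99.9th percentile, 8 background regions).

## Problem sizes

The default test and verification workload uses 13 windows × 30 ns at
dt = 0.002 ns (15,000 points per window), 10,000-event cytometry
samples (4,000-event samples for the 50-replicate negative-control
calibration), 100 qPCR repetitions, and 256×256 images with ≤ 12
cells — sizes at which every stage's statistical claims are testable
in seconds on a single core.

## Known limitations

- WHAM only: no MBAR, no autocorrelation-based decorrelation, no 2-D
  or periodic coordinates.
- The error-bar formula is the prescribed block-average expression;
  its 2σ coverage is a few percent below nominal because of the
  five-block Student-t factor and the shared minimum-anchoring offset.
- The outlier screen is a stated replacement for a visual check, not a
  reconstruction of it.
- Cytometry input is CSV only; no spectral compensation, clustering,
  or time gating.
- The microscopy stage measures; it does not segment, register, or
  correct bleaching.
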
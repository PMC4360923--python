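# Methods

## Noise model

A single-coil magnitude MR voxel is modelled as |z| = √((r + n₁)² + n₂²)
with true magnitude r ≥ 0 and independent n₁, n₂ ~ N(0, σ²) (the phase
of the complex signal is taken as 0, so the signal sits in the real
channel; the magnitude is phase-invariant, so this loses no
generality).  |z| is Rician with density
p(z|ν,σ) = (z/σ²)·exp(−(z²+ν²)/2σ²)·I₀(zν/σ²); at ν = 0 it is
Rayleigh.  Two facts drive the framework:

* **E|z|² = r² + 2σ²** — the squared magnitude has a constant,
  signal-independent bias, so a denoiser can run on |z|² and the bias
  can be removed afterwards (subtract 2σ², clamp at 0, square root).
* In a zero-signal background, **E|z|² = 2σ²**, giving the estimator
  σ = √(μ/2) from the background mean μ of the squared magnitude.

All moments are evaluated through exponentially scaled Bessel functions
(`scipy.special.ive`), stable for arbitrarily large ν/σ.

## Variance-stabilizing transform

The forward stabilizer f maps x = z/σ so that sd(f(z) | ν) ≈ 1 for all
ν.  It is constructed numerically on a dense grid (x ∈ [0, 100], 10⁴
points) from the classical stabilization integral
f(x) = a + ∫₀ˣ du / s(u), where s(u) is the Rician sd at the ν whose
*mean* equals u (Rayleigh sd below the Rayleigh mean); a is a free
offset, default 0.  The delta-method curve alone leaves the stabilized
std ≈ 0.89–1.06 at low SNR, so four refinement passes measure
sd(f(z)|ν) by quadrature on a low-SNR ν grid and divide the integrand
by it before re-integrating; the refined table holds the Monte-Carlo
stabilized std within a few percent of 1 over the whole SNR range
(within ±10% is asserted by the tests; the residual ripple of the fixed
point decays slowly, so more passes buy little).

The inverse is **exact-unbiased**: a table of E[f(z)|ν] (trapezoidal
quadrature over a ±12σ window around ν, normalized by the quadrature
mass so truncation cancels; ν grid of 2001 points) is inverted by
linear interpolation.  Filtered values below the table minimum map to
0; both curves are extended affinely with unit slope beyond the grid,
which is exact in the high-SNR Gaussian limit.  Tables serialize to a
versioned JSON artifact.

## Non-local means core

For voxel p the output is Σ_q w(p,q)·v(q) over a centred search window,
w(p,q) ∝ exp(−d²(p,q)/h²), where d² is the G_a-weighted (Gaussian over
patch offsets, normalized to unit sum, std 1 voxel by default) sum of
squared differences between the patches around p and q.  Defaults:
patch 5×5×5, search 11×11×11 — the standard choice for 1 mm³ isotropic
MRI.  Conventions:

* the centre voxel's weight uses its literal zero patch distance (no
  max-of-neighbours substitution);
* patches at borders use reflective padding (numpy `reflect`);
* search windows are clipped at borders and weights renormalized, so
  the output is a convex combination of observed values everywhere.

The pre-smoothed variant computes d² (hence the weights and the
normalizing constant) on a separately smoothed guide while averaging
the transformed volume; with guide == input it is exactly plain NLM,
which the tests assert bitwise.  The implementation loops over
search-window offsets, computing each offset's patch distances for all
voxels at once via a shifted squared difference and separable
correlation — O(|search|·N) with vectorized inner loops, matching a
brute-force voxel-loop oracle to ≤ 10⁻¹⁰.

## Pipelines

* **PSNLM1** (squared-magnitude path): background → σ → |z|² →
  pre-smooth → NLM with pre-smoothed weights → √(max(·−2σ², 0)).
* **PSNLM2** (VST path): σ → f(|z|/σ) → pre-smooth → NLM → exact-
  unbiased inverse → ×σ.
* **UNLM1/UNLM2** are the same paths with the identity pre-smoother
  (implemented as such, so the reduction is bitwise); **NLM** is the
  raw-magnitude baseline with no transform or bias correction.

The filtering degree h lives in the units of the filtered domain.  When
unset it defaults to `h_scale` × a representative domain noise scale:
σ (raw), 1 (VST domain), and 2σ·√(mean |z|² over the head) for the
squared domain, whose noise sd 2σ√(r²+σ²) is signal-dependent — the
head mean is a mid-signal representative.  With a ground-truth
reference available, `select_h` grid-searches h for maximum PSNR (ties
to the smallest h), which is how the simulation studies choose h; the
study grid spans 0.1–2 × the domain scale, wide enough that no method's
optimum sits on the boundary.  When σ estimates to exactly 0 (noise-free
input) h receives a tiny positive floor, which makes NLM the identity
(only exact-duplicate patches receive weight), and the VST path returns
its input unchanged since the stabilizer is undefined at σ = 0.

## Background extraction

median filter (3³) → Otsu threshold (foreground = above) →
morphological closing of the foreground (3D ball, radius 2) → 3D hole
filling → background = complement.  Otsu is implemented directly —
candidate thresholds are interior bin edges of a 256-bin histogram,
classes split as (≤ t, > t) with bin-centre class means, ties to the
lowest edge — and is tested against an exhaustive scan and against
scikit-image's implementation.  The median window and ball radius are
package defaults; no canonical values exist for them.

On piecewise-constant phantoms the extractor leaves a thin rim of
head-boundary voxels in the background (the median filter pulls the
outermost tissue layer below threshold), biasing the auto-σ by up to
~3% at high noise.  This is inherent to threshold-based extraction on
hard boundaries; the σ-recovery tests therefore feed `estimate_sigma`
the generator's exact zero-signal support, while the extractor is
tested separately for mask agreement (≥ 99% on ball phantoms).  Real
multi-modal workflows can pass an externally derived mask (e.g., a
T1-derived mask propagated by rigid registration, which this package
deliberately does not implement).

## Synthetic phantoms

`generate_phantom` produces a deterministic piecewise-constant head: an
ellipsoid (semi-axes ≈ 0.42 of each extent → background fraction
≈ 0.68) with a mid-intensity outer shell (the skull/scalp analogue that
makes the head outline clearly brighter than the background — the
working assumption of the background extractor) and an interior
partitioned into three tissue classes (0.3t, 0.65t, t) by quantile
cuts of a smoothed seeded Gaussian field modulated by a radial
gradient.  t is 150/250/255 for T1/T2/PD contrast.
`add_rician_noise` draws two independent standard-normal fields from
one seed (SeedSequence split), scales by σ = (percent/100)·t, and takes
the magnitude.

What the phantom does *not* emulate: real anatomy and texture, partial
voluming at tissue interfaces, intensity non-uniformity (bias fields),
and spatially correlated or non-central-Chi (multi-coil) noise.
Passing tests therefore demonstrate the correctness of the transforms,
the estimator, the filter and their composition under the stated noise
model — not clinical denoising quality on scanner data.

## Evaluation and study sizes

PSNR = 10·log₁₀(C²/MSE) with C defaulting to the reference maximum;
identical volumes report MSE 0 / PSNR +∞.  The simulation study (tests
and `scripts/acceptance.py`) uses 48³ phantoms at 17% noise with patch
5³ / search 11³ — large enough for several hundred thousand
voxel-window evaluations per run while keeping the whole study in the
minutes range on one core.  At this scale the variant ordering of the
method's motivating experiments reproduces cleanly:
plain NLM < UNLM1 < UNLM2 ≤ PSNLM1-Gaussian < PSNLM2-Gaussian.

## Known limitations

* Single-coil Rician noise only; non-central-Chi (parallel imaging)
  bias correction is out of scope.
* σ is global; spatially varying noise maps are not modelled.
* No blockwise or FFT acceleration of NLM; complexity is
  O(N·|search|·log-free) with vectorized constants, fine for desk-scale
  volumes, slow for 181×217×181 whole-head studies (hours, not
  minutes).
* The Otsu-based extractor assumes a bright, closed head outline; thin
  or dark skull (T2/PD) requires an external mask.
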
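# Methods

This note documents the models, numerical choices and design decisions
behind `dwspectra`, and what the synthetic phantoms do and do not show
about real data.

## Encoding spectra

The spectral chain follows the standard frequency-domain description of
time-dependent gradient encoding. Waveform samples sit on a uniform grid
t_n = n·dt; the dephasing vector is the cumulative trapezoid of γ·g(t).
q(ω) is computed by FFT with the e^{+iωt} sign convention and zero padding
(default 8×, so the two-sided frequency grid resolves centroid frequencies
and spectral percentiles well below the waveform's intrinsic line width).
b(ω) = q(ω)q(−ω)ᵀ/2π is Hermitian positive-semidefinite; all scalar
contractions use its real part, which is exact because the diffusion
spectra it is contracted with are real, symmetric and even in ω (the
imaginary part integrates to zero). All ω-integrals are trapezoidal on the
FFT grid. Consistency is asserted numerically: the integrated b-tensor
equals the time-domain ∫q qᵀ dt to better than 1e-6 relative, and the
pulsed-pair limit reproduces the b = γ²g²δ²(Δ − δ/3) closed form.

Eigenvalues of the b-tensor are labelled by the deviation-from-b/3
convention (|b_ZZ − b/3| > |b_XX − b/3| > |b_YY − b/3|); the XX/YY tie is
broken by descending eigenvalue, and the b_ZZ eigenvector is sign-flipped
into the upper hemisphere so Θ ∈ [0, π/2], Φ ∈ (−π, π]. A zero tensor
yields NaN scalars, never fabricated values.

### Double-rotation waveforms

Generated waveforms specify the dephasing trajectory directly:
q(t) = A(t)·d(t) with envelope A(t) = sin(πt/τ)·cos(2πn_osc t/τ) (zero at
both ends, hence self-refocusing; the n_osc sign reversals raise the
spectral content) and direction d(t) on a cone about z whose azimuth
advances by an integer number of turns *uniformly in the cumulative q²
measure*. The measure-uniform sweep makes the q²-weighted direction dyadic
exactly the cone average, so the cone half-angle alone sets the tensor
shape: 0 → linear (b_Δ = 1), the magic angle → spherical (b_Δ = 0), π/2 →
planar (b_Δ = −0.5). The gradient is the grid derivative of q/γ with the
per-axis DC offset removed (q(τ) ≡ 0 exactly) and the amplitude rescaled so
the realized b-value matches the target exactly (b is quadratic in
amplitude). Realized shapes are verified numerically — b_Δ lands within
~1e-4 of target, well inside the ±0.01 contract — rather than assumed from
the construction. Imaging-gradient cross-terms are not synthesized;
externally measured effective waveforms can be supplied as text files
instead.

## Synthetic protocols

The wide-frequency (preclinical-style) and narrow-frequency
(clinical-style) acquisition protocols are generated, not shipped: the
builders in `protocols.py` construct tables to the published summary
characteristics (acquisition count 1491 / 134; b range 0.033–4.25e9 /
≤3e9 s·m⁻²; b-weighted ω_cent percentiles 35/190/320 Hz and 5/9/11 Hz;
τ_R and τ_E ranges). Waveform durations per oscillation count and tensor
shape are root-found so each family realizes its target centroid frequency,
and per-family b-ladders are sized so the step-rule weighted percentiles
land on the stated values. The weighted percentile is deliberately a step
rule — cumulative normalized b-weights, first value reaching p, no
interpolation — because it is reproducible and matches a step-distribution
reading of a discrete acquisition list. The clinical-style table carries
centroid frequencies per record but no waveforms (the originals are
numerically optimized for whole-body hardware, out of scope here); for
such record-only acquisitions the forward model treats b(ω) as a spectral
line at ±ω_cent, which is exact for dispersion-free components — the only
regime in which the narrow-window analyses are quantitatively interpreted.

## Component model

Each component is [w, D_A, D_R, θ, φ, D₀, Γ_A, Γ_R, R₁, R₂] in strict SI.
D₀ ≥ max(D_A, D_R) is enforced (restriction lowers the low-frequency
diffusivity; D₀ is the common high-frequency limit); candidates violating
it are clipped at sampling time. Γ = ∞ encodes a frequency-independent
eigenvalue. τ_R = ∞ appears only as a finite sentinel (≥10⁶/min R₁) at the
S₀-extrapolation stage.

The frequency integral in the signal equation runs over the two-sided grid;
since every integrand is even in ω, the fast path integrates one-sided with
doubled weights. The vectorized kernel additionally rewrites each
Lorentzian integral as the *exact* frequency-independent contraction
(computed from the stored b-tensor) plus a dispersive correction
∫(1−L(ω;Γ))·b(ω)-moment dω evaluated on a common resampled 128-point grid.
Dispersion-free components therefore incur no resampling error at all
(machine precision agreement with the reference implementation), and
dispersive components agree with the per-acquisition trapezoid reference to
~1e-4. Grid adequacy is asserted against a 16×-padded reference integral in
the tests.

## Monte Carlo inversion

Weights are linear given the nonlinear parameters, so the estimator
alternates stochastic search with non-negative least squares
(`scipy.optimize.nnls`); regularization and sparsity constraints are
deliberately absent, with uncertainty quantified by bootstrap instead.
Default iteration counts are 20 proliferation rounds, 20 mutation/
extinction rounds, 200 fresh candidates per round, 10 output components,
and 100 bootstrap replicates; the tests and example runs reduce these
(typically 12–15 rounds, 100–150 candidates, 10–20 replicates) to keep
single-CPU runs in the seconds-to-minutes range — recovery accuracy at
those sizes is what the test suite certifies.

Sampling is log-uniform in all positive parameters and uniform on the
upper hemisphere for orientations. In ω-dependent mode a configurable
fraction (default 25%) of fresh candidates is drawn with Γ at the upper
limit — transitions far above any measured frequency — so the
frequency-independent subspace is always explicitly represented among the
candidates. This makes the nesting property (the ω-dependent optimum can
never be worse than the static optimum, up to Monte Carlo noise)
structural rather than asymptotic, and substantially accelerates
convergence on Gaussian voxels. Mutation multiplies positive parameters by
log-uniform factors in [1/1.2, 1.2] and tilts orientations within a 10°
cap; these magnitudes balance exploration against refinement and are
exposed in the configuration. Because survivors always re-enter the refit,
the best residual norm is non-increasing over rounds (recorded in
`rss_history`).

Static mode estimates the 6-parameter [D_A, D_R, θ, φ, R₁, R₂] space
against integrated b-tensors — it is a genuinely different model, not the
ω-dependent model with frozen Γ.

The bootstrap resamples *acquisitions* with replacement (the alternative,
residual resampling, is not implemented); each replicate fits on its
resampled rows and reports residuals on the full protocol. Seeds derive
from (master seed, voxel index, replicate index) via `SeedSequence`, so
serial and parallel runs are bit-identical.

## Derived metrics

Projections D_iso(ω) and D_Δ²(ω) follow the standard axisymmetric formulas;
the 64×64 mesh spans log₁₀ D_iso over the inversion limits and D_Δ²
linearly on [0, 1], with each component depositing its weight through a
3×3 truncated Gaussian kernel (σ = 0.75 grid spacings — the kernel width is
a visualization choice). Kernel spill past an axis edge (e.g. below
D_Δ² = 0 for isotropic components) is folded back onto the edge cells so
mesh mass is conserved exactly. Bin boundaries are strict inequalities
with equality assigned to the lower-D_iso / lower-D_Δ² bin, making the
three-bin partition exhaustive. Maps are marginal medians over bootstrap
replicates, evaluated at the protocol's ω_50% with dispersion metrics from
ω_10% and ω_90%; static-mode maps use the frequency-independent values and
have identically zero dispersion metrics. ROI projections pool the
components of every replicate of every masked voxel (weights scaled by the
replicate count) before meshing.

## Phantoms

The presets emulate reference systems with known diffusion signatures:
isotropic Gaussian (salt solution, D = 0.4e-9 m²/s, R₁ = 2 s⁻¹,
R₂ = 20 s⁻¹), planar Gaussian (lamellar, D_A ≈ 0, D_R = 1.5e-9 →
D_iso = 1.0e-9, D_Δ² = 0.25), prolate (WM-like, D_iso = 0.2e-9,
D_Δ² = 0.89), fast isotropic (CSF-like, 3e-9), and restricted systems
built from the closed-sphere spectrum
D(ω) = Σₖ Bₖ aₖ D₀ ω²/((aₖD₀)² + ω²), with aₖ = μₖ²/r²,
Bₖaₖ = 2/(μₖ² − 2), and μₖ the ascending roots of the first-order spherical
Bessel function's derivative (μ₁ ≈ 2.0816). The root-coefficient
sum Σ 2/(μₖ²−2) converges to 1 like 2/(π²k): it is ≈0.996 at 50 roots and
>0.999 near 160 — the default truncation of 50 roots bounds the
high-frequency plateau error below 0.5%.

Because the inversion's dispersion shape is Lorentzian while the
interpretation model is the sphere, the restricted presets (tumor, cortical
GM) carry Lorentzian parameters obtained by matching the sphere spectrum
exactly at two anchor frequencies (the wide protocol's ω_10% and ω_90%);
between the anchors the single Lorentzian transitions more sharply and
deviates from the sphere by up to ~12%. The cerebellar preset additionally
carries anisotropy that disperses away with frequency (D_Δ² ≈ 0.16 at the
low anchor decaying toward 0), realized by keeping the axial eigenvalue at
D₀ and letting only the radial one transition — the configuration the
Lorentzian model admits for a prolate tensor with a common isotropic
high-frequency limit.

Noise is Gaussian (S + n) or Rician (|S + n₁ + i n₂|) with σ = S₀/SNR. The
default phantom grid is 10×10×1 voxels: large enough for map statistics,
small enough for minutes-scale runs.

What passing tests show — and don't. The phantoms exercise the full
forward-inverse loop under known ground truth, including the qualitative
contrasts of interest (frequency-dependence improves fits and removes the
anisotropy bias on wide-window dispersive data; both modes coincide on
narrow-window Gaussian data). They do not emulate imaging artifacts,
spatially correlated noise, partial-volume geometry beyond simple mixtures,
exchange between components, or non-Lorentzian dispersion shapes, so
passing them does not certify performance against those features of real
scanner data.

## Degenerate inputs and tie-breaks

Zero b-tensors, zero S₀ and empty ROIs produce NaN sentinels or explicit
errors, never silent defaults. Image/protocol length mismatches are schema
errors. All-zero kernel columns are dropped from the NNLS solve with zero
weight. The XX/YY eigenvalue tie-break, the bin-boundary closure and the
step-percentile rule are documented above precisely because the underlying
conventions do not cover the degenerate cases.
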
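# dwspectra

Nonparametric frequency-dependent diffusion-tensor–relaxation distributions
(**D(ω)–R₁–R₂**) from multidimensional diffusion–relaxation MRI.

Diffusion MRI voxels are heterogeneous: tissue water populations differ in
local diffusivity, anisotropy, relaxation rates, and — when micrometer-scale
barriers restrict the motion — in how the apparent diffusivity depends on
the encoding frequency. `dwspectra` estimates, per voxel, a discrete
distribution of axisymmetric diffusion tensors with Lorentzian frequency
dispersion and nuclear relaxation rates from data acquired with
tensor-valued (linear, planar, spherical) diffusion encoding at variable
echo and recovery times. It is aimed at researchers working with
oscillating-gradient / spectrally modulated preclinical or clinical
protocols who want to compare frequency-dependent and frequency-independent
analyses of the same data.

## Model

A gradient waveform **g**(t) is characterized in the frequency domain via
the dephasing vector **q**(t) = γ∫₀ᵗ **g** dt′ and the tensor-valued
encoding spectrum

    b(ω) = q(ω) q(−ω)ᵀ / 2π,     q(ω) = ∫₀^τ q(t) e^{iωt} dt,

whose integral over ω is the conventional b-tensor with trace b, normalized
anisotropy b_Δ ∈ [−0.5, 1], orientation (Θ, Φ), and centroid frequency
ω_cent. The signal is a sum over discrete components i:

    S[b(ω), τ_R, τ_E] = Σᵢ wᵢ exp(−∫ b(ω) : Dᵢ(ω) dω)
                         · [1 − exp(−τ_R R₁ᵢ)] · exp(−τ_E R₂ᵢ),

where each axisymmetric spectrum **D**ᵢ(ω) interpolates between low-ω
eigenvalues (D_A, D_R) and a common high-ω isotropic diffusivity D₀ through
Lorentzians with mid-point frequencies Γ_A, Γ_R. When **D**ᵢ(ω) is constant
this reduces to the conventional exp(−**b** : **D**ᵢ) model, which is the
package's "static" mode.

The inversion is a Monte Carlo search (proliferation, mutation/extinction,
non-negative least-squares weight fits, no regularization) with bootstrap
replication by resampling acquisitions with replacement; maps are medians
over replicates. Derived metrics include D_iso(ω), D_Δ²(ω), bin-resolved
signal fractions (WM-/GM-/CSF-like), E[X] means, frequency-dispersion
metrics Δ_ω/2π E[X], normalized ω-dependent-vs-independent difference maps,
and per-voxel SNR estimates.

## Worked example

```python
import numpy as np
from dwspectra import encoding, inversion, metrics, phantoms, protocols

# 1. characterize a generated planar double-rotation waveform
wf = encoding.double_rotation_waveform(
    n_osc=2, duration=10e-3, b_delta_target=-0.5, b_target=2e9, g_max=np.inf)
acq = encoding.acquisition_from_waveform(wf, tau_r=1.0, tau_e=0.02)
print(f"b = {acq.b:.3e} s/m^2, b_delta = {acq.b_delta:+.3f}, "
      f"omega_cent/2pi = {acq.omega_cent / (2 * np.pi):.0f} Hz")

# 2. invert a dispersive tumor-like voxel on a wide-frequency protocol
protocol = protocols.make_reduced_preclinical_protocol()
model = inversion.SignalModel(protocol)
voxel = phantoms.make_preset("tumor")
signal = model.signals(voxel, "omega_dependent")
signal += np.random.default_rng(0).normal(0, voxel.s0 / 100, signal.shape)

config = inversion.InversionConfig(
    rng_seed=0, n_proliferation=15, n_mutation=15, n_in=150, n_bootstrap=10)
ensemble = inversion.bootstrap_invert(model, signal, config)

for f_hz in (35, 320):
    med = np.median([metrics.mean_d_iso(s.components, 2 * np.pi * f_hz)
                     for s in ensemble.solutions])
    print(f"E[D_iso]({f_hz:3d} Hz) = {med:.2e} m^2/s")
```

Output:

```
b = 2.000e+09 s/m^2, b_delta = -0.500, omega_cent/2pi = 924 Hz
E[D_iso]( 35 Hz) = 9.30e-10 m^2/s
E[D_iso](320 Hz) = 1.13e-09 m^2/s
```

The waveform realizes exactly the requested diffusion weighting and planar
tensor shape. The tumor-like voxel — generated from a closed-sphere
restricted-diffusion spectrum (local diffusivity 1.2e-9 m²/s, radius 7 µm)
— is recovered with the hallmark of restriction: the ensemble-median
isotropic diffusivity rises from ~0.93e-9 m²/s at 35 Hz to ~1.13e-9 m²/s at
320 Hz across the investigated frequency window (ground truth 0.84e-9 and
1.11e-9).

A command-line pipeline wraps the same functionality:

```sh
dwspectra simulate --preset tumor --protocol reduced --snr 100 --out sim/
dwspectra invert   --data sim/data.nii.gz --protocol reduced --out ens.h5
dwspectra maps     --ensembles ens.h5 --data sim/data.nii.gz \
                   --protocol reduced --out maps/
dwspectra compare  --data sim/data.nii.gz --protocol reduced --out cmp/
```

`compare` runs both inversion modes and writes residual comparisons and
normalized-difference maps.

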
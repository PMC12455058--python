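"""Tensor-valued encoding spectra b(omega) from gradient waveforms.

The diffusion weighting of a gradient waveform g(t) is described in the
frequency domain: the dephasing vector q(t) (time integral of the effective
gradient times the gyromagnetic ratio) is Fourier transformed to q(omega),
whose per-frequency outer product gives the tensor-valued encoding spectrum
b(omega).  Integrating b(omega) over frequency recovers the conventional
b-tensor, from which the scalar descriptors b (trace), b_delta (normalized
anisotropy), omega_cent (centroid frequency) and the orientation angles
(Theta, Phi) are derived.

Conventions
-----------
* Waveform samples sit on the uniform grid t_n = n*dt; cumulative integrals
  use the trapezoid rule on that grid.
* q(omega) = integral_0^tau q(t) exp(+i omega t) dt, evaluated by FFT with
  zero padding (>= 8x by default) to refine the frequency grid; the grid is
  two-sided and all omega-integrals are trapezoidal on it.
* b(omega) = q(omega) q(-omega)^T / (2 pi); for real g(t) this equals
  q(omega) conj(q(omega))^T / (2 pi), a Hermitian positive-semidefinite
  density whose real part is used in all scalar contractions.
* Eigenvalues of the b-tensor are labelled (b_XX, b_YY, b_ZZ) by the
  deviation-from-b/3 convention |b_ZZ - b/3| > |b_XX - b/3| > |b_YY - b/3|;
  ties in the XX/YY pair are broken by descending eigenvalue.  The ZZ
  eigenvector is sign-flipped into the upper hemisphere so that
  Theta in [0, pi/2] and Phi in (-pi, pi].

Strict SI units are used throughout (s m^-2, rad s^-1, T m^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

#: 1H gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_1H = 2.6752218744e8

#: Magic angle: cone half-angle for which cos^2 = 1/3.
_MAGIC_ANGLE = np.arccos(1.0 / np.sqrt(3.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientWaveform:
    """Uniformly sampled effective gradient vector g(t).

    Parameters
    ----------
    dt : float
        Sample spacing in seconds.
    samples : ndarray, shape (N, 3)
        Effective gradient in T m^-1 (sign-flipped after refocusing pulses).
    gamma : float
        Gyromagnetic ratio in rad s^-1 T^-1.
    """

    dt: float
    samples: np.ndarray
    gamma: float = GAMMA_1H

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ValueError("samples must have shape (N, 3)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if samples.shape[0] < 2:
            raise ValueError("waveform needs at least two samples")
        object.__setattr__(self, "samples", samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) * self.dt

    @property
    def duration(self) -> float:
        """Integration span tau of the waveform, seconds."""
        return (self.samples.shape[0] - 1) * self.dt

    def rotated(self, rotation: np.ndarray) -> "GradientWaveform":
        """Waveform with every gradient sample rotated by ``rotation`` (3x3)."""
        rotation = np.asarray(rotation, dtype=float)
        return replace(self, samples=self.samples @ rotation.T)


@dataclass(frozen=True)
class DephasingTrace:
    """Dephasing vector q(t) in rad m^-1 on the waveform's time grid."""

    times: np.ndarray
    q: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class EncodingSpectrum:
    """Tensor-valued encoding spectrum b(omega).

    ``density`` holds a 3x3 Hermitian PSD tensor per frequency in units of
    s m^-2 (rad s^-1)^-1 on the two-sided grid ``omega`` (rad s^-1).
    """

    omega: np.ndarray
    density: np.ndarray

    def trace(self) -> np.ndarray:
        """Encoding power spectrum b(omega) = trace{b(omega)} (real)."""
        return np.einsum("kii->k", self.density).real


@dataclass(frozen=True)
class AcquisitionEncoding:
    """Scalar encoding descriptors of one acquisition.

    Carries the integrated b-tensor, the derived scalars and the relaxation
    timing parameters (recovery time tau_r and echo time tau_e).  ``spectrum``
    is the full b(omega) density when the acquisition was built from a
    waveform, or ``None`` for table-only acquisitions (then ``omega_cent`` is
    taken from the table).
    """

    n_acq: int
    b_tensor: np.ndarray
    b: float
    b_delta: float
    omega_cent: float
    theta: float
    phi: float
    tau_r: float
    tau_e: float
    spectrum: EncodingSpectrum | None = None
    waveform_id: str | None = None


@dataclass
class Protocol:
    """Ordered list of acquisitions making up one measurement protocol."""

    acquisitions: list[AcquisitionEncoding] = field(default_factory=list)

    def __post_init__(self):
        if len(self.acquisitions) == 0:
            raise ValueError("protocol must contain at least one acquisition")
        ids = [a.n_acq for a in self.acquisitions]
        if len(set(ids)) != len(ids):
            raise ValueError("acquisition indices n_acq must be unique")

    def __len__(self) -> int:
        return len(self.acquisitions)

    def __iter__(self):
        return iter(self.acquisitions)

    def __getitem__(self, i):
        return self.acquisitions[i]

    @property
    def b(self) -> np.ndarray:
        return np.array([a.b for a in self.acquisitions])

    @property
    def omega_cent(self) -> np.ndarray:
        return np.array([a.omega_cent for a in self.acquisitions])

    @property
    def tau_r(self) -> np.ndarray:
        return np.array([a.tau_r for a in self.acquisitions])

    @property
    def tau_e(self) -> np.ndarray:
        return np.array([a.tau_e for a in self.acquisitions])


@dataclass(frozen=True)
class ProtocolSummary:
    """b-weighted omega_cent percentiles and total spectral content."""

    omega_10: float
    omega_50: float
    omega_90: float
    total_omega: np.ndarray | None = None
    total_spectral_content: np.ndarray | None = None


# ---------------------------------------------------------------------------
# spectral chain
# ---------------------------------------------------------------------------


def dephasing(waveform: GradientWaveform) -> DephasingTrace:
    """Dephasing vector q(t) = gamma * int_0^t g(t') dt' (trapezoid rule)."""
    q = waveform.gamma * cumulative_trapezoid(
        waveform.samples, dx=waveform.dt, axis=0, initial=0.0
    )
    return DephasingTrace(times=waveform.times, q=q)


def q_spectrum(trace: DephasingTrace, n_pad: int = 8):
    """Fourier transform q(omega) = int_0^tau q(t) exp(+i omega t) dt.

    Parameters
    ----------
    trace : DephasingTrace
    n_pad : int
        Zero-padding factor (>= 1); the FFT length is ``n_pad * len(q)``,
        refining the frequency grid accordingly.

    Returns
    -------
    omega : ndarray
        Two-sided angular frequency grid, rad s^-1, ascending.
    q_omega : ndarray, shape (len(omega), 3), complex
    """
    if n_pad < 1:
        raise ValueError("n_pad must be >= 1")
    dts = np.diff(trace.times)
    if not np.allclose(dts, dts[0], rtol=1e-9, atol=0.0):
        raise ValueError("dephasing trace must be uniformly sampled")
    n = trace.q.shape[0]
    n_fft = int(n_pad) * n
    # ifft carries the exp(+i omega t) sign convention used here
    q_omega = n_fft * trace.dt * np.fft.ifft(trace.q, n=n_fft, axis=0)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=trace.dt)
    order = np.fft.fftshift(np.arange(n_fft))
    return omega[order], q_omega[order]


def b_spectrum(omega: np.ndarray, q_omega: np.ndarray) -> EncodingSpectrum:
    """Encoding spectrum b(omega) = q(omega) q(-omega)^T / (2 pi).

    Assumes q(omega) is the transform of a real-valued q(t), so that
    q(-omega) = conj(q(omega)) and the density is Hermitian PSD.
    """
    density = np.einsum("ki,kj->kij", q_omega, np.conj(q_omega)) / (2.0 * np.pi)
    return EncodingSpectrum(omega=np.asarray(omega, float), density=density)


def integrate_b(spectrum: EncodingSpectrum) -> np.ndarray:
    """Integrated b-tensor b = int b(omega) domega (real symmetric 3x3)."""
    b = np.trapezoid(spectrum.density, spectrum.omega, axis=0)
    scale = max(np.abs(b.real).max(), 1e-300)
    if np.abs(b.imag).max() > 1e-8 * scale:
        raise ValueError("unexpectedly large imaginary residue in b-tensor")
    b = b.real
    return 0.5 * (b + b.T)


def encoding_scalars(b_tensor: np.ndarray, spectrum: EncodingSpectrum | None = None):
    """Scalar descriptors (b, b_delta, omega_cent, theta, phi) of a b-tensor.

    ``omega_cent`` is the |omega|-weighted centroid of trace{b(omega)} and
    requires ``spectrum``; it is returned as ``nan`` otherwise.  All scalars
    are ``nan`` for a zero tensor rather than fabricated.
    """
    b_tensor = np.asarray(b_tensor, dtype=float)
    b = float(np.trace(b_tensor))
    if b <= 0.0 or not np.isfinite(b):
        return b, np.nan, np.nan, np.nan, np.nan
    evals, evecs = np.linalg.eigh(b_tensor)
    dev = np.abs(evals - b / 3.0)
    i_zz = int(np.argmax(dev))
    rest = [i for i in range(3) if i != i_zz]
    # larger deviation -> XX; tie broken by descending eigenvalue
    if (dev[rest[0]], evals[rest[0]]) >= (dev[rest[1]], evals[rest[1]]):
        i_xx, i_yy = rest
    else:
        i_xx, i_yy = rest[1], rest[0]
    b_zz, b_xx, b_yy = evals[i_zz], evals[i_xx], evals[i_yy]
    b_delta = (b_zz - 0.5 * (b_yy + b_xx)) / b
    v = evecs[:, i_zz]
    if v[2] < 0:
        v = -v
    theta = float(np.arccos(np.clip(v[2], -1.0, 1.0)))
    phi = float(np.arctan2(v[1], v[0]))
    omega_cent = np.nan
    if spectrum is not None:
        tb = spectrum.trace()
        omega_cent = float(
            np.trapezoid(np.abs(spectrum.omega) * tb, spectrum.omega) / b
        )
    return b, float(b_delta), omega_cent, theta, phi


def acquisition_from_waveform(
    waveform: GradientWaveform,
    tau_r: float,
    tau_e: float,
    n_acq: int = 0,
    rotation: np.ndarray | None = None,
    n_pad: int = 8,
    waveform_id: str | None = None,
) -> AcquisitionEncoding:
    """Full chain: waveform (optionally rotated) -> AcquisitionEncoding."""
    if rotation is not None:
        waveform = waveform.rotated(rotation)
    trace = dephasing(waveform)
    omega, q_omega = q_spectrum(trace, n_pad=n_pad)
    spectrum = b_spectrum(omega, q_omega)
    b_tensor = integrate_b(spectrum)
    b, b_delta, omega_cent, theta, phi = encoding_scalars(b_tensor, spectrum)
    return AcquisitionEncoding(
        n_acq=n_acq,
        b_tensor=b_tensor,
        b=b,
        b_delta=b_delta,
        omega_cent=omega_cent,
        theta=theta,
        phi=phi,
        tau_r=tau_r,
        tau_e=tau_e,
        spectrum=spectrum,
        waveform_id=waveform_id,
    )


# ---------------------------------------------------------------------------
# double-rotation waveform generator
# ---------------------------------------------------------------------------


def double_rotation_waveform(
    n_osc: int,
    duration: float,
    b_delta_target: float,
    b_target: float,
    dt: float = 5e-6,
    gamma: float = GAMMA_1H,
    g_max: float = 3.0,
    n_turns: int = 4,
) -> GradientWaveform:
    """Self-refocusing waveform sweeping the q-vector on nested cones.

    The dephasing vector is q(t) = A(t) d(t) with amplitude envelope
    A(t) = sin(pi t/tau) cos(2 pi n_osc t/tau) (zero at both ends, so the
    waveform is self-refocusing, with n_osc sign reversals raising the
    spectral content) and direction d(t) on a cone of half-angle zeta about
    z whose azimuth advances by ``n_turns`` full turns uniformly in the
    cumulative q^2 measure.  That measure-uniform sweep makes the
    time-averaged direction dyadic exactly the cone average, so the cone
    angle fixes the b-tensor shape:

    * b_delta_target = 1   -> zeta = 0 (fixed axis, linear encoding),
    * b_delta_target = 0   -> zeta = magic angle (spherical encoding),
    * b_delta_target = -0.5 -> zeta = pi/2 (in-plane sweep, planar encoding).

    The gradient is the analytic-grid derivative of q divided by gamma, with
    a constant per-axis offset removed so the net gradient area (hence
    q(tau)) is exactly zero, and the amplitude rescaled so the realized
    b-value (time-domain integral of |q|^2) equals ``b_target``.

    Raises
    ------
    ValueError
        If the required amplitude exceeds ``g_max`` (the message states the
        required amplitude), or for an unsupported shape target.
    """
    if n_osc < 0 or int(n_osc) != n_osc:
        raise ValueError("n_osc must be a nonnegative integer")
    if duration <= 0 or dt <= 0 or duration < 10 * dt:
        raise ValueError("duration must be positive and well resolved by dt")
    shapes = {1.0: 0.0, 0.0: _MAGIC_ANGLE, -0.5: 0.5 * np.pi}
    if float(b_delta_target) not in shapes:
        raise ValueError("b_delta_target must be one of {-0.5, 0, 1}")
    zeta = shapes[float(b_delta_target)]

    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    tau = t[-1]
    envelope = np.sin(np.pi * t / tau) * np.cos(2.0 * np.pi * n_osc * t / tau)
    # azimuth uniform in the cumulative q^2 measure; integer turns null the
    # first and second circular moments of the sweep exactly
    cum = cumulative_trapezoid(envelope**2, dx=dt, initial=0.0)
    s = cum / cum[-1]
    psi = 2.0 * np.pi * n_turns * s
    direction = np.column_stack(
        [
            np.sin(zeta) * np.cos(psi),
            np.sin(zeta) * np.sin(psi),
            np.full(n, np.cos(zeta)),
        ]
    )
    q = envelope[:, None] * direction

    g = np.gradient(q, dt, axis=0) / gamma
    # remove per-axis DC so the reconstructed q(tau) vanishes identically
    g -= np.trapezoid(g, dx=dt, axis=0) / tau

    q_rec = gamma * cumulative_trapezoid(g, dx=dt, axis=0, initial=0.0)
    b_unit = np.trapezoid(np.einsum("ti,ti->t", q_rec, q_rec), dx=dt)
    scale = np.sqrt(b_target / b_unit)
    g *= scale
    g_req = float(np.max(np.linalg.norm(g, axis=1)))
    if g_req > g_max:
        raise ValueError(
            f"required gradient amplitude {g_req:.3f} T/m exceeds g_max={g_max} T/m"
        )
    return GradientWaveform(dt=dt, samples=g, gamma=gamma)


# ---------------------------------------------------------------------------
# protocol summary
# ---------------------------------------------------------------------------


def weighted_percentile(values: np.ndarray, weights: np.ndarray, p: float) -> float:
    """Step-rule weighted percentile.

    Values are sorted ascending; the percentile is the first value whose
    cumulative normalized weight reaches ``p`` (no interpolation).
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order]) / total
    idx = int(np.searchsorted(cum, p, side="left"))
    idx = min(idx, len(values) - 1)
    return float(values[order][idx])


def protocol_summary(
    protocol: Protocol, percentiles: Sequence[float] = (0.1, 0.5, 0.9)
) -> ProtocolSummary:
    """b-weighted omega_cent percentiles and total spectral content.

    The total spectral content is the sum of trace{b(omega)} over all
    acquisitions that carry a spectrum, interpolated onto the widest
    acquisition grid; ``None`` when no acquisition has a spectrum.
    """
    b = protocol.b
    wc = protocol.omega_cent
    if not np.any(b > 0):
        raise ValueError("protocol has no diffusion weighting (all b = 0)")
    q10, q50, q90 = (weighted_percentile(wc, b, p) for p in percentiles)

    spectra = [a.spectrum for a in protocol if a.spectrum is not None]
    total_omega = total = None
    if spectra:
        total_omega = max(spectra, key=lambda s: s.omega[-1]).omega
        total = np.zeros_like(total_omega)
        for s in spectra:
            total += np.interp(total_omega, s.omega, s.trace(), left=0.0, right=0.0)
    return ProtocolSummary(
        omega_10=q10,
        omega_50=q50,
        omega_90=q90,
        total_omega=total_omega,
        total_spectral_content=total,
    )
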
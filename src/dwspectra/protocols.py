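"""Synthetic acquisition protocols for the wide and narrow frequency ranges.

The raw measurement protocols these builders emulate are known only through
their summary characteristics, so the tables produced here are synthetic
stand-ins constructed to those characteristics:

* ``make_preclinical_protocol`` - wide-frequency microimaging protocol:
  1491 acquisitions from double-rotation waveforms with 0-5 oscillations at
  b-tensor anisotropies b_delta = -0.5, 0 and 1, b-values from 0.033e9 to
  4.25e9 s m^-2, recovery times 0.8-3.5 s, echo times 22-58 ms, and a
  b-weighted centroid-frequency distribution with percentiles
  omega_10/50/90 / 2pi = 35 / 190 / 320 Hz.  Waveform durations are solved
  numerically (per oscillation count and tensor shape) so each waveform
  family realizes its target centroid frequency, and the per-family b-value
  ladders are sized so the weighted percentiles land on the stated values.

* ``make_clinical_protocol`` - narrow-frequency whole-body protocol: 134
  volumes, b up to 3e9 s m^-2, tau_R 0.5-7.6 s, tau_E 33-150 ms, centroid
  frequencies between 5 and 11 Hz with percentiles 5 / 9 / 11 Hz.  The
  underlying numerically optimized waveforms are outside this package's
  scope, so the clinical table is record-only (no spectra): each record
  carries its centroid frequency and an axisymmetric b-tensor built from
  (b, b_delta, Theta, Phi).

* ``make_reduced_preclinical_protocol`` - a ~190-acquisition subset of the
  wide-frequency design (with full encoding spectra) sized for quick
  inversions.
"""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from . import encoding
from .encoding import (
    AcquisitionEncoding,
    EncodingSpectrum,
    GradientWaveform,
    Protocol,
    encoding_scalars,
)

_DT = 4e-6  # waveform sample spacing, s
_SHAPES = (-0.5, 0.0, 1.0)

# (n_osc, target centroid frequency Hz, ladder length, n rotations, b_max)
_PRECLINICAL_FAMILIES = (
    (0, 35.0, 8, 12, 4.25e9),
    (1, 110.0, 8, 12, 4.25e9),
    (2, 190.0, 8, 12, 4.25e9),
    (3, 320.0, 8, 12, 3.5e9),
    (4, 450.0, 7, 8, 1.2e9),
    (5, 600.0, 7, 8, 0.6e9),
)
_B_MIN = 0.033e9

_TAU_R_CYCLE = (0.8, 1.2, 2.0, 3.5)
_TAU_E_CYCLE = (0.022, 0.030, 0.040, 0.058)


def _omega_cent_fast(waveform: GradientWaveform, n_pad: int = 8) -> float:
    """Centroid frequency from |q(omega)|^2 without building the full
    tensor density (the trace of the density is |q|^2 / 2pi)."""
    trace = encoding.dephasing(waveform)
    omega, q_omega = encoding.q_spectrum(trace, n_pad=n_pad)
    power = np.einsum("ki,ki->k", q_omega, np.conj(q_omega)).real / (2 * np.pi)
    b = np.trapezoid(power, omega)
    return float(np.trapezoid(np.abs(omega) * power, omega) / b)


@lru_cache(maxsize=None)
def family_duration(n_osc: int, b_delta_target: float, target_hz: float, dt: float = _DT) -> float:
    """Waveform duration realizing the target centroid frequency.

    The centroid frequency decreases monotonically with duration at fixed
    oscillation count, so a bracketing root search on the duration suffices.
    """

    def excess(tau):
        wf = encoding.double_rotation_waveform(
            n_osc, tau, b_delta_target, 1e9, dt=dt, g_max=np.inf,
            n_turns=max(1, n_osc),
        )
        return _omega_cent_fast(wf) / (2 * np.pi) - target_hz

    return brentq(excess, 2.5e-3, 60e-3, xtol=1e-6)


def _truncate_spectrum(spec: EncodingSpectrum, mass: float = 1.0 - 1e-6) -> EncodingSpectrum:
    """Drop the far spectral tails (keeping the stated trace-mass fraction)."""
    tb = spec.trace()
    cum = np.cumsum(tb)
    cum /= cum[-1]
    lo = int(np.searchsorted(cum, (1 - mass) / 2))
    hi = int(np.searchsorted(cum, 1 - (1 - mass) / 2)) + 1
    lo, hi = max(lo - 1, 0), min(hi + 1, len(tb))
    return EncodingSpectrum(omega=spec.omega[lo:hi], density=spec.density[lo:hi])


@lru_cache(maxsize=None)
def _base_acquisition(n_osc: int, b_delta_target: float, target_hz: float, dt: float = _DT):
    """Unrotated unit-b acquisition (with truncated spectrum) for one family."""
    tau = family_duration(n_osc, b_delta_target, target_hz, dt)
    wf = encoding.double_rotation_waveform(
        n_osc, tau, b_delta_target, 1e9, dt=dt, g_max=np.inf, n_turns=max(1, n_osc)
    )
    acq = encoding.acquisition_from_waveform(
        wf, tau_r=np.nan, tau_e=np.nan,
        waveform_id=f"dr_n{n_osc}_bd{b_delta_target:+.1f}",
    )
    spectrum = _truncate_spectrum(acq.spectrum)
    # re-derive the b-tensor from the truncated spectrum so the stored
    # tensor and the stored density stay numerically identical integrals
    b_tensor = encoding.integrate_b(spectrum)
    b, b_delta, _, theta, phi = encoding_scalars(b_tensor)
    acq = replace(
        acq, spectrum=spectrum, b_tensor=b_tensor, b=b, b_delta=b_delta,
        theta=theta, phi=phi,
    )
    return acq, tau


def _rotation_set(n: int) -> list[np.ndarray]:
    """Deterministic well-spread rotations: map z onto Fibonacci-sphere
    directions on the upper hemisphere."""
    out = []
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for k in range(n):
        z = 1.0 - k / max(n, 2) * 0.98
        rho = np.sqrt(max(1.0 - z * z, 0.0))
        az = k * golden
        axis_to = np.array([rho * np.cos(az), rho * np.sin(az), z])
        zhat = np.array([0.0, 0.0, 1.0])
        v = np.cross(zhat, axis_to)
        s = np.linalg.norm(v)
        c = float(zhat @ axis_to)
        if s < 1e-12:
            out.append(np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0]))
            continue
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        out.append(np.eye(3) + vx + vx @ vx * ((1 - c) / s**2))
    return out


def _rotated_scaled(
    base: AcquisitionEncoding,
    rotation: np.ndarray,
    b_value: float,
    n_acq: int,
    tau_r: float,
    tau_e: float,
    with_spectrum: bool,
) -> AcquisitionEncoding:
    """Rotate and amplitude-scale a base acquisition without re-running the
    FFT chain (b is quadratic in amplitude; rotations commute with it)."""
    scale = b_value / base.b
    b_tensor = scale * rotation @ base.b_tensor @ rotation.T
    spectrum = None
    if with_spectrum and base.spectrum is not None:
        density = scale * np.einsum(
            "ij,kjl,ml->kim", rotation, base.spectrum.density, rotation
        )
        spectrum = EncodingSpectrum(omega=base.spectrum.omega, density=density)
    b, b_delta, _, theta, phi = encoding_scalars(b_tensor)
    return AcquisitionEncoding(
        n_acq=n_acq,
        b_tensor=b_tensor,
        b=b,
        b_delta=b_delta,
        omega_cent=base.omega_cent,
        theta=theta,
        phi=phi,
        tau_r=tau_r,
        tau_e=tau_e,
        spectrum=spectrum,
        waveform_id=base.waveform_id,
    )


def make_preclinical_protocol(with_spectra: bool = False, dt: float = _DT) -> Protocol:
    """Synthetic 1491-acquisition wide-frequency protocol (see module docs).

    ``with_spectra`` attaches the rotated encoding spectra to every
    acquisition (memory-heavy; scalars suffice for protocol summaries).
    """
    acqs = []
    n = 0
    for n_osc, target, ladder_len, n_rot, b_max in _PRECLINICAL_FAMILIES:
        ladder = np.geomspace(_B_MIN, b_max, ladder_len)
        rotations = _rotation_set(n_rot)
        for shape in _SHAPES:
            base, _tau = _base_acquisition(n_osc, shape, target, dt)
            for j, rot in enumerate(rotations):
                for b_val in ladder:
                    acqs.append(
                        _rotated_scaled(
                            base, rot, b_val, n,
                            _TAU_R_CYCLE[(n + j) % len(_TAU_R_CYCLE)],
                            _TAU_E_CYCLE[(n + 2 * j) % len(_TAU_E_CYCLE)],
                            with_spectra,
                        )
                    )
                    n += 1
    # three near-zero-b reference acquisitions (one per tensor shape)
    for shape in _SHAPES:
        base, _tau = _base_acquisition(0, shape, _PRECLINICAL_FAMILIES[0][1], dt)
        acqs.append(
            _rotated_scaled(base, np.eye(3), _B_MIN, n, 3.5, 0.022, with_spectra)
        )
        n += 1
    return Protocol(acqs)


def make_reduced_preclinical_protocol(dt: float = _DT) -> Protocol:
    """~190-acquisition wide-frequency protocol with full encoding spectra.

    Keeps the 35 / 190 / 320 Hz frequency anchors of the full design, a
    relaxation-encoding block at near-zero b, and 3 rotations per shape and
    b-value; sized for minutes-scale Monte Carlo inversions.
    """
    families = (
        (0, 35.0, (0.5e9, 1.5e9, 3.0e9, 4.25e9)),
        (2, 190.0, (0.5e9, 1.5e9, 3.0e9, 4.25e9)),
        (3, 320.0, (0.5e9, 1.5e9, 3.0e9)),
        (5, 600.0, (0.25e9, 0.6e9)),
    )
    rotations = _rotation_set(3)
    acqs = []
    n = 0
    # relaxation block: vary tau_R and tau_E at near-zero diffusion weighting
    base0, _ = _base_acquisition(0, 1.0, 35.0, dt)
    for tau_r in (0.3, 0.8, 1.5, 3.5):
        for tau_e in (0.013, 0.025, 0.045):
            acqs.append(_rotated_scaled(base0, np.eye(3), _B_MIN, n, tau_r, tau_e, True))
            n += 1
    for n_osc, target, ladder in families:
        for shape in _SHAPES:
            base, _tau = _base_acquisition(n_osc, shape, target, dt)
            for rot in rotations:
                for b_val in ladder:
                    acqs.append(_rotated_scaled(base, rot, b_val, n, 3.5, 0.025, True))
                    n += 1
    return Protocol(acqs)


# ---------------------------------------------------------------------------
# narrow-frequency (clinical-style) protocol
# ---------------------------------------------------------------------------

# per centroid-frequency level: (f_cent Hz, count, b-value cycle)
_CLINICAL_LEVELS = (
    (5.0, 24, (1.0e9, 2.0e9, 3.0e9)),
    (6.0, 16, (1.0e9, 2.0e9, 3.0e9)),
    (9.0, 40, (2.4e9, 3.0e9, 3.0e9)),
    (10.0, 24, (2.0e9, 3.0e9, 3.0e9)),
    (11.0, 24, (2.0e9, 3.0e9, 3.0e9)),
)
_CLINICAL_TAU_R = (0.5, 1.0, 2.0, 4.0, 7.6)
_CLINICAL_TAU_E = (0.033, 0.06, 0.09, 0.15)


def axisymmetric_b_tensor(b: float, b_delta: float, theta: float, phi: float) -> np.ndarray:
    """b-tensor with eigenvalues b(1+2 b_delta)/3 (axial, along (theta, phi))
    and b(1 - b_delta)/3 (radial, twofold)."""
    n = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    b_ax = b * (1.0 + 2.0 * b_delta) / 3.0
    b_rad = b * (1.0 - b_delta) / 3.0
    return b_rad * np.eye(3) + (b_ax - b_rad) * np.outer(n, n)


def make_clinical_protocol() -> Protocol:
    """Synthetic 134-volume narrow-frequency protocol (record-only).

    No gradient waveforms are attached (the originals are numerically
    optimized for whole-body hardware); each record carries b, b_delta,
    orientation, centroid frequency, tau_R and tau_E.
    """
    directions = _rotation_set(8)
    acqs = []
    n = 0
    for f_cent, count, b_cycle in _CLINICAL_LEVELS:
        for j in range(count):
            b_val = b_cycle[j % len(b_cycle)]
            b_delta = _SHAPES[j % len(_SHAPES)]
            rot = directions[j % len(directions)]
            axis = rot @ np.array([0.0, 0.0, 1.0])
            theta = float(np.arccos(np.clip(abs(axis[2]), -1, 1)))
            phi = float(np.arctan2(axis[1] * np.sign(axis[2]), axis[0] * np.sign(axis[2])))
            bt = axisymmetric_b_tensor(b_val, b_delta, theta, phi)
            acqs.append(
                AcquisitionEncoding(
                    n_acq=n,
                    b_tensor=bt,
                    b=b_val,
                    b_delta=b_delta,
                    omega_cent=2 * np.pi * f_cent,
                    theta=theta,
                    phi=phi,
                    tau_r=_CLINICAL_TAU_R[j % len(_CLINICAL_TAU_R)],
                    tau_e=_CLINICAL_TAU_E[j % len(_CLINICAL_TAU_E)],
                )
            )
            n += 1
    # six low-b reference volumes at the central frequency level
    for j in range(6):
        bt = axisymmetric_b_tensor(0.05e9, 1.0, 0.0, 0.0)
        acqs.append(
            AcquisitionEncoding(
                n_acq=n, b_tensor=bt, b=0.05e9, b_delta=1.0,
                omega_cent=2 * np.pi * 9.0, theta=0.0, phi=0.0,
                tau_r=_CLINICAL_TAU_R[j % len(_CLINICAL_TAU_R)],
                tau_e=_CLINICAL_TAU_E[j % len(_CLINICAL_TAU_E)],
            )
        )
        n += 1
    return Protocol(acqs)
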
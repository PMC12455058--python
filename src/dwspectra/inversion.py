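"""Per-voxel Monte Carlo inversion of diffusion-relaxation signals.

The signal equation is linear in the component weights once the nonlinear
parameters are fixed, so the estimation alternates stochastic search over
the nonlinear parameter space with non-negative least-squares (NNLS) weight
fits:

* proliferation: fresh candidates are drawn log-uniformly within the
  configured limits, pooled with the current survivors, and an NNLS fit
  discards every candidate receiving zero weight;
* mutation/extinction: survivors are jittered (log-uniform factors on the
  positive parameters, a capped random tilt on the orientation), the jittered
  copies compete with their parents in a refit, and zero-weight components
  go extinct;
* the final solution keeps the ``n_out`` largest-weight components.

Because the survivors always take part in every refit, the best residual
norm is non-increasing over rounds.  No Tikhonov regularization or sparsity
constraint is applied; uncertainty is quantified instead by bootstrap
replication (resampling acquisitions with replacement) and medians over the
replicate ensemble downstream.

Two modes are supported: ``omega_dependent`` estimates the full
[D_A, D_R, theta, phi, D_0, Gamma_A, Gamma_R, R_1, R_2] space against the
encoding spectra b(omega); ``static`` estimates the frequency-independent
[D_A, D_R, theta, phi, R_1, R_2] space against the integrated b-tensors.

All randomness flows from a single master seed: per-voxel and per-replicate
generators are spawned through ``numpy.random.SeedSequence``, which makes
serial and parallel execution bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls

from .dispersion import ComponentSet
from .encoding import Protocol

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterLimits:
    """Per-dimension sampling limits (SI units), all lower < upper."""

    d_min: float
    d_max: float
    gamma_min: float
    gamma_max: float
    r1_min: float
    r1_max: float
    r2_min: float
    r2_max: float

    def __post_init__(self):
        pairs = [
            (self.d_min, self.d_max),
            (self.gamma_min, self.gamma_max),
            (self.r1_min, self.r1_max),
            (self.r2_min, self.r2_max),
        ]
        if any(not (lo < hi) for lo, hi in pairs):
            raise ValueError("parameter limits must satisfy lower < upper")
        if self.d_min <= 0 or self.gamma_min <= 0 or self.r1_min <= 0 or self.r2_min <= 0:
            raise ValueError("limits must be positive (log-uniform sampling)")


#: Microimaging-system limits (wide frequency range).
PRECLINICAL_LIMITS = ParameterLimits(5e-12, 5e-9, 0.1, 1e5, 0.1, 4.0, 4.0, 150.0)
#: Whole-body-system limits (narrow frequency range).
CLINICAL_LIMITS = ParameterLimits(5e-11, 5e-9, 0.1, 1e4, 0.2, 2.0, 1.0, 30.0)

_PRESETS = {"preclinical": PRECLINICAL_LIMITS, "clinical": CLINICAL_LIMITS}


@dataclass(frozen=True)
class InversionConfig:
    """Monte Carlo inversion settings.

    Defaults are the full-scale settings (20 proliferation and 20
    mutation/extinction rounds, 200 input components per round, 10 output
    components, 100 bootstrap replicates); reduce them for quick runs.
    """

    mode: str = "omega_dependent"
    preset: str = "preclinical"
    n_proliferation: int = 20
    n_mutation: int = 20
    n_in: int = 200
    n_out: int = 10
    n_bootstrap: int = 100
    limits: ParameterLimits | None = None
    rng_seed: int = 0
    mutation_factor: float = 1.2
    mutation_angle: float = np.deg2rad(10.0)
    static_fraction: float = 0.25
    n_freq: int = 128
    s0_floor: float = 0.0

    def __post_init__(self):
        if self.mode not in ("omega_dependent", "static"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.limits is None:
            if self.preset not in _PRESETS:
                raise ValueError(f"unknown preset {self.preset!r}")
            object.__setattr__(self, "limits", _PRESETS[self.preset])
        if min(self.n_proliferation, self.n_mutation, self.n_in, self.n_out, self.n_bootstrap) < 1:
            raise ValueError("all iteration counts must be >= 1")

    def reduced(self, **kw) -> "InversionConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# vectorized forward model
# ---------------------------------------------------------------------------


class SignalModel:
    """Precomputed protocol arrays for fast kernel evaluation.

    The encoding spectra are resampled onto a common one-sided frequency
    grid of ``n_freq`` points (the real densities are even in omega, so
    one-sided integrals with doubled interior weights equal the two-sided
    trapezoids).  Acquisitions without spectra are treated as spectral
    lines at their centroid frequency, which is exact for dispersion-free
    components.
    """

    def __init__(self, protocol: Protocol, n_freq: int = 128):
        self.protocol = protocol
        n = len(protocol)
        self.b = protocol.b
        self.tau_r = protocol.tau_r
        self.tau_e = protocol.tau_e
        self.omega_cent = np.nan_to_num(protocol.omega_cent)

        # symmetric b-tensor in 6-vector form with off-diagonal duplicity,
        # so that beta = bt6 . [nx^2, ny^2, nz^2, nx ny, nx nz, ny nz]-style
        # contraction works as a plain dot product
        bt = np.stack([a.b_tensor for a in protocol])
        self.bt6 = np.stack(
            [
                bt[:, 0, 0],
                bt[:, 1, 1],
                bt[:, 2, 2],
                2 * bt[:, 0, 1],
                2 * bt[:, 0, 2],
                2 * bt[:, 1, 2],
            ],
            axis=1,
        )

        self.spec_idx = np.array(
            [i for i, a in enumerate(protocol) if a.spectrum is not None], dtype=int
        )
        self.line_idx = np.array(
            [i for i, a in enumerate(protocol) if a.spectrum is None], dtype=int
        )
        self.n_acq = n

        if self.spec_idx.size:
            omega_max = 0.0
            for i in self.spec_idx:
                s = protocol[i].spectrum
                tb = s.trace()
                cum = np.cumsum(tb * np.gradient(s.omega))
                total = cum[-1]
                pos = s.omega[np.searchsorted(cum, 0.9999 * total)]
                omega_max = max(omega_max, abs(pos))
            self.omega_grid = np.linspace(0.0, omega_max, n_freq)
            w_trap = np.full(n_freq, self.omega_grid[1] - self.omega_grid[0])
            w_trap[[0, -1]] *= 0.5
            w_trap *= 2.0  # two-sided integral of an even integrand

            btr_w = np.zeros((self.spec_idx.size, n_freq))
            b6_w = np.zeros((self.spec_idx.size, n_freq, 6))
            for j, i in enumerate(self.spec_idx):
                s = protocol[i].spectrum
                dens = s.density.real
                dens = 0.5 * (dens + np.swapaxes(dens, 1, 2))
                comps = [
                    dens[:, 0, 0],
                    dens[:, 1, 1],
                    dens[:, 2, 2],
                    2 * dens[:, 0, 1],
                    2 * dens[:, 0, 2],
                    2 * dens[:, 1, 2],
                ]
                for c, comp in enumerate(comps):
                    b6_w[j, :, c] = np.interp(
                        self.omega_grid, s.omega, comp, left=0.0, right=0.0
                    )
                b6_w[j] *= w_trap[:, None]
                btr_w[j] = b6_w[j, :, 0] + b6_w[j, :, 1] + b6_w[j, :, 2]
            self.btr_w = btr_w
            self.b6_w = b6_w
        else:
            self.omega_grid = np.zeros(0)
            self.btr_w = np.zeros((0, 0))
            self.b6_w = np.zeros((0, 0, 6))

    # -- kernels ----------------------------------------------------------

    @staticmethod
    def _nn6(theta, phi):
        st, ct = np.sin(theta), np.cos(theta)
        cp, sp = np.cos(phi), np.sin(phi)
        nx, ny, nz = st * cp, st * sp, ct
        return np.stack([nx * nx, ny * ny, nz * nz, nx * ny, nx * nz, ny * nz], axis=1)

    @staticmethod
    def _lorentz_complement(omega, gamma):
        # 1 - L(omega; gamma) = (omega/gamma)^2 / (1 + (omega/gamma)^2),
        # shape (M, K); gamma may be +inf (dispersion-free -> 0)
        with np.errstate(divide="ignore"):
            ratio = np.where(np.isinf(gamma)[:, None], 0.0, omega[None, :] / gamma[:, None])
        r2 = ratio**2
        return r2 / (1.0 + r2)

    def _beta_omega(self, cs: ComponentSet) -> np.ndarray:
        """Attenuation exponents, omega-dependent model, shape (A, M).

        The Lorentzian frequency integrals are written as the exact
        frequency-independent contraction (taken from the stored b-tensor)
        plus a dispersive correction integrated on the resampled grid, so
        dispersion-free components incur no resampling error at all.
        """
        nn6 = self._nn6(cs.theta, cs.phi)
        beta = np.zeros((self.n_acq, len(cs)))
        if self.spec_idx.size:
            m_r = self._lorentz_complement(self.omega_grid, cs.gamma_r)
            m_a = self._lorentz_complement(self.omega_grid, cs.gamma_a)
            j_r_tb = self.btr_w @ m_r.T  # (A_s, M): int (1-L_R) trace b(w) dw
            q_r = np.zeros_like(j_r_tb)
            q_a = np.zeros_like(j_r_tb)
            for c in range(6):
                q_r += (self.b6_w[:, :, c] @ m_r.T) * nn6[None, :, c]
                q_a += (self.b6_w[:, :, c] @ m_a.T) * nn6[None, :, c]
            b_spec = self.b[self.spec_idx]
            p_exact = self.bt6[self.spec_idx] @ nn6.T  # (A_s, M)
            dd_r = (cs.d_0 - cs.d_r)[None, :]
            dd_a = (cs.d_0 - cs.d_a)[None, :]
            # beta = D_R b + (D_A - D_R) p  +  dispersive corrections
            beta_s = (
                np.outer(b_spec, cs.d_r) + (cs.d_a - cs.d_r)[None, :] * p_exact
                + dd_r * (j_r_tb - q_r)
                + dd_a * q_a
            )
            beta[self.spec_idx] = beta_s
        if self.line_idx.size:
            wc = self.omega_cent[self.line_idx]
            m_r = self._lorentz_complement(wc, cs.gamma_r).T  # (A_l, M)
            m_a = self._lorentz_complement(wc, cs.gamma_a).T
            d_r_w = cs.d_r[None, :] + (cs.d_0 - cs.d_r)[None, :] * m_r
            d_a_w = cs.d_a[None, :] + (cs.d_0 - cs.d_a)[None, :] * m_a
            proj = self.bt6[self.line_idx] @ nn6.T
            beta_l = d_r_w * self.b[self.line_idx, None] + (d_a_w - d_r_w) * proj
            beta[self.line_idx] = beta_l
        return beta

    def _beta_static(self, cs: ComponentSet) -> np.ndarray:
        nn6 = self._nn6(cs.theta, cs.phi)
        proj = self.bt6 @ nn6.T
        return np.outer(self.b, cs.d_r) + (cs.d_a - cs.d_r)[None, :] * proj

    def kernel(self, cs: ComponentSet, mode: str) -> np.ndarray:
        """Signal kernel: rows = acquisitions, columns = unit-weight components."""
        if mode == "omega_dependent":
            beta = self._beta_omega(cs)
        elif mode == "static":
            beta = self._beta_static(cs)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        relax = (1.0 - np.exp(-np.outer(self.tau_r, cs.r_1))) * np.exp(
            -np.outer(self.tau_e, cs.r_2)
        )
        return np.exp(-np.clip(beta, 0.0, None)) * relax

    def signals(self, cs: ComponentSet, mode: str = "omega_dependent") -> np.ndarray:
        """Forward signal for a weighted component set (fast path)."""
        if len(cs) == 0:
            return np.zeros(self.n_acq)
        return self.kernel(cs, mode) @ cs.w


# ---------------------------------------------------------------------------
# candidate sampling and mutation
# ---------------------------------------------------------------------------


def _log_uniform(rng, lo, hi, n):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n))


def sample_candidates(config: InversionConfig, n: int, rng: np.random.Generator) -> ComponentSet:
    """Draw ``n`` candidates: log-uniform magnitudes, uniform hemisphere axes.

    In omega-dependent mode D_0 draws violating D_0 >= max(D_A, D_R) are
    clipped up to that bound, and a ``static_fraction`` share of the draws
    is placed at the upper Gamma limit (transition far above any measured
    frequency), so the frequency-independent subspace is always explicitly
    represented among the candidates.  In static mode the dispersion
    dimensions are fixed (Gamma = inf) so the candidate tensors are
    frequency-independent.
    """
    lim = config.limits
    d_a = _log_uniform(rng, lim.d_min, lim.d_max, n)
    d_r = _log_uniform(rng, lim.d_min, lim.d_max, n)
    theta = np.arccos(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(-np.pi, np.pi, n)
    r_1 = _log_uniform(rng, lim.r1_min, lim.r1_max, n)
    r_2 = _log_uniform(rng, lim.r2_min, lim.r2_max, n)
    if config.mode == "omega_dependent":
        d_0 = np.maximum(_log_uniform(rng, lim.d_min, lim.d_max, n), np.maximum(d_a, d_r))
        gamma_a = _log_uniform(rng, lim.gamma_min, lim.gamma_max, n)
        gamma_r = _log_uniform(rng, lim.gamma_min, lim.gamma_max, n)
        quasi_static = rng.uniform(0.0, 1.0, n) < config.static_fraction
        gamma_a[quasi_static] = lim.gamma_max
        gamma_r[quasi_static] = lim.gamma_max
        d_0[quasi_static] = np.maximum(d_a, d_r)[quasi_static]
    else:
        d_0 = np.maximum(d_a, d_r)
        gamma_a = np.full(n, np.inf)
        gamma_r = np.full(n, np.inf)
    return ComponentSet(
        w=np.zeros(n), d_a=d_a, d_r=d_r, theta=theta, phi=phi,
        d_0=d_0, gamma_a=gamma_a, gamma_r=gamma_r, r_1=r_1, r_2=r_2,
    )


def _tilt_axes(axes: np.ndarray, cap: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate each unit axis by a random angle <= cap about a random
    perpendicular direction."""
    n = axes.shape[0]
    alpha = rng.uniform(0.0, cap, n)
    raw = rng.normal(size=(n, 3))
    perp = raw - (np.einsum("ni,ni->n", raw, axes))[:, None] * axes
    norm = np.linalg.norm(perp, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    perp /= norm
    out = np.cos(alpha)[:, None] * axes + np.sin(alpha)[:, None] * perp
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def mutate(cs: ComponentSet, config: InversionConfig, rng: np.random.Generator) -> ComponentSet:
    """Jittered copies of the components, clipped to the configured limits."""
    lim = config.limits
    n = len(cs)
    lf = np.log(config.mutation_factor)

    def jitter(x, lo, hi):
        return np.clip(x * np.exp(rng.uniform(-lf, lf, n)), lo, hi)

    d_a = jitter(cs.d_a, lim.d_min, lim.d_max)
    d_r = jitter(cs.d_r, lim.d_min, lim.d_max)
    r_1 = jitter(cs.r_1, lim.r1_min, lim.r1_max)
    r_2 = jitter(cs.r_2, lim.r2_min, lim.r2_max)
    if config.mode == "omega_dependent":
        d_0 = np.maximum(jitter(cs.d_0, lim.d_min, lim.d_max), np.maximum(d_a, d_r))
        gamma_a = jitter(cs.gamma_a, lim.gamma_min, lim.gamma_max)
        gamma_r = jitter(cs.gamma_r, lim.gamma_min, lim.gamma_max)
    else:
        d_0 = np.maximum(d_a, d_r)
        gamma_a = np.full(n, np.inf)
        gamma_r = np.full(n, np.inf)
    axes = _tilt_axes(cs.axis, config.mutation_angle, rng)
    axes[axes[:, 2] < 0] *= -1.0  # fold to the upper hemisphere
    theta = np.arccos(np.clip(axes[:, 2], -1.0, 1.0))
    phi = np.arctan2(axes[:, 1], axes[:, 0])
    return ComponentSet(
        w=np.zeros(n), d_a=d_a, d_r=d_r, theta=theta, phi=phi,
        d_0=d_0, gamma_a=gamma_a, gamma_r=gamma_r, r_1=r_1, r_2=r_2,
    )


# ---------------------------------------------------------------------------
# weight fit
# ---------------------------------------------------------------------------


def fit_weights(kernel_matrix: np.ndarray, signals: np.ndarray) -> np.ndarray:
    """Non-negative least squares weights for the given kernel.

    All-zero columns (degenerate candidates) are excluded from the solve and
    assigned zero weight.
    """
    kernel_matrix = np.asarray(kernel_matrix, float)
    signals = np.asarray(signals, float)
    m = kernel_matrix.shape[1]
    w = np.zeros(m)
    if m == 0:
        return w
    keep = np.flatnonzero(kernel_matrix.any(axis=0))
    if keep.size == 0:
        return w
    sol, _ = nnls(kernel_matrix[:, keep], signals)
    w[keep] = sol
    return w


# ---------------------------------------------------------------------------
# per-voxel inversion
# ---------------------------------------------------------------------------


@dataclass
class VoxelSolution:
    """Fitted discrete distribution for one voxel (<= n_out components).

    ``rss_history`` records the residual sum of squares after each
    proliferation and mutation refit (diagnostic; non-increasing over the
    proliferation phase because survivors always re-enter the fit).
    """

    components: ComponentSet
    fitted: np.ndarray
    residual: np.ndarray
    rss: float
    rss_history: list = field(default_factory=list)


@dataclass
class BootstrapEnsemble:
    """Replicate solutions for one voxel with the resampled index sets."""

    solutions: list[VoxelSolution] = field(default_factory=list)
    indices: list[np.ndarray] = field(default_factory=list)

    def __len__(self):
        return len(self.solutions)


def invert_voxel(
    model: SignalModel,
    signals: np.ndarray,
    config: InversionConfig,
    rng: np.random.Generator,
    fit_rows: np.ndarray | None = None,
) -> VoxelSolution:
    """Monte Carlo inversion of one voxel's signal vector.

    ``fit_rows`` restricts the fit to a subset of acquisitions (used by the
    bootstrap); fitted signals and residuals are always reported on the full
    protocol.
    """
    signals = np.asarray(signals, float)
    if signals.shape[0] != model.n_acq:
        raise ValueError("signal vector length must match the protocol")
    rows = np.arange(model.n_acq) if fit_rows is None else np.asarray(fit_rows, int)

    history = []
    survivors = ComponentSet.empty()
    for _ in range(config.n_proliferation):
        fresh = sample_candidates(config, config.n_in, rng)
        cand = ComponentSet.concatenate([survivors, fresh])
        k = model.kernel(cand, config.mode)
        w = fit_weights(k[rows], signals[rows])
        history.append(float(np.sum((signals[rows] - k[rows] @ w) ** 2)))
        survivors = cand.with_weights(w).subset(w > 0)
    for _ in range(config.n_mutation):
        if len(survivors) == 0:
            break
        jittered = mutate(survivors, config, rng)
        cand = ComponentSet.concatenate([survivors, jittered])
        k = model.kernel(cand, config.mode)
        w = fit_weights(k[rows], signals[rows])
        history.append(float(np.sum((signals[rows] - k[rows] @ w) ** 2)))
        survivors = cand.with_weights(w).subset(w > 0)

    if len(survivors) > config.n_out:
        order = np.argsort(survivors.w)[::-1][: config.n_out]
        survivors = survivors.subset(np.sort(order))
        k = model.kernel(survivors, config.mode)
        w = fit_weights(k[rows], signals[rows])
        survivors = survivors.with_weights(w).subset(w > 0)

    fitted = model.signals(survivors, config.mode) if len(survivors) else np.zeros(model.n_acq)
    residual = signals - fitted
    rss = float(np.sum(residual[rows] ** 2))
    return VoxelSolution(
        components=survivors, fitted=fitted, residual=residual, rss=rss,
        rss_history=history,
    )


def voxel_seed_sequence(master_seed: int, voxel_index: int, replicate: int | None = None):
    """Stable per-voxel / per-replicate seed derivation."""
    entropy = [int(master_seed), int(voxel_index)]
    if replicate is not None:
        entropy.append(int(replicate))
    return np.random.SeedSequence(entropy)


def bootstrap_invert(
    model: SignalModel,
    signals: np.ndarray,
    config: InversionConfig,
    voxel_index: int = 0,
    full_first: bool = False,
) -> BootstrapEnsemble:
    """Bootstrap by resampling acquisitions with replacement.

    Each replicate resamples the acquisition indices (a multiset of the
    protocol length), runs :func:`invert_voxel` on the resampled rows with a
    replicate-derived seed, and stores the solution.  With ``full_first``
    the first replicate uses the full index set (no resampling), which makes
    a single-replicate ensemble coincide with a plain inversion.
    """
    ensemble = BootstrapEnsemble()
    n = model.n_acq
    for r in range(config.n_bootstrap):
        ss = voxel_seed_sequence(config.rng_seed, voxel_index, r)
        rng = np.random.default_rng(ss)
        if full_first and r == 0:
            idx = np.arange(n)
        else:
            idx = rng.integers(0, n, n)
        sol = invert_voxel(model, signals, config, rng, fit_rows=idx)
        ensemble.solutions.append(sol)
        ensemble.indices.append(idx)
    return ensemble


def residual_map(signals: np.ndarray, solution: VoxelSolution) -> np.ndarray:
    """(measured - back-calculated) / S0 per acquisition (nan when S0 = 0)."""
    s0 = solution.components.s0
    if s0 <= 0:
        return np.full(len(signals), np.nan)
    return (np.asarray(signals, float) - solution.fitted) / s0


def invert_volume(
    model: SignalModel,
    data: np.ndarray,
    config: InversionConfig,
    mask: np.ndarray | None = None,
    n_jobs: int = 1,
) -> dict[tuple, BootstrapEnsemble]:
    """Bootstrap-invert every masked voxel of a 4-D stack.

    ``data`` has shape (..., n_acq); the leading axes index voxels.  Voxels
    whose maximum signal falls below ``config.s0_floor`` are skipped.
    Per-voxel seeds derive from the flattened voxel index, so the result is
    independent of worker count.
    """
    shape = data.shape[:-1]
    if data.shape[-1] != model.n_acq:
        raise ValueError("data 4th dimension must match protocol length")
    if mask is None:
        mask = np.ones(shape, bool)
    voxels = [tuple(ix) for ix in np.argwhere(mask)]
    flat = {v: int(np.ravel_multi_index(v, shape)) for v in voxels}

    def run(v):
        sig = data[v]
        if sig.max() < config.s0_floor:
            return v, None
        return v, bootstrap_invert(model, sig, config, voxel_index=flat[v])

    if n_jobs == 1:
        results = [run(v) for v in voxels]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(run)(v) for v in voxels)
    return {v: ens for v, ens in results if ens is not None}
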
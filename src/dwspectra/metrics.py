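"""Derived quantities: projections, bins, meshes and parameter maps.

Each discrete component projects, at an evaluation frequency omega, onto the
isotropic diffusivity and squared normalized anisotropy

    D_iso(omega)    = (D_A(omega) + 2 D_R(omega)) / 3,
    D_Delta^2(omega) = ((D_A(omega) - D_R(omega)) / (D_A(omega) + 2 D_R(omega)))^2,

which span the 2-D plane used for visualization (64 x 64 mesh, Gaussian
deposition kernel), segmentation into three bins with white-matter-,
gray-matter- and CSF-like diffusion properties, and weighted means E[X].
Per-voxel map values are medians over the bootstrap replicates; frequency
dispersion within the investigated window is summarized as
(E[X(omega_90)] - E[X(omega_10)]) / ((omega_90 - omega_10)/2pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dispersion import ComponentSet, lorentzian_eigenvalue
from .inversion import BootstrapEnsemble

# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


def eigenvalues_at(cs: ComponentSet, omega: float):
    """(D_A(omega), D_R(omega)) arrays for every component of the set."""
    d_a = lorentzian_eigenvalue(omega, cs.d_a, cs.d_0, cs.gamma_a)
    d_r = lorentzian_eigenvalue(omega, cs.d_r, cs.d_0, cs.gamma_r)
    return d_a, d_r


def project_components(cs: ComponentSet, omega: float = 0.0):
    """(D_iso(omega), D_Delta^2(omega)) per component; nan where the trace
    vanishes."""
    d_a, d_r = eigenvalues_at(cs, omega)
    denom = d_a + 2.0 * d_r
    with np.errstate(divide="ignore", invalid="ignore"):
        d_iso = denom / 3.0
        d_delta2 = np.where(denom > 0.0, ((d_a - d_r) / denom) ** 2, np.nan)
    return d_iso, d_delta2


def project_component(component, omega: float = 0.0):
    """Scalar (D_iso(omega), D_Delta^2(omega)) for one component."""
    cs = ComponentSet.from_components([component])
    d_iso, d_delta2 = project_components(cs, omega)
    return float(d_iso[0]), float(d_delta2[0])


# ---------------------------------------------------------------------------
# bins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinDefinition:
    """Three-bin partition of the (D_iso, D_Delta^2) plane.

    bin1 (WM-like):  D_iso <= d_iso_split and D_Delta^2 > d_delta2_split
    bin2 (GM-like):  D_iso <= d_iso_split and D_Delta^2 <= d_delta2_split
    bin3 (CSF-like): D_iso > d_iso_split

    Equality goes to the lower-D_iso / lower-D_Delta^2 bin (the printed
    inequalities are strict and do not cover equality; this closure rule
    makes the partition exhaustive).
    """

    d_iso_split: float
    d_delta2_split: float = 0.25

    def assign(self, d_iso, d_delta2) -> np.ndarray:
        """Bin index (1, 2 or 3) per component."""
        d_iso = np.asarray(d_iso, float)
        d_delta2 = np.asarray(d_delta2, float)
        out = np.where(
            d_iso > self.d_iso_split, 3, np.where(d_delta2 > self.d_delta2_split, 1, 2)
        )
        return out


#: Ex vivo mouse-brain preset (D_iso split 1e-9 m^2 s^-1).
MOUSE_BINS = BinDefinition(1e-9)
#: In vivo human-brain preset (D_iso split 2e-9 m^2 s^-1).
HUMAN_BINS = BinDefinition(2e-9)


def s0(cs: ComponentSet) -> float:
    """Extrapolated signal S0 = sum of weights."""
    return cs.s0


def bin_fractions(cs: ComponentSet, bins: BinDefinition, omega: float = 0.0):
    """Signal fractions (f_bin1, f_bin2, f_bin3); nan triple when S0 = 0.

    For omega-dependent ensembles pass the evaluation frequency; for static
    ensembles omega = 0 reproduces the frequency-independent (D_A, D_R)
    values.
    """
    total = cs.s0
    if total <= 0.0:
        return np.full(3, np.nan)
    d_iso, d_delta2 = project_components(cs, omega)
    which = bins.assign(d_iso, d_delta2)
    return np.array([cs.w[which == k].sum() / total for k in (1, 2, 3)])


def rgb(fractions) -> np.ndarray:
    """Max-normalized [R, G, B] = f / max(f); nan triple when all zero."""
    f = np.asarray(fractions, float)
    top = np.nanmax(f)
    if not np.isfinite(top) or top <= 0:
        return np.full(3, np.nan)
    return f / top


# ---------------------------------------------------------------------------
# means and dispersion metrics
# ---------------------------------------------------------------------------


def ensemble_mean(cs: ComponentSet, values) -> float:
    """Weighted mean E[X] = sum(w X) / S0; nan when S0 = 0."""
    total = cs.s0
    if total <= 0.0:
        return np.nan
    return float(np.dot(cs.w, np.asarray(values, float)) / total)


def mean_d_iso(cs: ComponentSet, omega: float = 0.0) -> float:
    return ensemble_mean(cs, project_components(cs, omega)[0])


def mean_d_delta2(cs: ComponentSet, omega: float = 0.0) -> float:
    return ensemble_mean(cs, project_components(cs, omega)[1])


def dispersion_metric(e_at_omega90, e_at_omega10, omega_90, omega_10) -> float:
    """Frequency dispersion (E[X(w90)] - E[X(w10)]) / ((w90 - w10)/2pi),
    units of X per Hz."""
    if not omega_90 > omega_10:
        raise ValueError("omega_90 must exceed omega_10")
    return (e_at_omega90 - e_at_omega10) / ((omega_90 - omega_10) / (2.0 * np.pi))


def normalized_difference(y_omega_dependent, y_omega_independent) -> float:
    """Percent difference normalized by the pair mean."""
    denom = 0.5 * (y_omega_dependent + y_omega_independent)
    if denom == 0:
        raise ValueError("normalized difference undefined for zero-mean pair")
    return (y_omega_dependent - y_omega_independent) / denom * 100.0


def snr_estimate(s0_value: float, residuals) -> float:
    """S0 over the standard deviation of (measured - back-calculated)."""
    sd = float(np.std(np.asarray(residuals, float)))
    if sd == 0:
        return np.inf
    return s0_value / sd


# ---------------------------------------------------------------------------
# 2-D mesh projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeshConfig:
    """Axes of the (D_iso, D_Delta^2) projection mesh.

    D_iso is log10-spaced across the inversion limits; D_Delta^2 is linear
    on [0, 1]; the deposition kernel is a 3x3 truncated Gaussian with sigma
    of 0.75 grid spacings.
    """

    n_grid: int = 64
    log10_d_iso_min: float = np.log10(5e-12)
    log10_d_iso_max: float = np.log10(5e-9)
    d_delta2_min: float = 0.0
    d_delta2_max: float = 1.0
    kernel_sigma: float = 0.75

    @property
    def d_iso_axis(self) -> np.ndarray:
        return np.logspace(self.log10_d_iso_min, self.log10_d_iso_max, self.n_grid)

    @property
    def d_delta2_axis(self) -> np.ndarray:
        return np.linspace(self.d_delta2_min, self.d_delta2_max, self.n_grid)


@dataclass
class ProjectionMesh:
    """Weight grid over (D_iso, D_Delta^2); axis 0 = D_iso, axis 1 = D_Delta^2."""

    weights: np.ndarray
    config: MeshConfig
    omega: float

    @property
    def mass(self) -> float:
        return float(self.weights.sum())


def _kernel_3x3(sigma: float) -> np.ndarray:
    offs = np.arange(-1, 2)
    k = np.exp(-(offs[:, None] ** 2 + offs[None, :] ** 2) / (2.0 * sigma**2))
    return k / k.sum()


def mesh_projection(
    cs: ComponentSet, omega: float = 0.0, config: MeshConfig | None = None
) -> ProjectionMesh:
    """Deposit component weights on the 2-D mesh via the 3x3 Gaussian kernel.

    Components outside the axis ranges are clipped to the edge cells, and
    kernel spill beyond an edge is folded back onto the edge row/column so
    the total mesh mass equals the summed component weights.
    """
    config = config or MeshConfig()
    n = config.n_grid
    grid = np.zeros((n, n))
    if len(cs) == 0:
        return ProjectionMesh(weights=grid, config=config, omega=omega)
    d_iso, d_delta2 = project_components(cs, omega)
    x = (np.log10(np.clip(d_iso, 1e-300, None)) - config.log10_d_iso_min) / (
        config.log10_d_iso_max - config.log10_d_iso_min
    ) * (n - 1)
    y = (d_delta2 - config.d_delta2_min) / (
        config.d_delta2_max - config.d_delta2_min
    ) * (n - 1)
    ix = np.clip(np.rint(x).astype(int), 0, n - 1)
    iy = np.clip(np.rint(y).astype(int), 0, n - 1)
    kern = _kernel_3x3(config.kernel_sigma)
    for cx, cy, w in zip(ix, iy, cs.w):
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                gx = min(max(cx + dx, 0), n - 1)
                gy = min(max(cy + dy, 0), n - 1)
                grid[gx, gy] += w * kern[dx + 1, dy + 1]
    return ProjectionMesh(weights=grid, config=config, omega=omega)


def roi_projection(
    ensembles: dict, roi_voxels, omega: float = 0.0, config: MeshConfig | None = None
) -> ProjectionMesh:
    """Pooled mesh over an ROI: concatenate the components of every replicate
    of every masked voxel (weights scaled by 1/n_replicates) before meshing."""
    pools = []
    for v in roi_voxels:
        ens = ensembles.get(tuple(v))
        if ens is None:
            continue
        n_rep = max(len(ens), 1)
        for sol in ens.solutions:
            pools.append(sol.components.scaled_weights(1.0 / n_rep))
    if not pools:
        raise ValueError("empty ROI: no inverted voxels under the mask")
    return mesh_projection(ComponentSet.concatenate(pools), omega=omega, config=config)


# ---------------------------------------------------------------------------
# map assembly
# ---------------------------------------------------------------------------

MAP_NAMES = (
    "s0",
    "e_d_iso",
    "e_d_delta2",
    "e_r1",
    "e_r2",
    "f_bin1",
    "f_bin2",
    "f_bin3",
    "d_omega_e_d_iso",
    "d_omega_e_d_delta2",
    "snr",
)


def _replicate_scalars(sol, signals, omegas, bins):
    cs = cs_all = sol.components
    w10, w50, w90 = omegas
    vals = {"s0": cs.s0}
    vals["e_d_iso"] = mean_d_iso(cs, w50)
    vals["e_d_delta2"] = mean_d_delta2(cs, w50)
    vals["e_r1"] = ensemble_mean(cs, cs.r_1)
    vals["e_r2"] = ensemble_mean(cs, cs.r_2)
    f = bin_fractions(cs_all, bins, w50)
    vals["f_bin1"], vals["f_bin2"], vals["f_bin3"] = f
    if w90 > w10:
        vals["d_omega_e_d_iso"] = dispersion_metric(
            mean_d_iso(cs, w90), mean_d_iso(cs, w10), w90, w10
        )
        vals["d_omega_e_d_delta2"] = dispersion_metric(
            mean_d_delta2(cs, w90), mean_d_delta2(cs, w10), w90, w10
        )
    else:
        # static evaluation: no frequency window, dispersion is zero by
        # construction
        vals["d_omega_e_d_iso"] = 0.0
        vals["d_omega_e_d_delta2"] = 0.0
    vals["snr"] = snr_estimate(cs.s0, signals - sol.fitted) if cs.s0 > 0 else np.nan
    return vals


@dataclass
class ParameterMaps:
    """Voxel-wise maps (dict of name -> array of the volume shape)."""

    maps: dict
    omegas: tuple
    bins: BinDefinition

    def __getitem__(self, name):
        return self.maps[name]

    def rgb_volume(self) -> np.ndarray:
        """(..., 3) max-normalized bin-fraction composite."""
        f = np.stack([self.maps[f"f_bin{k}"] for k in (1, 2, 3)], axis=-1)
        top = np.nanmax(f, axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(top > 0, f / top, np.nan)


def map_assembly(
    ensembles: dict,
    data: np.ndarray,
    shape: tuple,
    omegas: tuple = (0.0, 0.0, 0.0),
    bins: BinDefinition = MOUSE_BINS,
    static: bool = False,
) -> ParameterMaps:
    """Medians over bootstrap replicates of the per-voxel scalar metrics.

    ``omegas`` are the (omega_10, omega_50, omega_90) evaluation frequencies
    of the protocol; for a static-mode inversion pass ``static=True`` (all
    metrics evaluated at the frequency-independent values, dispersion maps
    become zero by construction).
    """
    use_omegas = (0.0, 0.0, 0.0) if static else omegas
    maps = {name: np.full(shape, np.nan) for name in MAP_NAMES}
    for v, ens in ensembles.items():
        per_rep = {name: [] for name in MAP_NAMES}
        for sol in ens.solutions:
            vals = _replicate_scalars(sol, data[v], use_omegas, bins)
            for name in MAP_NAMES:
                per_rep[name].append(vals[name])
        for name in MAP_NAMES:
            arr = np.asarray(per_rep[name], float)
            if np.all(np.isnan(arr)):
                continue
            maps[name][v] = np.nanmedian(arr)
    return ParameterMaps(maps=maps, omegas=omegas, bins=bins)


def normalized_difference_maps(maps_omega: ParameterMaps, maps_static: ParameterMaps) -> dict:
    """Percent difference maps between omega-dependent and static results."""
    out = {}
    for name in ("s0", "e_d_iso", "e_d_delta2", "e_r1", "e_r2", "f_bin1", "f_bin2", "f_bin3"):
        a = maps_omega[name]
        b = maps_static[name]
        denom = 0.5 * (a + b)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(denom != 0, (a - b) / denom * 100.0, np.nan)
    return out
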
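"""File formats: waveforms, protocol tables, images, components, ensembles.

Plain-text formats are used wherever practical: waveforms as whitespace
tables with ``# dt`` / ``# gamma`` headers, protocols and component sets as
TSV (or JSON records), configuration as YAML.  Volumetric data (images,
masks, parameter maps) are NIfTI; per-voxel bootstrap ensembles go to an
HDF5 container (one group per voxel, one table per replicate, with a schema
version attribute).

Units at the I/O boundary follow common reporting practice: the protocol
table stores centroid frequencies in Hz (``omega_cent_hz``); everything
else is SI.  Internally everything is SI (rad s^-1, s m^-2).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .dispersion import ComponentSet
from .encoding import AcquisitionEncoding, GradientWaveform, Protocol, GAMMA_1H
from .inversion import BootstrapEnsemble, VoxelSolution
from .metrics import ParameterMaps
from .protocols import axisymmetric_b_tensor

ENSEMBLE_SCHEMA_VERSION = 1

PROTOCOL_COLUMNS = [
    "n_acq", "waveform_id", "theta", "phi", "psi",
    "b", "b_delta", "omega_cent_hz", "tau_r", "tau_e",
]

COMPONENT_COLUMNS = [
    "w", "d_a", "d_r", "theta", "phi", "d_0", "gamma_a", "gamma_r", "r_1", "r_2",
]


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------


def write_waveform(waveform: GradientWaveform, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# dt {waveform.dt:.17g}\n")
        fh.write(f"# gamma {waveform.gamma:.17g}\n")
        for gx, gy, gz in waveform.samples:
            fh.write(f"{gx:.17g} {gy:.17g} {gz:.17g}\n")


def read_waveform(path) -> GradientWaveform:
    path = Path(path)
    dt = gamma = None
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] in ("dt", "gamma"):
                if parts[0] == "dt":
                    dt = float(parts[1])
                else:
                    gamma = float(parts[1])
            continue
        vals = line.split()
        if len(vals) != 3:
            raise ValueError(f"waveform row must have 3 columns, got {line!r}")
        rows.append([float(v) for v in vals])
    if dt is None:
        raise ValueError("waveform file missing '# dt <seconds>' header")
    return GradientWaveform(
        dt=dt, samples=np.array(rows), gamma=gamma if gamma is not None else GAMMA_1H
    )


# ---------------------------------------------------------------------------
# protocol tables
# ---------------------------------------------------------------------------


def protocol_to_table(protocol: Protocol) -> pd.DataFrame:
    rows = []
    for a in protocol:
        rows.append(
            {
                "n_acq": a.n_acq,
                "waveform_id": a.waveform_id or "",
                "theta": a.theta,
                "phi": a.phi,
                "psi": 0.0,
                "b": a.b,
                "b_delta": a.b_delta,
                "omega_cent_hz": a.omega_cent / (2 * np.pi),
                "tau_r": a.tau_r,
                "tau_e": a.tau_e,
            }
        )
    return pd.DataFrame(rows, columns=PROTOCOL_COLUMNS)


def write_protocol(protocol: Protocol, path) -> None:
    """TSV (``.tsv``) or JSON-records (``.json``) protocol table."""
    path = Path(path)
    table = protocol_to_table(protocol)
    if path.suffix == ".json":
        path.write_text(table.to_json(orient="records", double_precision=15))
    else:
        table.to_csv(path, sep="\t", index=False)


def _table_to_protocol(table: pd.DataFrame) -> Protocol:
    required = {"n_acq", "b", "theta", "phi", "tau_r", "tau_e"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"protocol table missing columns: {sorted(missing)}")
    numeric = [c for c in PROTOCOL_COLUMNS if c != "waveform_id" and c in table.columns]
    if not np.all(np.isfinite(table[numeric].to_numpy(float))):
        raise ValueError("protocol table contains non-finite entries")
    acqs = []
    for _, row in table.iterrows():
        b = float(row["b"])
        b_delta = float(row.get("b_delta", 1.0))
        theta = float(row["theta"])
        phi = float(row["phi"])
        omega_cent = (
            2 * np.pi * float(row["omega_cent_hz"]) if "omega_cent_hz" in row else np.nan
        )
        acqs.append(
            AcquisitionEncoding(
                n_acq=int(row["n_acq"]),
                b_tensor=axisymmetric_b_tensor(b, b_delta, theta, phi),
                b=b,
                b_delta=b_delta,
                omega_cent=omega_cent,
                theta=theta,
                phi=phi,
                tau_r=float(row["tau_r"]),
                tau_e=float(row["tau_e"]),
                waveform_id=str(row.get("waveform_id", "")) or None,
            )
        )
    return Protocol(acqs)


def read_protocol(path) -> Protocol:
    """Protocol from a TSV/JSON table.

    b-tensors are reconstructed as axisymmetric tensors from (b, b_delta,
    theta, phi); centroid frequencies come from the ``omega_cent_hz``
    column.  Re-deriving them from waveform files instead is done with
    :func:`dwspectra.encoding.acquisition_from_waveform`.
    """
    path = Path(path)
    if path.suffix == ".json":
        table = pd.read_json(path, orient="records")
    else:
        table = pd.read_csv(path, sep="\t")
    return _table_to_protocol(table)


# ---------------------------------------------------------------------------
# component tables
# ---------------------------------------------------------------------------


def components_to_table(cs: ComponentSet) -> pd.DataFrame:
    return pd.DataFrame({c: getattr(cs, c) for c in COMPONENT_COLUMNS})


def write_components(cs: ComponentSet, path) -> None:
    components_to_table(cs).to_csv(Path(path), sep="\t", index=False)


def read_components(path) -> ComponentSet:
    table = pd.read_csv(Path(path), sep="\t")
    missing = set(COMPONENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"component table missing columns: {sorted(missing)}")
    return ComponentSet(**{c: table[c].to_numpy(float) for c in COMPONENT_COLUMNS})


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_image(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, np.float64), affine if affine is not None else np.eye(4)), str(path))


def read_image(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), float), img.affine


def read_dataset(image_path, protocol: Protocol, mask_path=None):
    """4-D image stack + optional mask, validated against the protocol.

    The image's 4th dimension must equal the protocol length; a mismatch is
    a schema error, never silent truncation.
    """
    data, affine = read_image(image_path)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D image, got shape {data.shape}")
    if data.shape[3] != len(protocol):
        raise ValueError(
            f"image has {data.shape[3]} volumes but protocol lists {len(protocol)}"
        )
    mask = None
    if mask_path is not None:
        mask, _ = read_image(mask_path)
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match image grid")
        mask = mask > 0
    return data, affine, mask


def write_maps(maps: ParameterMaps, out_dir, affine: np.ndarray | None = None,
               mode: str = "omega_dependent", bin_preset: str = "") -> None:
    """One NIfTI per metric, an RGB NIfTI, and a JSON sidecar with the
    evaluation frequencies, bin preset and inversion mode."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in maps.maps.items():
        write_image(arr, out_dir / f"{name}.nii.gz", affine)
    write_image(maps.rgb_volume(), out_dir / "rgb.nii.gz", affine)
    sidecar = {
        "omega_10_hz": maps.omegas[0] / (2 * np.pi),
        "omega_50_hz": maps.omegas[1] / (2 * np.pi),
        "omega_90_hz": maps.omegas[2] / (2 * np.pi),
        "bins": {"d_iso_split": maps.bins.d_iso_split, "d_delta2_split": maps.bins.d_delta2_split,
                 "preset": bin_preset},
        "mode": mode,
    }
    (out_dir / "maps.json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# ensembles (HDF5)
# ---------------------------------------------------------------------------


def save_ensembles(ensembles: dict, path) -> None:
    """Per-voxel bootstrap ensembles -> HDF5 (group per voxel, one component
    table and index set per replicate)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = ENSEMBLE_SCHEMA_VERSION
        for voxel, ens in ensembles.items():
            grp = fh.create_group("voxel_" + "_".join(str(i) for i in voxel))
            grp.attrs["voxel"] = list(voxel)
            for r, (sol, idx) in enumerate(zip(ens.solutions, ens.indices)):
                rep = grp.create_group(f"replicate_{r:03d}")
                table = np.column_stack(
                    [getattr(sol.components, c) for c in COMPONENT_COLUMNS]
                )
                rep.create_dataset("components", data=table)
                rep.create_dataset("indices", data=np.asarray(idx, np.int64))
                rep.create_dataset("fitted", data=sol.fitted)
                rep.create_dataset("residual", data=sol.residual)
                rep.attrs["rss"] = sol.rss


def load_ensembles(path) -> dict:
    out = {}
    with h5py.File(path, "r") as fh:
        if int(fh.attrs.get("schema_version", -1)) != ENSEMBLE_SCHEMA_VERSION:
            raise ValueError("unsupported ensemble container schema version")
        for key in fh:
            grp = fh[key]
            voxel = tuple(int(i) for i in grp.attrs["voxel"])
            ens = BootstrapEnsemble()
            for rep_key in sorted(grp):
                rep = grp[rep_key]
                tbl = np.asarray(rep["components"])
                cs = ComponentSet(
                    **{c: tbl[:, i] for i, c in enumerate(COMPONENT_COLUMNS)}
                )
                ens.solutions.append(
                    VoxelSolution(
                        components=cs,
                        fitted=np.asarray(rep["fitted"]),
                        residual=np.asarray(rep["residual"]),
                        rss=float(rep.attrs["rss"]),
                    )
                )
                ens.indices.append(np.asarray(rep["indices"]))
            out[voxel] = ens
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serializable pipeline configuration (YAML/JSON round-trip)."""

    protocol: str = ""
    images: str = ""
    mask: str = ""
    output: str = "out"
    mode: str = "omega_dependent"
    preset: str = "preclinical"
    bins: str = "mouse"
    seed: int = 0
    n_bootstrap: int = 100
    workers: int = 1
    inversion: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
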
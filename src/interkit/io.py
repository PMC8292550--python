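"""File formats: sensorgram CSVs with metadata sidecars, CD spectrum CSVs,
and coordinate frames from PDB (biotite) or PQR (MDAnalysis) files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contacts import Frame, Trajectory
from .errors import InvalidParameterError
from .kinetics import Sensorgram

__all__ = [
    "write_sensorgram_csv",
    "read_sensorgram_csv",
    "write_cd_csv",
    "read_cd_csv",
    "read_frames",
    "write_trajectory_pdb",
]

TIME_COL = "time_s"
RESP_COL = "response_RU"


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.yaml")


def write_sensorgram_csv(path, curve: Sensorgram) -> Path:
    """Write time/response columns plus a YAML metadata sidecar."""
    path = Path(path)
    pd.DataFrame({TIME_COL: curve.time, RESP_COL: curve.response}).to_csv(
        path, index=False, float_format="%.10g"
    )
    meta = {
        "concentration_M": float(curve.concentration),
        "label": curve.label,
    }
    if curve.phase_marks is not None:
        meta["t_inject_s"] = float(curve.t_inject)
        meta["t_dissoc_start_s"] = float(curve.t_dissoc_start)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_sensorgram_csv(path, concentration: float | None = None) -> Sensorgram:
    """Read a sensorgram CSV; metadata comes from the sidecar when present."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in (TIME_COL, RESP_COL):
        if col not in df.columns:
            raise InvalidParameterError(f"{path} lacks required column {col!r}")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    if concentration is None:
        concentration = float(meta.get("concentration_M", 0.0))
    time = df[TIME_COL].to_numpy(dtype=float)
    marks = None
    if "t_inject_s" in meta and "t_dissoc_start_s" in meta:
        i0 = int(np.argmin(np.abs(time - meta["t_inject_s"])))
        i1 = int(np.argmin(np.abs(time - meta["t_dissoc_start_s"])))
        marks = (i0, i1)
    return Sensorgram(
        time=time,
        response=df[RESP_COL].to_numpy(dtype=float),
        concentration=concentration,
        phase_marks=marks,
        label=str(meta.get("label", path.stem)),
    )


def write_cd_csv(path, spectrum) -> Path:
    path = Path(path)
    cols = {"wavelength_nm": spectrum.wavelength, "cd_mdeg": spectrum.raw_cd}
    if spectrum.theta is not None:
        cols["theta_deg_cm2_dmol"] = spectrum.theta
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    return path


def read_cd_csv(path, n_residues: int, path_length: float, concentration: float):
    from .cd_spectra import CDSpectrum

    df = pd.read_csv(path)
    return CDSpectrum(
        wavelength=df["wavelength_nm"].to_numpy(dtype=float),
        raw_cd=df["cd_mdeg"].to_numpy(dtype=float),
        n_residues=n_residues,
        path_length=path_length,
        concentration=concentration,
    )


# ---------------------------------------------------------------------------
# coordinate frames


def _tags_from_chains(chain_ids: np.ndarray, chain_a: str | None,
                      chain_b: str | None) -> np.ndarray:
    uniq = list(dict.fromkeys(chain_ids.tolist()))
    if chain_a is None or chain_b is None:
        if len(uniq) != 2:
            raise InvalidParameterError(
                f"expected exactly two chains, found {uniq}; pass chain_a/chain_b"
            )
        chain_a, chain_b = uniq
    tags = np.empty(len(chain_ids), dtype="<U1")
    tags[chain_ids == chain_a] = "A"
    tags[chain_ids == chain_b] = "B"
    if not np.all((tags == "A") | (tags == "B")):
        raise InvalidParameterError("atoms outside the two selected chains present")
    return tags


def read_frames(path, chain_a: str | None = None,
                chain_b: str | None = None) -> Trajectory:
    """Read a (multi-MODEL) PDB or a PQR file into a Trajectory.

    PQR input additionally provides per-atom partial charges.
    """
    path = Path(path)
    if path.suffix.lower() == ".pqr":
        return _read_pqr(path, chain_a, chain_b)
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    frames = []
    for i in range(stack.stack_depth()):
        arr = stack[i]
        tags = _tags_from_chains(arr.chain_id, chain_a, chain_b)
        frames.append(
            Frame(
                positions=arr.coord,
                residue_names=arr.res_name,
                residue_numbers=arr.res_id,
                molecule_tags=tags,
                frame_index=i,
            )
        )
    return Trajectory(frames)


def _read_pqr(path: Path, chain_a: str | None, chain_b: str | None) -> Trajectory:
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    atoms = u.atoms
    chain_ids = np.asarray(
        atoms.chainIDs if hasattr(atoms, "chainIDs") else atoms.segids
    )
    if np.all(chain_ids == "") or len(set(chain_ids.tolist())) < 2:
        chain_ids = np.asarray(atoms.segids)
    tags = _tags_from_chains(chain_ids, chain_a, chain_b)
    frames = [
        Frame(
            positions=atoms.positions.copy(),
            residue_names=atoms.resnames,
            residue_numbers=atoms.resids,
            molecule_tags=tags,
            charges=atoms.charges.copy(),
            frame_index=0,
        )
    ]
    return Trajectory(frames)


def write_trajectory_pdb(path, trajectory: Trajectory) -> Path:
    """Write frames as a multi-MODEL PDB (chains A/B from molecule tags)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    n = len(trajectory[0])
    arrays = []
    for frame in trajectory:
        arr = struc.AtomArray(n)
        arr.coord = frame.positions
        arr.chain_id = frame.molecule_tags.astype("<U4")
        arr.res_id = frame.residue_numbers
        arr.res_name = frame.residue_names.astype("<U5")
        arr.atom_name = np.array(
            [f"C{j % 100}" for j in range(n)], dtype="<U6"
        )
        arr.element = np.full(n, "C", dtype="<U2")
        arr.hetero = np.zeros(n, dtype=bool)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    return path
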
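"""Readers and writers for external formats.

Structures come in as PDB or mmCIF (parsed with gemmi), trajectories as
multi-model PDB or XYZ-plus-topology, tabular assay data as headed CSV and
spectra as two-column text. Downstream modules never touch files directly.

Unit conventions are declared in column headers: concentration columns are
``conc_M`` / ``conc_nM`` / ... and are converted to molar on read; an unknown
unit suffix is an error, never a guess. Wavenumbers are cm^-1.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .structures import AtomRecord, StructureModel, Trajectory

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory_pdb",
    "write_xyz",
    "read_table",
    "write_spectrum",
    "TABLE_SCHEMAS",
]

_CONC_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


# ---------------------------------------------------------------------------
# structures


def _convert_gemmi_model(model: gemmi.Model, model_id: int) -> StructureModel:
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            icode = res.seqid.icode.strip()
            for atom in res:
                if atom.altloc not in ("\0", "", "A"):
                    continue  # keep only the first altloc
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        is_hetero=is_het,
                        insertion_code=icode,
                    )
                )
    if not atoms:
        raise ValueError(f"model {model_id} contains no atoms")
    return StructureModel(atoms, model_id=model_id)


def _read_gemmi(path: str, format: str) -> gemmi.Structure:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown structure format {format!r}")
    try:
        st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path} contains no models")
    return st


def read_structure(
    path: str, format: str = "auto", model_index: int = 0
) -> StructureModel:
    """Read one model from a PDB or mmCIF file.

    Hetero records (ligands, waters) are retained with ``is_hetero=True``;
    only the first altloc of each atom is kept.
    """
    st = _read_gemmi(path, format)
    if model_index >= len(st):
        raise IndexError(
            f"model index {model_index} out of range ({len(st)} models)"
        )
    return _convert_gemmi_model(st[model_index], model_index + 1)


def _to_gemmi_structure(models: Sequence[StructureModel]) -> gemmi.Structure:
    st = gemmi.Structure()
    for i, m in enumerate(models, start=1):
        gm = gemmi.Model(i)
        chains: dict[str, gemmi.Chain] = {}
        chain_order: list[str] = []
        cur_res_key = None
        cur_res = None
        for a in m.atoms:
            if a.chain_id not in chains:
                chains[a.chain_id] = gemmi.Chain(a.chain_id)
                chain_order.append(a.chain_id)
                cur_res_key = None
            key = a.residue_key
            if key != cur_res_key:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
                res.het_flag = "H" if a.is_hetero else "A"
                # add_residue returns a reference to the stored residue
                cur_res = chains[a.chain_id].add_residue(res)
                cur_res_key = key
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.position)
            cur_res.add_atom(atom)
        # gemmi add_* copies by value, so chains go in only once complete
        for name in chain_order:
            gm.add_chain(chains[name])
        st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str, format: str = "auto") -> None:
    """Write a model as PDB or mmCIF (format inferred from extension)."""
    if format == "auto":
        format = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    st = _to_gemmi_structure([model])
    if format == "pdb":
        st.write_pdb(path)
    elif format == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown structure format {format!r}")


# ---------------------------------------------------------------------------
# trajectories


def _read_xyz_frames(path: str) -> tuple[list[str], np.ndarray]:
    """Parse a multi-frame XYZ file -> (element symbols, (F, N, 3) array)."""
    frames: list[np.ndarray] = []
    elements: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(
                f"{path}: expected atom count at line {i + 1}"
            ) from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(
                f"{path}: frame {frame_no} truncated "
                f"(expected {n} atom lines)"
            )
        coords = np.empty((n, 3))
        syms = []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: malformed atom line {i + 3 + j}"
                )
            syms.append(parts[0])
            coords[j] = [float(x) for x in parts[1:4]]
        if not elements:
            elements = syms
        elif len(syms) != len(elements):
            raise ValueError(
                f"{path}: frame {frame_no} has {len(syms)} atoms, "
                f"expected {len(elements)}"
            )
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return elements, np.stack(frames)


def read_trajectory(
    paths: str | Sequence[str],
    topology: StructureModel | None = None,
    frame_interval: float = 10.0,
) -> Trajectory:
    """Read a trajectory from multi-model PDB file(s) or XYZ series.

    Atom identities come from ``topology`` when given, otherwise from the
    first model of the first file. Frames keep file order.
    """
    if isinstance(paths, str):
        paths = [paths]
    frames: list[np.ndarray] = []
    frame_idx = 0
    for path in paths:
        if path.endswith(".xyz"):
            if topology is None:
                raise ValueError("XYZ trajectories require a topology")
            _, coords = _read_xyz_frames(path)
            for f in coords:
                frame_idx += 1
                if f.shape[0] != len(topology):
                    raise ValueError(
                        f"frame {frame_idx}: {f.shape[0]} atoms, topology "
                        f"has {len(topology)}"
                    )
                frames.append(f)
        else:
            st = _read_gemmi(path, "auto")
            for gm in st:
                frame_idx += 1
                model = _convert_gemmi_model(gm, frame_idx)
                if topology is None:
                    topology = model
                if len(model) != len(topology):
                    raise ValueError(
                        f"frame {frame_idx}: {len(model)} atoms, topology "
                        f"has {len(topology)}"
                    )
                frames.append(model.positions())
    if topology is None or not frames:
        raise ValueError("no frames read")
    return Trajectory(topology, np.stack(frames), frame_interval)


def write_trajectory_pdb(traj: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    models = [traj.frame_model(i) for i in range(traj.n_frames)]
    st = _to_gemmi_structure(models)
    st.write_pdb(path)


def write_xyz(traj: Trajectory, path: str) -> None:
    elements = [a.element for a in traj.topology.atoms]
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {i + 1}\n")
            for el, (x, y, z) in zip(elements, traj.frames[i]):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# tables

#: required columns per schema; a column written ``conc_<unit>`` matches
#: the ``conc_M`` slot and is converted to molar.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "dose_response": ["ligand", "pathway", "construct", "conc_M", "response", "replicate"],
    "kinetic_luminescence": ["well", "time_s", "counts", "construct", "ligand", "conc_M", "replicate"],
    "binding": ["mode", "conc_M", "counts_total", "counts_nonspecific", "replicate"],
    "spectrum": ["wavenumber_cm-1", "absorbance"],
}

_NUMERIC_COLS = {
    "conc_M", "response", "time_s", "counts", "counts_total",
    "counts_nonspecific", "wavenumber_cm-1", "absorbance",
}


def _coerce_numeric(df: pd.DataFrame, col: str, path: str) -> None:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based + header line
        raise ValueError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
            f"{col!r} at line {row}"
        )
    df[col] = coerced


def read_table(path: str, schema: str) -> pd.DataFrame:
    """Read a CSV matching one of the named schemas.

    Concentration columns are normalized to molar (column ``conc_M``);
    spectrum grids are re-ordered ascending in wavenumber.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(
            f"unknown schema {schema!r}; expected one of {sorted(TABLE_SCHEMAS)}"
        )
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]

    # resolve the concentration column and its declared unit
    required = list(TABLE_SCHEMAS[schema])
    if "conc_M" in required and "conc_M" not in df.columns:
        cand = [c for c in df.columns if c.startswith("conc_")]
        if len(cand) == 1:
            unit = cand[0][len("conc_"):]
            if unit not in _CONC_FACTORS:
                raise ValueError(
                    f"{path}: unknown concentration unit suffix {unit!r} "
                    f"(expected one of {sorted(_CONC_FACTORS)})"
                )
            _coerce_numeric(df, cand[0], path)
            df = df.rename(columns={cand[0]: "conc_M"})
            df["conc_M"] = df["conc_M"] * _CONC_FACTORS[unit]

    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing} for schema "
            f"{schema!r}; expected {required}"
        )
    for col in required:
        if col in _NUMERIC_COLS:
            _coerce_numeric(df, col, path)

    if schema == "spectrum":
        df = df.sort_values("wavenumber_cm-1", kind="stable").reset_index(drop=True)
    return df[required + [c for c in df.columns if c not in required]]


def write_spectrum(df: pd.DataFrame, path: str) -> None:
    df[["wavenumber_cm-1", "absorbance"]].to_csv(path, index=False)
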
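"""Rigid-body superposition and distance measurements on structure models.

"Backbone" means the N, CA, C, O atoms; residues are matched between models
by chain id + author residue number (+ insertion code), never by sequence
alignment. The optimal rigid transform is the least-squares (Kabsch)
solution; distances use heavy atoms only. Summaries round to 0.1 A, machine
output keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structures import StructureModel

__all__ = [
    "BACKBONE_ATOMS",
    "Superposition",
    "superpose",
    "residue_ligand_contacts",
    "named_distance",
    "parse_atom_spec",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Superposition:
    """A fitted rigid transform mobile -> target and its RMSD."""

    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # 3-vector, Angstrom
    rmsd: float
    n_pairs: int
    n_dropped: int
    selection: str

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def apply(self, model: StructureModel) -> StructureModel:
        return model.with_positions(self.transform(model.positions()))

    def summary(self) -> str:
        return (
            f"Superposition ({self.selection})\n"
            f"  atom pairs : {self.n_pairs}"
            + (f" ({self.n_dropped} unmatched dropped)\n" if self.n_dropped else "\n")
            + f"  RMSD       : {self.rmsd:.1f} A ({self.rmsd:.4f})"
        )


def _matched_pairs(
    mobile: StructureModel,
    target: StructureModel,
    atom_names: tuple[str, ...],
    chain: str | None,
    residue_range: tuple[int, int] | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    def index(model: StructureModel) -> dict[tuple, int]:
        out = {}
        for i, a in enumerate(model.atoms):
            if a.is_hetero or not a.is_heavy:
                continue
            if atom_names and a.atom_name not in atom_names:
                continue
            if chain is not None and a.chain_id != chain:
                continue
            if residue_range is not None and not (
                residue_range[0] <= a.residue_number <= residue_range[1]
            ):
                continue
            out[(a.chain_id, a.residue_number, a.insertion_code, a.atom_name)] = i
        return out

    mi = index(mobile)
    ti = index(target)
    common = sorted(set(mi) & set(ti))
    dropped = len(set(mi) ^ set(ti))
    if not common:
        raise ValueError("no matched atom pairs under the given selection")
    mpos = mobile.positions()[[mi[k] for k in common]]
    tpos = target.positions()[[ti[k] for k in common]]
    return mpos, tpos, dropped


def superpose(
    mobile: StructureModel,
    target: StructureModel,
    atom_names: tuple[str, ...] = BACKBONE_ATOMS,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
) -> Superposition:
    """Least-squares rigid superposition of matched atoms.

    Atoms are paired by (chain, author residue number, insertion code,
    atom name); counterparts missing on either side are dropped pairwise
    and counted. Needs >= 3 non-collinear pairs.
    """
    mpos, tpos, dropped = _matched_pairs(
        mobile, target, atom_names, chain, residue_range
    )
    if len(mpos) < 3:
        raise ValueError(f"need >= 3 matched atom pairs, got {len(mpos)}")
    mc = mpos.mean(axis=0)
    tc = tpos.mean(axis=0)
    m0 = mpos - mc
    t0 = tpos - tc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        raise ValueError("matched atoms are collinear; transform underdetermined")
    rot, _ = Rotation.align_vectors(t0, m0)
    R = rot.as_matrix()
    translation = tc - R @ mc
    moved = m0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - t0) ** 2, axis=1))))
    sel = f"atoms={','.join(atom_names)}"
    if chain is not None:
        sel += f" chain={chain}"
    if residue_range is not None:
        sel += f" residues={residue_range[0]}-{residue_range[1]}"
    return Superposition(R, translation, rmsd, len(mpos), dropped, sel)


def residue_ligand_contacts(
    model: StructureModel, ligand: str, cutoff: float = 4.0
) -> pd.DataFrame:
    """Per-residue minimum heavy-atom distance to a hetero ligand.

    Columns: chain, resnum, resname, min_distance, within_cutoff.
    """
    lig_idx = model.select_indices(residue_name=ligand, hetero=True, heavy_only=True)
    if not lig_idx:
        raise ValueError(
            f"ligand {ligand!r} not found; hetero residues present: "
            f"{model.hetero_residue_names()}"
        )
    pos = model.positions()
    lig = pos[lig_idx]
    rows = []
    for key, name, idx in model.residues():
        heavy = [
            i for i in idx
            if model.atoms[i].is_heavy and not model.atoms[i].is_hetero
        ]
        if not heavy:
            continue
        d = np.linalg.norm(pos[heavy][:, None, :] - lig[None, :, :], axis=-1)
        dmin = float(d.min())
        rows.append(
            {"chain": key[0], "resnum": key[1], "resname": name,
             "min_distance": dmin, "within_cutoff": dmin <= cutoff}
        )
    out = pd.DataFrame(rows)
    out.attrs["cutoff"] = cutoff
    return out


def parse_atom_spec(spec: str) -> tuple[str, int, str]:
    """Parse "chain/resnum/atom" (e.g. "R/312/OH")."""
    parts = spec.split("/")
    if len(parts) != 3:
        raise ValueError(f"atom spec {spec!r} is not 'chain/resnum/atom'")
    return parts[0], int(parts[1]), parts[2]


def named_distance(
    model: StructureModel,
    atom_a: str,
    atom_b: str | None = None,
    to_ligand: str | None = None,
) -> float:
    """Distance (A) from a named atom to another atom or to the nearest
    ligand heavy atom.

    ``atom_a``/``atom_b`` are "chain/resnum/atom" specs; give ``to_ligand``
    (a hetero residue name) instead of ``atom_b`` for nearest-heavy-atom
    mode.
    """
    ca, ra, na = parse_atom_spec(atom_a)
    try:
        ia = model.atom_index(ca, ra, na)
    except KeyError as exc:
        raise ValueError(f"cannot resolve atom spec {atom_a!r}: {exc}") from exc
    pa = np.asarray(model.atoms[ia].position)
    if (atom_b is None) == (to_ligand is None):
        raise ValueError("give exactly one of atom_b or to_ligand")
    if atom_b is not None:
        cb, rb, nb = parse_atom_spec(atom_b)
        try:
            ib = model.atom_index(cb, rb, nb)
        except KeyError as exc:
            raise ValueError(f"cannot resolve atom spec {atom_b!r}: {exc}") from exc
        pb = np.asarray(model.atoms[ib].position)
        return float(np.linalg.norm(pa - pb))
    lig_idx = model.select_indices(residue_name=to_ligand, hetero=True, heavy_only=True)
    if not lig_idx:
        raise ValueError(
            f"ligand {to_ligand!r} not found; hetero residues present: "
            f"{model.hetero_residue_names()}"
        )
    lig = model.positions()[lig_idx]
    return float(np.linalg.norm(lig - pa, axis=1).min())
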
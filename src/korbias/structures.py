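"""In-memory containers for structures and trajectories.

Coordinates are in Angstrom throughout and residues keep author numbering
(the Ballesteros-Weinstein residue map shipped with the package refers to
author numbers). Hydrogens are kept on read; "heavy atom" selections simply
exclude element H.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = ["AtomRecord", "StructureModel", "Trajectory", "ResidueKey"]

#: (chain_id, residue_number, insertion_code) — identity of a residue.
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity plus position (Angstrom)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    is_hetero: bool = False
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if not all(np.isfinite(self.position)):
            raise ValueError(
                f"non-finite position for atom {self.atom_name} "
                f"{self.chain_id}/{self.residue_number}"
            )

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class StructureModel:
    """An ordered collection of atoms forming one model.

    The (chain, residue number, insertion code, atom name) tuple is unique
    within a model; duplicate identities indicate a malformed file (or an
    altloc that should have been collapsed upstream).
    """

    atoms: list[AtomRecord]
    model_id: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("StructureModel must contain at least one atom")
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.insertion_code, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom identity {key} in model")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_positions(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            AtomRecord(
                a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                a.element, tuple(xyz), a.is_hetero, a.insertion_code,
            )
            for a, xyz in zip(self.atoms, coords)
        ]
        return StructureModel(atoms, self.model_id, dict(self.metadata))

    # -- selection helpers -------------------------------------------------

    def select_indices(
        self,
        chain: str | None = None,
        residue_number: int | None = None,
        residue_name: str | None = None,
        atom_name: str | None = None,
        hetero: bool | None = None,
        heavy_only: bool = False,
    ) -> list[int]:
        out = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain_id != chain:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if atom_name is not None and a.atom_name != atom_name:
                continue
            if hetero is not None and a.is_hetero != hetero:
                continue
            if heavy_only and not a.is_heavy:
                continue
            out.append(i)
        return out

    def atom_index(
        self, chain: str, residue_number: int, atom_name: str
    ) -> int:
        """Index of a uniquely identified atom; raises if absent."""
        idx = self.select_indices(
            chain=chain, residue_number=residue_number, atom_name=atom_name
        )
        if not idx:
            raise KeyError(
                f"atom {chain}/{residue_number}/{atom_name} not found"
            )
        return idx[0]

    def residues(self) -> Iterator[tuple[ResidueKey, str, list[int]]]:
        """Iterate residues in order: (key, residue_name, atom indices)."""
        order: list[ResidueKey] = []
        groups: dict[ResidueKey, list[int]] = {}
        names: dict[ResidueKey, str] = {}
        for i, a in enumerate(self.atoms):
            k = a.residue_key
            if k not in groups:
                groups[k] = []
                order.append(k)
                names[k] = a.residue_name
            groups[k].append(i)
        for k in order:
            yield k, names[k], groups[k]

    def hetero_residue_names(self) -> list[str]:
        names = []
        for _, name, idx in self.residues():
            if self.atoms[idx[0]].is_hetero and name not in names:
                names.append(name)
        return names


@dataclass
class Trajectory:
    """Ordered frames of coordinates over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Angstrom;
    ``frame_interval`` is informational (ps between stored frames).
    """

    topology: StructureModel
    frames: np.ndarray
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_model(self, i: int) -> StructureModel:
        """Topology with the coordinates of frame ``i``."""
        return self.topology.with_positions(self.frames[i])
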
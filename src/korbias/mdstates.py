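"""Conformational-state analysis of receptor MD trajectories.

Each frame is reduced to a feature triple: the distance d between
Calpha(S153^3.47) and Czeta(Y330^7.53), the side-chain dihedral chi
(C-CA-CG-CZ of Y330^7.53), and a flag for whether the R156^3.50 side chain
points toward the intracellular side ("downward"). Frames are mapped onto
four base states by rectangular (d, chi) regions; base states 2 and 3 are
split into A/B sub-states by the R156 flag, giving the six-state scheme
S1, S2A, S2B, S3A, S3B, S4 (S3A is the "alternative" conformation with both
R156 and Y330 intracellular). Frames outside every region are UNASSIGNED,
so population fractions always sum to one.

The membrane normal is the +z axis with +z = extracellular; "downward" means
a negative projection of the R156 CA->CZ vector on +z (threshold angle
configurable). State-region rectangles ship as a TOML configuration whose
SHA-256 hash is recorded in every population table.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import StructureModel, Trajectory

__all__ = [
    "distance",
    "dihedral",
    "r_orientation",
    "StateRegion",
    "StateBoundaries",
    "load_boundaries",
    "default_boundaries",
    "load_residue_map",
    "default_residue_map",
    "featurize",
    "classify",
    "state_labels",
    "PopulationTable",
    "populations",
    "occupancy_histogram",
    "Fingerprint",
    "fingerprint",
    "delta_fingerprint",
]

UNASSIGNED = "UNASSIGNED"


# ---------------------------------------------------------------------------
# geometry primitives


def distance(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """Euclidean distance between points (broadcasts over leading axes)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.linalg.norm(a - b, axis=-1)


def dihedral(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float | np.ndarray:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign, range (-180, 180].

    Computed with the atan2 form on the plane normals; an (almost) collinear
    triple makes the torsion undefined and raises.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    if np.any(norm1 < 1e-9) or np.any(norm2 < 1e-9):
        raise ValueError("dihedral undefined: three consecutive atoms are collinear")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return float(ang) if ang.ndim == 0 else ang


def r_orientation(
    ca: np.ndarray,
    cz: np.ndarray,
    membrane_normal: np.ndarray = (0.0, 0.0, 1.0),
    threshold_deg: float = 90.0,
) -> bool | np.ndarray:
    """True when the CA->CZ side-chain vector faces the intracellular side.

    The membrane normal points extracellular (+z by convention); the side
    chain is "down" when the angle between CA->CZ and the intracellular
    direction (-normal) is below ``threshold_deg``. With the default 90 deg
    this reduces to a negative projection on the normal.
    """
    ca = np.asarray(ca, dtype=float)
    cz = np.asarray(cz, dtype=float)
    n = np.asarray(membrane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    v = cz - ca
    vnorm = np.linalg.norm(v, axis=-1)
    if np.any(vnorm < 1e-9):
        raise ValueError("zero-length CA->CZ vector; orientation undefined")
    cos_down = np.sum(v * (-n), axis=-1) / vnorm
    cos_down = np.clip(cos_down, -1.0, 1.0)
    down = np.degrees(np.arccos(cos_down)) < threshold_deg
    return bool(down) if np.ndim(down) == 0 else down


# ---------------------------------------------------------------------------
# state boundaries


@dataclass(frozen=True)
class StateRegion:
    """Half-open rectangle [d_min, d_max) x [chi_min, chi_max) for one base state.

    A chi interval with chi_min > chi_max wraps across the +/-180 boundary.
    """

    base: int
    d_min: float
    d_max: float
    chi_min: float
    chi_max: float
    split_by_r: bool = False

    def chi_segments(self) -> list[tuple[float, float]]:
        if self.chi_min <= self.chi_max:
            return [(self.chi_min, self.chi_max)]
        return [(self.chi_min, 180.000001), (-180.0, self.chi_max)]

    def contains(self, d: np.ndarray, chi: np.ndarray) -> np.ndarray:
        d_ok = (d >= self.d_min) & (d < self.d_max)
        chi_ok = np.zeros_like(d_ok)
        for lo, hi in self.chi_segments():
            chi_ok |= (chi >= lo) & (chi < hi)
        return d_ok & chi_ok

    def labels(self) -> list[str]:
        if self.split_by_r:
            return [f"S{self.base}A", f"S{self.base}B"]
        return [f"S{self.base}"]


@dataclass
class StateBoundaries:
    """The full region configuration; validated disjoint at construction."""

    regions: list[StateRegion]
    source_hash: str | None = None

    def __post_init__(self) -> None:
        bases = [r.base for r in self.regions]
        if len(set(bases)) != len(bases):
            raise ValueError("duplicate base state in boundaries")
        for r in self.regions:
            if not (r.d_min < r.d_max):
                raise ValueError(f"empty d interval for base state {r.base}")
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                if a.d_min < b.d_max and b.d_min < a.d_max:
                    for lo1, hi1 in a.chi_segments():
                        for lo2, hi2 in b.chi_segments():
                            if lo1 < hi2 and lo2 < hi1:
                                raise ValueError(
                                    f"state regions {a.base} and {b.base} overlap"
                                )

    def region(self, base: int) -> StateRegion:
        for r in self.regions:
            if r.base == base:
                return r
        raise KeyError(f"no region for base state {base}")


def load_boundaries(path: str) -> StateBoundaries:
    """Load a state-region TOML file; records its SHA-256 hash."""
    with open(path, "rb") as fh:
        raw = fh.read()
    doc = tomllib.loads(raw.decode())
    regions = [
        StateRegion(
            base=int(s["base"]),
            d_min=float(s["d_min"]),
            d_max=float(s["d_max"]),
            chi_min=float(s["chi_min"]),
            chi_max=float(s["chi_max"]),
            split_by_r=bool(s.get("split_by_r", False)),
        )
        for s in doc["state"]
    ]
    return StateBoundaries(regions, source_hash=hashlib.sha256(raw).hexdigest())


def default_boundaries() -> StateBoundaries:
    with resources.as_file(
        resources.files("korbias.data") / "state_boundaries.toml"
    ) as p:
        return load_boundaries(str(p))


def load_residue_map(path: str) -> dict[str, dict]:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def default_residue_map() -> dict[str, dict]:
    with resources.as_file(
        resources.files("korbias.data") / "residue_map.toml"
    ) as p:
        return load_residue_map(str(p))


def state_labels(boundaries: StateBoundaries) -> list[str]:
    """The label enumeration of the scheme, excluding UNASSIGNED."""
    out: list[str] = []
    for r in sorted(boundaries.regions, key=lambda r: r.base):
        out.extend(r.labels())
    return out


# ---------------------------------------------------------------------------
# featurization and classification


def _marker_indices(topology: StructureModel, residue_map: dict) -> dict[str, int]:
    spec = {
        "s153_ca": ("S153", "CA"),
        "y330_c": ("Y330", "C"),
        "y330_ca": ("Y330", "CA"),
        "y330_cg": ("Y330", "CG"),
        "y330_cz": ("Y330", "CZ"),
        "r156_ca": ("R156", "CA"),
        "r156_cz": ("R156", "CZ"),
    }
    idx: dict[str, int] = {}
    for key, (res, atom) in spec.items():
        entry = residue_map[res]
        try:
            idx[key] = topology.atom_index(entry["chain"], entry["resnum"], atom)
        except KeyError as exc:
            raise KeyError(
                f"marker atom {atom} of {res} "
                f"({entry['chain']}/{entry['resnum']}) missing from topology"
            ) from exc
    return idx


def featurize(
    traj: Trajectory,
    residue_map: dict | None = None,
    membrane_normal: np.ndarray = (0.0, 0.0, 1.0),
    threshold_deg: float = 90.0,
) -> pd.DataFrame:
    """Per-frame features (columns ``d``, ``chi``, ``r_down``), frame order kept."""
    if residue_map is None:
        residue_map = default_residue_map()
    ix = _marker_indices(traj.topology, residue_map)
    F = traj.frames
    d = distance(F[:, ix["s153_ca"]], F[:, ix["y330_cz"]])
    chi = dihedral(
        F[:, ix["y330_c"]], F[:, ix["y330_ca"]],
        F[:, ix["y330_cg"]], F[:, ix["y330_cz"]],
    )
    r_down = r_orientation(
        F[:, ix["r156_ca"]], F[:, ix["r156_cz"]], membrane_normal, threshold_deg
    )
    return pd.DataFrame(
        {"d": np.atleast_1d(d), "chi": np.atleast_1d(chi),
         "r_down": np.atleast_1d(r_down)}
    )


def classify(
    features: pd.DataFrame, boundaries: StateBoundaries | None = None
) -> np.ndarray:
    """Map each frame's features to a state label (or UNASSIGNED)."""
    if boundaries is None:
        boundaries = default_boundaries()
    d = features["d"].to_numpy(dtype=float)
    chi = features["chi"].to_numpy(dtype=float)
    r_down = features["r_down"].to_numpy(dtype=bool)
    labels = np.full(len(features), UNASSIGNED, dtype=object)
    for region in boundaries.regions:
        mask = region.contains(d, chi)
        if region.split_by_r:
            labels[mask & r_down] = f"S{region.base}A"
            labels[mask & ~r_down] = f"S{region.base}B"
        else:
            labels[mask] = f"S{region.base}"
    return labels


# ---------------------------------------------------------------------------
# populations


@dataclass
class PopulationTable:
    """State fractions per replicate and pooled, plus R156-down proportions.

    ``pooled`` fractions include UNASSIGNED and sum to 1; ``r_down`` maps
    each base state to the pooled proportion of its frames with the R156
    side chain facing intracellular.
    """

    per_replicate: pd.DataFrame
    pooled: pd.Series
    r_down: dict[int, float]
    n_frames: int
    boundary_hash: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = self.per_replicate.copy()
        rows.loc["pooled"] = self.pooled
        return rows


def populations(
    labels_by_replicate: Sequence[np.ndarray],
    features_by_replicate: Sequence[pd.DataFrame] | None = None,
    boundaries: StateBoundaries | None = None,
) -> PopulationTable:
    """Pooled and per-replicate state fractions.

    Pooled fractions weight replicates by frame count (frames are pooled
    before dividing); per-replicate fractions are also reported so either
    summary convention is available. When per-frame features are supplied,
    R156-down proportions are computed for every base state; otherwise they
    come from the A/B sub-label counts of the split states.
    """
    if boundaries is None:
        boundaries = default_boundaries()
    if not labels_by_replicate or all(len(l) == 0 for l in labels_by_replicate):
        raise ValueError("populations requires at least one labeled frame")
    all_labels = state_labels(boundaries) + [UNASSIGNED]

    per_rep = {}
    for i, labels in enumerate(labels_by_replicate):
        labels = np.asarray(labels, dtype=object)
        counts = pd.Series(labels).value_counts()
        per_rep[i] = pd.Series(
            {lab: counts.get(lab, 0) / len(labels) for lab in all_labels}
        )
    per_replicate = pd.DataFrame(per_rep).T
    per_replicate.index.name = "replicate"

    pooled_labels = np.concatenate(
        [np.asarray(l, dtype=object) for l in labels_by_replicate]
    )
    n = len(pooled_labels)
    counts = pd.Series(pooled_labels).value_counts()
    pooled = pd.Series({lab: counts.get(lab, 0) / n for lab in all_labels})

    r_down: dict[int, float] = {}
    if features_by_replicate is not None:
        feats = pd.concat(list(features_by_replicate), ignore_index=True)
        down = feats["r_down"].to_numpy(dtype=bool)
        for region in boundaries.regions:
            base_mask = np.isin(
                pooled_labels, np.array(region.labels(), dtype=object)
            )
            if base_mask.any():
                r_down[region.base] = float(down[base_mask].mean())
    else:
        for region in boundaries.regions:
            if region.split_by_r:
                na = counts.get(f"S{region.base}A", 0)
                nb = counts.get(f"S{region.base}B", 0)
                if na + nb:
                    r_down[region.base] = na / (na + nb)
    return PopulationTable(
        per_replicate, pooled, r_down, n,
        boundary_hash=boundaries.source_hash,
    )


def occupancy_histogram(
    features: pd.DataFrame,
    d_edges: np.ndarray,
    chi_edges: np.ndarray,
) -> np.ndarray:
    """2-D (d, chi) occupancy counts on half-open bins [lo, hi).

    Every frame must fall inside the grid so that counts sum to n_frames.
    """
    d_edges = np.asarray(d_edges, dtype=float)
    chi_edges = np.asarray(chi_edges, dtype=float)
    for name, e in (("d", d_edges), ("chi", chi_edges)):
        if e.size < 2:
            raise ValueError(f"{name} bin edges need at least two values")
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"{name} bin edges must be strictly ascending")
    d = features["d"].to_numpy(dtype=float)
    chi = features["chi"].to_numpy(dtype=float)
    di = np.digitize(d, d_edges) - 1
    ci = np.digitize(chi, chi_edges) - 1
    if np.any((di < 0) | (di >= d_edges.size - 1)) or np.any(
        (ci < 0) | (ci >= chi_edges.size - 1)
    ):
        raise ValueError("feature outside histogram grid")
    grid = np.zeros((d_edges.size - 1, chi_edges.size - 1), dtype=int)
    np.add.at(grid, (di, ci), 1)
    return grid


# ---------------------------------------------------------------------------
# ligand-contact fingerprints


@dataclass
class Fingerprint:
    """Per-residue ligand-contact frequency over a trajectory."""

    frequencies: pd.DataFrame  # columns: chain, resnum, resname, frequency
    cutoff: float
    n_frames: int


def fingerprint(
    traj: Trajectory,
    ligand: str,
    cutoff: float = 6.0,
) -> Fingerprint:
    """Residue contact frequencies against a hetero ligand.

    A residue is in contact in a frame when the minimum heavy-atom to
    heavy-atom distance to the ligand is <= ``cutoff`` (inclusive boundary,
    default 6 A). Frequency = contact frames / total frames.
    """
    top = traj.topology
    lig_idx = top.select_indices(residue_name=ligand, hetero=True, heavy_only=True)
    if not lig_idx:
        available = top.hetero_residue_names()
        raise ValueError(
            f"ligand residue {ligand!r} not found; hetero residues present: "
            f"{available}"
        )
    res_keys: list[tuple] = []
    res_names: list[str] = []
    res_atoms: list[list[int]] = []
    for key, name, idx in top.residues():
        heavy = [
            i for i in idx
            if top.atoms[i].is_heavy and not top.atoms[i].is_hetero
        ]
        if heavy:
            res_keys.append(key)
            res_names.append(name)
            res_atoms.append(heavy)
    if not res_atoms:
        raise ValueError("no protein heavy atoms in topology")

    flat = np.concatenate([np.asarray(a) for a in res_atoms])
    bounds = np.cumsum([0] + [len(a) for a in res_atoms])
    contact_counts = np.zeros(len(res_atoms), dtype=int)
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        dmat = cdist(coords[flat], coords[lig_idx])
        atom_min = dmat.min(axis=1)
        res_min = np.minimum.reduceat(atom_min, bounds[:-1])
        contact_counts += res_min <= cutoff
    freq = pd.DataFrame(
        {
            "chain": [k[0] for k in res_keys],
            "resnum": [k[1] for k in res_keys],
            "resname": res_names,
            "frequency": contact_counts / traj.n_frames,
        }
    )
    return Fingerprint(freq, cutoff=cutoff, n_frames=traj.n_frames)


def delta_fingerprint(wt: Fingerprint, mutant: Fingerprint) -> pd.DataFrame:
    """Wild-type minus mutant contact frequencies over the union of residues.

    Positive values mean the mutation reduced the interaction, negative
    values mean it increased it. A residue absent from one fingerprint
    contributes frequency 0 there.
    """
    if wt.cutoff != mutant.cutoff:
        raise ValueError(
            f"fingerprint cutoffs differ ({wt.cutoff} vs {mutant.cutoff} A)"
        )
    key = ["chain", "resnum", "resname"]
    merged = wt.frequencies.merge(
        mutant.frequencies, on=key, how="outer", suffixes=("_wt", "_mut")
    ).fillna({"frequency_wt": 0.0, "frequency_mut": 0.0})
    merged["delta"] = merged["frequency_wt"] - merged["frequency_mut"]
    return merged.sort_values(["chain", "resnum"]).reset_index(drop=True)
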
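"""Seeded synthetic inputs for every analysis stage.

Each generator is a pure function of its inputs and a seed, producing data
with exactly the statistical/geometric structure the corresponding analysis
assumes:

* trajectories whose frames realize prescribed (distance, dihedral,
  R156-orientation) values inside chosen conformational-state regions, with
  optional ligand-contact patterns — frame geometry is built analytically
  (fixed bond lengths/angles, prescribed torsion; marker placement on a
  sphere of the prescribed distance), not by physics;
* 4PL dose-response tables with Gaussian replicate noise;
* one-site saturation and competition binding isotherms;
* absorbance spectra as additive Gaussian bands on a uniform wavenumber
  grid (default 2 cm^-1 step).

The membrane normal is +z with +z = extracellular, matching the convention
of :mod:`korbias.mdstates`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mdstates import StateBoundaries, StateRegion, default_boundaries
from .pharm import four_pl
from .structures import AtomRecord, StructureModel, Trajectory

__all__ = [
    "GeneratorConfig",
    "StateSpec",
    "FourPLTruth",
    "gen_trajectory",
    "gen_dose_response",
    "gen_binding",
    "gen_spectrum",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed and default noise levels for the generators."""

    seed: int = 0
    response_noise_sd: float = 0.0
    binding_noise_sd: float = 0.0
    spectrum_noise_sd: float = 0.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# trajectory generation


@dataclass
class StateSpec:
    """Frame counts per state plus geometry targets.

    ``counts`` keys are state labels: base labels (``"S2"``) or sub-labels
    (``"S2A"``). Sub-labels fix the R156 orientation (A = down, B = up);
    base labels draw it from ``r_down_prob`` (default 0 for unsplit states,
    0.5 for split ones). ``targets`` optionally overrides the (d, chi)
    sampling ranges per entry; defaults are the state region shrunk by 20%
    on each side so realized features sit strictly inside the region.
    """

    counts: Mapping[str, int]
    targets: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=dict
    )
    r_down_prob: Mapping[str, float] = field(default_factory=dict)

    def validate(self, boundaries: StateBoundaries) -> None:
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError("at least one state must have a positive count")
        for label, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative frame count for {label}")
            region = boundaries.region(_base_of(label))
            d_rng, chi_rng = _target_ranges(self, label, region)
            if not (region.d_min <= d_rng[0] < d_rng[1] <= region.d_max):
                raise ValueError(
                    f"{label}: d target {d_rng} outside region "
                    f"[{region.d_min}, {region.d_max})"
                )
            seg_ok = any(
                lo <= chi_rng[0] < chi_rng[1] <= hi
                for lo, hi in region.chi_segments()
            )
            if not seg_ok:
                raise ValueError(
                    f"{label}: chi target {chi_rng} outside region segments"
                )


def _base_of(label: str) -> int:
    core = label.lstrip("S").rstrip("AB")
    try:
        return int(core)
    except ValueError as exc:
        raise ValueError(f"malformed state label {label!r}") from exc


def _shrink(lo: float, hi: float, frac: float = 0.2) -> tuple[float, float]:
    m = frac * (hi - lo)
    return lo + m, hi - m


def _target_ranges(
    spec: StateSpec, label: str, region: StateRegion
) -> tuple[tuple[float, float], tuple[float, float]]:
    if label in spec.targets:
        return spec.targets[label]
    d_rng = _shrink(region.d_min, region.d_max)
    lo, hi = region.chi_segments()[0]
    chi_rng = _shrink(lo, min(hi, 180.0))
    return d_rng, chi_rng


def _place_dihedral_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom D with given C-D bond, B-C-D angle and A-B-C-D torsion."""
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    b1 = b - a
    b2 = c - b
    b2h = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2h)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * b2h + d_local[1] * m + d_local[2] * n


# fixed local geometry of the Y330 side-chain marker atoms (Angstrom / deg);
# values are synthetic stand-ins chosen for numerical robustness, not
# force-field parameters
_Y330_C = np.array([1.45, -0.90, 0.35])
_Y330_CA = np.array([0.0, 0.0, 0.0])
_Y330_CG = np.array([0.45, 1.45, -0.25])
_CG_CZ_BOND = 2.80
_CA_CG_CZ_ANGLE = 115.0


def _topology_atoms(
    residue_map: Mapping[str, Mapping],
    with_ligand: bool,
    contact_resnums: Sequence[int],
) -> list[AtomRecord]:
    rm = residue_map
    z = (0.0, 0.0, 0.0)
    atoms = [
        AtomRecord(rm["S153"]["chain"], rm["S153"]["resnum"], "SER", "CA", "C", z),
        AtomRecord(rm["R156"]["chain"], rm["R156"]["resnum"], "ARG", "CA", "C", z),
        AtomRecord(rm["R156"]["chain"], rm["R156"]["resnum"], "ARG", "CZ", "C", z),
        AtomRecord(rm["Y330"]["chain"], rm["Y330"]["resnum"], "TYR", "C", "C", z),
        AtomRecord(rm["Y330"]["chain"], rm["Y330"]["resnum"], "TYR", "CA", "C", z),
        AtomRecord(rm["Y330"]["chain"], rm["Y330"]["resnum"], "TYR", "CG", "C", z),
        AtomRecord(rm["Y330"]["chain"], rm["Y330"]["resnum"], "TYR", "CZ", "C", z),
    ]
    if with_ligand:
        atoms.append(AtomRecord("L", 901, "LIG", "C1", "C", z, is_hetero=True))
        for rn in contact_resnums:
            atoms.append(AtomRecord("A", rn, "GLY", "CA", "C", z))
    return atoms


def gen_trajectory(
    spec: StateSpec,
    boundaries: StateBoundaries | None = None,
    config: GeneratorConfig | None = None,
    residue_map: Mapping[str, Mapping] | None = None,
    contact_probs: Mapping[int, float] | None = None,
    frame_interval: float = 10.0,
) -> tuple[Trajectory, np.ndarray]:
    """Build a trajectory realizing the prescribed state composition.

    Returns the trajectory and the ground-truth sub-state label of every
    frame (aligned with the deterministic shuffle). When ``contact_probs``
    maps residue numbers to contact probabilities, a one-atom hetero ligand
    ("LIG") plus probe residues are added; each probe sits within 4 A of
    the ligand in a contact frame and at 12 A otherwise.
    """
    if boundaries is None:
        boundaries = default_boundaries()
    if config is None:
        config = GeneratorConfig()
    from .mdstates import default_residue_map

    if residue_map is None:
        residue_map = default_residue_map()
    spec.validate(boundaries)
    rng = config.rng()

    contact_resnums = sorted(contact_probs) if contact_probs else []
    atoms = _topology_atoms(residue_map, bool(contact_probs), contact_resnums)
    topology = StructureModel(atoms, model_id=1)
    name_to_idx = {
        (a.chain_id, a.residue_number, a.atom_name): i
        for i, a in enumerate(topology.atoms)
    }
    rm = residue_map
    i_s153 = name_to_idx[(rm["S153"]["chain"], rm["S153"]["resnum"], "CA")]
    i_rca = name_to_idx[(rm["R156"]["chain"], rm["R156"]["resnum"], "CA")]
    i_rcz = name_to_idx[(rm["R156"]["chain"], rm["R156"]["resnum"], "CZ")]
    i_yc = name_to_idx[(rm["Y330"]["chain"], rm["Y330"]["resnum"], "C")]
    i_yca = name_to_idx[(rm["Y330"]["chain"], rm["Y330"]["resnum"], "CA")]
    i_ycg = name_to_idx[(rm["Y330"]["chain"], rm["Y330"]["resnum"], "CG")]
    i_ycz = name_to_idx[(rm["Y330"]["chain"], rm["Y330"]["resnum"], "CZ")]

    frames: list[np.ndarray] = []
    labels: list[str] = []
    lig_pos = np.array([25.0, 0.0, 0.0])
    for label in sorted(spec.counts):
        count = spec.counts[label]
        if count == 0:
            continue
        base = _base_of(label)
        region = boundaries.region(base)
        d_rng, chi_rng = _target_ranges(spec, label, region)
        if label.endswith("A"):
            p_down = 1.0
        elif label.endswith("B"):
            p_down = 0.0
        else:
            p_down = spec.r_down_prob.get(
                label, 0.5 if region.split_by_r else 0.0
            )
        for _ in range(count):
            coords = np.zeros((len(atoms), 3))
            d = rng.uniform(*d_rng)
            chi = rng.uniform(*chi_rng)
            down = bool(rng.random() < p_down)

            coords[i_yc] = _Y330_C
            coords[i_yca] = _Y330_CA
            coords[i_ycg] = _Y330_CG
            cz = _place_dihedral_atom(
                _Y330_C, _Y330_CA, _Y330_CG, _CG_CZ_BOND, _CA_CG_CZ_ANGLE, chi
            )
            coords[i_ycz] = cz
            # S153 CA on the sphere of radius d about Y330 CZ
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords[i_s153] = cz + d * u
            # R156: CZ above/below CA along the membrane normal (+z = EC)
            rca = np.array([8.0, 8.0, 0.0])
            coords[i_rca] = rca
            lateral = rng.normal(scale=0.4, size=2)
            zmag = 2.0 + rng.uniform(0.0, 1.0)
            coords[i_rcz] = rca + np.array(
                [lateral[0], lateral[1], -zmag if down else zmag]
            )
            if contact_probs:
                i_lig = name_to_idx[("L", 901, "C1")]
                coords[i_lig] = lig_pos
                for rn in contact_resnums:
                    i_probe = name_to_idx[("A", rn, "CA")]
                    r = 4.0 if rng.random() < contact_probs[rn] else 12.0
                    coords[i_probe] = lig_pos + np.array([0.0, r, 0.0])
            frames.append(coords)
            if region.split_by_r:
                labels.append(f"S{base}{'A' if down else 'B'}")
            else:
                labels.append(f"S{base}")

    order = rng.permutation(len(frames))
    frame_arr = np.stack(frames)[order]
    label_arr = np.array(labels, dtype=object)[order]
    return Trajectory(topology, frame_arr, frame_interval), label_arr


# ---------------------------------------------------------------------------
# dose-response generation


@dataclass(frozen=True)
class FourPLTruth:
    """Ground-truth 4PL parameters of one curve."""

    bottom: float = 1.0
    top: float = 2.0
    pec50: float = 8.0
    hill: float = 1.0


def gen_dose_response(
    truth: Mapping[tuple[str, str, str], FourPLTruth],
    concentrations: Sequence[float] | None = None,
    n_conc: int = 8,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Dose-response tables from 4PL truth plus Gaussian replicate noise.

    ``truth`` maps (ligand, pathway, construct) to parameters. The default
    concentration grid is log-spaced over pEC50 +/- 3 of each curve; an
    explicit grid must span at least 3 log units around every EC50.
    """
    if config is None:
        config = GeneratorConfig()
    rng = config.rng()
    rows = []
    truth_out = {}
    for key in sorted(truth):
        t = truth[key]
        ligand, pathway, construct = key
        if concentrations is None:
            conc = np.logspace(-t.pec50 - 3.0, -t.pec50 + 3.0, n_conc)
        else:
            conc = np.asarray(concentrations, dtype=float)
            if np.any(conc <= 0):
                raise ValueError("concentrations must be positive")
            span = np.log10(conc.max()) - np.log10(conc.min())
            if span < 3.0:
                raise ValueError(
                    "concentration grid must span >= 3 log units around EC50"
                )
        clean = four_pl(conc, t.bottom, t.top, t.pec50, t.hill)
        for rep in range(1, n_replicates + 1):
            noisy = clean + rng.normal(scale=noise_sd, size=clean.shape) \
                if noise_sd > 0 else clean
            for c, y in zip(conc, noisy):
                rows.append(
                    {"ligand": ligand, "pathway": pathway,
                     "construct": construct, "conc_M": c, "response": y,
                     "replicate": rep}
                )
        truth_out[key] = t
    return pd.DataFrame(rows), {"truth": truth_out, "noise_sd": noise_sd}


# ---------------------------------------------------------------------------
# binding generation


def gen_binding(
    mode: str,
    truth: Mapping[str, float],
    concentrations: Sequence[float],
    config: GeneratorConfig | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Saturation or competition binding isotherms.

    Saturation truth: ``bmax``, ``kd`` (molar), ``ns`` (nonspecific counts
    per molar). Competition truth: ``top``, ``bottom``, ``ic50`` (molar),
    ``hill`` (> 0, descending) plus constant ``ns_counts``.
    """
    if config is None:
        config = GeneratorConfig()
    rng = config.rng()
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rows = []
    if mode == "saturation":
        kd = truth["kd"]
        if kd <= 0:
            raise ValueError("Kd must be positive")
        bmax = truth["bmax"]
        ns = truth.get("ns", 0.0)
        for rep in range(1, n_replicates + 1):
            spec = bmax * conc / (kd + conc)
            nsb = ns * conc
            total = spec + nsb
            if noise_sd > 0:
                total = total + rng.normal(scale=noise_sd, size=conc.shape)
                nsb = nsb + rng.normal(scale=noise_sd, size=conc.shape)
            for c, tt, nn in zip(conc, total, nsb):
                rows.append(
                    {"mode": "saturation", "conc_M": c, "counts_total": tt,
                     "counts_nonspecific": nn, "replicate": rep}
                )
    elif mode == "competition":
        ic50 = truth["ic50"]
        if ic50 <= 0:
            raise ValueError("IC50 must be positive")
        top = truth["top"]
        bottom = truth.get("bottom", 0.0)
        hill = truth.get("hill", 1.0)
        ns_counts = truth.get("ns_counts", 0.0)
        logc = np.log10(conc)
        for rep in range(1, n_replicates + 1):
            spec = bottom + (top - bottom) / (
                1.0 + 10.0 ** ((logc - np.log10(ic50)) * hill)
            )
            total = spec + ns_counts
            nsb = np.full_like(conc, ns_counts)
            if noise_sd > 0:
                total = total + rng.normal(scale=noise_sd, size=conc.shape)
                nsb = nsb + rng.normal(scale=noise_sd, size=conc.shape)
            for c, tt, nn in zip(conc, total, nsb):
                rows.append(
                    {"mode": "competition", "conc_M": c, "counts_total": tt,
                     "counts_nonspecific": nn, "replicate": rep}
                )
    else:
        raise ValueError(f"mode must be 'saturation' or 'competition', got {mode!r}")
    return pd.DataFrame(rows), {"truth": dict(truth), "noise_sd": noise_sd}


# ---------------------------------------------------------------------------
# spectrum generation


def gen_spectrum(
    bands: Sequence[tuple[float, float, float]],
    grid: tuple[float, float, float] = (1000.0, 3000.0, 2.0),
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Absorbance spectrum from additive Gaussian bands.

    ``bands`` is a list of (center cm^-1, amplitude, FWHM); ``grid`` is
    (min, max, step), default step 2 cm^-1 as recorded by the instrument.
    """
    lo, hi, step = grid
    if step <= 0:
        raise ValueError("grid step must be positive")
    x = np.arange(lo, hi + step / 2, step)
    y = np.full_like(x, float(baseline))
    for center, amp, fwhm in bands:
        if fwhm <= 0:
            raise ValueError(f"band FWHM must be positive (center {center})")
        if not (lo <= center <= hi):
            raise ValueError(f"band center {center} outside grid [{lo}, {hi}]")
        y = y + amp * np.exp(-4.0 * np.log(2.0) * (x - center) ** 2 / fwhm ** 2)
    if noise_sd > 0:
        if config is None:
            config = GeneratorConfig()
        y = y + config.rng().normal(scale=noise_sd, size=x.shape)
    return pd.DataFrame({"wavenumber_cm-1": x, "absorbance": y})
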
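import numpy as np
import pytest

from korbias.mdstates import StateBoundaries, StateRegion
from korbias.structures import AtomRecord, StructureModel


@pytest.fixture
def toy_boundaries():
    """Two well-separated rectangles, base 1 unsplit and base 3 split."""
    return StateBoundaries(
        [
            StateRegion(1, 5.0, 10.0, -180.0, -60.0, split_by_r=False),
            StateRegion(3, 10.0, 15.0, 40.0, 120.0, split_by_r=True),
        ]
    )


@pytest.fixture
def two_atom_pdb(tmp_path):
    text = (
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
        "ATOM      2  CB  ALA A   1       4.500   5.250   6.125  1.00  0.00           C\n"
        "END\n"
    )
    p = tmp_path / "two_atoms.pdb"
    p.write_text(text)
    return p


def make_model(coords, chain="A", start_res=1, atoms_per_res=1, hetero=None):
    """Helper: simple model with one CA-like atom per residue by default."""
    records = []
    names = ["CA", "CB", "CG", "CD", "CE"]
    for i, xyz in enumerate(coords):
        res = start_res + i // atoms_per_res
        records.append(
            AtomRecord(
                chain_id=chain,
                residue_number=res,
                residue_name="ALA",
                atom_name=names[i % atoms_per_res],
                element="C",
                position=tuple(float(v) for v in xyz),
                is_hetero=bool(hetero and res in hetero),
            )
        )
    return StructureModel(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
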
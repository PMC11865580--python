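import numpy as np
import pytest

from concavekit.structure_io import AtomRecord, model_from_atoms
from concavekit.scaffold import make_ball_socket_complex, make_toy_bundle

GLY_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      10.729   6.768  -4.145  1.00  0.00           C
TER
END
"""

@pytest.fixture
def gly_pdb(tmp_path):
    path = tmp_path / "gly.pdb"
    path.write_text(GLY_PDB)
    return path


@pytest.fixture
def gly_pdb_with_h(tmp_path):
    text = GLY_PDB.replace(
        "TER",
        "ATOM      4  H   GLY A   1      10.305   5.704  -6.716  1.00  0.00           H\nTER",
    )
    path = tmp_path / "glyh.pdb"
    path.write_text(text)
    return path


def pseudo_atom(serial, xyz, chain="A", element="C", radius=1.87, name="CA",
                resname="GLY", resnum=None):
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_number=serial if resnum is None else resnum, chain_id=chain,
        coords=np.asarray(xyz, dtype=float), is_heavy=element not in ("H", "D"),
        is_polar=element in ("N", "O"), vdw_radius=radius,
    )


@pytest.fixture
def pseudo_model_factory():
    def build(coords, chain="A", element="C", radius=1.87):
        atoms = [
            pseudo_atom(i + 1, xyz, chain=chain, element=element, radius=radius)
            for i, xyz in enumerate(coords)
        ]
        return model_from_atoms(atoms)

    return build


@pytest.fixture(scope="session")
def toy_bundle():
    return make_toy_bundle(face_curvature=-0.05, seed=0)


@pytest.fixture(scope="session")
def convex_bundle():
    return make_toy_bundle(face_curvature=+0.05, seed=0)


@pytest.fixture(scope="session")
def ball_socket():
    return make_ball_socket_complex(seed=0)
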
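import numpy as np
import pytest

from capsidkit.icosahedral_symmetry import expand_capsid, generate_operators
from capsidkit.structure_io import Atom, StructureModel
from capsidkit.synthetic_data import ShellSpec, make_shell_capsid


@pytest.fixture(scope="session")
def icos_ops():
    return generate_operators()


@pytest.fixture(scope="session")
def small_shell():
    """Ideal shell with radii uniform in [100, 130] Å, 500 atoms per AU."""
    return make_shell_capsid(
        ShellSpec(inner_radius=100.0, outer_radius=130.0, atoms_per_au=500, seed=1)
    )


@pytest.fixture(scope="session")
def small_shell_expanded(small_shell):
    return expand_capsid(small_shell.au, small_shell.ops)


@pytest.fixture(scope="session")
def dense_shell():
    """Thin, densely covered shell for watertight voxel flood-fill tests."""
    return make_shell_capsid(
        ShellSpec(
            inner_radius=100.0,
            outer_radius=100.5,
            atoms_per_au=600,
            seed=3,
            surface_coverage=4.0,
        )
    )


@pytest.fixture(scope="session")
def dense_shell_expanded(dense_shell):
    return expand_capsid(dense_shell.au, dense_shell.ops)


def make_atom(serial=1, name="CA", element="C", res_name="ALA", res_seq=1,
              chain_id="A", position=(0.0, 0.0, 0.0), **kwargs):
    return Atom(
        serial=serial, name=name, element=element, res_name=res_name,
        res_seq=res_seq, chain_id=chain_id, position=np.asarray(position, dtype=float),
        **kwargs,
    )


@pytest.fixture
def tiny_model():
    """Three atoms, one chain."""
    atoms = [
        make_atom(serial=1, name="N", element="N", position=(0.0, 0.0, 0.0)),
        make_atom(serial=2, name="CA", position=(1.5, 0.0, 0.0)),
        make_atom(serial=3, name="C", position=(2.5, 1.0, 0.0)),
    ]
    return StructureModel(atoms=atoms, source_format="memory")


@pytest.fixture
def backbone_chain():
    """13 residues x 4 backbone atoms on chain A plus one THR-114 CB marker."""
    atoms = []
    serial = 1
    for res in range(1, 14):
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(
                make_atom(serial=serial, name=name, element=elem, res_name="GLY",
                          res_seq=res, position=(res * 3.0, serial % 3, 0.0))
            )
            serial += 1
    atoms.append(
        make_atom(serial=serial, name="CB", res_name="THR", res_seq=114,
                  position=(50.0, 5.0, 1.0))
    )
    return StructureModel(atoms=atoms, source_format="memory")
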
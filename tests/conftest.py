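import numpy as np
import pytest

from conspocket import (
    Atom,
    FixtureSpec,
    PocketSpec,
    ResidueKey,
    assign_radii,
    make_pocketed_structure,
)


def make_atoms(coords, element="C", chain="A", start_serial=1, atoms_per_residue=1):
    """Build a list of radius-assigned atoms at the given coordinates."""
    atoms = []
    for i, xyz in enumerate(np.atleast_2d(np.asarray(coords, dtype=float))):
        resnum = i // atoms_per_residue + 1
        atoms.append(
            Atom(
                serial=start_serial + i,
                name="CA",
                element=element,
                coords=xyz,
                residue_key=ResidueKey(chain, resnum, "", "GLY"),
            )
        )
    return assign_radii(atoms)


@pytest.fixture(scope="session")
def pocketed():
    """One default pocketed pseudo-protein: (complex, grade map, truth)."""
    spec = FixtureSpec(pockets=(PocketSpec((0.0, 0.0, 1.0), 7.0, 9.5),), seed=11)
    return make_pocketed_structure(spec)


@pytest.fixture(scope="session")
def two_pocketed():
    """A fixture with two planted pockets far apart."""
    spec = FixtureSpec(
        shell_radius=17.0,
        pockets=(
            PocketSpec((0.0, 0.0, 1.0), 7.5, 9.5),
            PocketSpec((0.0, 0.94, -0.342), 7.5, 9.5),
        ),
        seed=12,
    )
    return make_pocketed_structure(spec)


@pytest.fixture(scope="session")
def convex_shell():
    """A pocket-free (convex) pseudo-protein."""
    spec = FixtureSpec(pockets=(), seed=13)
    return make_pocketed_structure(spec)
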
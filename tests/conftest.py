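import numpy as np
import pytest

from mechanomem.io_formats import Atom, AtomModel, FrameSet, MembraneFrame


def make_atom(chain="A", res_num=1, atom_name="CA", res_name="ALA",
              element="C", xyz=(0.0, 0.0, 0.0), icode="", occupancy=1.0):
    return Atom(chain, res_num, icode, res_name, atom_name, element,
                float(xyz[0]), float(xyz[1]), float(xyz[2]), occupancy, 0.0)


def poly_ala_model(n_res: int, chain: str = "A", start: int = 1,
                   atom_names=("N", "CA", "CB"), spacing: float = 3.8) -> AtomModel:
    """Synthetic poly-alanine chain with a few atoms per residue."""
    atoms = []
    for i in range(n_res):
        for j, name in enumerate(atom_names):
            atoms.append(make_atom(chain=chain, res_num=start + i, atom_name=name,
                                   xyz=(i * spacing, j * 1.0, 0.0)))
    return AtomModel(atoms)


def frame_from_beads(species, beads, coords, box=(100.0, 100.0, 100.0)):
    species = list(species)
    return MembraneFrame(
        species=np.array(species, dtype=object),
        mol_ids=np.arange(1, len(species) + 1),
        bead_names=np.array(list(beads), dtype=object),
        coords=np.asarray(coords, dtype=float),
        box=np.asarray(box, dtype=float),
    )


@pytest.fixture
def flat_bilayer_frame():
    """Four phosphates at z = 50 +- 19 in a 100 A box (midplane 50)."""
    coords = [(10, 10, 69), (90, 90, 69), (10, 90, 31), (90, 10, 31)]
    return frame_from_beads(["PE"] * 4, ["PO4"] * 4, coords)
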
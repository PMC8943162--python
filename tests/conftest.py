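import numpy as np
import pytest

from mdcoupling.synthetic import make_chain_topology
from mdcoupling.trajectory import FrameSet, SegmentDef, Topology


def pdb_line(serial, name, resname, chain, resnum, x, y, z,
             record="ATOM", element=None, occupancy=1.00, altloc=" "):
    element = element or name[0]
    return (f"{record:<6}{serial:>5} {name:^4}{altloc}{resname:>3} {chain}"
            f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00"
            f"          {element:>2}")


@pytest.fixture
def single_atom_pdb(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(pdb_line(1, "CA", "LYS", "A", 610, 1.0, 2.0, 3.0) + "\n")
    return path


@pytest.fixture
def lid_topology():
    """A 14-residue poly-ALA chain covering the pocket-lid range L663-Q676."""
    return make_chain_topology("A", [(663, 676)])


@pytest.fixture
def four_chain_pdb(tmp_path):
    """Four chains with identical per-chain residue ranges (2 residues each)."""
    lines = []
    serial = 1
    for chain in "ABCD":
        for resnum in (10, 11):
            for name in ("N", "CA"):
                lines.append(pdb_line(serial, name, "ALA", chain, resnum,
                                      float(serial), 0.0, 0.0))
                serial += 1
    path = tmp_path / "four.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_atom_frames():
    topo = Topology(
        atom_name=np.array(["CA", "CA"], dtype="U6"),
        residue_number=np.array([1, 2], dtype=np.int64),
        residue_name=np.array(["GLY", "GLY"], dtype="U5"),
        chain_id=np.array(["A", "A"], dtype="U4"),
        element=np.array(["C", "C"], dtype="U4"),
        is_hetero=np.zeros(2, dtype=bool),
    )
    coords = np.array([
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]],
        [[0.0, 0.5, 0.0], [1.0, 0.5, 0.0]],
        [[0.0, 1.0, 0.0], [1.0, 1.0, 0.0]],
    ])
    return FrameSet(coords, np.array([0.0, 1.0, 2.0]), topo)


@pytest.fixture
def lid_segment():
    return SegmentDef("lid", "A", 663, 676)
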
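import numpy as np
import pytest

import forkcg

MINI_PDB = """\
ATOM      1  N   ALA A   1      -0.525   1.362   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.520   0.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.153   1.062   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1      -0.507  -0.785  -1.206  1.00  0.00           C
ATOM      6  N   LYS A   2       2.100  -1.200   0.000  1.00  0.00           N
ATOM      7  CA  LYS A   2       3.550  -1.350   0.100  1.00  0.00           C
ATOM      8  C   LYS A   2       4.200  -0.250   0.950  1.00  0.00           C
ATOM      9  O   LYS A   2       5.420  -0.150   1.050  1.00  0.00           O
ATOM     10  N   GLU A   3       3.400   0.600   1.550  1.00  0.00           N
ATOM     11  CA  GLU A   3       3.900   1.750   2.350  1.00  0.00           C
ATOM     12  C   GLU A   3       4.600   2.800   1.500  1.00  0.00           C
ATOM     13  O   GLU A   3       5.500   3.500   1.960  1.00  0.00           O
END
"""


def helix_pdb(n_res=10):
    """Ideal poly-alanine α-helix with N/CA/C atoms, as PDB text."""
    lines = []
    serial = 1
    for i in range(n_res):
        for name, (dr, dphi, dz) in (("N", (1.5, -28.0, -0.9)),
                                     ("CA", (2.3, 0.0, 0.0)),
                                     ("C", (1.7, 26.0, 0.8))):
            a = np.radians(100.0 * i + dphi)
            x, y, z = dr * np.cos(a), dr * np.sin(a), 1.5 * i + dz
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} ALA A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           "
                f"{name[0]}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def mini_pdb(tmp_path_factory):
    p = tmp_path_factory.mktemp("pdb") / "mini.pdb"
    p.write_text(MINI_PDB)
    return p


@pytest.fixture(scope="session")
def helix_pdb_path(tmp_path_factory):
    p = tmp_path_factory.mktemp("pdb") / "helix.pdb"
    p.write_text(helix_pdb(10))
    return p


@pytest.fixture(scope="session")
def duplex():
    return forkcg.generate_bform_duplex("ACGTACGTAC")


@pytest.fixture(scope="session")
def duplex_system(duplex):
    from forkcg.model import duplex_stabilization_contacts
    from forkcg.system import compile_system

    cs = duplex_stabilization_contacts(duplex)
    return compile_system(duplex.topology, duplex.coords, [cs])


@pytest.fixture(scope="session")
def small_toy():
    return forkcg.build_toy_replisome(
        forkcg.ToySpec(chain_length=20, tail_length=40, carrier_length=24,
                       carrier_loop_length=12))
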
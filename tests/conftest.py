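"""Shared fixtures: typing table, synthetic pools, and a tiny PDB file."""

from __future__ import annotations

import numpy as np
import pytest

import hippo as hp


@pytest.fixture(scope="session")
def table():
    return hp.default_typing_table()


@pytest.fixture(scope="session")
def small_pool():
    """A reduced planted-signal pool for unit tests (150 NN / 1350 non)."""
    return hp.generate_pool(hp.GeneratorConfig(seed=7, n_near=150, n_non=1350))


@pytest.fixture(scope="session")
def small_hset(small_pool):
    return hp.derive_histogram_set(small_pool)


@pytest.fixture(scope="session")
def recovery_pool():
    """The default study-condition pool: 300 NN / 5700 non, planted contact."""
    return hp.generate_pool(hp.GeneratorConfig(seed=7))


def _atom_line(serial, name, res, chain, seq, x, y, z, el):
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {nm} {res:>3s} {chain}{seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
    )


CYTOSINE_ATOMS = [
    ("P", "P"), ("OP1", "O"), ("OP2", "O"),
    ("C5'", "C"), ("C4'", "C"), ("O4'", "O"),
    ("C3'", "C"), ("C2'", "C"), ("C1'", "C"), ("O2'", "O"), ("O3'", "O"),
    ("N1", "N"), ("C2", "C"), ("O2", "O"),
    ("N3", "N"), ("C4", "C"), ("N4", "N"),
    ("C5", "C"), ("C6", "C"),
]

TRP_ATOMS = [
    ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"),
    ("CB", "C"), ("CG", "C"), ("CD1", "C"), ("NE1", "N"),
    ("CD2", "C"), ("CE2", "C"), ("CE3", "C"),
    ("CZ2", "C"), ("CZ3", "C"), ("CH2", "C"),
]


def write_pdb(path, residues, coords=None):
    """residues: list of (resname, chain, seq, atom list); coords optional map."""
    lines = []
    serial = 0
    rng = np.random.default_rng(0)
    for resname, chain, seq, atoms in residues:
        for name, el in atoms:
            serial += 1
            if coords is not None and (seq, name) in coords:
                x, y, z = coords[(seq, name)]
            else:
                x, y, z = rng.uniform(0, 10, 3)
            lines.append(_atom_line(serial, name, resname, chain, seq, x, y, z, el))
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def cytosine_pdb(tmp_path):
    return write_pdb(tmp_path / "cyt.pdb", [("C", "B", 1, CYTOSINE_ATOMS)])


@pytest.fixture
def trp_pdb(tmp_path):
    return write_pdb(tmp_path / "trp.pdb", [("TRP", "A", 1, TRP_ATOMS)])
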
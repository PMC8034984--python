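"""Shared fixtures: tiny PDB texts, small models, and reusable BD runs."""

import numpy as np
import pytest

import rigidnse as rn


def atom_line(serial, name, resname, chain, resid, x, y, z, element=None):
    """Format one fixed-width PDB ATOM/HETATM record."""
    element = element or name[0]
    record = "HETATM" if resname in ("HOH", "LIG", "NAG") else "ATOM  "
    return (
        f"{record}{serial:5d} {name:^4s} {resname:>3s} {chain:1s}{resid:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture(scope="session")
def pdb_one_residue():
    lines = [
        atom_line(1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0, "N"),
        atom_line(2, "CA", "ALA", "A", 1, 2.0, 2.0, 3.0, "C"),
        atom_line(3, "C", "ALA", "A", 1, 3.0, 2.0, 3.0, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def pdb_collinear():
    """Three single-atom (CA-only) residues at x = 0, 1, 2 A."""
    lines = [
        atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
        atom_line(2, "CA", "GLY", "A", 2, 1.0, 0.0, 0.0, "C"),
        atom_line(3, "CA", "GLY", "A", 3, 2.0, 0.0, 0.0, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def pdb_mixed():
    """Seven amino-acid residues over two chains, plus waters and a ligand."""
    rng = np.random.default_rng(7)
    lines = []
    serial = 1
    resnames = ["ALA", "GLY", "SER", "LEU"]
    for chain, n_res in (("A", 4), ("B", 3)):
        for resid in range(1, n_res + 1):
            base = rng.uniform(-10, 10, 3)
            for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                x, y, z = base + rng.uniform(-1, 1, 3)
                lines.append(atom_line(serial, name, resnames[resid % 4],
                                       chain, resid, x, y, z, el))
                serial += 1
    for i in range(3):
        lines.append(atom_line(serial, "O", "HOH", "W", 100 + i,
                               float(i), 20.0, 20.0, "O"))
        serial += 1
    lines.append(atom_line(serial, "C1", "LIG", "L", 200, 5.0, 5.0, 5.0, "C"))
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def small_mab():
    return rn.make_synthetic_mab(beads_per_lobe=30, seed=3)


@pytest.fixture(scope="session")
def shell():
    return rn.make_spherical_shell(n_beads=200, radius=45.0)


@pytest.fixture(scope="session")
def iso_bd_traj(shell):
    """Isotropic free diffusion + rotation of the shell (spherical null)."""
    D = rn.DiffusionTensor.isotropic(D0=4.0, Dr=2.0e-3)
    return rn.run_bd(shell, D, dt=0.5, n_steps=12000, seed=11), D


@pytest.fixture(scope="session")
def mab_tensor(small_mab):
    return rn.estimate_diffusion_tensor(small_mab)
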
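import numpy as np
import pytest

from msagauss import MSA


@pytest.fixture
def tiny_msa() -> MSA:
    """Five short sequences with a gap and a duplicated pair."""
    return MSA(
        sequences=["ACDEF", "ACDEG", "ACDEG", "AC-EF", "MKVWY"],
        ids=["a", "b", "b2", "c", "d"],
    )


def format_pdb_atom(serial, name, resname, resseq, x, y, z, element, chain="A"):
    return (
        f"ATOM  {serial:5d} {name:^4s} {resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_toy_pdb(path, residues):
    """Write a minimal single-chain PDB.

    ``residues`` is a list of atom lists; each atom is
    (name, element, x, y, z).
    """
    lines = []
    serial = 1
    for resseq, atoms in enumerate(residues, start=1):
        for name, element, x, y, z in atoms:
            lines.append(format_pdb_atom(serial, name, "ALA", resseq, x, y, z, element))
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def random_toy_structure(rng: np.random.Generator, n_residues=8, max_atoms=4, box=25.0):
    """Random residues, each a small cloud of heavy atoms in a box."""
    residues = []
    for _ in range(n_residues):
        n_atoms = int(rng.integers(1, max_atoms + 1))
        center = rng.uniform(0, box, size=3)
        atoms = []
        for a in range(n_atoms):
            x, y, z = center + rng.normal(0, 1.5, size=3)
            atoms.append((f"C{a}", "C", x, y, z))
        residues.append(atoms)
    return residues


def brute_force_contacts(residues, threshold=8.0):
    """All-atom double loop over every atom pair (independent oracle)."""
    pairs = set()
    n = len(residues)
    for k in range(n):
        for l in range(k + 1, n):
            found = False
            for _, _, x1, y1, z1 in residues[k]:
                for _, _, x2, y2, z2 in residues[l]:
                    d = ((x1 - x2) ** 2 + (y1 - y2) ** 2 + (z1 - z2) ** 2) ** 0.5
                    if d < threshold:
                        found = True
                        break
                if found:
                    break
            if found:
                pairs.add((k + 1, l + 1))
    return pairs
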
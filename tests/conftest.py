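"""Shared fixtures: toy structures and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from methylassign.structure import Structure

#: side-chain heavy atoms per residue type, with plausible local geometry
_SIDE_CHAINS = {
    "LEU": {"CA": (0.0, 0.0, 0.0), "CB": (1.53, 0.0, 0.0),
            "CG": (2.1, 1.4, 0.0), "CD1": (3.63, 1.4, 0.0),
            "CD2": (1.55, 2.15, 1.2)},
    "VAL": {"CA": (0.0, 0.0, 0.0), "CB": (1.53, 0.0, 0.0),
            "CG1": (2.1, 1.4, 0.0), "CG2": (2.1, -0.75, 1.25)},
    "ILE": {"CA": (0.0, 0.0, 0.0), "CB": (1.53, 0.0, 0.0),
            "CG1": (2.1, 1.4, 0.0), "CG2": (2.1, -0.75, 1.25),
            "CD1": (3.63, 1.4, 0.0)},
    "MET": {"CA": (0.0, 0.0, 0.0), "CB": (1.53, 0.0, 0.0),
            "CG": (2.1, 1.4, 0.0), "SD": (3.9, 1.4, 0.0),
            "CE": (4.5, 3.0, 0.0)},
    "ALA": {"CA": (0.0, 0.0, 0.0), "CB": (1.53, 0.0, 0.0)},
}


def add_residue(structure: Structure, chain: str, number: int, restype: str,
                offset=(0.0, 0.0, 0.0)) -> None:
    """Place one residue with idealized-ish side-chain geometry at an offset."""
    for name, coord in _SIDE_CHAINS[restype].items():
        structure.add_atom(chain, number, restype, name,
                           np.asarray(coord) + np.asarray(offset))


def make_structure(residues, chain: str = "A", spacing: float = 20.0,
                   ) -> Structure:
    """Build a toy structure from a list of residue types, spaced apart."""
    st = Structure()
    for i, restype in enumerate(residues):
        add_residue(st, chain, i + 1, restype, offset=(spacing * i, 0.0, 0.0))
    return st


@pytest.fixture
def leucine_structure() -> Structure:
    return make_structure(["LEU"])


@pytest.fixture
def noise_free_dataset():
    from methylassign.synthetic import simulate_dataset

    return simulate_dataset(seed=11)


PDB_LINE = ("ATOM  {serial:5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}"
            "{num:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            "          {element:>2s}")


def structure_to_pdb(structure: Structure) -> str:
    """Render a toy Structure as minimal PDB text (for reader round-trips)."""
    lines = []
    serial = 1
    for (chain, num), res in sorted(structure.residues.items()):
        for name, coord in res.atoms.items():
            element = name[0] if name[0] in ("C", "N", "O", "S") else "C"
            lines.append(PDB_LINE.format(
                serial=serial, name=name, alt=" ", res=res.type, chain=chain,
                num=num, x=coord[0], y=coord[1], z=coord[2], occ=1.0, b=0.0,
                element=element))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
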
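"""Coordinate handling for methyl-bearing side chains.

Parses PDB/mmCIF files (via gemmi), enumerates the ILVM methyl groups that
carry signal in methyl-TROSY spectra of selectively labelled proteins, and
provides the geometric primitives the assignment workflow rests on:
inter-methyl distance matrices, nearest-methyl lookups, side-chain chi2
dihedrals and their rotamer classification.

Conventions
-----------
* Distances in angstroms, angles in degrees, IUPAC dihedral sign convention,
  chi2 in the half-open range (-180, +180].
* Methyl identifiers follow the grammar ``<one-letter><residue number>-<pseudo>``
  (e.g. ``L315-QD1``), where the pseudo-atom name is QD1 for Ile delta1 and
  Leu delta1, QD2 for Leu delta2, QG1/QG2 for Val gamma1/gamma2, QE for Met
  epsilon and QG2 for the optional Ile gamma2.
* Crystal structures usually lack protons; the methyl pseudo-atom (geometric
  centre of the three methyl protons) is then either approximated by the
  methyl carbon (``pseudo_mode="carbon"``, the default) or reconstructed on
  the local symmetry axis from idealized tetrahedral geometry
  (``pseudo_mode="ideal"``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("methylassign")

# Internal indexing is 0-based; residue numbers are kept exactly as authored
# in the coordinate file.

THREE_TO_ONE = {"ILE": "I", "LEU": "L", "VAL": "V", "MET": "M", "ALA": "A"}

#: residue type -> list of (label, methyl carbon, parent heavy atom,
#: pseudo-atom name, stereo descriptor). Heavy-atom path from CA is required
#: for a methyl to count as complete.
METHYL_DEFS: dict[str, list[tuple[str, str, str, str, str]]] = {
    "ILE": [("d1", "CD1", "CG1", "QD1", "n/a")],
    "LEU": [("d1", "CD1", "CG", "QD1", "pro-R"), ("d2", "CD2", "CG", "QD2", "pro-S")],
    "VAL": [("g1", "CG1", "CB", "QG1", "pro-R"), ("g2", "CG2", "CB", "QG2", "pro-S")],
    "MET": [("e", "CE", "SD", "QE", "n/a")],
}
#: optional Ile gamma2 (excluded by default: not labelled in standard schemes)
ILE_GAMMA2 = ("g2", "CG2", "CB", "QG2", "n/a")

#: heavy-atom chain from CA to the methyl carbon, per (residue type, label)
_HEAVY_PATH = {
    ("ILE", "d1"): ["CA", "CB", "CG1", "CD1"],
    ("ILE", "g2"): ["CA", "CB", "CG2"],
    ("LEU", "d1"): ["CA", "CB", "CG", "CD1"],
    ("LEU", "d2"): ["CA", "CB", "CG", "CD2"],
    ("VAL", "g1"): ["CA", "CB", "CG1"],
    ("VAL", "g2"): ["CA", "CB", "CG2"],
    ("MET", "e"): ["CA", "CB", "CG", "SD", "CE"],
}

#: three methyl protons, per methyl carbon name
_PROTON_NAMES = {
    "CD1": ["HD11", "HD12", "HD13"],
    "CD2": ["HD21", "HD22", "HD23"],
    "CG1": ["HG11", "HG12", "HG13"],
    "CG2": ["HG21", "HG22", "HG23"],
    "CE": ["HE1", "HE2", "HE3"],
}

# C-H bond 1.09 A at the tetrahedral angle puts the proton centroid
# 1.09*cos(180 - 109.47 deg) = 0.3633 A beyond the carbon on the bond axis.
_PSEUDO_AXIAL_OFFSET = 1.09 * math.cos(math.radians(180.0 - 109.47))

_LABEL_ORDER = {"d1": 0, "d2": 1, "g1": 2, "g2": 3, "e": 4}


@dataclass
class Residue:
    chain: str
    number: int
    type: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.number)


@dataclass
class Structure:
    """Minimal coordinate container: residues keyed by (chain, number)."""

    residues: dict[tuple[str, int], Residue] = field(default_factory=dict)

    @property
    def chains(self) -> list[str]:
        return sorted({c for c, _ in self.residues})

    def residue(self, chain: str, number: int) -> Residue:
        try:
            return self.residues[(chain, number)]
        except KeyError:
            raise KeyError(f"residue {number} not found in chain {chain!r}")

    def add_atom(self, chain: str, number: int, restype: str, name: str,
                 coord: Sequence[float], altloc: str = "") -> None:
        coord = np.asarray(coord, dtype=float)
        if not np.all(np.isfinite(coord)):
            raise ValueError(f"non-finite coordinate for {chain}/{number}/{name}")
        res = self.residues.setdefault((chain, number), Residue(chain, number, restype))
        if name in res.atoms and altloc not in ("", "A"):
            return
        res.atoms[name] = coord


def read_structure(path: str | Path) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only altloc '' or 'A' is kept (others are logged once per file); waters
    are skipped. The format is inferred from the file contents by gemmi.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    out = Structure()
    dropped_altloc = 0
    model = st[0]
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            for atom in res:
                if atom.altloc not in ("\0", "", "A"):
                    dropped_altloc += 1
                    continue
                out.add_atom(chain.name, res.seqid.num, res.name.upper(),
                             atom.name, [atom.pos.x, atom.pos.y, atom.pos.z])
    if dropped_altloc:
        logger.warning("%s: dropped %d atoms with altloc other than ''/'A'",
                       path, dropped_altloc)
    return out


@dataclass(frozen=True)
class MethylGroup:
    """One ILVM methyl site with its carbon and proton-centroid positions."""

    chain: str
    residue_number: int
    residue_type: str
    label: str              # d1, d2, g1, g2, e
    carbon: np.ndarray
    pseudo: np.ndarray      # geometric centre of the 3 methyl protons (or fallback)
    stereo: str             # pro-R | pro-S | n/a

    @property
    def pseudo_name(self) -> str:
        defs = METHYL_DEFS[self.residue_type] + (
            [ILE_GAMMA2] if self.residue_type == "ILE" else [])
        for lab, _c, _p, pseudo, _s in defs:
            if lab == self.label:
                return pseudo
        raise ValueError(f"unknown label {self.label}")  # pragma: no cover

    @property
    def id(self) -> str:
        return f"{THREE_TO_ONE[self.residue_type]}{self.residue_number}-{self.pseudo_name}"

    def sort_key(self) -> tuple:
        return (self.chain, self.residue_number, _LABEL_ORDER[self.label])


def _pseudo_atom(res: Residue, carbon_name: str, parent_name: str,
                 mode: str) -> Optional[np.ndarray]:
    """Proton centroid if protons are present, else the requested fallback."""
    protons = _PROTON_NAMES.get(carbon_name, [])
    if protons and all(h in res.atoms for h in protons):
        return np.mean([res.atoms[h] for h in protons], axis=0)
    carbon = res.atoms[carbon_name]
    if mode == "carbon":
        return carbon
    if mode == "ideal":
        axis = carbon - res.atoms[parent_name]
        norm = np.linalg.norm(axis)
        if norm == 0:
            return None
        return carbon + _PSEUDO_AXIAL_OFFSET * axis / norm
    raise ValueError(f"unknown pseudo_mode {mode!r}")


def extract_methyls(structure: Structure, chain: str = "A",
                    include_ile_gamma2: bool = False,
                    pseudo_mode: str = "carbon") -> list[MethylGroup]:
    """Enumerate the ILVM methyl groups of one chain.

    One group per Ile delta1, Met epsilon, Leu delta1/delta2 and Val
    gamma1/gamma2; Ile gamma2 only on request. Residues missing side-chain
    heavy atoms are excluded with a warning. Output is sorted by
    (residue number, label).
    """
    if chain not in structure.chains:
        raise KeyError(f"chain {chain!r} not present (have {structure.chains})")
    methyls: list[MethylGroup] = []
    for (ch, num), res in structure.residues.items():
        if ch != chain or res.type not in METHYL_DEFS:
            continue
        defs = list(METHYL_DEFS[res.type])
        if res.type == "ILE" and include_ile_gamma2:
            defs.append(ILE_GAMMA2)
        for label, cname, pname, _pseudo, stereo in defs:
            path_atoms = _HEAVY_PATH[(res.type, label)]
            if not all(a in res.atoms for a in path_atoms):
                missing = [a for a in path_atoms if a not in res.atoms]
                logger.warning("%s%d %s: incomplete side chain (missing %s); "
                               "methyl excluded", ch, num, label, ",".join(missing))
                continue
            pseudo = _pseudo_atom(res, cname, pname, pseudo_mode)
            if pseudo is None:
                logger.warning("%s%d %s: degenerate geometry; methyl excluded",
                               ch, num, label)
                continue
            methyls.append(MethylGroup(ch, num, res.type, label,
                                       res.atoms[cname], pseudo, stereo))
    methyls.sort(key=MethylGroup.sort_key)
    return methyls


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix between methyl pseudo-atoms."""

    ids: list[str]
    values: np.ndarray  # (n, n), angstroms

    def __post_init__(self) -> None:
        self._index = {m: i for i, m in enumerate(self.ids)}

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def __len__(self) -> int:
        return len(self.ids)


def methyl_distance_matrix(methyls: Sequence[MethylGroup],
                           use: str = "pseudo") -> DistanceMatrix:
    """Pairwise Euclidean distances between methyl sites.

    ``use`` selects the reference point: ``"pseudo"`` (proton centroid /
    fallback) or ``"carbon"``.
    """
    if not methyls:
        raise ValueError("need at least one methyl")
    pts = np.array([getattr(m, "pseudo" if use == "pseudo" else "carbon")
                    for m in methyls])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return DistanceMatrix([m.id for m in methyls], d)


def nearest_methyl(methyl_id: str, matrix: DistanceMatrix,
                   methyls: Sequence[MethylGroup],
                   exclude_same_residue: bool = True,
                   ) -> Optional[tuple[str, float]]:
    """Closest partner methyl (id, distance); ``None`` if the methyl is isolated.

    Ties are broken by lower residue number, then label order. With
    ``exclude_same_residue`` the geminal partner (and any other methyl of the
    same residue) is skipped.
    """
    by_id = {m.id: m for m in methyls}
    me = by_id[methyl_id]
    best: Optional[tuple[float, tuple, str]] = None
    for other in methyls:
        if other.id == methyl_id:
            continue
        if exclude_same_residue and (other.chain, other.residue_number) == \
                (me.chain, me.residue_number):
            continue
        d = matrix.distance(methyl_id, other.id)
        key = (d, other.sort_key(), other.id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], best[0]


def residue_nearest_methyl(structure_methyls: Sequence[MethylGroup],
                           matrix: DistanceMatrix, chain: str,
                           residue_number: int) -> Optional[tuple[str, float]]:
    """Closest external methyl to any methyl of one residue.

    This is the quantity quoted when a residue is called structurally
    isolated: the minimum over the residue's own methyls of the distance to
    the nearest methyl on a *different* residue.
    """
    own = [m for m in structure_methyls
           if m.chain == chain and m.residue_number == residue_number]
    if not own:
        raise KeyError(f"no methyls for {chain}/{residue_number}")
    best: Optional[tuple[str, float]] = None
    for m in own:
        hit = nearest_methyl(m.id, matrix, structure_methyls,
                             exclude_same_residue=True)
        if hit is not None and (best is None or hit[1] < best[1]):
            best = hit
    return best


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
             p4: np.ndarray) -> float:
    """Dihedral angle p1-p2-p3-p4 in degrees, IUPAC sign, range (-180, 180]."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or norm_b2 < 1e-10:
        raise ValueError("dihedral undefined for collinear atoms")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


_CHI2_ATOMS = {"LEU": ["CA", "CB", "CG", "CD1"],
               "ILE": ["CA", "CB", "CG1", "CD1"]}


def chi2_dihedral(structure: Structure, chain: str, residue_number: int) -> float:
    """chi2 side-chain dihedral (degrees) for a Leu or Ile residue.

    Leu: CA-CB-CG-CD1; Ile: CA-CB-CG1-CD1. Other residue types are not
    supported (Met chi3 is out of scope).
    """
    res = structure.residue(chain, residue_number)
    try:
        names = _CHI2_ATOMS[res.type]
    except KeyError:
        raise ValueError(f"chi2 not defined for residue type {res.type}")
    missing = [n for n in names if n not in res.atoms]
    if missing:
        raise ValueError(f"{chain}{residue_number}: missing atoms {missing}")
    return dihedral(*(res.atoms[n] for n in names))


def classify_rotamer(chi2: float) -> str:
    """Bin a chi2 angle into trans / gauche+ / gauche-.

    Half-open 120-degree bins: trans = (120, 180] u (-180, -120],
    gauche+ = (0, 120], gauche- = (-120, 0]. Total over (-180, 180].
    """
    if not (-180.0 < chi2 <= 180.0):
        raise ValueError(f"chi2 {chi2} outside (-180, 180]")
    if chi2 > 120.0 or chi2 <= -120.0:
        return "trans"
    if chi2 > 0.0:
        return "gauche+"
    return "gauche-"
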
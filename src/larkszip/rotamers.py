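"""Side-chain construction and a coarse backbone-independent rotamer library.

Ideal residue geometry (atom names, elements, bonds, coordinates) comes from
the chemical component dictionary bundled with biotite.  A side chain is
grafted by superposing the ideal residue's N/CA/C triad onto the target
backbone frame and then rotating each chi torsion to the requested rotamer
value.  The rotamer library is a plain chi grid (-60/60/180 per rotatable
bond, capped at 9 rotamers) — deliberately coarse so that exhaustive
enumeration over short templates stays cheap enough to serve as a test
oracle for the packer.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import biotite.structure.info as struc_info

from .geometry import dihedral, kabsch, rotation_about_axis

__all__ = [
    "AA1_TO_AA3",
    "AA3_TO_AA1",
    "CHI_ATOMS",
    "RotamerLibrary",
    "default_rotamer_library",
    "build_side_chain",
    "residue_atom_count",
]

AA1_TO_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_AA1 = {v: k for k, v in AA1_TO_AA3.items()}

# standard chi-angle atom quadruples
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

BACKBONE_NAMES = ("N", "CA", "C", "O")

# hydrogen-bond roles; donors are heavy atoms carrying at least one polar H
_DONOR_ATOMS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
}
_ACCEPTOR_EXTRA = {("HIS", "ND1"), ("HIS", "NE2")}

# atoms carrying (part of) a formal charge at neutral pH; their burial is
# penalised much more strongly than ordinary polar atoms (Born desolvation)
_CHARGED_ATOMS = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@lru_cache(maxsize=None)
def _ideal_residue(aa3: str):
    """Heavy-atom ideal residue: names, elements, coords, bond adjacency."""
    res = struc_info.residue(aa3)
    keep = (res.element != "H") & (res.atom_name != "OXT")
    # remap bonds onto the kept subset
    names = list(res.atom_name[keep])
    coords = res.coord[keep].astype(float)
    elements = list(res.element[keep])
    index_of = {n: i for i, n in enumerate(names)}
    adj: list[set] = [set() for _ in names]
    all_names = list(res.atom_name)
    for a, b, _ in res.bonds.as_array():
        na, nb = all_names[a], all_names[b]
        if na in index_of and nb in index_of:
            adj[index_of[na]].add(index_of[nb])
            adj[index_of[nb]].add(index_of[na])
    return names, elements, coords, adj


def residue_atom_count(aa1: str) -> int:
    """Heavy atoms per residue as threaded (backbone N/CA/C/O + side chain)."""
    names, _, _, _ = _ideal_residue(AA1_TO_AA3[aa1])
    return len(names)


def _downstream_atoms(adj, names, axis_a: str, axis_b: str) -> list[int]:
    """Atoms on the axis_b side of bond axis_a-axis_b (excluding both)."""
    index_of = {n: i for i, n in enumerate(names)}
    ia, ib = index_of[axis_a], index_of[axis_b]
    seen = {ia, ib}
    stack = [ib]
    out = []
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if j not in seen:
                seen.add(j)
                out.append(j)
                stack.append(j)
    return out


class SideChainAtoms:
    """Names / elements / coords of one residue's non-backbone heavy atoms,
    together with the per-atom metadata the energy function needs."""

    __slots__ = ("names", "elements", "coords", "radii", "polar", "charged",
                 "donor", "acceptor", "antecedent")

    def __init__(self, names, elements, coords, antecedent):
        self.names = names
        self.elements = elements
        self.coords = np.asarray(coords, float)
        self.radii = np.array([VDW_RADII[e] for e in elements])
        self.polar = np.array([e in ("N", "O") for e in elements])
        self.charged = np.zeros(len(names), bool)
        self.donor = np.zeros(len(names), bool)
        self.acceptor = np.zeros(len(names), bool)
        self.antecedent = np.asarray(antecedent, float)


def build_side_chain(aa1: str, backbone: dict, chis: tuple[float, ...]) -> SideChainAtoms:
    """Construct the side chain of residue type ``aa1`` on a backbone frame.

    ``backbone`` maps "N"/"CA"/"C" to coordinates.  ``chis`` must match the
    number of rotatable bonds of the residue type (empty for Gly/Ala/Pro).
    Returns atoms beyond the backbone (CB and outward); for glycine the atom
    list is empty.
    """
    aa3 = AA1_TO_AA3[aa1]
    names, elements, coords, adj = _ideal_residue(aa3)
    chi_defs = CHI_ATOMS.get(aa3, []) if aa3 != "PRO" else []
    if len(chis) != len(chi_defs):
        raise ValueError(f"{aa3} expects {len(chi_defs)} chi angles, got {len(chis)}")
    index_of = {n: i for i, n in enumerate(names)}
    work = coords.copy()
    # superpose ideal N/CA/C onto the target backbone frame
    tri = np.array([work[index_of["N"]], work[index_of["CA"]], work[index_of["C"]]])
    target = np.array([backbone["N"], backbone["CA"], backbone["C"]])
    R, t = kabsch(tri, target)
    work = work @ R.T + t
    # set each chi torsion
    for chi_def, chi in zip(chi_defs, chis):
        a, b, c, d = (index_of[n] for n in chi_def)
        current = dihedral(work[a], work[b], work[c], work[d])
        rot = rotation_about_axis(work[c] - work[b], chi - current)
        moving = _downstream_atoms(adj, names, chi_def[1], chi_def[2])
        work[moving] = (work[moving] - work[b]) @ rot.T + work[b]

    side_idx = [i for i, n in enumerate(names) if n not in BACKBONE_NAMES]
    out_names = [names[i] for i in side_idx]
    out_elem = [elements[i] for i in side_idx]
    out_coords = work[side_idx]
    # antecedent = first bonded heavy neighbour (for H-bond angle checks)
    ante = np.zeros((len(side_idx), 3))
    for k, i in enumerate(side_idx):
        nb = sorted(adj[i])
        ante[k] = work[nb[0]] if nb else work[index_of["CA"]]
    sc = SideChainAtoms(out_names, out_elem, out_coords, ante)
    for k, n in enumerate(out_names):
        if (aa3, n) in _DONOR_ATOMS:
            sc.donor[k] = True
        if out_elem[k] == "O" or (aa3, n) in _ACCEPTOR_EXTRA:
            sc.acceptor[k] = True
        if (aa3, n) in _CHARGED_ATOMS:
            sc.charged[k] = True
    return sc


class RotamerLibrary:
    """Map residue type (one-letter) -> list of chi tuples."""

    def __init__(self, chis_by_type: dict[str, list[tuple[float, ...]]]):
        missing = set(AA1_TO_AA3) - set(chis_by_type)
        if missing:
            raise ValueError(f"rotamer library missing residue types: {sorted(missing)}")
        for aa in ("G", "A"):
            if len(chis_by_type[aa]) != 1:
                raise ValueError("glycine and alanine must have exactly one trivial rotamer")
        self.chis_by_type = chis_by_type

    def rotamers(self, aa1: str) -> list[tuple[float, ...]]:
        return self.chis_by_type[aa1]

    def __len__(self) -> int:
        return sum(len(v) for v in self.chis_by_type.values())


#: residues whose chi2 rotates an sp2 ring plane: +-90 orients the ring
#: perpendicular to the CA-CB-CG plane, 0 keeps it eclipsed
_AROMATIC = {"PHE", "TYR", "TRP", "HIS"}


def default_rotamer_library() -> RotamerLibrary:
    """Chi grid of -60/60/180 on chi1 (and chi2 where present); chi3+ trans.

    Aromatic chi2 uses the sp2-appropriate -90/0/+90 grid instead.  Capped at
    9 rotamers per residue type; proline keeps its single ideal ring pucker.
    """
    grid = (-60.0, 60.0, 180.0)
    ring_grid = (-90.0, 0.0, 90.0)
    lib: dict[str, list[tuple[float, ...]]] = {}
    for aa1, aa3 in AA1_TO_AA3.items():
        if aa3 in ("GLY", "ALA", "PRO"):
            lib[aa1] = [()]
            continue
        n_chi = len(CHI_ATOMS[aa3])
        if n_chi == 1:
            lib[aa1] = [(c,) for c in grid]
        else:
            grid2 = ring_grid if aa3 in _AROMATIC else grid
            tail = (180.0,) * (n_chi - 2)
            lib[aa1] = [(c1, c2) + tail for c1 in grid for c2 in grid2]
    return RotamerLibrary(lib)
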
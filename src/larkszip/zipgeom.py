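"""Geometric analysis of fibril structures: strand/sheet detection, steric-
zipper class assignment (1-8), backbone conformation labelling, and buried
interface area.

A steric-zipper class is determined by three binary attributes:

* within-sheet strand orientation — parallel or antiparallel;
* face packing — whether the two mating sheets present the same side-chain
  face (face-to-face) or opposite faces (face-to-back), read from the residue
  parity of interface-pointing side chains;
* sheet polarity — whether the strand vectors of the closest cross-interface
  strand pair point the same way (up-up) or opposite ways (up-down).

The attribute-to-class mapping lives in ``CLASS_TABLE`` so it can be audited
against deposited reference structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import dihedral
from .io import StructureModel
from .templates import virtual_cb

logger = logging.getLogger(__name__)

#: phi/psi region bounds (degrees) for backbone conformation labels
CONFORMATION_REGIONS = {
    "extended_min_abs": 155.0,           # |phi| and |psi| at least this
    "pleated_phi": (-150.0, -90.0),
    "pleated_psi": (90.0, 150.0),
    "kink_psi_abs_max": 60.0,            # |psi| below this counts as kinked
}

#: (within_sheet, face_packing, sheet_polarity) -> class number
CLASS_TABLE = {
    ("parallel", "face-to-face", "up-up"): 1,
    ("parallel", "face-to-back", "up-up"): 2,
    ("parallel", "face-to-face", "up-down"): 3,
    ("parallel", "face-to-back", "up-down"): 4,
    ("antiparallel", "face-to-face", "up-up"): 5,
    ("antiparallel", "face-to-back", "up-up"): 6,
    ("antiparallel", "face-to-face", "up-down"): 7,
    ("antiparallel", "face-to-back", "up-down"): 8,
}

SHEET_LINK_CA_CUTOFF = 5.5   # A, min CA-CA distance linking strands of a sheet
SHEET_LINK_NO_CUTOFF = 3.8   # A, backbone N...O evidence of hydrogen bonding
INTERFACE_MAX_SPACING = 12.0  # A, beyond this no zipper interface exists

VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# strand extraction


@dataclass
class Strand:
    chain_id: str
    ca: np.ndarray          # (n, 3)
    n_atoms: np.ndarray     # backbone N coordinates
    o_atoms: np.ndarray     # backbone O coordinates
    side_vectors: np.ndarray  # per-residue CB(-like) minus CA

    @property
    def direction(self) -> np.ndarray:
        v = self.ca[-1] - self.ca[0]
        return v / np.linalg.norm(v)

    @property
    def centroid(self) -> np.ndarray:
        return self.ca.mean(axis=0)


@dataclass
class StrandSet:
    strands: list[Strand]
    sheets: list[list[int]]  # strand indices per sheet

    def sheet_of(self, idx: int) -> int:
        for s, members in enumerate(self.sheets):
            if idx in members:
                return s
        raise KeyError(idx)


@dataclass
class ZipperClassification:
    within_sheet: str
    face_packing: str
    sheet_polarity: str
    class_number: int


def _extract_strands(structure: StructureModel) -> list[Strand]:
    strands = []
    for cid in structure.chain_ids():
        residues = structure.chain_residues(cid)
        ca, nn, oo, side = [], [], [], []
        for _, name, atoms in residues:
            if not {"N", "CA", "C"} <= set(atoms):
                continue
            n = np.array(atoms["N"])
            c_a = np.array(atoms["CA"])
            c = np.array(atoms["C"])
            ca.append(c_a)
            nn.append(n)
            oo.append(np.array(atoms["O"]) if "O" in atoms else c)
            cb = np.array(atoms["CB"]) if "CB" in atoms else virtual_cb(n, c_a, c)
            side.append(cb - c_a)
        if len(ca) >= 2:
            strands.append(Strand(cid, np.array(ca), np.array(nn),
                                  np.array(oo), np.array(side)))
    return strands


def assign_strands(structure: StructureModel) -> StrandSet:
    """Detect strands and cluster them into sheets.

    Two strands belong to the same sheet when their minimum CA-CA distance is
    within 5.5 A and their backbones show N...O hydrogen-bond contacts;
    clustering is single linkage.
    """
    strands = _extract_strands(structure)
    if len(strands) < 2:
        raise GeometryError(
            "need at least two polymer chains; expand the fibril assembly "
            "(crystallographic neighbours) first")
    n = len(strands)
    linked = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = strands[i], strands[j]
            dca = np.linalg.norm(a.ca[:, None, :] - b.ca[None, :, :], axis=-1).min()
            dno = min(
                np.linalg.norm(a.n_atoms[:, None, :] - b.o_atoms[None, :, :], axis=-1).min(),
                np.linalg.norm(b.n_atoms[:, None, :] - a.o_atoms[None, :, :], axis=-1).min())
            linked[i, j] = linked[j, i] = (dca <= SHEET_LINK_CA_CUTOFF
                                           and dno <= SHEET_LINK_NO_CUTOFF)
    # single-linkage connected components
    sheets = []
    unassigned = set(range(n))
    while unassigned:
        seed = min(unassigned)
        comp = {seed}
        frontier = [seed]
        while frontier:
            i = frontier.pop()
            for j in range(n):
                if j not in comp and linked[i, j]:
                    comp.add(j)
                    frontier.append(j)
        unassigned -= comp
        sheets.append(sorted(comp))
    sheets.sort(key=lambda m: (-len(m), m[0]))
    return StrandSet(strands=strands, sheets=sheets)


def within_sheet_orientation(strand_set: StrandSet, sheet: int) -> str:
    """parallel / antiparallel / other for one sheet (>= 2 strands)."""
    members = strand_set.sheets[sheet]
    if len(members) < 2:
        raise GeometryError("sheet has fewer than two strands")
    strands = [strand_set.strands[i] for i in members]
    # order along the stacking axis: project centroids on the axis of largest
    # centroid spread
    cents = np.array([s.centroid for s in strands])
    axis = np.linalg.svd(cents - cents.mean(axis=0))[2][0]
    order = np.argsort(cents @ axis)
    dots = []
    for k in range(len(order) - 1):
        a = strands[order[k]]
        b = strands[order[k + 1]]
        dots.append(float(np.dot(a.direction, b.direction)))
    if all(d > 0 for d in dots):
        return "parallel"
    if all(d < 0 for d in dots):
        return "antiparallel"
    logger.warning("mixed strand orientations in sheet %d: %s", sheet,
                   np.round(dots, 2))
    return "other"


def _interface_normal(a: Strand, b: Strand) -> np.ndarray:
    v = b.centroid - a.centroid
    d = a.direction
    v = v - np.dot(v, d) * d
    return v / np.linalg.norm(v)


def _face_parity(strand: Strand, toward: np.ndarray) -> int:
    """0 if even-indexed residues point toward the interface, else 1."""
    proj = strand.side_vectors @ toward
    even = proj[0::2].mean()
    odd = proj[1::2].mean() if len(proj) > 1 else -even
    return 0 if even > odd else 1


def classify_zipper(structure: StructureModel) -> ZipperClassification:
    """Assign the steric-zipper class (1-8) of a two-sheet fibril."""
    ss = assign_strands(structure)
    if len(ss.sheets) < 2:
        raise GeometryError("only one sheet detected; no zipper interface")
    s0, s1 = 0, 1  # two largest sheets (sorted)
    strands0 = [ss.strands[i] for i in ss.sheets[s0]]
    strands1 = [ss.strands[i] for i in ss.sheets[s1]]
    # interface spacing check
    gap = min(np.linalg.norm(a.centroid - b.centroid)
              for a in strands0 for b in strands1)
    if gap > INTERFACE_MAX_SPACING:
        raise GeometryError(
            f"sheet spacing {gap:.1f} A exceeds {INTERFACE_MAX_SPACING} A; "
            "no detectable zipper interface")

    within0 = within_sheet_orientation(ss, s0) if len(strands0) > 1 else None
    within1 = within_sheet_orientation(ss, s1) if len(strands1) > 1 else None
    within = within0 or within1
    if within1 is not None and within0 is not None and within0 != within1:
        raise GeometryError("sheets disagree on strand orientation")
    if within is None or within == "other":
        raise GeometryError("cannot determine within-sheet orientation")

    # reference pair: closest strands across the interface (deterministic)
    pairs = [(np.linalg.norm(a.centroid - b.centroid), ia, ib)
             for ia, a in enumerate(strands0) for ib, b in enumerate(strands1)]
    _, ia, ib = min(pairs, key=lambda t: (round(t[0], 6), t[1], t[2]))
    a, b = strands0[ia], strands1[ib]

    polarity = "up-up" if float(np.dot(a.direction, b.direction)) > 0 else "up-down"
    n_ab = _interface_normal(a, b)
    parity_a = _face_parity(a, n_ab)
    parity_b = _face_parity(b, -n_ab)
    face = "face-to-face" if parity_a == parity_b else "face-to-back"

    cls = CLASS_TABLE[(within, face, polarity)]
    return ZipperClassification(within_sheet=within, face_packing=face,
                                sheet_polarity=polarity, class_number=cls)


# ---------------------------------------------------------------------------
# backbone conformation


def classify_backbone_conformation(phi: float, psi: float) -> str:
    """Label a (phi, psi) pair: extended / pleated / kinked / other."""
    r = CONFORMATION_REGIONS
    if abs(phi) >= r["extended_min_abs"] and abs(psi) >= r["extended_min_abs"]:
        return "extended"
    lo, hi = r["pleated_phi"]
    plo, phi_hi = r["pleated_psi"]
    if lo <= phi <= hi and plo <= psi <= phi_hi:
        return "pleated"
    if phi > 0 or abs(psi) < r["kink_psi_abs_max"]:
        return "kinked"
    return "other"


def measure_dihedrals_chain(structure: StructureModel, chain_id: str):
    """Per-residue (res_seq, phi, psi) for interior residues of a chain."""
    residues = structure.chain_residues(chain_id)
    out = []
    for k in range(1, len(residues) - 1):
        _, _, prev_atoms = residues[k - 1]
        seq, _, atoms = residues[k]
        _, _, next_atoms = residues[k + 1]
        needed = ("C" in prev_atoms and {"N", "CA", "C"} <= set(atoms)
                  and "N" in next_atoms)
        if not needed:
            out.append((seq, None, None))
            continue
        phi = dihedral(prev_atoms["C"], atoms["N"], atoms["CA"], atoms["C"])
        psi = dihedral(atoms["N"], atoms["CA"], atoms["C"], next_atoms["N"])
        out.append((seq, phi, psi))
    return out


def pleat_profile(structure: StructureModel, chain_id: str) -> list[tuple[int, str]]:
    """Conformation label per interior residue of a chain (terminals skipped)."""
    residues = structure.chain_residues(chain_id)
    if len(residues) < 3:
        raise GeometryError("chain must have at least 3 residues")
    profile = []
    for seq, phi, psi in measure_dihedrals_chain(structure, chain_id):
        if phi is None:
            logger.warning("chain %s residue %d missing backbone atoms", chain_id, seq)
            profile.append((seq, "other"))
        else:
            profile.append((seq, classify_backbone_conformation(phi, psi)))
    return profile


# ---------------------------------------------------------------------------
# surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
         n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point sampling."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe
    n = len(coords)
    pts = _sphere_points(n_points)
    out = np.zeros(n)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    for i in range(n):
        neigh = np.where((d2[i] < (radii[i] + radii) ** 2) & (np.arange(n) != i))[0]
        surface = coords[i] + radii[i] * pts
        if len(neigh):
            dist2 = np.sum((surface[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=-1)
            buried = (dist2 < (radii[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return out


def _atom_arrays(structure: StructureModel, chains: list[str],
                 include_ligands: bool = False):
    coords, radii = [], []
    for a in structure.atoms:
        if a.record_class == "water":
            continue
        if a.record_class == "ligand" and not include_ligands:
            continue
        if a.record_class == "polymer" and a.chain_id not in chains:
            continue
        if a.record_class == "ligand" and a.chain_id not in chains:
            continue
        if a.element == "H":
            continue
        coords.append((a.x, a.y, a.z))
        radii.append(VDW.get(a.element or a.name[:1], 1.70))
    return np.array(coords), np.array(radii)


def buried_interface_area(structure: StructureModel, probe: float = 1.4,
                          n_points: int = 960,
                          include_ligands: bool = False) -> float:
    """Surface area buried between the two sheets, in A^2 per strand layer.

    buried = [SASA(sheet A) + SASA(sheet B) - SASA(complex)] / 2, divided by
    the number of strand layers (strands per sheet).
    """
    ss = assign_strands(structure)
    if len(ss.sheets) < 2:
        raise GeometryError("need two sheets for an interface")
    chains_a = [ss.strands[i].chain_id for i in ss.sheets[0]]
    chains_b = [ss.strands[i].chain_id for i in ss.sheets[1]]
    ca_, ra_ = _atom_arrays(structure, chains_a, include_ligands)
    cb_, rb_ = _atom_arrays(structure, chains_b, include_ligands)
    cab = np.vstack([ca_, cb_])
    rab = np.concatenate([ra_, rb_])
    sa = sasa(ca_, ra_, probe, n_points).sum()
    sb = sasa(cb_, rb_, probe, n_points).sum()
    sab = sasa(cab, rab, probe, n_points).sum()
    buried = max(0.0, (sa + sb - sab) / 2.0)
    n_layers = max(len(chains_a), len(chains_b))
    return buried / n_layers
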
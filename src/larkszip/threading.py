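"""Fixed-backbone threading: graft a sequence onto a fibril assembly, pack
side chains by discrete rotamer search, and score with a decomposed energy.

The energy is an original four-term function in arbitrary units:

* ``E_rep``  — steric repulsion over atom pairs closer than the clash onset
  r0 = 0.85 (rvdw_i + rvdw_j): soft-quadratic in the fractional overlap plus
  a hard sixth-power term so that grazing contacts are tolerated but deep
  interpenetration is prohibitive; always >= 0.
* ``E_att``  — packing attraction: every nonpolar heavy atom accumulates a
  short-range contact well from nonpolar partners (1 at vdW contact, ramping
  to 0 one Angstrom further out), saturated per atom, and contributes its
  negative; always <= 0.  The short range means only genuine interdigitation
  pays — atoms merely sharing the assembly do not.
* ``E_solv`` — burial signed by polarity: per-atom occlusion (linear kernel,
  5.5 A cutoff) saturates to a burial fraction in [0, 1]; buried polar atoms
  cost +1, buried nonpolar atoms pay -0.5, scaled by that fraction.
* ``E_hb``   — geometric hydrogen bonds (donor-acceptor heavy-atom distance
  2.6-3.5 A, >= 90 deg at both donor and acceptor antecedents); -1 each.

Per-atom saturation is what keeps the score from growing without bound with
side-chain size: an atom can only be buried once, so a tryptophan cannot buy
unlimited attraction simply by touching many symmetry copies.

``E_total = w_rep E_rep + w_att E_att + w_solv E_solv + w_hb E_hb`` holds as
an exact identity.  No correspondence with Rosetta magnitudes is intended:
only orderings and thresholded calls are meaningful.

Packing is symmetry-coupled: all strand copies of the fibril assembly adopt
the same rotamer at each position (fibrils are stacks of identical layers),
so the search space is one rotamer choice per position.  The packer runs
greedy per-position best-rotamer sweeps from a small deterministic set of
starting assignments and keeps the best end point; ties are resolved by the
lowest rotamer index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rotamers import (
    AA1_TO_AA3,
    RotamerLibrary,
    build_side_chain,
    default_rotamer_library,
)
from .templates import BackboneTemplate, FibrilAssembly, expand_fibril

__all__ = [
    "EnergyWeights",
    "EnergyBreakdown",
    "ThreadedModel",
    "graft_sequence",
    "pack_side_chains",
    "compute_energy",
    "thread_window",
    "DEFAULT_CONTEXT",
]

#: fibril context used for scoring: (strands per sheet, sheets)
DEFAULT_CONTEXT = (5, 2)

# ---------------------------------------------------------------------------
# energy parameters

CLASH_FACTOR = 0.85     # fraction of summed vdW radii where repulsion starts
REP_HARD = 100.0        # weight of the hard (sixth-power) overlap term
ATT_RAMP = 1.0          # contact well ramps to zero this far beyond vdW contact
ATT_SAT = 3.0           # per-atom cap on the summed attraction wells
SOLV_CUTOFF = 5.5       # A
OCC_SAT = 6.0           # occlusion sum at which an atom counts as fully buried
SOLV_POLAR = 1.0        # burial sign weight for polar atoms (penalty)
SOLV_NONPOLAR = -0.5    # burial sign weight for nonpolar atoms (reward)
SOLV_CHARGED = 3.0      # burial sign weight for formal-charge atoms (penalty)
HB_DMIN, HB_DMAX = 2.6, 3.5
#: raw repulsion added per proline threaded onto a backbone position whose
#: template phi lies outside the proline-compatible range (the ring constrains
#: phi to roughly -100..-30 deg); threading is allowed but strained.
PRO_PHI_PENALTY = 3.0
PRO_PHI_RANGE = (-100.0, -30.0)
#: raw strain per glycine pinned at a beta-region template position (phi <= 0).
#: Glycine's accessible Ramachandran area is by far the largest, so fixing it
#: in an extended/pleated strand costs the most conformational freedom; at a
#: positive-phi kink position (where only glycine is comfortable) it pays
#: nothing.  This is what lets a Gly-rich segment genuinely prefer a kinked
#: backbone over a pleated zipper.
GLY_BETA_STRAIN = 0.25


@dataclass(frozen=True)
class EnergyWeights:
    w_rep: float = 20.0
    w_att: float = 0.3
    w_solv: float = 2.0
    w_hb: float = 2.0


@dataclass
class EnergyBreakdown:
    e_rep: float
    e_att: float
    e_solv: float
    e_hb: float
    weights: EnergyWeights

    @property
    def e_total(self) -> float:
        w = self.weights
        return (w.w_rep * self.e_rep + w.w_att * self.e_att
                + w.w_solv * self.e_solv + w.w_hb * self.e_hb)

    def as_dict(self) -> dict:
        return {
            "E_total": self.e_total, "E_rep": self.e_rep, "E_att": self.e_att,
            "E_solv": self.e_solv, "E_hb": self.e_hb,
            "w_rep": self.weights.w_rep, "w_att": self.weights.w_att,
            "w_solv": self.weights.w_solv, "w_hb": self.weights.w_hb,
        }


# role codes used for bonded-neighbour exclusions
_ROLE_N, _ROLE_CA, _ROLE_C, _ROLE_O, _ROLE_CB, _ROLE_PCG, _ROLE_PCD, _ROLE_X = range(8)

# atom pairs of residues (i, i+1) within three covalent bonds of each other
_ADJ_EXCL = np.zeros((8, 8), bool)
for _a, _b in [
    (_ROLE_C, _ROLE_N), (_ROLE_C, _ROLE_CA), (_ROLE_C, _ROLE_C), (_ROLE_C, _ROLE_CB),
    (_ROLE_CA, _ROLE_N), (_ROLE_CA, _ROLE_CA), (_ROLE_CB, _ROLE_N),
    (_ROLE_O, _ROLE_N), (_ROLE_O, _ROLE_CA), (_ROLE_N, _ROLE_N),
    # proline: its ring CD (and CG) bond back to N
    (_ROLE_C, _ROLE_PCD), (_ROLE_CA, _ROLE_PCD), (_ROLE_O, _ROLE_PCD), (_ROLE_C, _ROLE_PCG),
]:
    _ADJ_EXCL[_a, _b] = True


class AtomSet:
    """Flat numpy arrays describing a group of atoms for the energy terms."""

    __slots__ = ("coords", "radii", "polar", "charged", "donor", "acceptor",
                 "antecedent", "copy_idx", "pos_idx", "role")

    def __init__(self, n: int):
        self.coords = np.zeros((n, 3))
        self.radii = np.zeros(n)
        self.polar = np.zeros(n, bool)
        self.charged = np.zeros(n, bool)
        self.donor = np.zeros(n, bool)
        self.acceptor = np.zeros(n, bool)
        self.antecedent = np.zeros((n, 3))
        self.copy_idx = np.zeros(n, int)
        self.pos_idx = np.zeros(n, int)
        self.role = np.full(n, _ROLE_X, int)

    def __len__(self) -> int:
        return len(self.radii)

    @staticmethod
    def concatenate(sets: list["AtomSet"]) -> "AtomSet":
        out = AtomSet(sum(len(s) for s in sets))
        i = 0
        for s in sets:
            j = i + len(s)
            for name in AtomSet.__slots__:
                getattr(out, name)[i:j] = getattr(s, name)
            i = j
        return out


class PairKernels:
    """Pairwise terms between two atom groups under an exclusion mask.

    ``rep`` and ``hb`` are scalars (pair-additive energies); ``occ_a/occ_b``
    and ``att_a/att_b`` are per-atom accumulator contributions (occlusion and
    attraction-well sums) received by each group from the other.
    """

    __slots__ = ("rep", "hb", "occ_a", "occ_b", "att_a", "att_b")

    def __init__(self, rep, hb, occ_a, occ_b, att_a, att_b):
        self.rep = rep
        self.hb = hb
        self.occ_a = occ_a
        self.occ_b = occ_b
        self.att_a = att_a
        self.att_b = att_b


def _kernels(A: AtomSet, B: AtomSet, mask: np.ndarray, same_set: bool) -> PairKernels:
    if len(A) == 0 or len(B) == 0:
        return PairKernels(0.0, 0.0, np.zeros(len(A)), np.zeros(len(B)),
                           np.zeros(len(A)), np.zeros(len(B)))
    diff = B.coords[None, :, :] - A.coords[:, None, :]
    d = np.sqrt(np.maximum(np.einsum("ijk,ijk->ij", diff, diff), 1e-12))
    sym_mask = mask & np.triu(np.ones(d.shape, bool), k=1) if same_set else mask

    rsum = A.radii[:, None] + B.radii[None, :]
    r0 = CLASH_FACTOR * rsum
    viol = np.clip(r0 - d, 0.0, None) / r0
    rep = float(np.sum(np.where(sym_mask, viol * viol + REP_HARD * viol ** 6, 0.0)))

    occ = np.where(mask, np.clip(1.0 - d / SOLV_CUTOFF, 0.0, 1.0), 0.0)
    occ_a = occ.sum(axis=1)
    occ_b = occ.sum(axis=0)

    nonpolar_pair = (~A.polar)[:, None] & (~B.polar)[None, :]
    well = np.where(mask & nonpolar_pair,
                    np.clip((rsum + ATT_RAMP - d) / ATT_RAMP, 0.0, 1.0), 0.0)
    att_a = well.sum(axis=1)
    att_b = well.sum(axis=0)

    hb = 0.0
    # for a same-set evaluation the full matrix already contains both ordered
    # directions of every donor/acceptor pair, so a single pass suffices
    passes = ((A, B, diff, d, mask),) if same_set else (
        (A, B, diff, d, mask), (B, A, -np.swapaxes(diff, 0, 1), d.T, mask.T))
    for X, Y, v, dx, m in passes:
        # X donates to Y; v points donor -> acceptor
        pair = X.donor[:, None] & Y.acceptor[None, :] & m & (dx >= HB_DMIN) & (dx <= HB_DMAX)
        if not pair.any():
            continue
        dotD = np.einsum("ik,ijk->ij", X.antecedent - X.coords, v)
        dotA = np.einsum("jk,ijk->ij", Y.antecedent - Y.coords, -v)
        hb -= float(np.sum(pair & (dotD <= 0.0) & (dotA <= 0.0)))
    if same_set:
        # each undirected pair was seen twice in the accumulators' source
        # matrix only via its own row/col, which is correct; hb already
        # counted each ordered pair once via the two passes over the full
        # matrix, so halve nothing.  rep used the upper triangle.
        pass
    return PairKernels(rep, hb, occ_a, occ_b, att_a, att_b)


def _pair_mask(A: AtomSet, B: AtomSet) -> np.ndarray:
    """Standard exclusion mask: drop intra-residue pairs and bonded-neighbour
    pairs between consecutive residues of the same strand copy (and, for
    same-set use, the diagonal via the intra-residue rule)."""
    same_copy = A.copy_idx[:, None] == B.copy_idx[None, :]
    dpos = B.pos_idx[None, :] - A.pos_idx[:, None]
    mask = ~(same_copy & (dpos == 0))
    adj_f = same_copy & (dpos == 1) & _ADJ_EXCL[A.role[:, None], B.role[None, :]]
    adj_b = same_copy & (dpos == -1) & _ADJ_EXCL[B.role[None, :], A.role[:, None]]
    return mask & ~adj_f & ~adj_b


def _saturate_occ(occ: np.ndarray) -> np.ndarray:
    return np.minimum(occ, OCC_SAT) / OCC_SAT


def _solv_sign(atoms: "AtomSet") -> np.ndarray:
    s = np.where(atoms.polar, SOLV_POLAR, SOLV_NONPOLAR)
    return np.where(atoms.charged, SOLV_CHARGED, s)


def _solv_energy(occ: np.ndarray, sign: np.ndarray) -> float:
    return float(np.sum(sign * _saturate_occ(occ)))


def _att_energy(att: np.ndarray) -> float:
    return -float(np.sum(np.minimum(att, ATT_SAT)))


# ---------------------------------------------------------------------------
# model construction


def _backbone_atomset(assembly: FibrilAssembly, sequence: str) -> AtomSet:
    """Backbone N/CA/C/O of every strand copy, with H-bond roles."""
    strands = assembly.strand_backbones()
    L = assembly.template.residue_count
    n = len(strands) * L * 4
    out = AtomSet(n)
    k = 0
    for c, bb in enumerate(strands):
        for i in range(L):
            aa = sequence[i]
            for name, elem, role in (("N", "N", _ROLE_N), ("CA", "C", _ROLE_CA),
                                     ("C", "C", _ROLE_C), ("O", "O", _ROLE_O)):
                out.coords[k] = bb[name][i]
                out.radii[k] = {"N": 1.55, "C": 1.70, "O": 1.52}[elem]
                out.polar[k] = elem in ("N", "O")
                out.copy_idx[k] = c
                out.pos_idx[k] = i
                out.role[k] = role
                if name == "N":
                    out.donor[k] = aa != "P"
                    out.antecedent[k] = bb["CA"][i]
                elif name == "O":
                    out.acceptor[k] = True
                    out.antecedent[k] = bb["C"][i]
                else:
                    out.antecedent[k] = bb["CA"][i]
                k += 1
    return out


def _rotamer_atomset(assembly: FibrilAssembly, position: int, aa: str,
                     chis: tuple[float, ...]) -> AtomSet:
    """Side-chain atoms (CB and beyond) of one rotamer at one position,
    replicated across every strand copy by the assembly's rigid operators."""
    base = assembly.template.strand_coords()
    frame = {k: base[k][position] for k in ("N", "CA", "C")}
    sc = build_side_chain(aa, frame, chis)
    n_atoms = len(sc.names)
    n_copies = assembly.n_strands
    out = AtomSet(n_atoms * n_copies)
    aa3 = AA1_TO_AA3[aa]
    roles = []
    for nm in sc.names:
        if nm == "CB":
            roles.append(_ROLE_CB)
        elif aa3 == "PRO" and nm == "CG":
            roles.append(_ROLE_PCG)
        elif aa3 == "PRO" and nm == "CD":
            roles.append(_ROLE_PCD)
        else:
            roles.append(_ROLE_X)
    k = 0
    for c, (R, t) in enumerate(assembly.operators):
        j = k + n_atoms
        out.coords[k:j] = sc.coords @ R.T + t
        out.antecedent[k:j] = sc.antecedent @ R.T + t
        out.radii[k:j] = sc.radii
        out.polar[k:j] = sc.polar
        out.charged[k:j] = sc.charged
        out.donor[k:j] = sc.donor
        out.acceptor[k:j] = sc.acceptor
        out.copy_idx[k:j] = c
        out.pos_idx[k:j] = position
        out.role[k:j] = roles
        k = j
    return out


def _backbone_strain(template: BackboneTemplate, sequence: str, n_copies: int) -> float:
    """Raw torsional-compatibility strain for the threaded sequence.

    Prolines pay a fixed penalty at positions whose template phi is outside
    the ring-compatible range; glycines pay a small entropy strain at
    beta-region (phi <= 0) positions.
    """
    lo, hi = PRO_PHI_RANGE
    strain = 0.0
    for i, aa in enumerate(sequence):
        phi = template.dihedrals[i, 0]
        if aa == "P" and not (lo <= phi <= hi):
            strain += PRO_PHI_PENALTY * n_copies
        elif aa == "G" and phi <= 0.0:
            strain += GLY_BETA_STRAIN * n_copies
    return strain


@dataclass
class ThreadedModel:
    """A sequence threaded onto a template inside its fibril assembly."""

    template: BackboneTemplate
    assembly: FibrilAssembly
    sequence: str
    rotamer_indices: list[int]
    library: RotamerLibrary
    energy: EnergyBreakdown | None = None
    packed: bool = False
    converged: bool = True
    sweep_energies: list[float] = field(default_factory=list)

    def rotamer_chis(self, position: int) -> tuple[float, ...]:
        return self.library.rotamers(self.sequence[position])[self.rotamer_indices[position]]

    def atom_sets(self) -> tuple[AtomSet, list[AtomSet]]:
        """(backbone atoms, one side-chain AtomSet per position)."""
        bb = _backbone_atomset(self.assembly, self.sequence)
        side = [
            _rotamer_atomset(self.assembly, i, aa, self.rotamer_chis(i))
            for i, aa in enumerate(self.sequence)
        ]
        return bb, side

    @property
    def atom_count(self) -> int:
        bb, side = self.atom_sets()
        return len(bb) + sum(len(s) for s in side)

    def to_structure(self):
        """Export as an :class:`larkszip.io.StructureModel` (one chain per strand)."""
        from .io import AtomRecord, StructureModel

        chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        strands = self.assembly.strand_backbones()
        records = []
        serial = 1
        for c, bb in enumerate(strands):
            chain = chains[c % len(chains)]
            for i, aa in enumerate(self.sequence):
                res3 = AA1_TO_AA3[aa]
                for name in ("N", "CA", "C", "O"):
                    records.append(AtomRecord(
                        serial=serial, name=name, res_name=res3, chain_id=chain,
                        res_seq=i + 1, x=bb[name][i][0], y=bb[name][i][1],
                        z=bb[name][i][2], element=name[0], record_class="polymer"))
                    serial += 1
                frame = {k: bb[k][i] for k in ("N", "CA", "C")}
                sc = build_side_chain(aa, frame, self.rotamer_chis(i))
                for nm, el, xyz in zip(sc.names, sc.elements, sc.coords):
                    records.append(AtomRecord(
                        serial=serial, name=str(nm), res_name=res3, chain_id=chain,
                        res_seq=i + 1, x=xyz[0], y=xyz[1], z=xyz[2],
                        element=str(el), record_class="polymer"))
                    serial += 1
        return StructureModel(records)


def graft_sequence(assembly: FibrilAssembly, sequence: str,
                   library: RotamerLibrary | None = None) -> ThreadedModel:
    """Thread ``sequence`` onto every strand copy of the assembly (in-register
    homotypic stacking), side chains initialised at the first rotamer."""
    sequence = sequence.upper()
    L = assembly.template.residue_count
    if len(sequence) != L:
        raise ValueError(f"sequence length {len(sequence)} != template length {L}")
    bad = set(sequence) - set(AA1_TO_AA3)
    if bad:
        raise ValueError(f"unsupported residue letters for threading: {sorted(bad)}")
    library = library or default_rotamer_library()
    return ThreadedModel(
        template=assembly.template, assembly=assembly, sequence=sequence,
        rotamer_indices=[0] * L, library=library, packed=False)


def compute_energy(model: ThreadedModel,
                   weights: EnergyWeights | None = None) -> EnergyBreakdown:
    """Score a model by direct evaluation over all its atoms.

    This is the reference evaluator; the packer's table-based energies must
    agree with it (and the test suite checks that they do).
    """
    if weights is None:
        weights = model.energy.weights if model.energy is not None else EnergyWeights()
    bb, side = model.atom_sets()
    allatoms = AtomSet.concatenate([bb] + side)
    if not np.all(np.isfinite(allatoms.coords)):
        raise ValueError("non-finite coordinates in model")
    mask = _pair_mask(allatoms, allatoms)
    K = _kernels(allatoms, allatoms, mask, same_set=True)
    e_rep = K.rep + _backbone_strain(model.template, model.sequence, model.assembly.n_strands)
    e_att = _att_energy(K.att_a)
    e_solv = _solv_energy(K.occ_a, _solv_sign(allatoms))
    eb = EnergyBreakdown(e_rep, e_att, e_solv, K.hb, weights=weights)
    model.energy = eb
    return eb


# ---------------------------------------------------------------------------
# table-based packing

_table_cache: dict = {}

#: most pair tables are re-hit constantly during a proteome scan, but the key
#: space grows with the alphabet; an LRU bound keeps memory flat (~0.2 MB/entry)
_PAIR_TABLE_LRU = 1000  # per template/context


def _batch_pair_kernels(rots_a: list[AtomSet], rots_b: list[AtomSet],
                        mask: np.ndarray | None):
    """Kernels for every rotamer pair of two positions in one vectorised pass.

    Returns (scal (Ra,Rb,2), occ_a (Ra,Rb,Na), att_a, occ_b (Ra,Rb,Nb),
    att_b).  ``mask`` is an (Na, Nb) exclusion mask shared by all rotamer
    pairs (atom metadata does not depend on the rotamer); None means all
    pairs allowed.
    """
    Ra, Rb = len(rots_a), len(rots_b)
    na, nb = len(rots_a[0]), len(rots_b[0])
    if na == 0 or nb == 0:
        return (np.zeros((Ra, Rb, 2)), np.zeros((Ra, Rb, na)), np.zeros((Ra, Rb, na)),
                np.zeros((Ra, Rb, nb)), np.zeros((Ra, Rb, nb)))
    A = rots_a[0]
    B = rots_b[0]
    ca = np.stack([r.coords for r in rots_a])            # (Ra, na, 3)
    cb = np.stack([r.coords for r in rots_b])            # (Rb, nb, 3)
    aa = np.stack([r.antecedent for r in rots_a])
    ab = np.stack([r.antecedent for r in rots_b])
    if mask is None:
        mask = np.ones((na, nb), bool)

    diff = cb[None, :, None, :, :] - ca[:, None, :, None, :]   # (Ra,Rb,na,nb,3)
    d = np.sqrt(np.maximum(np.einsum("abijk,abijk->abij", diff, diff), 1e-12))

    rsum = A.radii[:, None] + B.radii[None, :]
    r0 = CLASH_FACTOR * rsum
    viol = np.clip(r0[None, None] - d, 0.0, None) / r0[None, None]
    rep = np.sum(np.where(mask[None, None], viol * viol + REP_HARD * viol ** 6, 0.0),
                 axis=(2, 3))

    occ = np.where(mask[None, None], np.clip(1.0 - d / SOLV_CUTOFF, 0.0, 1.0), 0.0)
    occ_a = occ.sum(axis=3)
    occ_b = occ.sum(axis=2)

    nonpolar = ((~A.polar)[:, None] & (~B.polar)[None, :]) & mask
    well = np.where(nonpolar[None, None],
                    np.clip((rsum[None, None] + ATT_RAMP - d) / ATT_RAMP, 0.0, 1.0), 0.0)
    att_a = well.sum(axis=3)
    att_b = well.sum(axis=2)

    hb = np.zeros((Ra, Rb))
    dwin = (d >= HB_DMIN) & (d <= HB_DMAX) & mask[None, None]
    if dwin.any():
        dot_a = np.einsum("aik,abijk->abij", aa - ca, diff)      # donor/acceptor side of A
        dot_b = np.einsum("bjk,abijk->abij", ab - cb, -diff)
        geom = dwin & (dot_a <= 0.0) & (dot_b <= 0.0)
        role1 = A.donor[:, None] & B.acceptor[None, :]
        role2 = A.acceptor[:, None] & B.donor[None, :]
        hb = -(np.sum(geom & role1[None, None], axis=(2, 3))
               + np.sum(geom & role2[None, None], axis=(2, 3))).astype(float)
    scal = np.stack([rep, hb], axis=-1)
    return scal, occ_a, att_a, occ_b, att_b


class _PackingTables:
    """Cached per-(template, context) interaction tables.

    Scalar parts (repulsion, H-bonds) are pair-additive; occlusion and
    attraction-well sums are cached as per-atom contribution vectors so the
    saturating terms can be reassembled exactly for any rotamer assignment.
    """

    def __init__(self, assembly: FibrilAssembly, library: RotamerLibrary):
        self.assembly = assembly
        self.library = library
        from collections import OrderedDict

        self.rot_atoms: dict = {}
        self.self_terms: dict = {}
        self.pair_terms: "OrderedDict" = OrderedDict()
        self.bb_cache: dict = {}

    def backbone(self, sequence: str):
        """(AtomSet, scalar (rep, hb), occ base, att base) for the backbone.

        Depends on sequence only through proline N donors.
        """
        key = tuple(i for i, aa in enumerate(sequence) if aa == "P")
        if key not in self.bb_cache:
            bb = _backbone_atomset(self.assembly, sequence)
            K = _kernels(bb, bb, _pair_mask(bb, bb), same_set=True)
            self.bb_cache[key] = (bb, np.array([K.rep, K.hb]), K.occ_a, K.att_a)
        return self.bb_cache[key]

    def rotamers_at(self, i: int, aa: str) -> list[AtomSet]:
        key = (i, aa)
        if key not in self.rot_atoms:
            self.rot_atoms[key] = [
                _rotamer_atomset(self.assembly, i, aa, chis)
                for chis in self.library.rotamers(aa)
            ]
        return self.rot_atoms[key]

    def self_table(self, i: int, aa: str, bb: AtomSet, bb_key):
        """Per-rotamer arrays: scal (R,2); occ/att on own atoms (R, Ni) from
        backbone plus same-position symmetry copies; occ/att contributed onto
        each backbone atom (R, Nb)."""
        key = (i, aa, bb_key)
        if key not in self.self_terms:
            rots = self.rotamers_at(i, aa)
            R = len(rots)
            ni = len(rots[0])
            if ni == 0:
                self.self_terms[key] = (np.zeros((R, 2)), np.zeros((R, 0)),
                                        np.zeros((R, 0)), np.zeros((R, len(bb))),
                                        np.zeros((R, len(bb))))
            else:
                mask_bb = _pair_mask(rots[0], bb)
                scal, occ_own, att_own, occ_b, att_b = _batch_pair_kernels(
                    rots, [bb], mask_bb[None][0])
                # _batch_pair_kernels expects lists of equal-shape AtomSets;
                # wrap the single backbone "rotamer"
                scal = scal[:, 0]
                occ_own = occ_own[:, 0]
                att_own = att_own[:, 0]
                occ_b = occ_b[:, 0]
                att_b = att_b[:, 0]
                # same-position symmetry copies interact with each other
                cross = rots[0].copy_idx[:, None] != rots[0].copy_idx[None, :]
                for r, rot in enumerate(rots):
                    K2 = _kernels(rot, rot, cross, same_set=True)
                    scal[r] += (K2.rep, K2.hb)
                    occ_own[r] += K2.occ_a
                    att_own[r] += K2.att_a
                self.self_terms[key] = (scal, occ_own, att_own, occ_b, att_b)
        return self.self_terms[key]

    def pair_table(self, i: int, aa_i: str, j: int, aa_j: str):
        """Batched arrays over all rotamer pairs of positions i < j:
        (scal (Ri,Rj,2), occ_i, att_i (Ri,Rj,Ni), occ_j, att_j (Ri,Rj,Nj))."""
        key = (i, aa_i, j, aa_j)
        entry = self.pair_terms.get(key)
        if entry is None:
            rots_i = self.rotamers_at(i, aa_i)
            rots_j = self.rotamers_at(j, aa_j)
            entry = _batch_pair_kernels(rots_i, rots_j, None)
            self.pair_terms[key] = entry
            if len(self.pair_terms) > _PAIR_TABLE_LRU:
                self.pair_terms.pop(next(iter(self.pair_terms)))
        else:
            self.pair_terms.move_to_end(key)
        return entry


def _get_tables(assembly: FibrilAssembly, library: RotamerLibrary) -> _PackingTables:
    key = (assembly.template.name, assembly.n_strands, id(library))
    tables = _table_cache.get(key)
    if tables is None or tables.assembly.template is not assembly.template:
        tables = _PackingTables(assembly, library)
        _table_cache[key] = tables
    return tables


def pack_side_chains(model: ThreadedModel, library: RotamerLibrary | None = None,
                     max_cycles: int = 10) -> ThreadedModel:
    """Optimise rotamers by symmetry-coupled greedy sweeps on cached tables.

    Deterministic multistart: for short templates (<= 4 positions) every
    single-rotamer seeding is swept; for full-length windows the all-first-
    rotamer start and a self-energy-greedy start are used.  Each start is
    swept until no single-position change lowers the energy (or
    ``max_cycles``); the best end point wins, exact ties going to the
    lexicographically smaller assignment.
    """
    if max_cycles < 1:
        raise ValueError("max_cycles must be >= 1")
    library = library or model.library
    seq = model.sequence
    L = len(seq)
    weights = model.energy.weights if model.energy is not None else EnergyWeights()
    wvec = np.array([weights.w_rep, weights.w_hb])
    tables = _get_tables(model.assembly, library)
    bb_key = tuple(i for i, aa in enumerate(seq) if aa == "P")
    bb, bb_scal, bb_occ0, bb_att0 = tables.backbone(seq)
    selfs = [tables.self_table(i, seq[i], bb, bb_key) for i in range(L)]
    pair_store = {(i, j): tables.pair_table(i, seq[i], j, seq[j])
                  for i in range(L) for j in range(i + 1, L)}
    signs = [_solv_sign(tables.rotamers_at(i, seq[i])[0]) for i in range(L)]
    bb_sign = _solv_sign(bb)
    n_rot = [len(library.rotamers(aa)) for aa in seq]
    strain = _backbone_strain(model.template, seq, model.assembly.n_strands)

    def pair_arrays(i, j):
        """(scal, occ_i, att_i, occ_j, att_j) indexed [a_i, a_j, ...]."""
        if i < j:
            return pair_store[(i, j)]
        scal, occ_j, att_j, occ_i, att_i = pair_store[(j, i)]
        sw = lambda x: np.swapaxes(x, 0, 1)
        return sw(scal), sw(occ_i), sw(att_i), sw(occ_j), sw(att_j)

    def breakdown(assign) -> EnergyBreakdown:
        scal = bb_scal.copy()
        occ_bb = bb_occ0.copy()
        att_bb = bb_att0.copy()
        occs, atts = [], []
        for i in range(L):
            s, occ_own, att_own, occ_b, att_b = selfs[i]
            a = assign[i]
            scal = scal + s[a]
            occ_bb = occ_bb + occ_b[a]
            att_bb = att_bb + att_b[a]
            occs.append(occ_own[a].copy())
            atts.append(att_own[a].copy())
        for i in range(L):
            for j in range(i + 1, L):
                s, occ_i, att_i, occ_j, att_j = pair_store[(i, j)]
                a, b = assign[i], assign[j]
                scal = scal + s[a, b]
                occs[i] += occ_i[a, b]
                atts[i] += att_i[a, b]
                occs[j] += occ_j[a, b]
                atts[j] += att_j[a, b]
        e_solv = _solv_energy(occ_bb, bb_sign)
        e_att = _att_energy(att_bb)
        for i in range(L):
            e_solv += _solv_energy(occs[i], signs[i])
            e_att += _att_energy(atts[i])
        return EnergyBreakdown(scal[0] + strain, e_att, e_solv, scal[1], weights=weights)

    def total(assign) -> float:
        return breakdown(assign).e_total

    def candidate_energies(assign, i) -> np.ndarray:
        """Energy of every rotamer choice at position i, others fixed."""
        others = [j for j in range(L) if j != i]
        # environment (everything not involving position i)
        scal_env = bb_scal.copy()
        occ_bb_env = bb_occ0.copy()
        att_bb_env = bb_att0.copy()
        occ_env, att_env = {}, {}
        for j in others:
            s, occ_own, att_own, occ_b, att_b = selfs[j]
            a = assign[j]
            scal_env = scal_env + s[a]
            occ_bb_env = occ_bb_env + occ_b[a]
            att_bb_env = att_bb_env + att_b[a]
            occ_env[j] = occ_own[a].copy()
            att_env[j] = att_own[a].copy()
        for x in range(len(others)):
            for y in range(x + 1, len(others)):
                j, k = others[x], others[y]
                s, occ_j, att_j, occ_k, att_k = pair_store[(j, k)]
                a, b = assign[j], assign[k]
                scal_env = scal_env + s[a, b]
                occ_env[j] += occ_j[a, b]
                att_env[j] += att_j[a, b]
                occ_env[k] += occ_k[a, b]
                att_env[k] += att_k[a, b]

        R = n_rot[i]
        s_i, occ_own_i, att_own_i, occ_b_i, att_b_i = selfs[i]
        scal_all = scal_env[None, :] + s_i                       # (R, 2)
        occ_bb_all = occ_bb_env[None, :] + occ_b_i               # (R, Nb)
        att_bb_all = att_bb_env[None, :] + att_b_i
        occ_i_all = occ_own_i.copy()                             # (R, Ni)
        att_i_all = att_own_i.copy()
        e_others_solv = np.zeros(R)
        e_others_att = np.zeros(R)
        for j in others:
            s, occ_i_ij, att_i_ij, occ_j_ij, att_j_ij = pair_arrays(i, j)
            a_j = assign[j]
            scal_all = scal_all + s[:, a_j]
            occ_i_all = occ_i_all + occ_i_ij[:, a_j]
            att_i_all = att_i_all + att_i_ij[:, a_j]
            occ_j_all = occ_env[j][None, :] + occ_j_ij[:, a_j]   # (R, Nj)
            att_j_all = att_env[j][None, :] + att_j_ij[:, a_j]
            e_others_solv += (np.minimum(occ_j_all, OCC_SAT) / OCC_SAT) @ signs[j]
            e_others_att += -np.minimum(att_j_all, ATT_SAT).sum(axis=1)
        e_solv = ((np.minimum(occ_bb_all, OCC_SAT) / OCC_SAT) @ bb_sign
                  + ((np.minimum(occ_i_all, OCC_SAT) / OCC_SAT) @ signs[i]
                     if occ_i_all.shape[1] else 0.0)
                  + e_others_solv)
        e_att = (-np.minimum(att_bb_all, ATT_SAT).sum(axis=1)
                 - (np.minimum(att_i_all, ATT_SAT).sum(axis=1)
                    if att_i_all.shape[1] else 0.0)
                 + e_others_att)
        e_rep = scal_all[:, 0] + strain
        e_hb = scal_all[:, 1]
        return (weights.w_rep * e_rep + weights.w_att * e_att
                + weights.w_solv * e_solv + weights.w_hb * e_hb)

    def sweep(assign):
        assign = list(assign)
        energy = total(assign)
        history = [energy]
        converged = False
        for _ in range(max_cycles):
            changed = False
            for i in range(L):
                if n_rot[i] <= 1:
                    continue
                cand = candidate_energies(assign, i)
                best = int(np.argmin(cand))  # argmin takes the lowest index on ties
                if cand[best] < cand[assign[i]] - 1e-12:
                    assign[i] = best
                    changed = True
                    energy = float(cand[best])
            history.append(energy)
            if not changed:
                converged = True
                break
        return assign, energy, history, converged

    starts = [[0] * L]
    if L <= 4:
        for i in range(L):
            for a in range(1, n_rot[i]):
                s = [0] * L
                s[i] = a
                starts.append(s)
    else:
        # a second, self-energy-greedy start for full-length windows
        greedy = []
        for i in range(L):
            s_i, occ_own_i, att_own_i, occ_b_i, att_b_i = selfs[i]
            e = (s_i @ wvec
                 + weights.w_solv * ((np.minimum(occ_own_i, OCC_SAT) / OCC_SAT) @ signs[i]
                                     if occ_own_i.shape[1] else 0.0)
                 - weights.w_att * np.minimum(att_own_i, ATT_SAT).sum(axis=1))
            greedy.append(int(np.argmin(e)))
        if greedy != starts[0]:
            starts.append(greedy)

    best = None
    for s in starts:
        assign, energy, history, conv = sweep(s)
        if best is None or energy < best[1] - 1e-12 or (
                abs(energy - best[1]) <= 1e-12 and assign < best[0]):
            best = (assign, energy, history, conv)
    assign, energy, history, conv = best
    model.rotamer_indices = list(assign)
    model.packed = True
    model.converged = conv
    model.sweep_energies = history
    model.energy = breakdown(assign)
    return model


def thread_window(window: str, template: BackboneTemplate,
                  weights: EnergyWeights | None = None,
                  library: RotamerLibrary | None = None,
                  context: tuple[int, int] = DEFAULT_CONTEXT,
                  max_cycles: int = 10) -> tuple[ThreadedModel, float]:
    """Graft, pack and score one window on one template; returns (model, E_total).

    Deterministic for fixed inputs and rotamer-library order.
    """
    weights = weights or EnergyWeights()
    library = library or default_rotamer_library()
    assembly = _assembly_for(template, context)
    model = graft_sequence(assembly, window, library)
    model.energy = EnergyBreakdown(0, 0, 0, 0, weights)  # carries weights into packing
    model = pack_side_chains(model, library, max_cycles=max_cycles)
    return model, model.energy.e_total


_assembly_cache: dict = {}


def _assembly_for(template: BackboneTemplate, context: tuple[int, int]) -> FibrilAssembly:
    key = (template.name, context)
    asm = _assembly_cache.get(key)
    if asm is None or asm.template is not template:
        asm = expand_fibril(template, *context)
        _assembly_cache[key] = asm
    return asm
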
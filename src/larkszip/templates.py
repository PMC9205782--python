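"""Fixed backbone templates for threading and their expansion into fibril context.

A template is a short strand (typically a 6-mer) defined purely by per-residue
(phi, psi, omega) dihedrals realised with standard peptide bond lengths and
angles.  Four templates ship with the package: three kinked LARKS backbones,
named after the low-complexity segments whose fibril structures defined the
kinked-beta motif (STGGYS, SYSGYS, GYNGFG), and one pleated parallel
steric-zipper backbone.  Dihedral tables live in ``data/templates.cfg`` so they
can be inspected and versioned like any other configuration.

Fibril context: strands stack along z (the fibril axis) with a fixed rise, the
strand runs along y, and a mating sheet is generated by a rigid transform
(rotation + inter-sheet offset along x).  Antiparallel sheets are a two-strand
repeat (period twice the rise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .geometry import dihedral, kabsch, place_atom, rotation_about_axis

__all__ = [
    "BackboneTemplate",
    "FibrilAssembly",
    "build_backbone_from_dihedrals",
    "expand_fibril",
    "load_builtin_templates",
    "load_template_config",
    "virtual_cb",
]

# Engh-Huber-style ideal peptide geometry (lengths in Angstrom, angles in deg)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

#: default axial translation between stacked strands of one sheet (Angstrom)
DEFAULT_RISE = 4.8
#: default backbone-to-backbone spacing between the two mating sheets (Angstrom)
DEFAULT_SHEET_SEPARATION = 9.5


def build_backbone_from_dihedrals(dihedral_table, sequence_length: int):
    """Build N/CA/C/O coordinates for a strand from a (phi, psi, omega) table.

    ``dihedral_table`` holds one triple per residue; phi of the first residue
    and omega of the last are not used to propagate the chain (psi of the last
    residue only orients its carbonyl).  Returns a dict of (L, 3) arrays with
    keys ``"N", "CA", "C", "O"`` plus ``"CB"`` — a virtual C-beta direction
    stub computed from the backbone (also defined for glycine).
    """
    table = np.asarray(dihedral_table, float)
    if table.shape != (sequence_length, 3):
        raise ValueError(
            f"dihedral table shape {table.shape} does not match "
            f"sequence_length={sequence_length} (expected ({sequence_length}, 3))"
        )
    L = sequence_length
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    O = np.zeros((L, 3))

    # seed the first residue in a canonical local frame
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(L - 1):
        psi = table[i, 1]
        omega = table[i, 2]
        phi_next = table[i + 1, 0]
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, omega)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi_next)
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    # carbonyl of the final residue from its (otherwise unused) psi
    O[L - 1] = place_atom(N[L - 1], CA[L - 1], C[L - 1], BOND_C_O, ANGLE_CA_C_O, table[L - 1, 1] + 180.0)

    CB = np.array([virtual_cb(N[i], CA[i], C[i]) for i in range(L)])
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta position from the local backbone frame (works for Gly)."""
    return place_atom(n, c, ca, 1.53, 110.1, 122.6)


def measure_dihedrals(bb: dict) -> np.ndarray:
    """Recompute (phi, psi, omega) from built backbone coordinates.

    Entries that are undefined at the chain termini are returned as NaN.
    """
    N, CA, C = bb["N"], bb["CA"], bb["C"]
    L = len(N)
    out = np.full((L, 3), np.nan)
    for i in range(L):
        if i > 0:
            out[i, 0] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < L - 1:
            out[i, 1] = dihedral(N[i], CA[i], C[i], N[i + 1])
            out[i, 2] = dihedral(CA[i], C[i], N[i + 1], CA[i + 1])
    return out


@dataclass
class BackboneTemplate:
    """A fixed threading backbone plus the symmetry that builds its fibril."""

    name: str
    category: str  # "LARKS" | "zipper"
    dihedrals: np.ndarray  # (L, 3) phi/psi/omega in degrees
    strand_rise: float = DEFAULT_RISE
    sheet_separation: float = DEFAULT_SHEET_SEPARATION
    sheet_axial_offset: float = DEFAULT_RISE / 2.0
    antiparallel_in_sheet: bool = False
    #: symmetry op for the mating sheet: "rz" | "ry" | "rx" | "t" (see expand_fibril)
    sheet_op: str = "rz"

    def __post_init__(self):
        self.dihedrals = np.asarray(self.dihedrals, float)
        L = self.residue_count
        if L < 2:
            raise ValueError("template must have at least 2 residues")
        omegas = self.dihedrals[:-1, 2]
        if np.any(np.abs(np.abs(omegas) - 180.0) > 20.0):
            raise ValueError("all omega dihedrals must be within 20 deg of trans")
        if not (4.0 <= self.strand_rise <= 10.0):
            raise ValueError("strand_rise must lie in [4.0, 10.0] Angstrom")

    @property
    def residue_count(self) -> int:
        return int(self.dihedrals.shape[0])

    def strand_coords(self) -> dict:
        """Backbone of a single strand, canonically oriented:

        strand axis (first CA -> last CA) along +y, mean carbonyl axis along z,
        CA centroid at the origin.  The canonical frame is what makes a pure
        z-translation by ``strand_rise`` an in-register stacking operation.
        """
        bb = build_backbone_from_dihedrals(self.dihedrals, self.residue_count)
        CA, C, O = bb["CA"], bb["C"], bb["O"]
        ey = CA[-1] - CA[0]
        ey = ey / np.linalg.norm(ey)
        # alternating carbonyls point +/- the sheet-stacking axis in beta strands
        co = np.zeros(3)
        for i in range(len(CA) - 1):
            co += ((-1.0) ** i) * (O[i] - C[i])
        ez = co - np.dot(co, ey) * ey
        ez = ez / np.linalg.norm(ez)
        ex = np.cross(ey, ez)
        R = np.vstack([ex, ey, ez])  # rows are new basis -> world-to-local
        centroid = CA.mean(axis=0)
        return {k: (v - centroid) @ R.T for k, v in bb.items()}


@dataclass
class FibrilAssembly:
    """Rigid copies of a template strand arranged as sheets of a fibril."""

    template: BackboneTemplate
    #: per-copy rigid ops: list of (R 3x3, t 3) applied to the canonical strand
    operators: list = field(default_factory=list)
    #: per-copy (sheet label "A"/"B", stack index)
    labels: list = field(default_factory=list)

    @property
    def n_strands(self) -> int:
        return len(self.operators)

    def strand_backbones(self) -> list[dict]:
        base = self.template.strand_coords()
        out = []
        for R, t in self.operators:
            out.append({k: v @ R.T + t for k, v in base.items()})
        return out

    def central_strand_index(self, sheet: str = "A") -> int:
        """Index of the middle strand of a sheet (the threading query strand)."""
        idx = [i for i, (s, _) in enumerate(self.labels) if s == sheet]
        if not idx:
            raise ValueError(f"no sheet {sheet!r} in assembly")
        idx.sort(key=lambda i: self.labels[i][1])
        return idx[len(idx) // 2]


_SHEET_OPS = {
    "rz": rotation_about_axis([0.0, 0.0, 1.0], 180.0),  # face-to-face, up-down
    "ry": rotation_about_axis([0.0, 1.0, 0.0], 180.0),  # face-to-face, up-up
    "rx": rotation_about_axis([1.0, 0.0, 0.0], 180.0),  # face-to-back, up-down
    "t": np.eye(3),  # face-to-back, up-up
}


def expand_fibril(template: BackboneTemplate, n_strands_per_sheet: int, n_sheets: int) -> FibrilAssembly:
    """Expand a template strand into ``n_sheets`` sheets of stacked strands.

    Sheet A stacks the canonical strand along +z every ``strand_rise`` (for an
    antiparallel sheet, every second strand is flipped by a 180-deg rotation
    about the x axis through its own stack height).  Sheet B applies the
    template's ``sheet_op`` rotation followed by a translation of
    ``sheet_separation`` along +x and ``sheet_axial_offset`` along +z.
    """
    if n_strands_per_sheet < 1:
        raise ValueError("n_strands_per_sheet must be >= 1")
    if n_sheets not in (1, 2):
        raise ValueError("n_sheets must be 1 or 2")
    rise = template.strand_rise
    flip = rotation_about_axis([1.0, 0.0, 0.0], 180.0)
    ops: list[tuple[np.ndarray, np.ndarray]] = []
    labels: list[tuple[str, int]] = []
    k0 = (n_strands_per_sheet - 1) / 2.0
    for k in range(n_strands_per_sheet):
        z = (k - k0) * rise
        if template.antiparallel_in_sheet and (k % 2 == 1):
            R = flip
        else:
            R = np.eye(3)
        ops.append((R, np.array([0.0, 0.0, z])))
        labels.append(("A", k))
    if n_sheets == 2:
        Rb = _SHEET_OPS[template.sheet_op]
        tb = np.array([template.sheet_separation, 0.0, template.sheet_axial_offset])
        for k in range(n_strands_per_sheet):
            z = (k - k0) * rise
            if template.antiparallel_in_sheet and (k % 2 == 1):
                R = Rb @ flip
            else:
                R = Rb
            ops.append((R, Rb @ np.array([0.0, 0.0, z]) + tb))
            labels.append(("B", k))
    return FibrilAssembly(template=template, operators=ops, labels=labels)


# ---------------------------------------------------------------------------
# built-in template configuration


def load_template_config(text: str) -> list[BackboneTemplate]:
    """Parse the flat text template configuration format.

    Blocks start with ``[name]``; keys: ``category``, ``rise``,
    ``sheet_separation``, ``sheet_axial_offset``, ``sheet_op``,
    ``antiparallel_in_sheet`` and one ``residue = phi psi omega`` line per
    residue, in order.
    """
    templates = []
    name = None
    fields: dict = {}
    rows: list = []

    def flush():
        if name is None:
            return
        templates.append(
            BackboneTemplate(
                name=name,
                category=fields.get("category", "LARKS"),
                dihedrals=np.array(rows, float),
                strand_rise=float(fields.get("rise", DEFAULT_RISE)),
                sheet_separation=float(fields.get("sheet_separation", DEFAULT_SHEET_SEPARATION)),
                sheet_axial_offset=float(fields.get("sheet_axial_offset", DEFAULT_RISE / 2.0)),
                antiparallel_in_sheet=fields.get("antiparallel_in_sheet", "false").lower() == "true",
                sheet_op=fields.get("sheet_op", "rz"),
            )
        )

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            name = line[1:-1].strip()
            fields = {}
            rows = []
        elif "=" in line:
            key, val = (s.strip() for s in line.split("=", 1))
            if key == "residue":
                rows.append([float(x) for x in val.split()])
            else:
                fields[key] = val
    flush()
    return templates


def load_builtin_templates() -> list[BackboneTemplate]:
    """The three kinked LARKS templates plus the pleated zipper template."""
    text = resources.files("larkszip.data").joinpath("templates.cfg").read_text()
    return load_template_config(text)


def get_template(name: str) -> BackboneTemplate:
    for t in load_builtin_templates():
        if t.name == name:
            return t
    raise KeyError(name)
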
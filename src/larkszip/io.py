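"""External representations: FASTA sequences, missense variant tables, PDB
coordinate files, and tabular reports.

The variant table is a plain TSV dialect defined by this package (one row per
single missense substitution, protein-level coordinates):

    protein_id  position  wt  mut  significance  source

``significance`` is one of ``pathogenic`` / ``benign`` / ``other`` (anything
else is coerced to ``other`` with a warning).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
SIGNIFICANCE_LABELS = ("pathogenic", "benign", "other")

#: modified residues mapped to their parent standard residue on PDB input
MODIFIED_PARENT = {"MSE": "MET", "SEC": "CYS", "MLY": "LYS", "CSO": "CYS",
                   "PTR": "TYR", "SEP": "SER", "TPO": "THR", "HYP": "PRO"}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

AA3_SET = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
           "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
           "TYR", "VAL"}


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# sequences


@dataclass
class ProteinRecord:
    """A protein sequence with explicit residue numbering.

    ``numbering_offset`` is the residue number of the first sequence
    character; sequences printed without the initiator methionine use
    offset 2.
    """

    id: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - STANDARD_AA - {"X"}
        if bad:
            raise FormatError(f"invalid residue letters {sorted(bad)} in {self.id!r}")
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def first_residue(self) -> int:
        return self.numbering_offset

    @property
    def last_residue(self) -> int:
        return self.numbering_offset + len(self.sequence) - 1

    def residue_at(self, number: int) -> str:
        if not (self.first_residue <= number <= self.last_residue):
            raise IndexError(
                f"residue {number} outside numbered range "
                f"{self.first_residue}..{self.last_residue} of {self.id}")
        return self.sequence[number - self.numbering_offset]


def _parse_offset(description: str) -> int:
    for token in description.split():
        if token.startswith("offset="):
            return int(token.split("=", 1)[1])
    return 1


def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased and whitespace-stripped; letters outside the 20
    standard residues are mapped to X with a warning.  An ``offset=N`` token
    in the description sets the record's numbering offset.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        cleaned = []
        for ch in seq:
            if ch in STANDARD_AA or ch == "X":
                cleaned.append(ch)
            else:
                logger.warning("record %s: unknown residue letter %r mapped to X", rec.id, ch)
                cleaned.append("X")
        records.append(ProteinRecord(rec.id, "".join(cleaned),
                                     _parse_offset(rec.description)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            offset = f" offset={rec.numbering_offset}" if rec.numbering_offset != 1 else ""
            fh.write(f">{rec.id}{offset}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class VariantRecord:
    """A single missense substitution in protein coordinates."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    significance: str = "other"
    source_db: str = ""

    def __post_init__(self):
        if self.wt_aa not in STANDARD_AA or self.mut_aa not in STANDARD_AA:
            raise ValueError(f"non-standard residue in variant {self.label}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"synonymous variant {self.label}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1 in variant {self.label}")
        if self.significance not in SIGNIFICANCE_LABELS:
            raise ValueError(f"bad significance {self.significance!r}")

    @property
    def label(self) -> str:
        return f"{self.protein_id}:{self.wt_aa}{self.position}{self.mut_aa}"


REQUIRED_VARIANT_COLUMNS = ("protein_id", "position", "wt", "mut", "significance", "source")


def read_variant_table(path) -> list[VariantRecord]:
    """Read the package's variant TSV; invalid rows are rejected with a warning.

    Parsing is order-preserving: the returned list follows file order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table missing columns {missing}")
    out = []
    for idx, row in df.iterrows():
        try:
            position = int(str(row["position"]))
        except (TypeError, ValueError):
            logger.warning("row %d: non-integer position %r rejected", idx, row["position"])
            continue
        wt = str(row["wt"]).strip().upper()
        mut = str(row["mut"]).strip().upper()
        if wt == mut:
            logger.warning("row %d: wt == mut (%s) rejected", idx, wt)
            continue
        sig = str(row["significance"]).strip().lower()
        if sig not in SIGNIFICANCE_LABELS:
            logger.warning("row %d: significance %r coerced to 'other'", idx, sig)
            sig = "other"
        try:
            out.append(VariantRecord(str(row["protein_id"]).strip(), position,
                                     wt, mut, sig, str(row["source"]).strip()))
        except ValueError as exc:
            logger.warning("row %d rejected: %s", idx, exc)
    return out


def write_variant_table(variants: list[VariantRecord], path) -> None:
    df = pd.DataFrame(
        [{"protein_id": v.protein_id, "position": v.position, "wt": v.wt_aa,
          "mut": v.mut_aa, "significance": v.significance, "source": v.source_db}
         for v in variants])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# structures


@dataclass
class AtomRecord:
    serial: int
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    x: float
    y: float
    z: float
    element: str = ""
    occupancy: float = 1.0
    record_class: str = "polymer"  # polymer | ligand | water

    def __post_init__(self):
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError("non-finite coordinate in atom record")


@dataclass
class StructureModel:
    """A light container for one coordinate model."""

    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self):
        if not any(a.record_class == "polymer" for a in self.atoms):
            raise FormatError("structure contains no polymer atoms")
        # polymer residues must be strictly ordered within each chain
        last: dict[str, int] = {}
        for a in self.atoms:
            if a.record_class != "polymer":
                continue
            prev = last.get(a.chain_id)
            if prev is not None and a.res_seq < prev:
                raise FormatError(
                    f"polymer residues out of order in chain {a.chain_id}")
            last[a.chain_id] = a.res_seq

    def chain_ids(self) -> list[str]:
        seen = []
        for a in self.atoms:
            if a.record_class == "polymer" and a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def chain_residues(self, chain_id: str) -> list[tuple[int, str, dict]]:
        """[(res_seq, res_name, {atom_name: (x, y, z)})] for one chain."""
        residues: dict[int, tuple[str, dict]] = {}
        for a in self.atoms:
            if a.record_class != "polymer" or a.chain_id != chain_id:
                continue
            name, coords = residues.setdefault(a.res_seq, (a.res_name, {}))
            coords[a.name] = (a.x, a.y, a.z)
        return [(seq, residues[seq][0], residues[seq][1]) for seq in sorted(residues)]

    def polymer_sequence(self, chain_id: str) -> list[str]:
        return [name for _, name, _ in self.chain_residues(chain_id)]


def _classify_residue(res_name: str) -> str:
    if res_name in WATER_NAMES:
        return "water"
    if res_name in AA3_SET or res_name in MODIFIED_PARENT:
        return "polymer"
    return "ligand"


def read_structure(path) -> StructureModel:
    """Read a PDB file into a StructureModel.

    Modified residues (e.g. selenomethionine) are mapped to their parent
    standard residue; waters and ligands are flagged by record class.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: list[AtomRecord] = []
    serial = 1
    model = st[0]
    for chain in model:
        for res in chain:
            res_name = res.name.strip()
            cls = _classify_residue(res_name)
            mapped = MODIFIED_PARENT.get(res_name, res_name)
            for atom in res:
                name = atom.name
                if cls == "polymer" and res_name in MODIFIED_PARENT and name == "SE":
                    name = "SD"  # selenomethionine selenium -> parent sulfur
                atoms.append(AtomRecord(
                    serial=serial, name=name,
                    res_name=mapped if cls == "polymer" else res_name,
                    chain_id=chain.name, res_seq=res.seqid.num,
                    x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                    element=atom.element.name, occupancy=atom.occ,
                    record_class=cls))
                serial += 1
    return StructureModel(atoms)


def write_structure(model: StructureModel, path) -> None:
    """Write a StructureModel as a PDB file (coordinates to 3 decimals)."""
    st = gemmi.Structure()
    st.name = "larkszip"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        chain = chains.get(a.chain_id)
        if chain is None:
            chain = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = chain
        if (len(chain) == 0 or chain[-1].seqid.num != a.res_seq
                or chain[-1].name != a.res_name):
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, " ")
            res.het_flag = "A" if a.record_class == "polymer" else "H"
            chain.add_residue(res)
        res = chain[-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.pos = gemmi.Position(a.x, a.y, a.z)
        atom.occ = a.occupancy
        atom.element = gemmi.Element(a.element or a.name[0])
        res.add_atom(atom)
    for chain in chains.values():
        md.add_chain(chain)
    st.add_model(md)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# reports


def write_report(df: pd.DataFrame, path, fmt: str | None = None) -> None:
    """Write a tabular report as TSV or JSON (by extension if fmt is None)."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "tsv")
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1, default=str))
    else:
        raise ValueError(f"unknown report format {fmt!r}")
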
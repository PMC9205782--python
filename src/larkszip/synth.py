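"""Synthetic data generators: low-complexity proteomes with planted kinked
segments, pathogenic-like/benign-like variant tables, and idealised two-sheet
fibril structures of each steric-zipper class.

Every generator is a pure function of (spec, seed): identical inputs give
byte-identical outputs.  Ground truth (planted windows, planted conversions,
planted zipper attributes) is returned alongside the data so downstream
recovery can be scored without reference to generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import random_rigid_transform
from .io import ProteinRecord, VariantRecord
from .templates import BackboneTemplate, expand_fibril
from .threading import graft_sequence
from .zipgeom import CLASS_TABLE

#: glycine/serine/tyrosine-rich low-complexity composition (head-domain-like)
LCD_PROFILE = {
    "G": 0.26, "S": 0.22, "Y": 0.10, "A": 0.10, "T": 0.08, "N": 0.07,
    "Q": 0.06, "P": 0.04, "F": 0.03, "V": 0.02, "L": 0.01, "M": 0.01,
}

#: planted kinked-segment motifs: Gly at kink-pocket-compatible positions,
#: drawn from the same sequence family as the calibration positives
PLANTED_MOTIFS = ("GGYGGA", "GYGGAS", "SGMGGI", "GMGGIT", "STGGYS", "SYSGYS")

#: substitutions planted as conversion-positive ground truth (kink Gly ->
#: small hydrophobic / cysteine)
PATHOGENIC_TRUTH_SUBS = ("A", "C", "V")
#: additional pathogenic-like substitutions drawn but not counted as truth
PATHOGENIC_OTHER_SUBS = ("S", "H")

#: conservative benign-like substitution table (glycine excluded: Gly
#: replacements are precisely the pathogenic-like class)
BENIGN_SUBS = {
    "S": "T", "T": "S", "I": "V", "V": "I", "L": "M", "M": "L",
    "F": "Y", "Y": "F", "N": "Q", "Q": "N", "D": "E", "E": "D",
    "K": "R", "R": "K", "A": "S",
}


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_proteins: int = 12
    protein_length: int = 60
    composition: dict = field(default_factory=lambda: dict(LCD_PROFILE))
    windows_per_protein: int = 2
    motifs: tuple = PLANTED_MOTIFS
    #: pathogenic-like rows per planted window (drawn at its kink glycine)
    pathogenic_per_window: int = 2
    #: fraction of pathogenic-like rows using truth substitutions (A/C/V)
    truth_fraction: float = 0.8
    n_benign: int = 60

    def __post_init__(self):
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("composition must sum to 1")
        if self.protein_length < max(len(m) for m in self.motifs):
            raise ValueError("protein_length shorter than planted window")


def _rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def generate_synthetic_proteome(spec: SyntheticSpec):
    """Seeded LCD-like proteome with planted kinked windows.

    Returns (records, truth) where truth is a DataFrame with one row per
    planted window: protein_id, start, end, motif, kink_positions (1-based
    residue numbers of the motif's glycines at kink-pocket positions).
    """
    rng = _rng(spec)
    aas = list(spec.composition)
    probs = np.array([spec.composition[a] for a in aas])
    records, truth_rows = [], []
    for pi in range(spec.n_proteins):
        L = spec.protein_length
        seq = list(rng.choice(aas, size=L, p=probs))
        # choose non-overlapping window slots
        starts = []
        attempts = 0
        while len(starts) < spec.windows_per_protein and attempts < 200:
            attempts += 1
            s = int(rng.integers(0, L - 6 + 1))
            if all(abs(s - t) >= 8 for t in starts):
                starts.append(s)
        starts.sort()
        pid = f"SYN{pi:03d}"
        for s in starts:
            motif = str(rng.choice(spec.motifs))
            seq[s:s + len(motif)] = list(motif)
            kinks = [s + 1 + i for i, aa in enumerate(motif) if aa == "G"]
            truth_rows.append({"protein_id": pid, "start": s + 1,
                               "end": s + len(motif), "motif": motif,
                               "kink_positions": tuple(kinks)})
        records.append(ProteinRecord(pid, "".join(seq)))
    truth = pd.DataFrame(truth_rows)
    return records, truth


def generate_synthetic_variants(records: list[ProteinRecord],
                                window_truth: pd.DataFrame,
                                spec: SyntheticSpec):
    """Pathogenic-like and benign-like variant tables with planted truth.

    Pathogenic-like rows substitute a glycine of a planted window; rows using
    A/C/V are flagged ``planted_converted`` (the recovery ground truth).
    Benign-like rows apply conservative substitutions at uniform positions
    outside any planted window.  All rows are consistent with the sequences.

    Returns (variants, truth) where truth is a DataFrame aligned with the
    variant list (columns: label, klass, planted_converted).
    """
    rng = _rng(spec)
    by_id = {r.id: r for r in records}
    variants, truth_rows = [], []

    for _, row in window_truth.iterrows():
        protein = by_id[row["protein_id"]]
        kinks = list(row["kink_positions"])
        if not kinks:
            continue
        for _ in range(spec.pathogenic_per_window):
            pos = int(rng.choice(kinks))
            if rng.random() < spec.truth_fraction:
                mut = str(rng.choice(PATHOGENIC_TRUTH_SUBS))
                planted = True
            else:
                mut = str(rng.choice(PATHOGENIC_OTHER_SUBS))
                planted = False
            v = VariantRecord(protein.id, pos, "G", mut, "pathogenic", "synthetic")
            variants.append(v)
            truth_rows.append({"label": v.label, "klass": "pathogenic",
                               "planted_converted": planted})

    in_window = {
        (row["protein_id"], p)
        for _, row in window_truth.iterrows()
        for p in range(row["start"], row["end"] + 1)}
    n_drawn = 0
    attempts = 0
    while n_drawn < spec.n_benign and attempts < spec.n_benign * 200:
        attempts += 1
        rec = records[int(rng.integers(0, len(records)))]
        pos = int(rng.integers(rec.first_residue, rec.last_residue + 1))
        wt = rec.residue_at(pos)
        if wt not in BENIGN_SUBS or (rec.id, pos) in in_window:
            continue
        v = VariantRecord(rec.id, pos, wt, BENIGN_SUBS[wt], "benign", "synthetic")
        variants.append(v)
        truth_rows.append({"label": v.label, "klass": "benign",
                           "planted_converted": False})
        n_drawn += 1
    return variants, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# idealised zipper structures

#: class attributes -> mating-sheet symmetry op of the generator
_OP_OF_ATTRS = {
    ("face-to-face", "up-up"): "ry",
    ("face-to-back", "up-up"): "t",
    ("face-to-face", "up-down"): "rz",
    ("face-to-back", "up-down"): "rx",
}

_ATTRS_OF_CLASS = {v: k for k, v in CLASS_TABLE.items()}


def make_ideal_zipper_structure(class_number: int, sequence: str, seed: int = 0):
    """Idealised 2-sheet x 4-strand fibril realising a steric-zipper class.

    The assembly is built from the pleated strand geometry, grafted with
    ``sequence`` (first rotamer), and given a seeded random rigid-body
    orientation.  Returns (StructureModel, ground_truth dict).
    """
    if class_number not in _ATTRS_OF_CLASS:
        raise ValueError(f"class_number must be 1..8, got {class_number}")
    if not (2 <= len(sequence) <= 7):
        raise ValueError("sequence length must be 2..7")
    within, face, polarity = _ATTRS_OF_CLASS[class_number]
    antiparallel = within == "antiparallel"
    template = BackboneTemplate(
        name=f"ideal_class{class_number}",
        category="zipper",
        dihedrals=np.array([[-120.0, 120.0, 180.0]] * len(sequence)),
        strand_rise=4.8,
        sheet_separation=9.5,
        # Antiparallel sheets are a two-strand repeat, so the axial offset of
        # the mating sheet selects which flip-phase faces the reference
        # strand: a full-rise offset swaps the apparent sheet polarity while
        # leaving face packing unchanged.  Classes 5 and 8 need the shifted
        # phase; parallel classes use the usual half-rise stagger.
        sheet_axial_offset=(4.8 if class_number in (5, 8) else 0.0)
        if antiparallel else 2.4,
        antiparallel_in_sheet=antiparallel,
        sheet_op=_OP_OF_ATTRS[(face, polarity)],
    )
    assembly = expand_fibril(template, 4, 2)
    model = graft_sequence(assembly, sequence)
    structure = model.to_structure()
    rng = np.random.default_rng(seed)
    R, t = random_rigid_transform(rng)
    for a in structure.atoms:
        xyz = R @ np.array([a.x, a.y, a.z]) + t
        a.x, a.y, a.z = map(float, xyz)
    truth = {"class_number": class_number, "within_sheet": within,
             "face_packing": face, "sheet_polarity": polarity,
             "sequence": sequence, "seed": seed}
    return structure, truth
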
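"""The end-to-end mutation screen: scan proteins for LARKS windows, map
missense variants onto them, thread wild-type and mutant windows onto the
steric-zipper backbone, and call conversions.

Pipeline (mirroring the screen's four steps):

1. ``scan_larks``   — every k-mer window of a protein is threaded onto the
   three kinked LARKS templates; a window is accepted when its best energy is
   at or below the calibrated ``tau_L``.
2. ``map_variants_to_larks`` — variants are matched to every accepted window
   whose residue range contains their position.
3. ``score_zipper_pair`` — wild-type and mutant windows are threaded onto the
   pleated zipper backbone with identical settings; ``delta`` is mutant minus
   wild type.
4. conversion call — a variant is *converted* when its retained register has
   ``E_zip_mut <= tau_Z`` (absolute zipper viability) and ``delta <=
   delta_max`` (a strict decrease).  When several windows cover a variant,
   the retained register is the zipper-viable one with the lowest delta —
   the register where the mutation most increases zipper propensity — and
   only if no register is viable, the one with the lowest mutant energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibrate import shipped_calibration
from .io import ProteinRecord, VariantRecord, STANDARD_AA
from .templates import BackboneTemplate, load_builtin_templates
from .threading import EnergyWeights, thread_window

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SequenceWindow:
    """A contiguous window of a protein, 1-based inclusive coordinates."""

    protein_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("window coordinates do not match sequence length")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class LarksCall:
    window: SequenceWindow
    best_template: str
    e_larks: float
    accepted: bool


@dataclass
class ZipperScorePair:
    variant: VariantRecord
    wt_window: SequenceWindow
    mut_window: SequenceWindow
    e_zip_wt: float
    e_zip_mut: float
    converted: bool = False

    @property
    def delta(self) -> float:
        return self.e_zip_mut - self.e_zip_wt


@dataclass
class MutationMatrix:
    """20x20 integer counts of (wild-type, mutant) residue pairs."""

    counts: pd.DataFrame

    @classmethod
    def empty(cls) -> "MutationMatrix":
        z = pd.DataFrame(0, index=list(AA_ORDER), columns=list(AA_ORDER), dtype=int)
        return cls(z)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())


@dataclass
class ScreenConfig:
    tau_L: float
    tau_Z: float
    delta_max: float
    k: int = 6
    weights: EnergyWeights = field(default_factory=EnergyWeights)
    seed: int = 0

    def __post_init__(self):
        if self.delta_max > 0:
            raise ValueError("delta_max must be <= 0")

    @classmethod
    def default(cls) -> "ScreenConfig":
        cal = shipped_calibration()
        w = cal["weights"]
        return cls(tau_L=cal["tau_L"], tau_Z=cal["tau_Z"],
                   delta_max=cal["delta_max"],
                   weights=EnergyWeights(w["w_rep"], w["w_att"],
                                         w["w_solv"], w["w_hb"]))


# ---------------------------------------------------------------------------
# window operations


def extract_window(protein: ProteinRecord, start: int, end: int) -> SequenceWindow:
    """The exact substring at residues [start, end] under the protein's
    numbering offset."""
    if start > end:
        raise ValueError("start must be <= end")
    if start < protein.first_residue or end > protein.last_residue:
        raise IndexError(
            f"window {start}..{end} outside numbered range "
            f"{protein.first_residue}..{protein.last_residue} of {protein.id}")
    off = protein.numbering_offset
    return SequenceWindow(protein.id, start, end,
                          protein.sequence[start - off:end - off + 1])


def apply_mutation(window: SequenceWindow, variant: VariantRecord) -> SequenceWindow:
    """Substitute the variant residue inside the window (coordinates kept)."""
    if not window.contains(variant.position):
        raise ValueError(f"variant {variant.label} outside window "
                         f"{window.start}..{window.end}")
    i = variant.position - window.start
    if window.sequence[i] != variant.wt_aa:
        raise ValueError(
            f"wild-type mismatch for {variant.label}: window has "
            f"{window.sequence[i]!r} at position {variant.position} "
            "(check numbering offsets)")
    seq = window.sequence[:i] + variant.mut_aa + window.sequence[i + 1:]
    return replace(window, sequence=seq)


# ---------------------------------------------------------------------------
# screen steps


def _split_templates(templates: list[BackboneTemplate]):
    larks = [t for t in templates if t.category == "LARKS"]
    zippers = [t for t in templates if t.category == "zipper"]
    if not larks or not zippers:
        raise ValueError("need both LARKS and zipper templates")
    return larks, zippers[0]


def scan_larks(protein: ProteinRecord, templates: list[BackboneTemplate],
               config: ScreenConfig) -> list[LarksCall]:
    """Thread every sliding k-mer window on all LARKS templates (stride 1).

    Windows containing X are skipped with a warning.
    """
    larks, _ = _split_templates(templates)
    k = config.k
    if len(protein) < k:
        raise ValueError(f"protein {protein.id} shorter than window length {k}")
    calls = []
    for start in range(protein.first_residue, protein.last_residue - k + 2):
        window = extract_window(protein, start, start + k - 1)
        if "X" in window.sequence:
            logger.warning("window %s %d..%d contains X; skipped",
                           protein.id, window.start, window.end)
            continue
        energies = {t.name: thread_window(window.sequence, t, weights=config.weights)[1]
                    for t in larks}
        best = min(energies, key=energies.get)
        e = energies[best]
        calls.append(LarksCall(window=window, best_template=best, e_larks=e,
                               accepted=bool(e <= config.tau_L)))
    return calls


def map_variants_to_larks(variants: list[VariantRecord],
                          larks_calls: list[LarksCall]
                          ) -> tuple[list[tuple[VariantRecord, list[LarksCall]]], list[VariantRecord]]:
    """Match each variant to every *accepted* window containing its position.

    Returns (matched, unmatched); matching is set-like and independent of
    window-list order.
    """
    accepted = [c for c in larks_calls if c.accepted]
    matched, unmatched = [], []
    for v in variants:
        hits = sorted(
            (c for c in accepted
             if c.window.protein_id == v.protein_id and c.window.contains(v.position)),
            key=lambda c: (c.window.start, c.window.end))
        if hits:
            matched.append((v, hits))
        else:
            unmatched.append(v)
    return matched, unmatched


def score_zipper_pair(variant: VariantRecord, window: SequenceWindow,
                      zipper_template: BackboneTemplate,
                      config: ScreenConfig) -> ZipperScorePair:
    """Thread the wild-type and mutant window onto the zipper backbone."""
    mut_window = apply_mutation(window, variant)
    e_wt = thread_window(window.sequence, zipper_template, weights=config.weights)[1]
    e_mut = thread_window(mut_window.sequence, zipper_template, weights=config.weights)[1]
    pair = ZipperScorePair(variant=variant, wt_window=window, mut_window=mut_window,
                           e_zip_wt=e_wt, e_zip_mut=e_mut)
    pair.converted = bool(pair.e_zip_mut <= config.tau_Z
                          and pair.delta <= config.delta_max)
    return pair


def select_pair(pairs: list[ZipperScorePair], config: ScreenConfig) -> ZipperScorePair:
    """Retain one register per variant: the zipper-viable register with the
    lowest delta; if no register is viable, the lowest-energy one."""
    if not pairs:
        raise ValueError("no score pairs to select from")
    viable = [p for p in pairs if p.e_zip_mut <= config.tau_Z]
    if viable:
        return min(viable, key=lambda p: (p.delta, p.e_zip_mut))
    return min(pairs, key=lambda p: (p.e_zip_mut, p.delta))


# ---------------------------------------------------------------------------
# descriptive outputs


def mutation_heatmap(variants: list[VariantRecord]) -> MutationMatrix:
    """Counts of (wild-type, mutant) residue pairs over a variant list."""
    m = MutationMatrix.empty()
    for v in variants:
        m.counts.loc[v.wt_aa, v.mut_aa] += 1
    return m


def compare_pathogenic_benign(pairs_pathogenic: list[ZipperScorePair],
                              pairs_benign: list[ZipperScorePair]) -> dict:
    """Group medians, converted fractions, and a scatter-ready table."""
    if not pairs_pathogenic or not pairs_benign:
        raise ValueError("both groups must be non-empty")

    def summarise(pairs):
        e = np.array([p.e_zip_mut for p in pairs])
        d = np.array([p.delta for p in pairs])
        return {"median_e_zip_mut": float(np.median(e)),
                "median_delta": float(np.median(d)),
                "fraction_converted": float(np.mean([p.converted for p in pairs])),
                "n": len(pairs)}

    rows = []
    for group, pairs in (("pathogenic", pairs_pathogenic), ("benign", pairs_benign)):
        for p in pairs:
            rows.append({"group": group, "variant": p.variant.label,
                         "e_zip_mut": p.e_zip_mut, "delta": p.delta,
                         "converted": p.converted})
    return {"pathogenic": summarise(pairs_pathogenic),
            "benign": summarise(pairs_benign),
            "scatter": pd.DataFrame(rows)}


def residue_context_enrichment(variants: list[VariantRecord],
                               background_frequencies: dict[str, float]) -> pd.DataFrame:
    """Observed/background frequency ratio per residue type, for the
    wild-type and mutant sides separately.

    Zero-background residues are flagged and reported as NaN.
    """
    if not variants:
        return pd.DataFrame(columns=["residue", "side", "observed", "background",
                                     "enrichment", "undefined"])
    rows = []
    n = len(variants)
    for side, getter in (("wt", lambda v: v.wt_aa), ("mut", lambda v: v.mut_aa)):
        counts: dict[str, int] = {}
        for v in variants:
            counts[getter(v)] = counts.get(getter(v), 0) + 1
        for aa in AA_ORDER:
            obs = counts.get(aa, 0) / n
            bg = float(background_frequencies.get(aa, 0.0))
            undefined = bg == 0.0
            rows.append({"residue": aa, "side": side, "observed": obs,
                         "background": bg,
                         "enrichment": (obs / bg) if not undefined else np.nan,
                         "undefined": undefined})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full screen


@dataclass
class ScreenReport:
    table: pd.DataFrame                  # one row per scored variant
    rejected: pd.DataFrame               # quarantined variants with reasons
    heatmap: MutationMatrix
    larks_calls: dict[str, list[LarksCall]]
    group_summary: dict | None = None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self) -> str:
        import json
        return json.dumps(self.table.to_dict(orient="records"), indent=1, default=str)


def run_screen(proteins: list[ProteinRecord], variants: list[VariantRecord],
               config: ScreenConfig | None = None,
               templates: list[BackboneTemplate] | None = None) -> ScreenReport:
    """Compose scan -> map -> score -> classify over a set of proteins.

    Variants whose stated wild-type residue does not match the sequence are
    quarantined into the rejected table rather than silently dropped.  The
    whole run is deterministic for a fixed configuration.
    """
    config = config or ScreenConfig.default()
    templates = templates or load_builtin_templates()
    _, zipper = _split_templates(templates)
    by_id = {p.id: p for p in proteins}

    rejected_rows = []
    usable = []
    for v in variants:
        p = by_id.get(v.protein_id)
        if p is None:
            rejected_rows.append({"variant": v.label, "reason": "unknown protein"})
            continue
        if not (p.first_residue <= v.position <= p.last_residue):
            rejected_rows.append({"variant": v.label, "reason": "position out of range"})
            continue
        if p.residue_at(v.position) != v.wt_aa:
            rejected_rows.append({
                "variant": v.label,
                "reason": f"wild-type mismatch (sequence has "
                          f"{p.residue_at(v.position)})"})
            continue
        usable.append(v)

    larks_calls = {pid: scan_larks(p, templates, config)
                   for pid, p in by_id.items()
                   if len(p) >= config.k}
    all_calls = [c for calls in larks_calls.values() for c in calls]
    matched, unmatched = map_variants_to_larks(usable, all_calls)
    if not matched:
        logger.warning("no variant overlaps an accepted LARKS window; empty report")

    rows = []
    for v, hits in matched:
        pairs = [score_zipper_pair(v, c.window, zipper, config) for c in hits]
        best_call = min(hits, key=lambda c: c.e_larks)
        pair = select_pair(pairs, config)
        rows.append({
            "variant": v.label, "protein_id": v.protein_id, "position": v.position,
            "wt": v.wt_aa, "mut": v.mut_aa, "significance": v.significance,
            "n_windows": len(hits),
            "window": f"{pair.wt_window.start}-{pair.wt_window.end}",
            "wt_seq": pair.wt_window.sequence, "mut_seq": pair.mut_window.sequence,
            "E_larks": best_call.e_larks,
            "E_zip_wt": pair.e_zip_wt, "E_zip_mut": pair.e_zip_mut,
            "delta": pair.delta, "converted": pair.converted,
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        # per-protein normalized zipper score alongside the raw one
        table["E_zip_mut_norm"] = table.groupby("protein_id")["E_zip_mut"].transform(
            lambda s: s - s.median())

    report = ScreenReport(
        table=table,
        rejected=pd.DataFrame(rejected_rows, columns=["variant", "reason"]),
        heatmap=mutation_heatmap([v for v, _ in matched]),
        larks_calls=larks_calls)

    scored = {r["variant"]: r for r in rows}
    path_pairs = [p for v, hits in matched if v.significance == "pathogenic"
                  for p in [_pair_of(scored, v)] if p is not None]
    ben_pairs = [p for v, hits in matched if v.significance == "benign"
                 for p in [_pair_of(scored, v)] if p is not None]
    if path_pairs and ben_pairs:
        report.group_summary = {
            "pathogenic": _summary_from_rows(path_pairs),
            "benign": _summary_from_rows(ben_pairs)}
    return report


def _pair_of(scored: dict, v: VariantRecord):
    return scored.get(v.label)


def _summary_from_rows(rows: list[dict]) -> dict:
    return {"median_e_zip_mut": float(np.median([r["E_zip_mut"] for r in rows])),
            "median_delta": float(np.median([r["delta"] for r in rows])),
            "fraction_converted": float(np.mean([r["converted"] for r in rows])),
            "n": len(rows)}
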
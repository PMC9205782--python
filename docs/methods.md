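# Methods

## The model

Amyloid fibrils are stacks of identical peptide strands hydrogen-bonded into
β-sheets; in pathogenic amyloid two pleated sheets mate through interdigitated
side chains (a *steric zipper*), while the reversible assemblies formed by
low-complexity domains are built from *kinked* β-strands (LARKS) whose kinks
limit sheet adhesion. `larkszip` operationalises the hypothesis that a
missense mutation can convert a reversible kinked segment into an
irreversible zipper: a sequence window is threaded onto fixed kinked and
pleated fibril backbones, scored with a packing energy, and a variant is
called *converted* when its mutant window forms a markedly better zipper
than the wild type.

All energies are in arbitrary units. Only orderings and thresholded calls
carry meaning; no correspondence with any force-field scale is intended.

## Backbone templates

Templates are short strands defined purely by per-residue (φ, ψ, ω)
dihedrals, realised with ideal peptide geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, trans ω). They ship as a plain-text table
(`data/templates.cfg`).

* **Three LARKS templates** (named after published kinked low-complexity
  segments STGGYS, SYSGYS, GYNGFG): mostly-β 6-mers with glycine-sized kink
  pockets — φ = +45°, ψ = +105°, a positive-φ conformation comfortable only
  for glycine — at positions 2, 4, or both (0-based). Kink values were
  selected so that the strand stacks in register at the 4.8 Å fibril rise
  without backbone clashes while a β-carbon at the kink position is
  genuinely strained. Mating sheets sit 9.0 Å apart.
* **One zipper template**: the canonical pleated parallel in-register
  β-strand (φ = −120°, ψ = +120°), sheets 9.5 Å apart with a half-rise
  (2.4 Å) axial stagger. The tight fixed interface is deliberate: small and
  medium side chains (Ala, Cys, Val, His, Met, Ile) interdigitate, while
  oversized aromatics (Tyr, Trp) cannot avoid deep overlap — the steric
  basis for the Tyr→His conversion signal.

Fibril context for scoring is fixed at 2 sheets × 5 strands with the query
sequence on every strand (homotypic in-register stacking, as in real fibril
cores). Antiparallel sheets are modelled as a two-strand repeat with a 9.6 Å
period.

## Energy function

Four decomposed terms; `E_total = w_rep·E_rep + w_att·E_att + w_solv·E_solv
+ w_hb·E_hb` holds as an exact identity on every scored model.

| term | form | default weight |
|------|------|----------------|
| `E_rep` | per-pair overlap `v² + 100·v⁶`, `v = max(0, r0−d)/r0`, onset `r0 = 0.85(rᵢ+rⱼ)`; plus torsional strain (below) | 20 |
| `E_att` | per-atom capped contact well: nonpolar partners contribute a ramp 1 → 0 over [vdW contact, contact+1 Å]; per-atom sum capped at 3 | 0.3 |
| `E_solv` | per-atom occlusion (linear kernel, 5.5 Å) saturating to a burial fraction; signed +1 polar, −0.5 nonpolar, +3 formal-charge atoms | 2 |
| `E_hb` | geometric hydrogen bonds: donor–acceptor heavy atoms 2.6–3.5 Å, ≥ 90° at both antecedents; −1 each | 2 |

Per-atom saturation of burial and attraction is the load-bearing choice: an
atom can only be buried once, so a large side chain cannot accumulate
unbounded reward simply by touching many symmetry copies. The hard `v⁶`
component makes deep interpenetration prohibitive while tolerating grazing
contacts of ideal-geometry models.

Torsional-compatibility strain (added to `E_rep` as raw units per strand
copy): proline pays 3.0 at positions whose template φ is outside −100…−30°;
glycine pays 0.25 at β-region (φ ≤ 0) positions — glycine's accessible
Ramachandran area is by far the largest, so pinning it in an extended or
pleated strand costs the most conformational freedom, and it pays nothing at
a positive-φ kink. This term is what lets a Gly-rich segment genuinely
prefer a kinked backbone over the pleated zipper, and it contributes the
"kink-glycine removal" component of conversion deltas.

## Side chains and packing

Ideal residue geometry (atom names, elements, bonds, coordinates) comes from
the chemical component dictionary bundled with biotite; side chains are
grafted by superposing the ideal N/CA/C triad and rotating χ torsions. The
rotamer library is a coarse backbone-independent grid — χ1 (and aliphatic
χ2) ∈ {−60°, +60°, 180°}, aromatic χ2 ∈ {−90°, 0°, +90°}, χ3+ trans, ≤ 9
rotamers per type — deliberately small so exhaustive enumeration over short
templates stays cheap enough to serve as a test oracle for the packer.

Packing is symmetry-coupled (one rotamer choice per position, shared by all
strand copies) and proceeds by greedy per-position best-rotamer sweeps on
precomputed interaction tables; pair-additive terms are cached as scalars and
the saturating terms as per-atom contribution vectors, so any assignment's
energy is reassembled exactly. Starts: every single-rotamer seeding for
templates of ≤ 4 positions (where the exhaustive oracle applies), otherwise
the all-first-rotamer and a self-energy-greedy start. Ties resolve to the
lowest rotamer index; repeated runs are bit-identical. A direct evaluator
recomputes the energy from raw coordinates and must agree with the table
route to machine precision (tested).

## The screen and its thresholds

1. every 6-mer window (stride 1) is threaded on the three LARKS templates;
   `E_larks` is the minimum, and the window is accepted when
   `E_larks ≤ τ_L`;
2. variants are matched to every accepted window containing their position
   (wild-type-mismatching variants are quarantined, not dropped);
3. wild-type and mutant windows are threaded on the zipper template;
   `Δ = E_zip(mut) − E_zip(wt)`;
4. per variant, the retained register is the zipper-viable one
   (`E_zip_mut ≤ τ_Z`) with the lowest Δ — the register where the mutation
   most increases zipper propensity; a variant is *converted* when that
   register has `E_zip_mut ≤ τ_Z` and `Δ ≤ δ_max`.

Min-Δ selection (rather than min-`E_zip_mut`) matters when a wild-type
register contains an oversized interface residue: the conversion signal
lives exactly in the register where the mutation relieves that residue, and
picking the register by mutant energy alone would hide it.

Thresholds are calibrated, versioned constants (`data/calibration.json`,
regenerated deterministically by `larkszip calibrate`):

* `τ_L` = worst control positive + 25% of the gap to the best control
  negative. Positives: the template name-sake segments plus the KRT8
  head-domain 6-mers; negatives: scrambled charged/bulky sequences
  (WWWWWW, KWEWRF, REKDKE, WRWDWK, KRKRKR, WFYWFY, YKEWRY, EDEDED).
  Shipped value 76.7 with a separation margin of ≈ 250 units.
* `τ_Z` = worst zipper-improving control register + 10% (shipped 300.5):
  every control conversion is zipper-viable.
* `δ_max` = 80% of the weakest control conversion's Δ (shipped −40.7): a
  conversion must be commensurate with the weakest experimentally confirmed
  control, not merely any decrease. With a permissive `δ_max` almost half
  of conservative benign-like substitutions show some small negative Δ.

## Zipper geometry analysis

Strands are chains with ≥ 2 residues; sheets are single-linkage clusters of
strands with minimum CA–CA distance ≤ 5.5 Å and backbone N···O contact
≤ 3.8 Å. The zipper class (1–8) is the product of three binary attributes:
within-sheet orientation (sign of adjacent strand-vector dot products), face
packing (whether the closest cross-interface strand pair presents the same
residue parity to the interface, read from CB−CA projections; glycine uses a
virtual CB), and sheet polarity (sign of the reference pair's strand-vector
dot product). The attribute→class table is a module constant
(`zipgeom.CLASS_TABLE`), transcribed from the standard steric-zipper
taxonomy; the generator/classifier round-trip over all 8 idealised classes
and the deposited-structure worked examples (when the files are available)
are its audits.

Backbone conformation labels partition the φ/ψ plane: *extended* when both
|φ|, |ψ| ≥ 155° ("nearly |180°|" operationalised), *pleated* when
φ ∈ [−150, −90] and ψ ∈ [90, 150], *kinked* when φ > 0 or |ψ| < 60°, else
*other*. Bounds live in `zipgeom.CONFORMATION_REGIONS`.

Buried interface area uses an in-package Shrake–Rupley implementation
(deterministic golden-spiral sphere points, default 960/atom, probe 1.4 Å),
cross-checked against biotite's SASA in the tests:
`buried = [SASA(A) + SASA(B) − SASA(AB)]/2`, normalised per strand layer.
Doubling the point density moves the result by < 2%; random rigid
reorientation by < 3%.

## Synthetic data

The proteome generator emulates G/S/Y-rich low-complexity domains
(composition ≈ G 0.26, S 0.22, Y 0.10, A 0.10, T 0.08, N 0.07, Q 0.06,
P 0.04, F 0.03, V 0.02, L 0.01, M 0.01) with planted kinked 6-mers drawn
from the calibration-positive family. Pathogenic-like variants substitute a
planted window's glycine; rows using A/C/V are the recovery ground truth,
rows using S/H are drawn but not counted as truth. Benign-like variants are
conservative swaps (S↔T, I↔V, D↔E, K↔R, F↔Y, …; glycine excluded, since
glycine replacement is precisely the pathogenic-like class) at uniform
positions outside planted windows. Everything is a pure function of
(spec, seed).

What the generator does *not* emulate: real proteome length and domain
structure, isoform/numbering mismatches (exercised separately via the
quarantine path), genuinely ambiguous variant effects, and any
sequence-context correlation beyond composition. Passing recovery therefore
demonstrates that the pipeline's machinery is self-consistent at realistic
composition, not that its calls transfer to clinical data.

The idealised fibril generator realises each of the 8 zipper classes as a
2-sheet × 4-strand assembly (pleated strands, 9.5 Å sheet gap) under a
seeded random rigid transform. For antiparallel classes the mating sheet's
axial offset selects which flip-phase faces the reference strand, which is
how classes 5/8 differ from 7/6 in the generator.

## Problem sizes and determinism

The default test suite and the acceptance script use: the KRT8 head-domain
core (residues 45–70) for screen anchors; a 12-protein × 60-residue
synthetic proteome with 24 planted windows, ~72 pathogenic-like rows (≥ 50
ground-truth conversions) and 60 benign-like rows; 24 classifier round-trip
cases; and 50 packing-oracle cases on 2–3-residue truncated templates with
≤ 6 rotamers/residue. On one CPU the synthetic screen takes a few minutes;
everything else is seconds. All randomness flows through explicit
`numpy.random.default_rng` seeds; threading itself is fully deterministic.

## Known limitations

* The backbone never relaxes: threading is strictly fixed-backbone, so
  borderline fits that a flexible backbone would admit are scored as
  clashes. This is intentional (it is the discrimination mechanism) but
  means absolute energies are not comparable across templates with
  different strain profiles.
* The rotamer grid is coarse; packed energies are upper bounds relative to
  a fine library.
* No electrostatics beyond the charged-burial penalty; salt bridges and
  polar zippers (e.g. Asn/Gln ladders) are under-rewarded.
* Purely aliphatic bulky sequences (e.g. LILVLI) thread acceptably onto the
  kinked templates; the LARKS acceptance threshold separates Gly-rich
  segments from charged/aromatic-bulky scrambles, not from every
  zipper-prone hydrophobic segment.
* The attribute→class table is audited against idealised structures in all
  environments, but against deposited fibril structures only when those
  files are locally available.
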
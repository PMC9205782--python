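# Backbone template dihedral tables (phi psi omega, degrees).
#
# LARKS templates: mostly-beta 6-mer strands with glycine-sized kink pockets
# (phi = +45, psi = +105 — a positive-phi conformation comfortable only for
# glycine) at the positions marked below.  Kink values were chosen so the
# strand stacks in register at the fibril rise without backbone clashes while
# a C-beta at the kink position is genuinely strained.  The three templates
# are named after the published kinked low-complexity segments they model.
#
# Zipper template: ideal pleated parallel in-register beta strand
# (phi = -120, psi = +120), the canonical steric-zipper backbone.  Its mating
# sheet is tighter than the LARKS templates', so oversized side chains cannot
# interdigitate at the zipper interface.
#
# sheet_op encodes the symmetry of the mating sheet:
#   ry = face-to-face, sheets parallel (class-1-like packing)

[LARKS_STGGYS]
category = LARKS
rise = 4.8
sheet_separation = 9.0
sheet_axial_offset = 2.4
sheet_op = ry
residue = -120.0 125.0 180.0
residue = -125.0 120.0 180.0
residue =   45.0 105.0 180.0
residue = -125.0 120.0 180.0
residue = -120.0 125.0 180.0
residue = -125.0 120.0 180.0

[LARKS_SYSGYS]
category = LARKS
rise = 4.8
sheet_separation = 9.0
sheet_axial_offset = 2.4
sheet_op = ry
residue = -120.0 125.0 180.0
residue = -125.0 120.0 180.0
residue = -120.0 125.0 180.0
residue = -125.0 120.0 180.0
residue =   45.0 105.0 180.0
residue = -125.0 120.0 180.0

[LARKS_GYNGFG]
category = LARKS
rise = 4.8
sheet_separation = 9.0
sheet_axial_offset = 2.4
sheet_op = ry
residue = -120.0 125.0 180.0
residue = -125.0 120.0 180.0
residue =   45.0 105.0 180.0
residue = -125.0 120.0 180.0
residue =   45.0 105.0 180.0
residue = -125.0 120.0 180.0

[ZIPPER_P1]
category = zipper
rise = 4.8
sheet_separation = 9.5
sheet_axial_offset = 2.4
sheet_op = ry
residue = -120.0 120.0 180.0
residue = -120.0 120.0 180.0
residue = -120.0 120.0 180.0
residue = -120.0 120.0 180.0
residue = -120.0 120.0 180.0
residue = -120.0 120.0 180.0
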
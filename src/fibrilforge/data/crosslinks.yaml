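# Crosslink type registry, version 1.
#
# Each entry maps a crosslink type name to its valence (number of
# participating residues), the residue codes of the unit members, and
# the reactive side-chain atom names per residue code.  Users may append
# their own entries (load_registry accepts extra files).
#
# Residue codes for the modified residues are package conventions:
#   HYK  hydroxylysine member of an HLKNL crosslink
#   KNL  keto-norleucine (lysine-aldehyde derived) member of HLKNL
#   PYD  hydroxylysine member of a pyridinoline (PYD) crosslink
#   XLS  synthetic fixture crosslink residue (laterally extended reactive
#        atoms; used only by the synthetic template/fibril generators)
version: 1
types:
  HLKNL:
    valence: divalent
    description: hydroxylysine-keto-norleucine, immature divalent crosslink
    residues: [HYK, KNL]
    reactive_atoms:
      HYK: [NZ]
      KNL: [CE]
  PYD:
    valence: trivalent
    description: hydroxylysyl-pyridinoline, mature trivalent crosslink
    residues: [PYD, PYD, PYD]
    reactive_atoms:
      PYD: [NZ]
  SYNX:
    valence: divalent
    description: synthetic fixture crosslink (test plumbing, not chemistry)
    residues: [XLS, XLS]
    reactive_atoms:
      XLS: [NZ1, NZ2, NZ3, NZ4]
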
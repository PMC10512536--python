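# Canonical opsin functional-site catalog, bovine rhodopsin numbering (1-based).
# Edit to add or re-weight sites; positions must lie within the 348-aa reference.
chromophore_lysine: 296
disulfide_cysteines: [110, 187]
counterion_candidates: [83, 94, 113, 181]
spectral_tuning:
  83: {canonical: D, blue_shift: N}     # D83N shifts absorbance toward blue
  292: {canonical: A, blue_shift: S}    # A292S likewise
ery:
  span: [134, 136]
  pattern: "[DE]R[YW]"                  # Asp/Glu-Arg-Tyr/Trp activation tripeptide
npxxy:
  span: [302, 306]
  pattern: "NP..Y"
g_protein_tripeptide:
  span: [310, 312]
  known_states:
    NKQ: c-opsin
    HMK: r-opsin
    HKQ: Tcop13
fr_motif:
  span: [313, 314]
  pattern: "FR"
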
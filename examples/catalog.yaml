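# Motif catalog for the selenium-binding-protein family.
# Tokens: uppercase letter = literal residue, x = any canonical residue,
# [ABC] = enumerated class, {phi}/{pol} = property classes defined below.
classes:
  phi: FILMVWY       # bulky hydrophobic
  pol: CDEHKNQRSTY   # polar
motifs:
  CC: {pattern: CC, max_edits: 1}
  CxxC: {pattern: CxxC, max_edits: 2}
  CSSC: {pattern: CSSC, max_edits: 2}
  starDEL: {pattern: "[GKRDN]DEL", max_edits: 2}
  HxD: {pattern: HxD, max_edits: 2}
  HxxD: {pattern: HxxD, max_edits: 2}
  HxxHC: {pattern: HxxHC, max_edits: 2}
  clathrin_box: {pattern: "{pol}L{phi}{pol}{phi}{pol}", max_edits: 2}
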
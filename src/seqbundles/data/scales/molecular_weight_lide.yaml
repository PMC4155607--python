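# Average molecular weights of the free amino acids (g/mol), as tabulated
# in standard chemistry reference handbooks.  The Y-axis order runs small
# (top) to large (bottom); the tie between isoleucine and leucine is broken
# alphabetically.  Edit or replace this file to supply your own values.
name: molecular_weight_lide
units: g/mol
direction: ascending   # property value increases from top slot to bottom slot
gap: top
values:
  G: 75.07
  A: 89.09
  S: 105.09
  P: 115.13
  V: 117.15
  T: 119.12
  C: 121.16
  I: 131.17
  L: 131.17
  N: 132.12
  D: 133.10
  Q: 146.15
  K: 146.19
  E: 147.13
  M: 149.21
  H: 155.15
  F: 165.19
  R: 174.20
  Y: 181.19
  W: 204.23
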
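# Hydropathy ordering of the 20 amino acids, hydrophilic (top) to
# hydrophobic (bottom).  The numeric values are the Kyte-Doolittle
# hydropathy index, shipped as a stand-in for whichever hydrophobicity
# tabulation you prefer: the encoding consumes only the ORDER, and this
# file is meant to be edited or replaced by the user.  Ties are broken
# alphabetically.
name: hydrophobicity_wampler
units: hydropathy index
direction: ascending   # hydrophilic (low) at top, hydrophobic (high) at bottom
gap: top
values:
  R: -4.5
  K: -3.9
  D: -3.5
  E: -3.5
  N: -3.5
  Q: -3.5
  H: -3.2
  P: -1.6
  Y: -1.3
  W: -0.9
  S: -0.8
  T: -0.7
  G: -0.4
  A: 1.8
  M: 1.9
  C: 2.5
  F: 2.8
  L: 3.8
  V: 4.2
  I: 4.5
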
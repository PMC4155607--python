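"""Bridge tables and exact motif counts: when two columns disagree.

Two residues can each be frequent in their own column while almost no
sequence carries both — the 'bridge' (joint count of adjacent-column
pairs) exposes this, where per-column profiles cannot.
"""

from seqbundles import (
    bridge_counts,
    contest_like,
    motif_match_count,
    position_profile,
)

ga, manifest = contest_like(seed=1)
xor = manifest["groups"]["Gram-positive"]["features"][1]
p, res = xor["position"], xor["residue"]

left = position_profile(ga, "Gram-positive", p).count(res)
right = position_profile(ga, "Gram-positive", p + 1).count(res)
print(f"{res} at column {p}: {left} sequences; at column {p + 1}: {right}")

table = bridge_counts(ga, "Gram-positive", p)
print(f"{res}-{res} bridge (both columns on the same sequence): "
      f"{table.count(res, res)}")
# the single-column counts are large but the joint count is tiny: most
# sequences carry the residue at exactly one of the two columns

n_exact = motif_match_count(ga, "Gram-positive", p, res * 2)
print(f"sequences matching the exact {res}{res} motif: {n_exact}")
assert n_exact == table.count(res, res)
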
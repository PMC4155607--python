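# Methods

## The encoding

An MSA is a rectangular matrix of residue symbols over an alphabet plus
the gap character `-`. Each row becomes one unbroken line: at every
1-based column *p* the line is anchored at the Y-slot of its residue on
the active scale, and consecutive anchors are joined by a smooth curve.
Nothing is ever filtered: a path has exactly `n_cols` anchors, and the
rendered document contains exactly one path element per sequence (plus
any highlight copies drawn on top).

**Y-axis scales.** A scale is an ordered bijection between the alphabet
∪ {gap} and vertical slots. Two scales ship as editable YAML data:
residues by molecular weight (standard handbook values; the
isoleucine/leucine tie broken alphabetically) and a hydrophobicity
ordering, hydrophilic at the top. The hydrophobicity file carries
Kyte–Doolittle hydropathy values as a documented, user-replaceable
stand-in — the encoding consumes only the order, and the unit tests pin
order properties (lightest residue on top of the weight scale, bijection,
one gap slot), not literature values. The gap slot defaults to the
topmost position with extra padding, keeping the property gradient of the
remaining slots uninterrupted; this placement is cosmetic and
configurable. Every statistic is computed on the residue matrix alone and
is therefore invariant under any reordering of the scale; the only
statistic that touches a scale at all is the consensus *tie-break* (see
below).

**Stacking.** Within each group and each (column, slot) cell
independently, the j-th group sequence (in MSA order) to visit the cell
takes stack offset `j mod stack_size` (default 10), staggered by one line
thickness and centred on the slot's centre line. Lines beyond the stack
size overlay earlier offsets exactly — `floor(n / stack_size)` complete
overlay layers — which is what makes conserved cells dark. The
alternative reading of "stacking in sets of 10" (a global row-index
modulus) was rejected because it would not produce uniform per-cell
stacks: the overlay arithmetic (886 lines → 88 full layers in one cell)
only works out per cell.

**Smoothing.** Between consecutive anchors the curve is the cubic Hermite
segment with zero end slopes, emitted as a cubic Bézier whose control
handles are horizontal and one third of the column spacing long. This
interpolant passes through every anchor, is monotone between anchors (no
vertical overshoot beyond the anchor extremes), and has horizontal
tangents at every site, so coincident sub-paths flatten and read as one
bundle. A single-column alignment degenerates to a horizontal tick one
column width wide.

**Compositing.** Per-line opacity α in normal (source-over) blending
gives darkness `d(n) = 1 − (1 − α)^n` for `n` coincident lines; `d` is
strictly increasing in both arguments and equals α at `n = 1`. The
default α = 0.02 matches the reference figures. When α is unset,
auto-balancing solves `d(L) = 0.95` for α, where `L` is the number of
full overlay layers a completely conserved column of the largest group
would produce — so sample size does not silently change how dark
"conserved" looks. Group *g* is shifted vertically by *g* × one line
thickness (configurable) after slot placement, keeping sub-bundles
distinguishable without occlusion; with default geometry the shift plus
the stack stagger always stays inside the slot band.

**Output.** SVG is the canonical backend: a small deterministic
serializer with fixed coordinate precision, one `<path>` per sequence
carrying explicit `stroke`, `stroke-width` and `opacity` attributes, so
identical inputs yield byte-identical files and the structure is
auditable by XML parsing. PDF and PNG replay the same element list
through matplotlib (render-then-rasterize for PNG, at a configurable
pixels-per-unit scale). Canvas units are points; canvas Y increases
downward with slot 0 at the top.

## Statistics

All counting is exact and gap-inclusive (the gap is a first-class symbol:
it has a Y-slot, participates in profiles, may win a consensus column,
and matches literally in motifs).

* **Profile / bridges.** `position_profile` counts symbols in one column
  of one group; `bridge_counts` counts joint symbol pairs at adjacent
  columns. Marginals of a bridge table equal the two adjacent profiles —
  an invariant asserted on every random input in the suite.
* **Consensus.** Per column, the most frequent symbol. Ties are broken by
  the lowest slot on the active scale when one is supplied (so the
  rendered consensus row matches the plot), otherwise alphabetically with
  the gap ordered last. The tie-break is the only scale-dependence in the
  package.
* **Selection.** `select_by_residue` returns the member ids, the modal
  full-row sequence among them (ties to the earliest in MSA order), the
  count of members identical to it, and the columns at which any member
  deviates. Percentages are left to the caller
  (`SelectionReport.fraction_of`) against whichever group size the caller
  considers the denominator, since "fraction of the dataset" is ambiguous
  when groups overlap conceptually.
* **Group summary.** Sizes, total, and each size per 100 of the largest
  group, rounded to the nearest integer; the legend prints the ratio
  largest-first (923 and 886 → `100:96`).

## Thread extraction

No canonical algorithm exists for turning the visual impression of
interweaving streamgraph threads into numbers, so the procedure here is
this package's own definition, anchored by an exhaustive-enumeration
oracle in the test suite:

1. Build a trellis over the column interval: nodes are the top-k residues
   per column (by count, ties alphabetical); edge weights are the bridge
   joint counts.
2. Repeatedly extract the path maximising its minimum edge weight; ties
   go to the higher total weight, then to the lexicographically smallest
   residue string. Subtract the path's bottleneck from its edges.
3. Stop when no path's bottleneck reaches `min_support × depth`
   (defaults: k = 2, min_support = 0.25).

The optimal path is found exactly in three passes: a max-bottleneck DP
fixes the optimal bottleneck B\*; restricting to edges ≥ B\*, an additive
DP fixes the optimal total T\*; a greedy forward walk against a suffix DP
yields the lexicographically smallest path attaining both. This provably
matches brute-force enumeration (asserted on 200+ random trellises),
which a single-pass heuristic DP with ad-hoc tie handling would not
guarantee. Reported per-step supports are the residual edge weights at
extraction time, i.e. each thread's support is net of the threads
extracted before it. A single-column interval degenerates to the top-k
residues above threshold.

A **bifurcation** is flagged when at least two threads are extracted and
every thread's bottleneck strictly exceeds the minimum per-step bridge
count of the consensus path (computed on the original, unsubtracted
table). In a conserved region the first thread *is* the consensus path,
the comparison is not strict, and no bifurcation is flagged.

## Synthetic data

The generator emulates the structure of a curated two-group bacterial
protein MSA (the demonstration dataset of the original visual analysis is
not publicly deposited): per-column categorical background plus planted
features, all count-exact.

* **Background.** Each column gets its own categorical distribution drawn
  from a Dirichlet with parameter `1 / concentration` (gap down-weighted
  by `gap_weight = 0.15`); higher concentration means sharper, more
  conserved columns, and `concentration = ∞` degenerates to a fully
  conserved alignment. Default concentration 2.0 produces columns with a
  clear mode plus realistic clutter.
* **Conserved cluster** (`size`, marker position/residue,
  `divergence_edits`): `size` rows copy one template carrying the marker;
  `divergence_edits` of them receive `edits_per_row = 2` random
  substitutions at columns no other feature claims. Background rows are
  barred from the marker residue at the marker column, so the selection
  recovers exactly (`size`, `size − divergence_edits`).
* **XOR pair** (position *p*, residue, `n_both` or `frac_both`): the
  non-cluster rows carry the residue at exactly one of columns *p*,
  *p + 1*, split evenly, except exactly `n_both` rows carrying both — so
  both marginals are large while the joint count is exactly `n_both`.
* **Bifurcation** (interval, motif A, motif B, fractions): motifs must
  differ at every column; `round(frac × pool)` rows carry each motif and
  the remaining minority carries the alternating pattern
  `M[i] = B[i]` (even *i*) / `A[i]` (odd *i*). Since each column of `M`
  coincides with one motif, `M` wins every column's plurality: the
  column-wise consensus equals `M`, equals neither motif, and only the
  minority actually bridges consecutive consensus residues — exactly the
  planted bifurcation geometry.

Rows are allocated by slicing a seeded permutation (never Bernoulli
draws), so every manifest quantity is exact, and all randomness flows
through one `numpy.random.Generator`: one integer seed reproduces the
FASTA byte for byte. Feature columns within a group must be disjoint
(cluster rows are disjoint from the pool the other features share), which
the validator enforces along with size/fraction feasibility.

`contest_like(seed)` fixes the study conditions: 886 + 923 rows × 36
columns; a 48-member cluster with 46 identical copies (N at column 13,
second group); a 12-member cluster with 6 identical (F at column 35), an
XOR lysine pair at columns 17–18 with exactly 23 double carriers, and a
KVEGI/AKADV bifurcation at columns 19–23 (40% + 40% + 174-row minority),
all in the first group. The two overlapping-in-reality features (XOR pair
and bifurcation) are planted on disjoint columns so both ground truths
stay exact.

**What passing tests do and do not show.** The planted fixtures have
noise-free feature columns and independently drawn background columns; no
phylogeny, no substitution model, no alignment error. Exact recovery
therefore validates the *bookkeeping* (counting, extraction, rendering
contracts), not robustness to evolutionary correlation or mis-curated
alignments — on real data, thread support levels and selection identity
counts will be noisier than any planted truth.

## Numerical and design choices

* Positions are 1-based at every user-facing surface, 0-based internally.
* Input residues are upper-cased before validation; the plain-text
  dialect is one row per line, blank lines ignored, optional `id<TAB>`
  prefix, ids defaulting to `seq_<k>`.
* Determinism everywhere: layout and SVG bytes are pure functions of
  (alignment, scale, render spec); all tie-breaks (consensus, trellis
  nodes, path extraction, modal sequence) are specified rather than
  incidental.
* Default geometry: line thickness 1.2 pt, slot height 12 thicknesses
  (a 10-line stack plus one line of padding on each side), column width
  24 pt, stacks centred on the slot centre (a downward stagger would be
  equally valid; centring is cosmetic).
* Problem sizes in the test suite: oracle equivalence runs on 200 random
  alignments of ≤ 20 rows × ≤ 8 columns with trellises of ≤ 6 columns and
  k ≤ 3, where exhaustive path enumeration is exact and fast; recovery
  runs at full contest scale (1809 × 36).

## Known limitations

* No alignment, curation or data selection: input MSAs are taken as
  given (ragged or invalid input is rejected, never repaired).
* No line-crossing minimisation; heavily variable regions can look
  entangled.
* The streamgraph is a static band/ribbon view; it does not attempt exact
  flow-conserving ribbon packing within a band.
* Statistical significance of motifs and information-content displays are
  deliberately out of scope.
* PDF/PNG text metrics come from matplotlib and may differ slightly from
  an SVG viewer's font rendering; geometry is identical.
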
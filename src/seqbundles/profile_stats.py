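"""Alignment statistics underlying the Sequence Bundles encoding and its
motif-discovery workflow.

Everything here is exact counting over a :class:`~seqbundles.msa_io.GroupedAlignment`
and is independent of any Y-axis scale or rendering parameter:

* per-column symbol profiles and the column-wise consensus;
* group size summaries (sizes, total, and the per-100 ratio shown in the
  plot legend);
* residue selections — all group members showing one residue at one
  position, with how many of them are identical copies (the signature of
  extreme sub-cluster conservation);
* exact motif occurrence counts over a column window;
* "bridges": joint counts of residue pairs in adjacent columns, which is
  what the bundle's connecting line segments encode (a pair can be common
  at both columns yet rarely co-occur on the same sequence);
* thread extraction over a column interval — repeatedly pulling the
  maximum-bottleneck path out of the top-k residue trellis, which is how a
  consensus bifurcation (two high-support threads that diverge and
  reconverge, neither matching the column-wise consensus) is detected.

All positions are 1-based, matching how alignment columns are cited.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .msa_io import GAP, AlignmentError, GroupedAlignment
from .scales import YAxisScale


@dataclass(frozen=True)
class PositionProfile:
    """Symbol counts at one alignment column within one group."""

    position: int  # 1-based column
    counts: Mapping[str, int]
    depth: int

    def count(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def frequency(self, symbol: str) -> float:
        return self.count(symbol) / self.depth


@dataclass(frozen=True)
class TransitionTable:
    """Joint counts of symbol pairs at adjacent columns (p, p+1).

    ``joint[(a, b)]`` is the number of group sequences carrying *a* at
    column ``position`` and *b* at ``position + 1`` — the thickness of the
    a->b bridge in the plot.
    """

    position: int  # 1-based left column of the pair
    joint: Mapping[tuple[str, str], int]
    depth: int

    def count(self, a: str, b: str) -> int:
        return self.joint.get((a, b), 0)

    def marginal_left(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (a, _), c in self.joint.items():
            out[a] = out.get(a, 0) + c
        return out

    def marginal_right(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_, b), c in self.joint.items():
            out[b] = out.get(b, 0) + c
        return out


@dataclass(frozen=True)
class SelectionReport:
    """All group members carrying one residue at one position.

    ``modal_sequence`` is the most frequent full row among the members
    (ties resolved to the earliest in MSA order); ``identical_count`` is
    how many members equal it exactly, and ``variable_positions`` lists the
    1-based columns where any member deviates from it.
    """

    group: Optional[str]
    position: int
    residue: str
    member_ids: tuple[str, ...]
    modal_sequence: str
    identical_count: int
    variable_positions: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def fraction_of(self, group_size: int) -> float:
        """Selection size as a fraction of a stated group size."""
        return self.size / group_size if group_size else 0.0


@dataclass(frozen=True)
class Thread:
    """One extracted residue path over an interval, with per-step support."""

    residues: str
    support: tuple[int, ...]

    @property
    def bottleneck(self) -> int:
        return min(self.support)


@dataclass(frozen=True)
class ThreadSet:
    """Threads extracted over a column interval plus the consensus path."""

    interval: tuple[int, int]
    threads: tuple[Thread, ...]
    consensus: str
    consensus_support: tuple[int, ...]
    depth: int
    bifurcation: bool


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sizes plus the legend arithmetic (total and 100:x ratio)."""

    labels: tuple[str, ...]
    sizes: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.sizes)

    @property
    def per_100_of_largest(self) -> tuple[int, ...]:
        """Each group size per 100 of the largest group, nearest integer."""
        largest = max(self.sizes)
        return tuple(round(100 * s / largest) for s in self.sizes)

    @property
    def ratio_string(self) -> str:
        """The legend ratio, largest group first, e.g. ``100:96``."""
        return ":".join(
            str(v)
            for v in sorted(self.per_100_of_largest, reverse=True)
        )


def _rows(ga: GroupedAlignment, group: Optional[str]) -> list[str]:
    return [ga.alignment.rows[i] for i in ga.group_rows(group)]


def _check_column(ga: GroupedAlignment, p: int) -> None:
    n = ga.alignment.n_cols
    if not 1 <= p <= n:
        raise AlignmentError(f"column {p} outside 1..{n}")


def position_profile(
    ga: GroupedAlignment, group: Optional[str], p: int
) -> PositionProfile:
    """Exact symbol counts of one group at 1-based column *p*.

    *group* is a group label, or None for the whole alignment.
    """
    _check_column(ga, p)
    rows = _rows(ga, group)
    counts = Counter(row[p - 1] for row in rows)
    return PositionProfile(p, dict(counts), len(rows))


def _winner(counts: Counter, scale: Optional[YAxisScale]) -> str:
    """Most frequent symbol; ties go to the lowest slot on the active
    scale, then alphabetically (gap last when no scale is active)."""
    if scale is not None:
        key = lambda s: (-counts[s], scale.slot_of(s), s)
    else:
        key = lambda s: (-counts[s], s == GAP, s)
    return min(counts, key=key)


def consensus(
    ga: GroupedAlignment,
    group: Optional[str] = None,
    scale: Optional[YAxisScale] = None,
) -> str:
    """Column-wise consensus: the most frequent symbol per column.

    The gap character participates and may win a column.  Ties are broken
    deterministically: by lowest slot on *scale* when one is given (so the
    rendered consensus row matches the plot), otherwise alphabetically with
    the gap ordered last.
    """
    rows = _rows(ga, group)
    if not rows:
        raise AlignmentError(f"group {group!r} is empty")
    out = []
    for c in range(ga.alignment.n_cols):
        counts = Counter(row[c] for row in rows)
        out.append(_winner(counts, scale))
    return "".join(out)


def summarize_groups(ga: GroupedAlignment) -> GroupSummary:
    """Sizes per group, their total, and the per-100-of-largest ratio.

    For groups of 923 and 886 sequences this yields total 1809 and the
    ratio ``100:96`` displayed in the legend.
    """
    return GroupSummary(
        labels=ga.labels,
        sizes=tuple(g.size for g in ga.groups),
    )


def select_by_residue(
    ga: GroupedAlignment, group: Optional[str], p: int, residue: str
) -> SelectionReport:
    """Select every group member with *residue* at column *p*.

    An empty selection is a valid report of size 0.  This is the operation
    behind highlighting, and its report quantifies sub-cluster
    conservation: a large selection with a high ``identical_count`` marks a
    block of near-identical sequences sharing the marker residue.
    """
    _check_column(ga, p)
    indices = [
        i for i in ga.group_rows(group)
        if ga.alignment.rows[i][p - 1] == residue
    ]
    ids = tuple(ga.alignment.ids[i] for i in indices)
    if not indices:
        return SelectionReport(group, p, residue, (), "", 0, ())
    rows = [ga.alignment.rows[i] for i in indices]
    freq = Counter(rows)
    best = max(freq.values())
    modal = next(r for r in rows if freq[r] == best)  # earliest in MSA order
    identical = freq[modal]
    variable = tuple(
        c + 1
        for c in range(ga.alignment.n_cols)
        if any(r[c] != modal[c] for r in rows)
    )
    return SelectionReport(group, p, residue, ids, modal, identical, variable)


def motif_match_count(
    ga: GroupedAlignment, group: Optional[str], start: int, motif: str
) -> int:
    """Number of group rows whose columns ``[start, start+len(motif)-1]``
    equal *motif* exactly.

    Gaps mismatch unless the motif itself contains ``-``.  Counting exact
    window matches is how one checks whether the column-wise consensus is
    actually carried by whole sequences — e.g. a PPKK consensus window that
    only a handful of sequences display in full.
    """
    valid = ga.alignment.alphabet | {GAP}
    bad = [s for s in motif if s not in valid]
    if bad:
        raise AlignmentError(f"motif symbol {bad[0]!r} outside alphabet")
    if not motif:
        raise AlignmentError("empty motif")
    _check_column(ga, start)
    end = start + len(motif) - 1
    _check_column(ga, end)
    return sum(
        1 for row in _rows(ga, group) if row[start - 1 : end] == motif
    )


def bridge_counts(
    ga: GroupedAlignment, group: Optional[str], p: int
) -> TransitionTable:
    """Joint symbol counts between columns *p* and *p+1*.

    Marginals reconcile exactly with the two adjacent position profiles.
    A pair of residues can each be near-fixed in its own column while the
    (a, a) bridge stays thin — most sequences carrying one but not both.
    """
    _check_column(ga, p)
    _check_column(ga, p + 1)
    joint = Counter(
        (row[p - 1], row[p]) for row in _rows(ga, group)
    )
    return TransitionTable(p, dict(joint), sum(joint.values()))


# --------------------------------------------------------------------------
# Thread extraction
# --------------------------------------------------------------------------

def _top_k_nodes(counts: Counter, k: int) -> list[str]:
    """Top-k symbols by count, ties broken alphabetically."""
    ranked = sorted(counts, key=lambda s: (-counts[s], s))
    return ranked[:k]


def _best_path(
    nodes: Sequence[Sequence[str]],
    weight: Sequence[Mapping[tuple[str, str], int]],
) -> tuple[tuple[str, ...], int, int]:
    """Optimal path through the trellis under the extraction order:
    maximum bottleneck (min edge weight), then maximum total weight, then
    lexicographically smallest residue string.

    Solved exactly in three passes: a max-bottleneck DP fixes the optimal
    bottleneck B*; restricting to edges of weight >= B*, an additive DP
    fixes the optimal total T*; a greedy forward walk against a suffix DP
    then yields the lexicographically smallest path attaining (B*, T*).
    Returns (path, bottleneck, total).
    """
    n = len(nodes)
    w = [dict(layer) for layer in weight]

    def edge(c: int, a: str, b: str) -> int:
        return w[c].get((a, b), 0)

    # pass 1: optimal bottleneck
    val = {a: math.inf for a in nodes[0]}
    for c in range(n - 1):
        nxt = {}
        for b in nodes[c + 1]:
            nxt[b] = max(
                (min(val[a], edge(c, a, b)) for a in nodes[c]),
                default=-math.inf,
            )
        val = nxt
    b_star = max(val.values())

    # pass 2: max total weight using only edges >= B*
    tot = {a: 0 for a in nodes[0]}
    for c in range(n - 1):
        nxt = {}
        for b in nodes[c + 1]:
            cands = [
                tot[a] + edge(c, a, b)
                for a in nodes[c]
                if edge(c, a, b) >= b_star
            ]
            nxt[b] = max(cands, default=-math.inf)
        tot = nxt
    t_star = max(tot.values())

    # pass 3: suffix DP, then greedy lexicographic walk
    suffix: list[dict[str, float]] = [dict() for _ in range(n)]
    for b in nodes[n - 1]:
        suffix[n - 1][b] = 0
    for c in range(n - 2, -1, -1):
        for a in nodes[c]:
            cands = [
                edge(c, a, b) + suffix[c + 1][b]
                for b in nodes[c + 1]
                if edge(c, a, b) >= b_star
            ]
            suffix[c][a] = max(cands, default=-math.inf)
    path = [
        min(a for a in nodes[0] if suffix[0][a] == t_star)
    ]
    acc = 0
    for c in range(n - 1):
        a = path[-1]
        b = min(
            b
            for b in nodes[c + 1]
            if edge(c, a, b) >= b_star
            and acc + edge(c, a, b) + suffix[c + 1][b] == t_star
        )
        acc += edge(c, a, b)
        path.append(b)
    bottleneck = min(edge(c, path[c], path[c + 1]) for c in range(n - 1))
    return tuple(path), bottleneck, acc


def detect_threads(
    ga: GroupedAlignment,
    group: Optional[str],
    interval: tuple[int, int],
    k: int = 2,
    min_support: float = 0.25,
    scale: Optional[YAxisScale] = None,
) -> ThreadSet:
    """Extract high-support residue threads over 1-based columns
    ``interval = (start, end)`` and test for a consensus bifurcation.

    A trellis is built whose nodes are the top-*k* residues per column (by
    count) and whose edge weights are the adjacent-column bridge counts.
    Threads are extracted greedily: the path maximising its minimum edge
    weight is pulled out (ties to higher total weight, then lexicographic
    residue order), its bottleneck count is subtracted from its edges, and
    extraction stops once no path's bottleneck reaches
    ``min_support * depth``.

    The consensus path's per-step bridge counts (on the original,
    unsubtracted table) are reported alongside.  A bifurcation is flagged
    when at least two threads were extracted and every thread's bottleneck
    exceeds the consensus path's minimum bridge count — the situation where
    the column-wise consensus is a chimera no strong thread actually
    follows.
    """
    start, end = interval
    _check_column(ga, start)
    _check_column(ga, end)
    if end < start:
        raise AlignmentError(f"empty interval {interval}")
    if k < 1:
        raise AlignmentError("k must be >= 1")
    if not 0 < min_support <= 1:
        raise AlignmentError("min_support must be in (0, 1]")

    rows = _rows(ga, group)
    depth = len(rows)
    if depth == 0:
        raise AlignmentError(f"group {group!r} is empty")
    threshold = min_support * depth
    windows = [row[start - 1 : end] for row in rows]
    n = end - start + 1

    col_counts = [Counter(wd[c] for wd in windows) for c in range(n)]
    cons = "".join(_winner(c, scale) for c in col_counts)

    if n == 1:
        picked = [
            s for s in _top_k_nodes(col_counts[0], k)
            if col_counts[0][s] >= threshold
        ]
        threads = tuple(Thread(s, (col_counts[0][s],)) for s in picked)
        return ThreadSet(
            interval, threads, cons, (col_counts[0][cons],), depth, False
        )

    nodes = [_top_k_nodes(col_counts[c], k) for c in range(n)]
    original = [
        Counter((wd[c], wd[c + 1]) for wd in windows) for c in range(n - 1)
    ]
    residual = [dict(layer) for layer in original]

    threads: list[Thread] = []
    while True:
        path, bottleneck, _total = _best_path(nodes, residual)
        if bottleneck < threshold or bottleneck <= 0:
            break
        support = tuple(
            residual[c][(path[c], path[c + 1])] for c in range(n - 1)
        )
        threads.append(Thread("".join(path), support))
        for c in range(n - 1):
            residual[c][(path[c], path[c + 1])] -= bottleneck
        if len(threads) > k ** 2 + len(nodes[0]) * n:  # safety bound
            break

    cons_support = tuple(
        original[c].get((cons[c], cons[c + 1]), 0) for c in range(n - 1)
    )
    bifurcation = (
        len(threads) >= 2
        and all(t.bottleneck > min(cons_support) for t in threads)
    )
    return ThreadSet(
        interval, tuple(threads), cons, cons_support, depth, bifurcation
    )
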
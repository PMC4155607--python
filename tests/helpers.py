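"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes quantities by direct rescans or exhaustive
enumeration, sharing no code path with the package internals it checks.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from seqbundles import Alignment, GroupedAlignment, assign_groups

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def random_grouped_alignment(
    rng: np.random.Generator,
    max_rows: int = 20,
    max_cols: int = 8,
    n_symbols: int = 6,
    gap_prob: float = 0.1,
) -> GroupedAlignment:
    """A random small alignment over a reduced alphabet, split into one
    or two groups at a random boundary."""
    n_rows = int(rng.integers(2, max_rows + 1))
    n_cols = int(rng.integers(2, max_cols + 1))
    symbols = list(ALPHABET[:n_symbols])
    rows = []
    for _ in range(n_rows):
        row = [
            "-" if rng.random() < gap_prob
            else symbols[int(rng.integers(len(symbols)))]
            for _ in range(n_cols)
        ]
        rows.append("".join(row))
    ids = tuple(f"s{i}" for i in range(n_rows))
    aln = Alignment(ids, tuple(rows))
    if n_rows >= 4 and rng.random() < 0.5:
        cut = int(rng.integers(1, n_rows))
        spec = [
            ("g1", "#000000", list(range(cut))),
            ("g2", "#33A6E6", list(range(cut, n_rows))),
        ]
    else:
        spec = [("g1", "#000000", list(range(n_rows)))]
    return assign_groups(aln, spec)


def rescan_profile(ga: GroupedAlignment, group, p: int) -> dict[str, int]:
    rows = [ga.alignment.rows[i] for i in ga.group_rows(group)]
    return dict(Counter(r[p - 1] for r in rows))


def rescan_joint(ga: GroupedAlignment, group, p: int) -> dict:
    rows = [ga.alignment.rows[i] for i in ga.group_rows(group)]
    return dict(Counter((r[p - 1], r[p]) for r in rows))


def rescan_motif(ga: GroupedAlignment, group, start: int, motif: str) -> int:
    rows = [ga.alignment.rows[i] for i in ga.group_rows(group)]
    return sum(
        1 for r in rows
        if all(r[start - 1 + i] == m for i, m in enumerate(motif))
    )


def enumerate_threads(
    ga: GroupedAlignment, group, interval, k: int, min_support: float
):
    """Thread extraction by exhaustive path enumeration: the same greedy
    subtract-the-bottleneck loop, but with the optimal path at each round
    found by scoring every node combination in the trellis."""
    start, end = interval
    rows = [ga.alignment.rows[i] for i in ga.group_rows(group)]
    depth = len(rows)
    windows = [r[start - 1 : end] for r in rows]
    n = end - start + 1
    col_counts = [Counter(w[c] for w in windows) for c in range(n)]
    nodes = [
        sorted(col_counts[c], key=lambda s: (-col_counts[c][s], s))[:k]
        for c in range(n)
    ]
    residual = [
        Counter((w[c], w[c + 1]) for w in windows) for c in range(n - 1)
    ]
    threshold = min_support * depth
    out = []
    while True:
        best = None
        for combo in itertools.product(*nodes):
            weights = [
                residual[c].get((combo[c], combo[c + 1]), 0)
                for c in range(n - 1)
            ]
            score = (min(weights), sum(weights), tuple(-ord(s) for s in combo))
            if best is None or score > best[0]:
                best = (score, combo, weights)
        (bottleneck, _total, _), combo, weights = best
        if bottleneck < threshold or bottleneck <= 0:
            break
        out.append(("".join(combo), tuple(weights)))
        for c in range(n - 1):
            residual[c][(combo[c], combo[c + 1])] -= bottleneck
    return out
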
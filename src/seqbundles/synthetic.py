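"""Seeded synthetic alignments with planted, exactly-recoverable structure.

The original two-group alignment of 1809 adenylate-kinase-lid sequences
used to demonstrate the encoding was never deposited with an accession,
so this module generates grouped
alignments that emulate its statistical structure: per-column categorical
background noise plus planted features of the three classes the
motif-discovery operations are designed to expose —

* a **conserved cluster**: m near-identical copies of one template row all
  carrying a marker residue at a marker column, a given number of them
  perturbed by single-residue edits (so a residue selection at the marker
  recovers m members, m - edits of them identical);
* an **XOR pair**: at two adjacent columns, most designated rows carry a
  residue at exactly one of the two columns and only a fixed count carry
  it at both, producing strong single-column counts but a thin
  (residue, residue) bridge;
* a **bifurcation**: two motifs carried by large row fractions over an
  interval, plus an alternating minority pattern that makes the
  column-wise consensus a chimera matching neither motif, so the consensus
  path's minimum bridge count sits strictly below each thread's
  bottleneck.

Planting is count-exact (rows are assigned deterministically after a
seeded shuffle, never by Bernoulli sampling), so every planted quantity in
the returned manifest is recovered exactly by the corresponding
profile-statistics operation.  All randomness flows through one
``numpy.random.Generator`` seeded from the integer seed, so the same seed
reproduces the alignment byte for byte on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

import numpy as np

from .msa_io import (
    GAP,
    Alignment,
    AlignmentError,
    Group,
    GroupedAlignment,
    PROTEIN_ALPHABET,
)


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


@dataclass(frozen=True)
class ConservedCluster:
    """m template copies marked by one residue at one column, with
    ``divergence_edits`` of them perturbed away from the template."""

    marker_pos: int        # 1-based column
    marker_residue: str
    size: int
    divergence_edits: int = 0
    edits_per_row: int = 2

    def columns(self) -> set[int]:
        # a cluster claims the full row; only the marker column needs
        # protecting from other features
        return {self.marker_pos}


@dataclass(frozen=True)
class XorPair:
    """Residue at columns (p, p+1): designated rows carry it at exactly
    one of the two columns, except ``n_both`` (or ``frac_both``) rows."""

    position: int          # 1-based left column of the pair
    residue: str
    frac_both: float = 0.05
    n_both: Optional[int] = None

    def columns(self) -> set[int]:
        return {self.position, self.position + 1}


@dataclass(frozen=True)
class Bifurcation:
    """Two motifs over an interval carried by fractions of the rows, plus
    an alternating minority pattern that owns the column-wise consensus."""

    interval: tuple[int, int]   # 1-based inclusive
    motif_a: str
    motif_b: str
    frac_a: float = 0.4
    frac_b: float = 0.4

    def columns(self) -> set[int]:
        return set(range(self.interval[0], self.interval[1] + 1))

    @property
    def mixed_pattern(self) -> str:
        """Alternating pattern carried by the remaining rows; by
        construction it wins every column's plurality, so the consensus
        equals it while only the minority actually bridges its steps."""
        return "".join(
            self.motif_b[i] if i % 2 == 0 else self.motif_a[i]
            for i in range(len(self.motif_a))
        )


Feature = Union[ConservedCluster, XorPair, Bifurcation]


@dataclass(frozen=True)
class GroupFixture:
    label: str
    color: str
    n_rows: int
    features: tuple[Feature, ...] = ()


@dataclass(frozen=True)
class FixtureSpec:
    """Full recipe for one synthetic grouped alignment."""

    groups: tuple[GroupFixture, ...]
    n_cols: int
    seed: int
    alphabet: frozenset[str] = PROTEIN_ALPHABET
    concentration: float = 2.0   # per-column sharpness; inf => conserved
    gap_weight: float = 0.15     # relative Dirichlet weight of the gap


def _validate(spec: FixtureSpec) -> None:
    if spec.n_cols < 1:
        raise FixtureError("n_cols must be >= 1")
    if not spec.groups:
        raise FixtureError("at least one group required")
    for gf in spec.groups:
        if gf.n_rows < 1:
            raise FixtureError(f"group {gf.label!r}: n_rows must be >= 1")
        clusters = [f for f in gf.features if isinstance(f, ConservedCluster)]
        others = [f for f in gf.features if not isinstance(f, ConservedCluster)]
        if sum(c.size for c in clusters) > gf.n_rows:
            raise FixtureError(
                f"group {gf.label!r}: cluster sizes exceed n_rows"
            )
        pool = gf.n_rows - sum(c.size for c in clusters)
        claimed: set[int] = set()
        for f in gf.features:
            cols = f.columns()
            if min(cols) < 1 or max(cols) > spec.n_cols:
                raise FixtureError(
                    f"group {gf.label!r}: feature columns {sorted(cols)} "
                    f"outside 1..{spec.n_cols}"
                )
            if cols & claimed:
                raise FixtureError(
                    f"group {gf.label!r}: feature columns overlap at "
                    f"{sorted(cols & claimed)}"
                )
            claimed |= cols
        for c in clusters:
            if c.divergence_edits > c.size:
                raise FixtureError("divergence_edits exceeds cluster size")
            if c.marker_residue not in spec.alphabet:
                raise FixtureError(
                    f"marker residue {c.marker_residue!r} outside alphabet"
                )
        for f in others:
            if isinstance(f, XorPair):
                if f.residue not in spec.alphabet:
                    raise FixtureError(
                        f"xor residue {f.residue!r} outside alphabet"
                    )
                n_both = f.n_both if f.n_both is not None else round(
                    f.frac_both * pool
                )
                if not 0 <= n_both <= pool:
                    raise FixtureError(
                        f"group {gf.label!r}: n_both={n_both} infeasible "
                        f"for pool of {pool}"
                    )
            elif isinstance(f, Bifurcation):
                lo, hi = f.interval
                length = hi - lo + 1
                if len(f.motif_a) != length or len(f.motif_b) != length:
                    raise FixtureError("motif length != interval length")
                if any(a == b for a, b in zip(f.motif_a, f.motif_b)):
                    raise FixtureError(
                        "motifs must differ at every interval column"
                    )
                bad = [s for s in f.motif_a + f.motif_b
                       if s not in spec.alphabet]
                if bad:
                    raise FixtureError(
                        f"motif symbol {bad[0]!r} outside alphabet"
                    )
                if f.frac_a + f.frac_b > 1:
                    raise FixtureError("frac_a + frac_b exceeds 1")
                n_a = round(f.frac_a * pool)
                n_b = round(f.frac_b * pool)
                if pool - n_a - n_b < 1:
                    raise FixtureError(
                        "no rows left for the consensus-owning mixed "
                        "pattern; lower frac_a/frac_b"
                    )


def _column_distributions(
    spec: FixtureSpec, rng: np.random.Generator, symbols: list[str]
) -> np.ndarray:
    """Per-column categorical probabilities, Dirichlet-drawn with
    sharpness ``concentration`` (higher = more conserved columns)."""
    k = len(symbols)
    if math.isinf(spec.concentration):
        probs = np.zeros((spec.n_cols, k))
        picks = rng.integers(0, k - 1, size=spec.n_cols)  # never the gap
        probs[np.arange(spec.n_cols), picks] = 1.0
        return probs
    alpha = np.full(k, 1.0 / spec.concentration)
    alpha[-1] *= spec.gap_weight  # gap symbol is last
    return rng.dirichlet(alpha, size=spec.n_cols)


def _draw(
    rng: np.random.Generator,
    probs: np.ndarray,
    symbols: list[str],
    forbid: frozenset[str] = frozenset(),
) -> str:
    """One symbol from a column distribution, renormalised to exclude
    *forbid* (used to keep background clear of planted markers)."""
    p = probs.copy()
    for i, s in enumerate(symbols):
        if s in forbid:
            p[i] = 0.0
    total = p.sum()
    if total <= 0:
        p = np.array([0.0 if s in forbid else 1.0 for s in symbols])
        total = p.sum()
    return symbols[int(rng.choice(len(symbols), p=p / total))]


def generate(spec: FixtureSpec) -> tuple[GroupedAlignment, dict[str, Any]]:
    """Generate the grouped alignment plus a ground-truth manifest.

    The manifest records every planted quantity (cluster member ids and
    identical counts, XOR joint counts, bifurcation motif counts and the
    expected consensus over the interval) so recovery tests can compare
    exactly.
    """
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    symbols = sorted(spec.alphabet) + [GAP]
    manifest: dict[str, Any] = {
        "seed": spec.seed,
        "n_cols": spec.n_cols,
        "groups": {},
    }

    all_ids: list[str] = []
    all_rows: list[str] = []
    groups: list[Group] = []
    base = 0
    for gf in spec.groups:
        probs = _column_distributions(spec, rng, symbols)
        clusters = [f for f in gf.features if isinstance(f, ConservedCluster)]
        others = [f for f in gf.features if not isinstance(f, ConservedCluster)]
        # protect every marker column from accidental marker residues
        forbid_at: dict[int, set[str]] = {}
        for c in clusters:
            forbid_at.setdefault(c.marker_pos, set()).add(c.marker_residue)
        feature_cols: set[int] = set()
        for f in gf.features:
            feature_cols |= f.columns()

        def background_symbol(col: int, extra_forbid: frozenset[str] = frozenset()) -> str:
            forbid = frozenset(forbid_at.get(col, set())) | extra_forbid
            return _draw(rng, probs[col - 1], symbols, forbid)

        # deterministic row allocation after a seeded shuffle
        perm = list(rng.permutation(gf.n_rows))
        cursor = 0
        rows: list[Optional[list[str]]] = [None] * gf.n_rows
        ids = [f"{gf.label}_{i + 1}" for i in range(gf.n_rows)]
        group_manifest: dict[str, Any] = {
            "size": gf.n_rows, "features": []
        }

        for c in clusters:
            members = sorted(perm[cursor : cursor + c.size])
            cursor += c.size
            template = []
            for col in range(1, spec.n_cols + 1):
                if col == c.marker_pos:
                    template.append(c.marker_residue)
                    continue
                # avoid colliding with symbols other features plant
                avoid: set[str] = set()
                for f in others:
                    if col in f.columns():
                        if isinstance(f, XorPair):
                            avoid.add(f.residue)
                        else:
                            i = col - f.interval[0]
                            avoid |= {f.motif_a[i], f.motif_b[i],
                                      f.mixed_pattern[i]}
                avoid.add(GAP)
                template.append(background_symbol(col, frozenset(avoid)))
            template_row = "".join(template)
            free_cols = [
                col for col in range(1, spec.n_cols + 1)
                if col not in feature_cols
            ]
            divergent = members[: c.divergence_edits]
            edited_rows: dict[int, str] = {}
            for ri in divergent:
                row = list(template_row)
                n_edits = min(c.edits_per_row, len(free_cols))
                cols = rng.choice(len(free_cols), size=n_edits, replace=False)
                for ci in sorted(int(x) for x in cols):
                    col = free_cols[ci]
                    old = row[col - 1]
                    row[col - 1] = background_symbol(
                        col, frozenset({old, GAP})
                    )
                edited_rows[ri] = "".join(row)
            for ri in members:
                rows[ri] = list(edited_rows.get(ri, template_row))
            group_manifest["features"].append({
                "type": "conserved_cluster",
                "marker_pos": c.marker_pos,
                "marker_residue": c.marker_residue,
                "size": c.size,
                "identical": c.size - c.divergence_edits,
                "template": template_row,
                "member_ids": [ids[ri] for ri in members],
            })

        pool = sorted(perm[cursor:])
        for ri in pool:
            rows[ri] = [
                background_symbol(col) for col in range(1, spec.n_cols + 1)
            ]

        for f in others:
            if isinstance(f, XorPair):
                n_both = (
                    f.n_both if f.n_both is not None
                    else round(f.frac_both * len(pool))
                )
                rest = len(pool) - n_both
                n_left = rest // 2 + rest % 2
                n_right = rest // 2
                p = f.position
                order = [pool[int(i)] for i in rng.permutation(len(pool))]
                for ri in order[:n_both]:
                    rows[ri][p - 1] = f.residue
                    rows[ri][p] = f.residue
                for ri in order[n_both : n_both + n_left]:
                    rows[ri][p - 1] = f.residue
                    rows[ri][p] = background_symbol(
                        p + 1, frozenset({f.residue, GAP})
                    )
                for ri in order[n_both + n_left :]:
                    rows[ri][p - 1] = background_symbol(
                        p, frozenset({f.residue, GAP})
                    )
                    rows[ri][p] = f.residue
                group_manifest["features"].append({
                    "type": "xor_pair",
                    "position": p,
                    "residue": f.residue,
                    "n_both": n_both,
                    "n_left_only": n_left,
                    "n_right_only": n_right,
                    "pool_size": len(pool),
                })
            elif isinstance(f, Bifurcation):
                lo, hi = f.interval
                n_a = round(f.frac_a * len(pool))
                n_b = round(f.frac_b * len(pool))
                order = [pool[int(i)] for i in rng.permutation(len(pool))]
                carriers = {
                    "a": order[:n_a],
                    "b": order[n_a : n_a + n_b],
                    "mixed": order[n_a + n_b :],
                }
                patterns = {
                    "a": f.motif_a, "b": f.motif_b, "mixed": f.mixed_pattern
                }
                for key, members in carriers.items():
                    pat = patterns[key]
                    for ri in members:
                        for i, col in enumerate(range(lo, hi + 1)):
                            rows[ri][col - 1] = pat[i]
                group_manifest["features"].append({
                    "type": "bifurcation",
                    "interval": [lo, hi],
                    "motif_a": f.motif_a,
                    "motif_b": f.motif_b,
                    "n_a": n_a,
                    "n_b": n_b,
                    "n_mixed": len(pool) - n_a - n_b,
                    "mixed_pattern": f.mixed_pattern,
                    "expected_consensus": f.mixed_pattern,
                })

        manifest["groups"][gf.label] = group_manifest
        all_ids.extend(ids)
        all_rows.extend("".join(r) for r in rows)  # type: ignore[arg-type]
        groups.append(
            Group(gf.label, gf.color,
                  tuple(range(base, base + gf.n_rows)))
        )
        base += gf.n_rows

    alignment = Alignment(
        tuple(all_ids), tuple(all_rows), spec.alphabet
    )
    return GroupedAlignment(alignment, tuple(groups)), manifest


_FEATURE_TYPES = {
    "conserved_cluster": ConservedCluster,
    "xor_pair": XorPair,
    "bifurcation": Bifurcation,
}


def spec_from_dict(raw: dict[str, Any]) -> FixtureSpec:
    """Build a :class:`FixtureSpec` from a plain mapping (YAML/JSON)."""
    try:
        groups = []
        for g in raw["groups"]:
            features = []
            for f in g.get("features", []):
                kind = f["type"]
                if kind not in _FEATURE_TYPES:
                    raise FixtureError(f"unknown feature type {kind!r}")
                kwargs = {k: v for k, v in f.items() if k != "type"}
                if kind == "bifurcation" and "interval" in kwargs:
                    kwargs["interval"] = tuple(kwargs["interval"])
                features.append(_FEATURE_TYPES[kind](**kwargs))
            groups.append(
                GroupFixture(
                    g["label"], g.get("color", "#000000"),
                    g["n_rows"], tuple(features),
                )
            )
        kwargs: dict[str, Any] = {}
        if "alphabet" in raw:
            kwargs["alphabet"] = frozenset(raw["alphabet"])
        for key in ("concentration", "gap_weight"):
            if key in raw:
                kwargs[key] = float(raw[key])
        return FixtureSpec(
            groups=tuple(groups),
            n_cols=int(raw["n_cols"]),
            seed=int(raw["seed"]),
            **kwargs,
        )
    except (KeyError, TypeError) as exc:
        raise FixtureError(f"malformed fixture spec: {exc}") from exc


def load_fixture_spec(path) -> FixtureSpec:
    """Load a fixture spec from a YAML file."""
    import yaml

    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def contest_like(seed: int = 0) -> tuple[GroupedAlignment, dict[str, Any]]:
    """A stand-in for the unavailable 1809-sequence demonstration dataset.

    Two groups — 886 "Gram-positive" rows (black) and 923 "Gram-negative"
    rows (blue) — over 36 columns, with one planted instance of each
    feature class: a 48-member cluster (46 identical) marked by N at
    column 13 in the Gram-negatives; a 12-member cluster (6 identical)
    marked by F at column 35, an XOR lysine pair at columns 17-18 with
    exactly 23 double carriers, and a two-motif bifurcation (KVEGI vs
    AKADV) over columns 19-23, all in the Gram-positives.
    """
    spec = FixtureSpec(
        groups=(
            GroupFixture(
                "Gram-positive", "#000000", 886,
                features=(
                    ConservedCluster(35, "F", 12, divergence_edits=6),
                    XorPair(17, "K", n_both=23),
                    Bifurcation((19, 23), "KVEGI", "AKADV", 0.4, 0.4),
                ),
            ),
            GroupFixture(
                "Gram-negative", "#33A6E6", 923,
                features=(
                    ConservedCluster(13, "N", 48, divergence_edits=2),
                ),
            ),
        ),
        n_cols=36,
        seed=seed,
    )
    return generate(spec)
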
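"""Reading, validating and writing aligned sequence sets and group assignments.

An :class:`Alignment` is a rectangular matrix of residue symbols (gap ``-``
allowed); a :class:`GroupedAlignment` partitions its rows into ordered,
labelled, coloured groups (e.g. Gram-positive vs Gram-negative).  Row order
is never changed by parsing: downstream stacking relies on sequences keeping
the order in which they reside in the MSA file.

Positions are 1-based in every user-facing argument; storage is 0-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: One-letter codes of the 20 standard amino acids.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Canonical DNA alphabet, supported because the encoding is universal over
#: any alphabet that can be laid out on the Y-axis.
DNA_ALPHABET = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised for any structural violation of an alignment or group spec."""


@dataclass(frozen=True)
class Alignment:
    """A validated rectangular multiple sequence alignment.

    Parameters
    ----------
    ids:
        Unique sequence identifiers, one per row, in MSA order.
    rows:
        Residue strings over ``alphabet`` plus the gap character; all rows
        have identical length.
    alphabet:
        The residue alphabet (gap excluded); defaults to the 20 standard
        amino-acid one-letter codes.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet: frozenset[str] = PROTEIN_ALPHABET

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        if len(self.ids) != len(self.rows):
            raise AlignmentError(
                f"{len(self.ids)} ids for {len(self.rows)} rows"
            )
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise AlignmentError(f"duplicate sequence id {dup!r}")
        n_cols = len(self.rows[0])
        valid = self.alphabet | {GAP}
        for rid, row in zip(self.ids, self.rows):
            if len(row) != n_cols:
                raise AlignmentError(
                    f"row {rid!r} has length {len(row)}, expected {n_cols}"
                )
            for pos, sym in enumerate(row, start=1):
                if sym not in valid:
                    raise AlignmentError(
                        f"row {rid!r} position {pos}: symbol {sym!r} not in "
                        f"alphabet"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, p: int) -> tuple[str, ...]:
        """Symbols of 1-based column *p*, top to bottom in MSA order."""
        if not 1 <= p <= self.n_cols:
            raise AlignmentError(f"column {p} outside 1..{self.n_cols}")
        return tuple(row[p - 1] for row in self.rows)


@dataclass(frozen=True)
class Group:
    label: str
    color: str
    row_indices: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.row_indices)


@dataclass(frozen=True)
class GroupedAlignment:
    """An alignment plus an ordered, exhaustive, disjoint row partition."""

    alignment: Alignment
    groups: tuple[Group, ...]

    def __post_init__(self) -> None:
        n = self.alignment.n_rows
        seen: dict[int, str] = {}
        for g in self.groups:
            if list(g.row_indices) != sorted(g.row_indices):
                raise AlignmentError(
                    f"group {g.label!r} does not preserve MSA row order"
                )
            for i in g.row_indices:
                if not 0 <= i < n:
                    raise AlignmentError(
                        f"group {g.label!r} references row index {i} "
                        f"outside 0..{n - 1}"
                    )
                if i in seen:
                    raise AlignmentError(
                        f"row {i} assigned to both {seen[i]!r} and "
                        f"{g.label!r}"
                    )
                seen[i] = g.label
        if len(seen) != n:
            missing = sorted(set(range(n)) - set(seen))
            raise AlignmentError(
                f"rows not covered by any group: {missing[:10]}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.groups)

    def group(self, label: str) -> Group:
        for g in self.groups:
            if g.label == label:
                return g
        raise AlignmentError(f"unknown group {label!r}")

    def group_rows(self, label: str | None) -> tuple[int, ...]:
        """Row indices of one group, or of all rows when *label* is None."""
        if label is None:
            return tuple(range(self.alignment.n_rows))
        return self.group(label).row_indices


def _validate_format(format: str) -> str:
    if format not in ("fasta", "txt"):
        raise AlignmentError(f"unknown alignment format {format!r}")
    return format


def read_alignment(
    path: Union[str, Path],
    format: str = "fasta",
    alphabet: Iterable[str] = PROTEIN_ALPHABET,
) -> Alignment:
    """Read an aligned FASTA or plain-text file into an :class:`Alignment`.

    The ``txt`` dialect is one aligned row per line, blank lines ignored,
    with an optional leading ``id<TAB>``; missing ids default to ``seq_<k>``
    (1-based).  Residues are upper-cased before validation.  Row order
    equals file order.
    """
    _validate_format(format)
    path = Path(path)
    if not path.exists():
        raise AlignmentError(f"no such file: {path}")
    ids: list[str] = []
    rows: list[str] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
    else:
        for k, line in enumerate(path.read_text().splitlines()):
            line = line.rstrip()
            if not line:
                continue
            if "\t" in line:
                rid, row = line.split("\t", 1)
            else:
                rid, row = f"seq_{len(ids) + 1}", line
            ids.append(rid)
            rows.append(row.upper())
    if not rows:
        raise AlignmentError(f"empty alignment file: {path}")
    return Alignment(tuple(ids), tuple(rows), frozenset(alphabet))


def write_alignment(
    alignment: Alignment, path: Union[str, Path], format: str = "fasta"
) -> None:
    """Write an alignment as aligned FASTA or id<TAB>row plain text.

    Round-trips: ``read_alignment(write_alignment(a)) == a`` for both
    formats.
    """
    _validate_format(format)
    path = Path(path)
    if format == "fasta":
        records = [
            SeqRecord(Seq(row), id=rid, description="")
            for rid, row in zip(alignment.ids, alignment.rows)
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        with open(path, "w") as fh:
            for rid, row in zip(alignment.ids, alignment.rows):
                fh.write(f"{rid}\t{row}\n")


GroupSpecItem = tuple[str, str, Union[Sequence[str], Sequence[int], range]]


def assign_groups(
    alignment: Alignment, spec: Sequence[GroupSpecItem]
) -> GroupedAlignment:
    """Partition alignment rows into labelled, coloured groups.

    Each spec item is ``(label, color, members)`` where members is a list
    of sequence ids, a list of 0-based row indices, or a range.  Every row
    must be assigned to exactly one group.
    """
    id_to_index = {rid: i for i, rid in enumerate(alignment.ids)}
    groups = []
    for label, color, members in spec:
        indices: list[int] = []
        for m in members:
            if isinstance(m, str):
                if m not in id_to_index:
                    raise AlignmentError(
                        f"group {label!r}: unknown sequence id {m!r}"
                    )
                indices.append(id_to_index[m])
            else:
                indices.append(int(m))
        indices.sort()
        groups.append(Group(label, color, tuple(indices)))
    return GroupedAlignment(alignment, tuple(groups))


def single_group(
    alignment: Alignment, label: str = "all", color: str = "#000000"
) -> GroupedAlignment:
    """Wrap an alignment as one group covering every row."""
    return assign_groups(alignment, [(label, color, range(alignment.n_rows))])


def load_group_config(path: Union[str, Path]) -> list[GroupSpecItem]:
    """Load a YAML/JSON group spec: a list of {label, color, members}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise AlignmentError("group config must be a list of group entries")
    spec: list[GroupSpecItem] = []
    for entry in raw:
        try:
            spec.append(
                (entry["label"], entry.get("color", "#000000"),
                 entry["members"])
            )
        except (TypeError, KeyError) as exc:
            raise AlignmentError(f"malformed group entry: {entry!r}") from exc
    return spec
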
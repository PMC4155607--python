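"""The Y-axis of a Sequence Bundles plot: residues ordered by a
physicochemical property, plus one dedicated slot for the alignment gap.

A :class:`YAxisScale` is an ordered bijection symbol -> vertical slot.
Reordering the scale changes only where lines are drawn; every alignment
statistic is scale-independent.  Two scales ship as editable YAML data
(a hydrophobicity ordering and one by residue molecular weight); users can
load their own with :func:`load_scale` or build one with
:func:`custom_scale`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

from .msa_io import GAP, PROTEIN_ALPHABET

BUILTIN_SCALES = ("hydrophobicity_wampler", "molecular_weight_lide")


class ScaleError(ValueError):
    """Raised for malformed or unknown Y-axis scales."""


@dataclass(frozen=True)
class YAxisScale:
    """An ordered arrangement of residue symbols on the vertical axis.

    ``order`` lists symbols from the top slot to the bottom slot and is a
    permutation of the alphabet plus the gap character.  ``values`` holds
    the underlying property values when the scale derives from one.
    """

    name: str
    order: tuple[str, ...]
    values: Mapping[str, float] | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ScaleError(f"scale {self.name!r} has duplicate slots")
        if self.order.count(GAP) != 1:
            raise ScaleError(
                f"scale {self.name!r} must contain exactly one gap slot"
            )
        object.__setattr__(
            self,
            "_slot",
            {sym: i for i, sym in enumerate(self.order)},
        )

    @property
    def gap_slot(self) -> int:
        return self.order.index(GAP)

    @property
    def n_slots(self) -> int:
        return len(self.order)

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(s for s in self.order if s != GAP)

    def slot_of(self, symbol: str) -> int:
        """Vertical slot index of *symbol* (0 = top)."""
        try:
            return self._slot[symbol]  # type: ignore[attr-defined]
        except KeyError:
            raise ScaleError(
                f"symbol {symbol!r} not on scale {self.name!r}"
            ) from None


def _insert_gap(residues: list[str], gap_position: Union[str, int]) -> list[str]:
    order = list(residues)
    if gap_position == "top":
        order.insert(0, GAP)
    elif gap_position == "bottom":
        order.append(GAP)
    elif isinstance(gap_position, int):
        order.insert(gap_position, GAP)
    else:
        raise ScaleError(f"bad gap position {gap_position!r}")
    return order


def custom_scale(
    order: Iterable[str],
    gap_position: Union[str, int] = "top",
    name: str = "custom",
    alphabet: Iterable[str] = PROTEIN_ALPHABET,
) -> YAxisScale:
    """Build a scale from an explicit residue ordering.

    *order* must be a permutation of *alphabet* (gap excluded); the gap
    slot is inserted at ``"top"``, ``"bottom"`` or an integer index.  Any
    alphabet works — a 4-letter DNA ordering yields a 5-slot scale.
    """
    order = list(order)
    alphabet = set(alphabet)
    if set(order) != alphabet or len(order) != len(alphabet):
        missing = sorted(alphabet - set(order))
        extra = sorted(set(order) - alphabet)
        parts = []
        if missing:
            parts.append(f"missing {missing}")
        if extra:
            parts.append(f"unexpected {extra}")
        if len(order) != len(set(order)):
            parts.append("duplicates present")
        raise ScaleError(f"order is not a permutation of the alphabet: "
                         f"{'; '.join(parts) or 'length mismatch'}")
    return YAxisScale(name, tuple(_insert_gap(order, gap_position)))


def _scale_from_mapping(raw: Mapping, source: str) -> YAxisScale:
    try:
        name = raw["name"]
        values = {str(k): float(v) for k, v in raw["values"].items()}
    except (KeyError, TypeError, AttributeError) as exc:
        raise ScaleError(f"malformed scale file {source}") from exc
    direction = raw.get("direction", "ascending")
    if direction not in ("ascending", "descending"):
        raise ScaleError(f"{source}: direction must be ascending|descending")
    reverse = direction == "descending"
    # property sort, ties broken alphabetically for determinism
    residues = sorted(values, key=lambda s: (values[s], s))
    if reverse:
        residues = sorted(values, key=lambda s: (-values[s], s))
    order = _insert_gap(residues, raw.get("gap", "top"))
    return YAxisScale(
        name, tuple(order), values=values, units=raw.get("units")
    )


def load_scale(path: Union[str, Path]) -> YAxisScale:
    """Load a scale from a YAML file (``name``, ``values``, ``direction``,
    ``gap``, optional ``units``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _scale_from_mapping(raw, str(path))


def builtin_scale(name: str) -> YAxisScale:
    """Return one of the shipped scales.

    ``molecular_weight_lide`` orders residues by molecular weight, small at
    the top; ``hydrophobicity_wampler`` runs hydrophilic (top) to
    hydrophobic (bottom).  Both place the gap slot topmost.
    """
    if name not in BUILTIN_SCALES:
        raise ScaleError(
            f"unknown scale {name!r}; built-ins: {', '.join(BUILTIN_SCALES)}"
        )
    ref = resources.files("seqbundles").joinpath(f"data/scales/{name}.yaml")
    raw = yaml.safe_load(ref.read_text())
    return _scale_from_mapping(raw, f"builtin:{name}")
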
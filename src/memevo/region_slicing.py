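"""Topology-aware alignment slicing.

A membrane protein's per-residue topology annotation indexes the residues of
a reference sequence, not alignment columns. Slicing therefore first maps
each reference residue to the alignment column holding it, then routes every
reference-present column to the sub-alignment named by that residue's label
(inside, outside, membrane). Columns where the reference is gapped, and
columns whose residue is unlabelled or labelled unknown, are ignored. The
"aqueous" sub-alignment is the inside columns followed by the outside
columns; pi is column-order invariant so the concatenation order is a pure
reproducibility convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io_formats import Alignment, GAP_CHAR, TopologyAnnotation, ValidationError
from .diversity import nei_pi

REGIONS = ("inside", "outside", "membrane", "aqueous")
_LABEL_TO_REGION = {"I": "inside", "O": "outside", "M": "membrane"}

__all__ = [
    "REGIONS",
    "SlicedAlignment",
    "map_reference_positions",
    "slice_alignment",
    "has_inside_outside",
    "best_reference_for_og",
]


@dataclass(frozen=True)
class SlicedAlignment:
    """Four sub-alignments carved from one MSA via a reference annotation.

    ``columns`` records the original 1-based alignment columns that make up
    each slice; ``ignored_columns`` are columns routed to no slice (the
    reference is gapped there, or the residue's label is unknown). Empty
    slices are represented as None.
    """

    og_id: str | None
    reference_id: str
    slices: dict
    columns: dict
    ignored_columns: tuple[int, ...]


def map_reference_positions(alignment: Alignment, ref_id: str) -> dict[int, int]:
    """Map 1-based reference residue index -> 1-based alignment column.

    The mapping is strictly increasing and covers exactly the reference's
    non-gap columns.
    """
    try:
        ref_row = alignment.row(ref_id)
    except KeyError:
        raise ValidationError(f"reference {ref_id!r} absent from alignment") from None
    mapping: dict[int, int] = {}
    residue = 0
    for col, char in enumerate(ref_row, start=1):
        if char != GAP_CHAR:
            residue += 1
            mapping[residue] = col
    return mapping


def slice_alignment(
    alignment: Alignment,
    annotation: TopologyAnnotation,
    ref_id: str,
    og_id: str | None = None,
) -> SlicedAlignment:
    """Slice an alignment into inside/outside/membrane/aqueous parts using
    the reference sequence's per-residue topology."""
    posmap = map_reference_positions(alignment, ref_id)
    ref_len = len(posmap)
    if annotation.max_position > ref_len:
        raise ValidationError(
            f"annotation reaches residue {annotation.max_position} but reference "
            f"{ref_id!r} has only {ref_len} residues"
        )
    labels = annotation.labels(ref_len)
    ref_cols = set(posmap.values())
    columns: dict[str, list[int]] = {"inside": [], "outside": [], "membrane": []}
    ignored = [col for col in range(1, alignment.n_cols + 1) if col not in ref_cols]
    for residue in range(1, ref_len + 1):
        region = _LABEL_TO_REGION.get(labels[residue - 1])
        if region is None:
            ignored.append(posmap[residue])
        else:
            columns[region].append(posmap[residue])
    ignored.sort()

    n_ref_present = ref_len
    n_routed = sum(len(v) for v in columns.values())
    n_ignored_present = sum(1 for c in ignored if c in ref_cols)
    assert n_routed + n_ignored_present == n_ref_present, "column conservation violated"

    col_map = {r: tuple(columns[r]) for r in ("inside", "outside", "membrane")}
    col_map["aqueous"] = col_map["inside"] + col_map["outside"]
    slices = {
        region: alignment.select_columns(cols) if cols else None
        for region, cols in col_map.items()
    }
    return SlicedAlignment(
        og_id=og_id,
        reference_id=ref_id,
        slices=slices,
        columns=col_map,
        ignored_columns=tuple(ignored),
    )


def has_inside_outside(annotation: TopologyAnnotation) -> bool:
    """True iff the annotation distinguishes inside- from outside-facing
    residues. Proteins without this distinction are skipped entirely:
    an undifferentiated aqueous label cannot be sliced meaningfully."""
    return annotation.has_label("I") and annotation.has_label("O")


def best_reference_for_og(
    candidates: Mapping[str, tuple[Alignment, TopologyAnnotation]],
) -> tuple[str, TopologyAnnotation]:
    """Among candidate annotated references for one ortholog group, keep the
    one whose whole alignment has the lowest Nei's pi (best alignment);
    ties break lexicographically on the reference id."""
    if not candidates:
        raise ValidationError("no candidate reference")
    best = min(
        ((nei_pi(aln), ref_id) for ref_id, (aln, _) in candidates.items()),
    )
    ref_id = best[1]
    return ref_id, candidates[ref_id][1]
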
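"""Membrane / water-soluble / extracellular classification.

A protein is a membrane protein (MP) iff its topology annotation contains at
least one membrane-spanning (M) interval; everything else is water-soluble
(WS) — mirroring topology predictors that only assert positives. At the
ortholog-group level both the MP/WS call and the signal-peptide call are
strict-majority censuses over members (ties resolve to WS / negative).

The refined three-way split is: membrane (group majority MP), extracellular
(not MP and signal-peptide census positive), cytosolic (the rest).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import OrthologGroup, ProteinRecord
from . import stats_core

logger = logging.getLogger(__name__)

MP, WS = "MP", "WS"
CYTOSOLIC, EXTRACELLULAR, MEMBRANE = "cytosolic", "extracellular", "membrane"

__all__ = [
    "MP",
    "WS",
    "classify_protein",
    "og_majority_class",
    "og_signal_census",
    "og_refined_class",
    "extracellular_fraction",
    "bin_by_extracellularity",
    "extracellularity_regression",
]


def classify_protein(record: ProteinRecord, warn_missing: bool = True) -> str:
    """MP iff the topology contains >= 1 membrane-spanning interval.

    A record with no topology at all classifies WS (with a logged warning):
    absence of a prediction is not evidence of a membrane segment.
    """
    if record.topology is None:
        if warn_missing:
            logger.warning(
                "protein %s has no topology annotation; classified WS",
                record.protein_id,
            )
        return WS
    return MP if record.topology.has_label("M") else WS


def og_majority_class(og: OrthologGroup, warn_missing: bool = False) -> str:
    """MP iff strictly more than half of the members classify MP."""
    if og.size == 0:
        raise ValueError(f"{og.og_id}: empty ortholog group")
    n_mp = sum(1 for m in og.members if classify_protein(m, warn_missing) == MP)
    return MP if 2 * n_mp > og.size else WS


def og_signal_census(og: OrthologGroup) -> bool:
    """True iff strictly more than half of members carry a positive
    signal-peptide flag; an absent flag counts negative."""
    if og.size == 0:
        raise ValueError(f"{og.og_id}: empty ortholog group")
    n_pos = sum(1 for m in og.members if m.signal_peptide is True)
    return 2 * n_pos > og.size


def og_refined_class(og: OrthologGroup) -> str:
    """Three-way class; the membrane call takes precedence over the
    signal-peptide call (extracellular requires not being membrane-bound)."""
    if og_majority_class(og) == MP:
        return MEMBRANE
    return EXTRACELLULAR if og_signal_census(og) else CYTOSOLIC


def extracellular_fraction(og: OrthologGroup) -> float | None:
    """Summed outside-facing residue count over summed sequence length,
    across the MP-classified members. None when no member is MP."""
    total_o = 0
    total_len = 0
    for m in og.members:
        if classify_protein(m, warn_missing=False) != MP:
            continue
        labels = m.topology.labels(len(m.sequence))
        total_o += labels.count("O")
        total_len += len(m.sequence)
    if total_len == 0:
        return None
    return total_o / total_len


def _bin_index(fraction: float) -> int:
    """1..10 for ten equal-width bins of [0, 1]; the last bin is closed at 1."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    return min(int(fraction * 10), 9) + 1


def bin_by_extracellularity(ogs: Iterable[OrthologGroup]) -> pd.DataFrame:
    """Mean OG size in ten extracellularity bins.

    Membrane OGs are binned by their extracellular residue fraction;
    cytosolic WS OGs are forced into the first bin, extracellular WS OGs
    into the last. Empty bins report a missing mean.
    """
    sizes: dict[int, list[int]] = {b: [] for b in range(1, 11)}
    for og in ogs:
        refined = og_refined_class(og)
        if refined == MEMBRANE:
            frac = extracellular_fraction(og)
            b = _bin_index(frac)
        elif refined == CYTOSOLIC:
            b = 1
        else:
            b = 10
        sizes[b].append(og.size)
    rows = []
    for b in range(1, 11):
        vals = sizes[b]
        rows.append(
            {
                "bin": b,
                "lo": (b - 1) / 10,
                "hi": b / 10,
                "midpoint": (b - 0.5) / 10,
                "n_ogs": len(vals),
                "mean_og_size": float(np.mean(vals)) if vals else np.nan,
            }
        )
    return pd.DataFrame(rows)


def extracellularity_regression(bins: pd.DataFrame) -> stats_core.LinRegResult:
    """Linear regression of per-bin mean OG size on bin midpoints; empty
    bins are excluded."""
    use = bins.dropna(subset=["mean_og_size"])
    return stats_core.linear_regression(
        use["midpoint"].to_numpy(), use["mean_og_size"].to_numpy()
    )
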
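"""Ancestral gene-loss census within clades of closely related species.

Within a clade of closely related species (same name at the fifth taxonomic
level, at least ten members), an ortholog group shared by a strict majority
of the clade is inferred ancestral: in such tight clades orthologs are
unlikely to have diverged beyond recognition, so a member species lacking
the group is counted as a true gene loss. Comparing the mean sharing
proportion of ancestral membrane groups against water-soluble ones, per
clade and paired across clades, quantifies differential loss.

The ancestral threshold is a strict majority (> half) by default; the
inclusive reading (>= half) is available via ``threshold="at_least"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import Lineage, OrthologGroup
from .topology_classify import MP, WS, og_majority_class
from . import stats_core

logger = logging.getLogger(__name__)

TIER_MP_GE_WS = "MP>=WS"
TIER_MP_LT_WS_NS = "MP<WS (n.s.)"
TIER_MP_LT_WS_SIG = "MP<WS (p<0.05)"

__all__ = [
    "CladeSet",
    "CladeCensus",
    "find_close_clades",
    "census_clade",
    "cross_clade_summary",
]


@dataclass(frozen=True)
class CladeSet:
    """Species grouped by a shared taxonomic-level name."""

    name: str
    species: frozenset[str]

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass
class CladeCensus:
    clade_name: str
    n_species: int
    table: pd.DataFrame  # og_id, og_class, n_sharing, proportion, ancestral
    ws_mean: float
    ws_sem: float
    mp_mean: float
    mp_sem: float
    welch: stats_core.TTestResult | None
    tier: str


def find_close_clades(
    lineages: Mapping[str, Lineage], min_members: int = 10, level: int = 5
) -> list[CladeSet]:
    """Maximal groups of species sharing the level-``level`` name, keeping
    those with at least ``min_members`` species."""
    by_name: dict[str, set[str]] = {}
    for sp, lin in lineages.items():
        by_name.setdefault(lin.level(level), set()).add(sp)
    return [
        CladeSet(name, frozenset(members))
        for name, members in sorted(by_name.items())
        if len(members) >= min_members
    ]


def _sem(vals: np.ndarray) -> float:
    return float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")


def census_clade(
    clade: CladeSet,
    ogs: Iterable[OrthologGroup],
    threshold: str = "strict",
    alpha: float = 0.05,
) -> CladeCensus:
    """Census ancestral ortholog groups of one clade.

    For each group with any member in the clade, ``n_sharing`` counts the
    distinct clade species represented. Ancestral means sharing strictly
    more than half the clade ("strict", default) or at least half
    ("at_least"). The group's class is the membrane/water-soluble majority
    census over all its members. Reported per class: mean and SEM of the
    ancestral sharing proportions, a Welch test on the proportions, and a
    significance tier (MP>=WS / MP<WS not significant / MP<WS p<alpha).
    """
    if clade.n_species < 2:
        raise ValueError(f"clade {clade.name}: need >= 2 species")
    if threshold not in ("strict", "at_least"):
        raise ValueError("threshold must be 'strict' or 'at_least'")
    half = clade.n_species / 2.0
    rows = []
    for og in ogs:
        sharing = {m.species_id for m in og.members} & clade.species
        if not sharing:
            continue
        n_sharing = len(sharing)
        ancestral = n_sharing > half if threshold == "strict" else n_sharing >= half
        rows.append(
            {
                "og_id": og.og_id,
                "og_class": og_majority_class(og),
                "n_sharing": n_sharing,
                "proportion": n_sharing / clade.n_species,
                "ancestral": ancestral,
            }
        )
    table = pd.DataFrame(
        rows, columns=["og_id", "og_class", "n_sharing", "proportion", "ancestral"]
    )
    anc = table[table["ancestral"]]
    props = {
        cls: anc.loc[anc["og_class"] == cls, "proportion"].to_numpy()
        for cls in (WS, MP)
    }
    welch = None
    if props[WS].size >= 2 and props[MP].size >= 2:
        try:
            welch = stats_core.welch_t(props[MP], props[WS])
        except stats_core.StatsError as exc:
            logger.warning("clade %s: Welch test skipped: %s", clade.name, exc)
    else:
        logger.warning(
            "clade %s: a class has < 2 ancestral groups; test skipped", clade.name
        )
    ws_mean = float(props[WS].mean()) if props[WS].size else float("nan")
    mp_mean = float(props[MP].mean()) if props[MP].size else float("nan")
    if not (mp_mean < ws_mean):
        tier = TIER_MP_GE_WS
    elif welch is not None and welch.p < alpha:
        tier = TIER_MP_LT_WS_SIG
    else:
        tier = TIER_MP_LT_WS_NS
    return CladeCensus(
        clade_name=clade.name,
        n_species=clade.n_species,
        table=table,
        ws_mean=ws_mean,
        ws_sem=_sem(props[WS]),
        mp_mean=mp_mean,
        mp_sem=_sem(props[MP]),
        welch=welch,
        tier=tier,
    )


def cross_clade_summary(censuses: Sequence[CladeCensus]) -> dict:
    """Pair each clade's water-soluble and membrane mean sharing
    proportions; paired t across clades plus the count of clades where the
    membrane mean is lower."""
    if len(censuses) < 2:
        raise ValueError("need >= 2 clade censuses")
    pairs = pd.DataFrame(
        {
            "clade": [c.clade_name for c in censuses],
            "ws_mean": [c.ws_mean for c in censuses],
            "mp_mean": [c.mp_mean for c in censuses],
            "tier": [c.tier for c in censuses],
        }
    ).dropna(subset=["ws_mean", "mp_mean"])
    n_mp_below = int((pairs["mp_mean"] < pairs["ws_mean"]).sum())
    test = None
    if len(pairs) >= 2:
        try:
            test = stats_core.paired_t(
                pairs["ws_mean"].to_numpy(), pairs["mp_mean"].to_numpy()
            )
        except stats_core.StatsError as exc:
            logger.warning("cross-clade paired t skipped: %s", exc)
    return {
        "pairs": pairs,
        "paired_t": test,
        "n_clades": len(pairs),
        "n_mp_below_ws": n_mp_below,
    }
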
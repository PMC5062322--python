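"""Phylogenetic-spread analyses of ortholog groups.

Covers three related questions about how widely a protein family is shared:
per-species mean group sizes split by membrane/water-soluble class, the
water-soluble over membrane size ratio compared across organismal groups,
and a quasi-binomial logistic model of the probability that a group is
membrane-bound as a function of how many taxonomic clades share it.

Densely sequenced lineages (many strains of one species) would otherwise
dominate the spread counts, so groups are first dereplicated to one
representative per clade at a configurable taxonomic level (level 6 by
default, e.g. genus-like for bacteria).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import Lineage, OrthologGroup, ValidationError
from .topology_classify import MP, WS, classify_protein, og_majority_class
from . import stats_core

logger = logging.getLogger(__name__)

DOMAIN_NAMES = {"archaea", "bacteria", "eukaryota"}

__all__ = [
    "dereplicate_og",
    "dereplicated_size",
    "build_spread_table",
    "species_mean_sizes",
    "group_ratios",
    "filter_cross_domain",
    "spread_logistic",
    "count_level_clades",
]


def _level_name(lineages: Mapping[str, Lineage], species_id: str, level: int) -> str:
    lin = lineages.get(species_id)
    if lin is None:
        raise ValidationError(f"no lineage for species {species_id!r}")
    return lin.level(level)


def dereplicate_og(
    og: OrthologGroup,
    lineages: Mapping[str, Lineage],
    level: int = 6,
    rng: np.random.Generator | None = None,
    preferred_species: Sequence[str] = (),
) -> OrthologGroup:
    """Collapse a group to one member per distinct clade at ``level``.

    The representative is taken from ``preferred_species`` (well-annotated
    species) when one is present in the clade, otherwise uniformly at random
    under the run seed. Deterministic given the generator state.
    """
    rng = rng or np.random.default_rng(0)
    preferred = {s: i for i, s in enumerate(preferred_species)}
    by_clade: dict[str, list] = {}
    for m in og.members:
        by_clade.setdefault(_level_name(lineages, m.species_id, level), []).append(m)
    members = []
    for clade in sorted(by_clade):
        cands = sorted(by_clade[clade], key=lambda m: m.protein_id)
        wanted = [m for m in cands if m.species_id in preferred]
        if wanted:
            members.append(min(wanted, key=lambda m: preferred[m.species_id]))
        elif len(cands) == 1:
            members.append(cands[0])
        else:
            members.append(cands[int(rng.integers(len(cands)))])
    return OrthologGroup(og_id=og.og_id, members=members)


def dereplicated_size(
    og: OrthologGroup, lineages: Mapping[str, Lineage], level: int = 6
) -> int:
    """Number of distinct level-``level`` clades represented in the group."""
    return len({_level_name(lineages, m.species_id, level) for m in og.members})


def count_level_clades(lineages: Mapping[str, Lineage], level: int = 6) -> int:
    """Total number of distinct clades at ``level`` across the dataset; the
    normalizer for spread-fraction binning."""
    return len({lin.level(level) for lin in lineages.values()})


def _domain_of(lineage: Lineage) -> str | None:
    name = lineage.domain.lower()
    return name if name in DOMAIN_NAMES else None


def build_spread_table(
    ogs: Iterable[OrthologGroup],
    lineages: Mapping[str, Lineage],
    level: int = 6,
) -> pd.DataFrame:
    """One row per OG: raw size, dereplicated size, majority class and the
    set of domains present."""
    rows = []
    for og in ogs:
        domains = set()
        for m in og.members:
            lin = lineages.get(m.species_id)
            if lin is not None:
                d = _domain_of(lin)
                if d:
                    domains.add(d)
        rows.append(
            {
                "og_id": og.og_id,
                "raw_size": og.size,
                "dereplicated_size": dereplicated_size(og, lineages, level),
                "og_class": og_majority_class(og),
                "domains": frozenset(domains),
            }
        )
    return pd.DataFrame(rows)


def species_mean_sizes(
    ogs: Iterable[OrthologGroup], species: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-species mean ortholog-group size by the member protein's class.

    Every OG containing a species contributes its size once to that species
    (groups shared by several species are counted once per species). Columns:
    mean, SEM and count for each of WS and MP. Species present in no group
    are excluded with a warning.
    """
    sizes: dict[str, dict[str, list[int]]] = {}
    for og in ogs:
        for m in og.members:
            cls = classify_protein(m, warn_missing=False)
            sizes.setdefault(m.species_id, {WS: [], MP: []})[cls].append(og.size)
    wanted = list(species) if species is not None else sorted(sizes)
    rows = []
    for sp in wanted:
        if sp not in sizes:
            logger.warning("species %r appears in no ortholog group; excluded", sp)
            continue
        row: dict = {"species_id": sp}
        for cls, key in ((WS, "ws"), (MP, "mp")):
            vals = np.asarray(sizes[sp][cls], dtype=float)
            row[f"{key}_n"] = vals.size
            row[f"{key}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{key}_sem"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def group_ratios(
    per_species_means: pd.DataFrame, organism_groups: Mapping[str, str]
) -> tuple[pd.DataFrame, stats_core.AnovaResult | None]:
    """WS/MP mean-size ratio per species, compared across organismal groups
    by one-way ANOVA with omega-squared. Species with no MP mean (or zero)
    are excluded with a warning; the ANOVA is skipped unless at least two
    groups have two or more species."""
    rows = []
    for row in per_species_means.itertuples():
        if not np.isfinite(row.mp_mean) or row.mp_mean == 0:
            logger.warning("species %r: MP mean undefined or 0; excluded", row.species_id)
            continue
        if not np.isfinite(row.ws_mean):
            logger.warning("species %r: no WS groups; excluded", row.species_id)
            continue
        grp = organism_groups.get(row.species_id)
        rows.append(
            {
                "species_id": row.species_id,
                "organism_group": grp,
                "ratio": row.ws_mean / row.mp_mean,
            }
        )
    df = pd.DataFrame(rows)
    anova = None
    if not df.empty:
        groups = [
            g["ratio"].to_numpy()
            for _, g in df.groupby("organism_group")
            if len(g) >= 2
        ]
        if len(groups) >= 2:
            try:
                anova = stats_core.one_way_anova(groups)
            except stats_core.StatsError as exc:
                logger.warning("ANOVA skipped: %s", exc)
    return df, anova


def filter_cross_domain(
    ogs: Iterable[OrthologGroup], lineages: Mapping[str, Lineage]
) -> list[OrthologGroup]:
    """Keep groups whose members span at least one eukaryote and at least
    one prokaryote (archaeon or bacterium)."""
    kept = []
    for og in ogs:
        domains = {
            _domain_of(lineages[m.species_id])
            for m in og.members
            if m.species_id in lineages
        }
        if "eukaryota" in domains and ({"archaea", "bacteria"} & domains):
            kept.append(og)
    return kept


def spread_logistic(
    spread_table: pd.DataFrame,
    max_taxa: int,
    min_clades: int = 3,
) -> tuple[stats_core.GlmFit | None, pd.DataFrame]:
    """Quasi-binomial logistic fit of membrane-ness on phylogenetic spread,
    plus independently computed binned proportions.

    Only groups spanning at least ``min_clades`` dereplicated clades enter.
    The response is 1 for membrane groups and 0 for water-soluble ones; the
    predictor is the dereplicated group size. The ten bins are equal-width
    intervals of dereplicated_size / max_taxa; bin proportions are computed
    from the same filtered rows but entirely independently of the fit.
    Returns (fit, bins); the fit is None for one-class input (bins are
    still produced).
    """
    use = spread_table[spread_table["dereplicated_size"] >= min_clades]
    y = (use["og_class"] == MP).astype(float).to_numpy()
    x = use["dereplicated_size"].astype(float).to_numpy()

    frac = x / float(max_taxa)
    bin_idx = np.minimum((frac * 10).astype(int), 9) + 1
    rows = []
    for b in range(1, 11):
        mask = bin_idx == b
        rows.append(
            {
                "bin": b,
                "lo": (b - 1) / 10,
                "hi": b / 10,
                "n_ogs": int(mask.sum()),
                "proportion_mp": float(y[mask].mean()) if mask.any() else np.nan,
            }
        )
    bins = pd.DataFrame(rows)

    fit = None
    if 0 < y.sum() < y.size and y.size >= 10:
        fit = stats_core.quasibinomial_irls(y, x)
    else:
        logger.warning("logistic fit skipped: one-class or undersized input")
    return fit, bins
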
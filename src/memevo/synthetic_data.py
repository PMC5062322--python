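"""Synthetic ortholog groups evolving with region-specific rates and
class-specific gene loss.

The generator emulates the statistical structure the downstream analyses
assume: a clade-structured species set (a star of clade stars with unit
branch lengths), ortholog groups of three localization classes (cytosolic
water-soluble, extracellular water-soluble, membrane), substitution-only
sequence evolution whose per-site rate depends on the residue's topology
region (membrane proteins) or the protein's class (water-soluble proteins),
and independent per-species gene loss with class-specific probability.

Substitution-only evolution means each group's extant sequences are already
aligned — slicing and diversity estimation operate on them directly, and the
per-branch substitution probability 1 - exp(-rate * length) gives closed
forms for expected p-distances used in parameter-recovery tests. A real
pre-aligned FASTA can replace the simulated one at any pipeline stage.

Along a branch, a substituting site draws uniformly among the 19 alternative
residues (Jukes-Cantor-like exchangeability); loss happens at the leaves
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import (
    AA_ALPHABET,
    Lineage,
    OrthologGroup,
    ProteinRecord,
    TopologyAnnotation,
    dump_config,
    write_fasta,
    write_lineage_tsv,
    write_og_tsv,
    write_results_tsv,
    write_signal_tsv,
    write_topology_tsv,
)

CLASSES = ("cytosolic_WS", "extracellular_WS", "MP")
DOMAIN_CYCLE = ("Bacteria", "Archaea", "Eukaryota")

DEFAULT_MP_LAYOUT = (
    ("I", 15), ("M", 20), ("O", 15), ("M", 20), ("I", 15), ("M", 20), ("O", 15),
)

__all__ = [
    "CLASSES",
    "SimulationConfig",
    "SyntheticDataset",
    "generate_species_tree",
    "evolve_og",
    "generate_ogs",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Rates are expected substitutions per site per unit branch length; loss
    probabilities are per extant species copy. For membrane proteins the
    protein length must equal the summed layout segment lengths.
    """

    n_clades: int = 6
    species_per_clade: int = 4
    n_ogs_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"cytosolic_WS": 200, "extracellular_WS": 100, "MP": 200}
    )
    protein_length: int = 120
    mp_layout: tuple[tuple[str, int], ...] = DEFAULT_MP_LAYOUT
    rate_inside: float = 0.2
    rate_membrane: float = 0.1
    rate_outside: float = 0.6
    rate_cytosolic: float = 0.12
    rate_extracellular: float = 0.22
    loss_prob: Mapping[str, float] = field(
        default_factory=lambda: {"cytosolic_WS": 0.05, "extracellular_WS": 0.40, "MP": 0.30}
    )
    per_clade_ogs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.rate_inside,
            self.rate_membrane,
            self.rate_outside,
            self.rate_cytosolic,
            self.rate_extracellular,
        )
        if any(r < 0 for r in rates):
            raise ValueError("substitution rates must be >= 0")
        for cls, p in self.loss_prob.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"loss_prob[{cls}] must be in [0, 1)")
        layout = tuple((str(lab).upper(), int(n)) for lab, n in self.mp_layout)
        object.__setattr__(self, "mp_layout", layout)
        if any(lab not in "IMO" for lab, _ in layout):
            raise ValueError("mp_layout labels must be I, M or O")
        if self.n_ogs_per_class.get("MP", 0) > 0:
            if sum(n for _, n in layout) != self.protein_length:
                raise ValueError(
                    "protein_length must equal the summed mp_layout segment lengths"
                )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "mp_layout" in d:
            layout = []
            for item in d["mp_layout"]:
                if isinstance(item, str):
                    lab, n = item.split(":")
                else:
                    lab, n = item
                layout.append((str(lab), int(n)))
            d["mp_layout"] = tuple(layout)
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "n_clades": self.n_clades,
            "species_per_clade": self.species_per_clade,
            "n_ogs_per_class": dict(self.n_ogs_per_class),
            "protein_length": self.protein_length,
            "mp_layout": [f"{lab}:{n}" for lab, n in self.mp_layout],
            "rate_inside": self.rate_inside,
            "rate_membrane": self.rate_membrane,
            "rate_outside": self.rate_outside,
            "rate_cytosolic": self.rate_cytosolic,
            "rate_extracellular": self.rate_extracellular,
            "loss_prob": dict(self.loss_prob),
            "per_clade_ogs": self.per_clade_ogs,
            "seed": self.seed,
        }


def _species_code(clade_idx: int, species_idx: int) -> str:
    """OMA-style 5-letter/-digit species code, unique per (clade, species)."""
    letters = chr(ord("A") + clade_idx // 26) + chr(ord("A") + clade_idx % 26)
    return f"{letters}{species_idx:03d}"


def generate_species_tree(
    config: SimulationConfig,
) -> tuple[TreeNode, dict[str, Lineage]]:
    """Star-of-stars species tree plus matching lineages.

    The root joins ``n_clades`` clade nodes, each a star of
    ``species_per_clade`` leaves; every branch has unit length. Lineages are
    built so that level 5 names the clade and level 6 subdivides it into
    pairs of species; domains cycle Bacteria/Archaea/Eukaryota across
    clades. Fully deterministic.
    """
    if config.n_clades < 2 or config.species_per_clade < 2:
        raise ValueError("need n_clades >= 2 and species_per_clade >= 2")
    root = TreeNode(name="root")
    lineages: dict[str, Lineage] = {}
    for ci in range(config.n_clades):
        clade_name = f"Clade{ci:02d}"
        domain = DOMAIN_CYCLE[ci % len(DOMAIN_CYCLE)]
        clade_node = TreeNode(name=clade_name, length=1.0)
        for si in range(config.species_per_clade):
            code = _species_code(ci, si)
            clade_node.append(TreeNode(name=code, length=1.0))
            lineages[code] = Lineage(
                code,
                (
                    domain,
                    f"{domain}_phylum",
                    f"{clade_name}_class",
                    f"{clade_name}_order",
                    clade_name,
                    f"{clade_name}.sub{si // 2:02d}",
                    f"{clade_name} species {si}",
                ),
            )
        root.append(clade_node)
    return root, lineages


def organism_groups(config: SimulationConfig) -> dict[str, str]:
    """Per-species organism-group labels: prokaryote for bacterial/archaeal
    clades; eukaryotic clades alternate unicellular/multicellular."""
    groups: dict[str, str] = {}
    n_euk_seen = 0
    for ci in range(config.n_clades):
        domain = DOMAIN_CYCLE[ci % len(DOMAIN_CYCLE)]
        if domain == "Eukaryota":
            grp = (
                "unicellular_eukaryote"
                if n_euk_seen % 2 == 0
                else "multicellular_eukaryote"
            )
            n_euk_seen += 1
        else:
            grp = "prokaryote"
        for si in range(config.species_per_clade):
            groups[_species_code(ci, si)] = grp
    return groups


# ---------------------------------------------------------------------------
# evolution

def _mutate(seq: np.ndarray, p_site: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One branch of substitution-only evolution.

    Each site substitutes with its per-site probability; a substituting site
    moves to one of the 19 other residues uniformly (offset 1..19 mod 20).
    """
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < p_site)
    if hits.size:
        offsets = rng.integers(1, 20, size=hits.size)
        out[hits] = (out[hits] + offsets) % 20
    return out


def _site_rates(config: SimulationConfig, og_class: str) -> np.ndarray:
    if og_class == "MP":
        pieces = []
        rate_of = {
            "I": config.rate_inside,
            "M": config.rate_membrane,
            "O": config.rate_outside,
        }
        for lab, n in config.mp_layout:
            pieces.append(np.full(n, rate_of[lab]))
        return np.concatenate(pieces)
    rate = (
        config.rate_cytosolic if og_class == "cytosolic_WS" else config.rate_extracellular
    )
    return np.full(config.protein_length, rate)


def _layout_annotation(layout: Sequence[tuple[str, int]]) -> TopologyAnnotation:
    intervals = []
    pos = 1
    for lab, n in layout:
        intervals.append((pos, pos + n - 1, lab))
        pos += n
    return TopologyAnnotation(tuple(intervals))


def _decode(seq: np.ndarray) -> str:
    return "".join(AA_ALPHABET[i] for i in seq)


def evolve_og(
    ancestral_record: ProteinRecord,
    tree: TreeNode,
    config: SimulationConfig,
    rng: np.random.Generator,
    og_class: str,
    og_id: str | None = None,
    apply_loss: bool = True,
) -> OrthologGroup:
    """Evolve an ancestral protein down a tree into an ortholog group.

    Per-site substitution rates come from the site's topology region for
    membrane proteins and from the protein's class otherwise; descendants
    inherit the ancestral topology annotation unchanged (no indels). After
    evolution each species' copy is independently deleted with the class's
    loss probability. The returned group may be empty if every copy is lost.
    """
    og_id = og_id or f"OG_{ancestral_record.protein_id}"
    rates = _site_rates(config, og_class)
    anc = np.array(
        [AA_ALPHABET.index(c) for c in ancestral_record.sequence], dtype=np.int64
    )
    if anc.size != rates.size:
        raise ValueError("ancestral sequence length does not match configured length")
    leaf_seqs: list[tuple[str, np.ndarray]] = []

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            p_site = 1.0 - np.exp(-rates * float(child.length or 0.0))
            child_seq = _mutate(seq, p_site, rng)
            if child.is_tip():
                leaf_seqs.append((child.name, child_seq))
            else:
                descend(child, child_seq)

    descend(tree, anc)
    loss_p = config.loss_prob.get(og_class, 0.0) if apply_loss else 0.0
    keep = rng.random(len(leaf_seqs)) >= loss_p
    members = []
    for (species, seq), kept in zip(leaf_seqs, keep):
        if not kept:
            continue
        members.append(
            ProteinRecord(
                protein_id=f"{og_id}.{species}",
                species_id=species,
                sequence=_decode(seq),
                topology=ancestral_record.topology,
                signal_peptide=ancestral_record.signal_peptide,
            )
        )
    return OrthologGroup(og_id=og_id, members=members)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    tree: TreeNode
    lineages: dict[str, Lineage]
    ogs: list[OrthologGroup]
    truth: pd.DataFrame
    groups: dict[str, str]


def _ancestral_record(
    og_id: str, og_class: str, config: SimulationConfig, rng: np.random.Generator
) -> ProteinRecord:
    seq = _decode(rng.integers(0, 20, size=config.protein_length))
    if og_class == "MP":
        topo = _layout_annotation(config.mp_layout)
    else:
        topo = TopologyAnnotation(())  # explicitly empty: predicted, no segments
    return ProteinRecord(
        protein_id=f"{og_id}.ANC",
        species_id="ANC",
        sequence=seq,
        topology=topo,
        signal_peptide=(og_class == "extracellular_WS"),
    )


def generate_ogs(
    config: SimulationConfig, seed: int | None = None
) -> SyntheticDataset:
    """Generate the full in-memory dataset for a configuration.

    One ortholog group per requested ancestral protein; deterministic given
    the seed. With ``per_clade_ogs`` each class's OG count applies per clade
    and each group evolves on a single clade's subtree (ancestor at the
    clade node) — the shape the ancestral-loss census analyses. Groups whose
    every copy is lost keep their truth row (n_extant = 0) but are excluded
    from the OG list.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tree, lineages = generate_species_tree(config)
    ogs: list[OrthologGroup] = []
    truth_rows: list[dict] = []
    counter = 0

    if config.per_clade_ogs:
        units = [(clade.name, clade) for clade in tree.children]
    else:
        units = [(None, tree)]

    for og_class in CLASSES:
        n = int(config.n_ogs_per_class.get(og_class, 0))
        for clade_name, subtree in units:
            for _ in range(n):
                og_id = f"OG{counter:05d}"
                counter += 1
                anc = _ancestral_record(og_id, og_class, config, rng)
                og = evolve_og(anc, subtree, config, rng, og_class, og_id=og_id)
                truth_rows.append(
                    {
                        "og_id": og_id,
                        "og_class": og_class,
                        "clade": clade_name or "all",
                        "n_extant": og.size,
                        "rate_inside": config.rate_inside if og_class == "MP" else np.nan,
                        "rate_membrane": config.rate_membrane if og_class == "MP" else np.nan,
                        "rate_outside": config.rate_outside if og_class == "MP" else np.nan,
                        "rate_class": (
                            np.nan
                            if og_class == "MP"
                            else (
                                config.rate_cytosolic
                                if og_class == "cytosolic_WS"
                                else config.rate_extracellular
                            )
                        ),
                    }
                )
                if og.size > 0:
                    ogs.append(og)
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(
        config=config,
        tree=tree,
        lineages=lineages,
        ogs=ogs,
        truth=truth,
        groups=organism_groups(config),
    )


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Write a complete simulated dataset to disk.

    Produces proteins.fasta, ogs.tsv, topology.tsv (membrane proteins only),
    lineages.tsv, signal.tsv, groups.tsv, truth.tsv, tree.nwk and a config
    snapshot; byte-identical for identical config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = generate_ogs(config, seed=seed)

    paths = {
        "fasta": out / "proteins.fasta",
        "ogs": out / "ogs.tsv",
        "topology": out / "topology.tsv",
        "lineages": out / "lineages.tsv",
        "signal": out / "signal.tsv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.tsv",
        "tree": out / "tree.nwk",
        "config": out / "config.yaml",
    }
    records = [m for og in ds.ogs for m in og.members]
    write_fasta(records, paths["fasta"])
    write_og_tsv(ds.ogs, paths["ogs"])
    topo = {
        m.protein_id: m.topology
        for m in records
        if m.topology is not None and m.topology.intervals
    }
    write_topology_tsv(topo, paths["topology"])
    write_lineage_tsv(ds.lineages, paths["lineages"])
    write_signal_tsv(
        {m.protein_id: bool(m.signal_peptide) for m in records}, paths["signal"]
    )
    groups_df = pd.DataFrame(
        [{"species_id": sp, "organism_group": g} for sp, g in sorted(ds.groups.items())]
    )
    write_results_tsv(groups_df, paths["groups"])
    write_results_tsv(ds.truth, paths["truth"])
    with open(paths["tree"], "w") as fh:
        ds.tree.write(fh)
    dump_config(config.to_dict(), paths["config"])
    return paths
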
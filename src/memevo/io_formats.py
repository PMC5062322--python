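"""Readers/writers for on-disk artifacts and the shared data model.

All TSV and prose coordinates are 1-based inclusive; conversion to Python's
0-based half-open convention happens here and nowhere else.

FASTA headers follow the fixed dialect ``species_id|protein_id`` so that
sequence files join unambiguously against the ortholog-group and lineage
tables without a lookup table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHAR = "-"
UNKNOWN_CHAR = "X"
TOPOLOGY_LABELS = frozenset("IMOU")

__all__ = [
    "AA_ALPHABET",
    "GAP_CHAR",
    "FormatError",
    "ValidationError",
    "TopologyAnnotation",
    "ProteinRecord",
    "OrthologGroup",
    "Lineage",
    "Alignment",
    "read_fasta",
    "write_fasta",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_topology_tsv",
    "write_topology_tsv",
    "read_og_tsv",
    "write_og_tsv",
    "build_ortholog_groups",
    "read_lineage_tsv",
    "write_lineage_tsv",
    "read_signal_tsv",
    "write_signal_tsv",
    "write_results_tsv",
    "load_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


def to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start - 1, end


@dataclass(frozen=True)
class TopologyAnnotation:
    """Per-residue localization labels for a reference protein sequence.

    Intervals are 1-based inclusive with labels I (inside-facing), M
    (membrane-spanning), O (outside-facing) or U (unknown). Residues not
    covered by any interval are implicitly U — membrane-protein structures
    frequently have unresolved stretches, so absence of a label carries no
    information.
    """

    intervals: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        norm = []
        for iv in self.intervals:
            start, end, label = int(iv[0]), int(iv[1]), str(iv[2]).upper()
            if label not in TOPOLOGY_LABELS:
                raise ValidationError(f"unknown topology label {label!r}")
            if start < 1 or end < start:
                raise ValidationError(f"bad interval ({start}, {end})")
            norm.append((start, end, label))
        norm.sort()
        prev_end = 0
        merged: list[tuple[int, int, str]] = []
        for start, end, label in norm:
            if start <= prev_end:
                raise ValidationError(
                    f"overlapping topology intervals at position {start}"
                )
            if merged and merged[-1][2] == label and merged[-1][1] + 1 == start:
                merged[-1] = (merged[-1][0], end, label)
            else:
                merged.append((start, end, label))
            prev_end = end
        object.__setattr__(self, "intervals", tuple(merged))

    @property
    def span(self) -> int:
        """Total number of annotated residues."""
        return sum(end - start + 1 for start, end, _ in self.intervals)

    @property
    def max_position(self) -> int:
        return self.intervals[-1][1] if self.intervals else 0

    def labels(self, length: int) -> str:
        """Per-residue label string of ``length``; unannotated residues are U."""
        if self.max_position > length:
            raise ValidationError(
                f"annotation extends to {self.max_position} beyond length {length}"
            )
        out = ["U"] * length
        for start, end, label in self.intervals:
            lo, hi = to_internal(start, end)
            out[lo:hi] = label * (hi - lo)
        return "".join(out)

    def has_label(self, label: str) -> bool:
        return any(lab == label for _, _, lab in self.intervals)


@dataclass
class ProteinRecord:
    """One protein sequence with its species, optional topology and
    signal-peptide flag."""

    protein_id: str
    species_id: str
    sequence: str
    topology: TopologyAnnotation | None = None
    signal_peptide: bool | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - set(AA_ALPHABET + UNKNOWN_CHAR)
        if bad:
            raise ValidationError(
                f"{self.protein_id}: invalid residues {sorted(bad)}"
            )
        if self.topology is not None and self.topology.max_position > len(self.sequence):
            raise ValidationError(
                f"{self.protein_id}: topology exceeds sequence length"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrthologGroup:
    """A set of proteins asserted orthologous; its size (member count) is
    the central phylogenetic-spread statistic."""

    og_id: str
    members: list[ProteinRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def species(self) -> set[str]:
        return {m.species_id for m in self.members}

    def __iter__(self):
        return iter(self.members)


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomic lineage for one species, root first.

    ``level(k)`` is 1-based: for
    Bacteria;...;Enterobacteriaceae;Escherichia;Escherichia coli,
    level 6 is "Escherichia".
    """

    species_id: str
    levels: tuple[str, ...]

    def level(self, k: int) -> str:
        if k < 1 or k > len(self.levels):
            raise ValidationError(
                f"{self.species_id}: lineage has no level {k} (depth {len(self.levels)})"
            )
        return self.levels[k - 1]

    @property
    def domain(self) -> str:
        return self.levels[0]


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: (row_id, gapped sequence) pairs of
    equal length; gap character '-'."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("alignment with no rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValidationError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.rows)

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(row_id)

    def select_columns(self, columns: Sequence[int]) -> "Alignment":
        """New alignment keeping the given 1-based columns, in the given order."""
        idx = [c - 1 for c in columns]
        return Alignment(
            tuple((rid, "".join(seq[i] for i in idx)) for rid, seq in self.rows)
        )


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(header: str, where: str) -> tuple[str, str]:
    token = header.split()[0] if header.split() else ""
    parts = token.split("|")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise FormatError(
            f"{where}: malformed FASTA header {header!r}; expected 'species_id|protein_id'"
        )
    return parts[0], parts[1]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read ungapped protein records with ``species|protein`` headers.

    Sequences are uppercased; a single terminal '*' is stripped.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        species_id, protein_id = _parse_header(rec.description, f"{path} record {i}")
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if protein_id in seen:
            raise ValidationError(f"{path}: duplicate protein_id {protein_id!r}")
        seen.add(protein_id)
        records.append(ProteinRecord(protein_id, species_id, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=f"{r.species_id}|{r.protein_id}", description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_alignment_fasta(path: str | Path) -> Alignment:
    """Read a gapped FASTA alignment; row ids are the raw header tokens."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append((rec.id, str(rec.seq).upper()))
    if not rows:
        raise FormatError(f"{path}: empty alignment file")
    return Alignment(tuple(rows))


def write_alignment_fasta(alignment: Alignment, path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in alignment.rows]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV tables

def read_topology_tsv(path: str | Path) -> dict[str, TopologyAnnotation]:
    """TSV columns protein_id, start, end, label (1-based inclusive) ->
    per-protein annotations. Overlaps and unknown labels are errors."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "label": str})
    required = {"protein_id", "start", "end", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out: dict[str, TopologyAnnotation] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        intervals = tuple(
            (int(r.start), int(r.end), str(r.label)) for r in grp.itertuples()
        )
        try:
            out[str(pid)] = TopologyAnnotation(intervals)
        except ValidationError as exc:
            raise ValidationError(f"{path}: protein {pid}: {exc}") from exc
    return out


def write_topology_tsv(
    annotations: Mapping[str, TopologyAnnotation], path: str | Path
) -> None:
    rows = [
        {"protein_id": pid, "start": s, "end": e, "label": lab}
        for pid, ann in annotations.items()
        for s, e, lab in ann.intervals
    ]
    pd.DataFrame(rows, columns=["protein_id", "start", "end", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_og_tsv(path: str | Path) -> pd.DataFrame:
    """Ortholog-group membership table: og_id, protein_id, species_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"og_id", "protein_id", "species_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return df


def write_og_tsv(ogs: Iterable[OrthologGroup], path: str | Path) -> None:
    rows = [
        {"og_id": og.og_id, "protein_id": m.protein_id, "species_id": m.species_id}
        for og in ogs
        for m in og.members
    ]
    pd.DataFrame(rows, columns=["og_id", "protein_id", "species_id"]).to_csv(
        path, sep="\t", index=False
    )


def build_ortholog_groups(
    og_table: pd.DataFrame, records: Sequence[ProteinRecord]
) -> list[OrthologGroup]:
    """Join the membership table against parsed records.

    Raises on referential-integrity failures: a protein named in the table
    but absent from the FASTA, or a species mismatch. No row is silently
    dropped.
    """
    by_id = {r.protein_id: r for r in records}
    groups: dict[str, OrthologGroup] = {}
    for row in og_table.itertuples():
        rec = by_id.get(row.protein_id)
        if rec is None:
            raise ValidationError(
                f"OG {row.og_id}: protein {row.protein_id!r} not found in FASTA"
            )
        if rec.species_id != row.species_id:
            raise ValidationError(
                f"OG {row.og_id}: species mismatch for {row.protein_id!r} "
                f"({row.species_id!r} vs FASTA {rec.species_id!r})"
            )
        groups.setdefault(row.og_id, OrthologGroup(row.og_id)).members.append(rec)
    n_members = sum(g.size for g in groups.values())
    if n_members != len(og_table):
        raise ValidationError("membership rows lost during grouping")  # pragma: no cover
    return list(groups.values())


def read_lineage_tsv(path: str | Path) -> dict[str, Lineage]:
    """Lineage table: species_id, lineage (semicolon-separated, root first)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_id", "lineage"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out: dict[str, Lineage] = {}
    for row in df.itertuples():
        levels = tuple(part.strip() for part in row.lineage.split(";") if part.strip())
        if not levels:
            raise ValidationError(f"{path}: species {row.species_id}: empty lineage")
        out[row.species_id] = Lineage(row.species_id, levels)
    return out


def write_lineage_tsv(lineages: Mapping[str, Lineage], path: str | Path) -> None:
    rows = [
        {"species_id": lin.species_id, "lineage": ";".join(lin.levels)}
        for lin in lineages.values()
    ]
    pd.DataFrame(rows, columns=["species_id", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


def read_signal_tsv(path: str | Path) -> dict[str, bool]:
    """Signal-peptide flags: protein_id, signal_peptide (true/false/1/0)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "signal_peptide"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    truthy = {"true", "1", "yes"}
    falsy = {"false", "0", "no"}
    out: dict[str, bool] = {}
    for row in df.itertuples():
        val = str(row.signal_peptide).strip().lower()
        if val in truthy:
            out[row.protein_id] = True
        elif val in falsy:
            out[row.protein_id] = False
        else:
            raise FormatError(f"{path}: bad signal_peptide value {row.signal_peptide!r}")
    return out


def write_signal_tsv(flags: Mapping[str, bool], path: str | Path) -> None:
    rows = [
        {"protein_id": pid, "signal_peptide": str(bool(v)).lower()}
        for pid, v in flags.items()
    ]
    pd.DataFrame(rows, columns=["protein_id", "signal_peptide"]).to_csv(
        path, sep="\t", index=False
    )


def write_results_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) key-value configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data


def dump_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
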
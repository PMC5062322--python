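"""Shared fixtures: tiny hand-built proteins/groups and independent oracles."""

import itertools

import numpy as np
import pytest

from memevo.io_formats import (
    Alignment,
    OrthologGroup,
    ProteinRecord,
    TopologyAnnotation,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_protein(pid, species="SPEC1", seq="MKTAYIAKQR", topology=None, signal=None):
    return ProteinRecord(
        protein_id=pid,
        species_id=species,
        sequence=seq,
        topology=topology,
        signal_peptide=signal,
    )


def mp_protein(pid, species="SPEC1", length=30):
    """A membrane protein: 10 inside, 10 membrane, 10 outside residues."""
    topo = TopologyAnnotation(((1, 10, "I"), (11, 20, "M"), (21, 30, "O")))
    rng = np.random.default_rng(abs(hash(pid)) % 2**31)
    seq = "".join(AA[i] for i in rng.integers(0, 20, size=length))
    return make_protein(pid, species, seq, topology=topo)


def ws_protein(pid, species="SPEC1", length=30, signal=False):
    rng = np.random.default_rng(abs(hash(pid)) % 2**31)
    seq = "".join(AA[i] for i in rng.integers(0, 20, size=length))
    return make_protein(pid, species, seq, topology=TopologyAnnotation(()), signal=signal)


def brute_force_pi(rows, per_pair_denominator=True):
    """Independent O(n^2 L) re-computation of Nei's pi on gapped strings."""
    vals = []
    raw_diffs = []
    ncols = len(rows[0])
    for a, b in itertools.combinations(rows, 2):
        num = den = 0
        for ca, cb in zip(a, b):
            if ca in "-X" or cb in "-X":
                continue
            den += 1
            num += ca != cb
        if den:
            vals.append(num / den)
            raw_diffs.append(num)
    if not vals:
        raise ValueError("all pairs excluded")
    if per_pair_denominator:
        return sum(vals) / len(vals)
    return (sum(raw_diffs) / len(raw_diffs)) / ncols


def random_alignment(rng, n_rows=8, n_cols=40, gap_frac=0.1, ids=None):
    chars = list(AA)
    rows = []
    for i in range(n_rows):
        seq = [
            "-" if rng.random() < gap_frac else chars[rng.integers(0, 20)]
            for _ in range(n_cols)
        ]
        rows.append((ids[i] if ids else f"seq{i}", "".join(seq)))
    return Alignment(tuple(rows))


def fig8_toy():
    """The 20-column worked slicing example.

    The reference is present at all columns except 10-11 and 20; reading the
    annotation in reference-residue coordinates, residues 1-2 and 13-17 are
    inside, 6-7 outside, 3-9 (split 3-5 and 8-9) and 10-12 membrane-spanning.
    In alignment coordinates that is inside {1,2,15-19}, outside {6,7},
    membrane {3-5,8-9,12-14}, ignored {10,11,20}.
    """
    ref = "ACDEFGHIK" + "--" + "LMNPQRST" + "-"
    assert len(ref) == 20
    other1 = "ACDEFGHIKWWLMNPQRSTY"
    other2 = "ACDEYGHIKWWLMNPARSTY"
    aln = Alignment((("REF", ref), ("S1", other1), ("S2", other2)))
    ann = TopologyAnnotation(
        ((1, 2, "I"), (3, 5, "M"), (6, 7, "O"), (8, 9, "M"), (10, 12, "M"), (13, 17, "I"))
    )
    expected = {
        "inside": (1, 2, 15, 16, 17, 18, 19),
        "outside": (6, 7),
        "membrane": (3, 4, 5, 8, 9, 12, 13, 14),
        "ignored": (10, 11, 20),
    }
    return aln, ann, expected


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def mixed_og():
    """3 MP + 2 WS members across 5 species."""
    members = [mp_protein(f"P{i}", species=f"SP{i:03d}") for i in range(3)]
    members += [ws_protein(f"P{i}", species=f"SP{i:03d}") for i in range(3, 5)]
    return OrthologGroup("OG_MIX", members)
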
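"""Evolutionary-rate estimation for ortholog-group alignments.

Two estimators are provided:

* Nei's sequence diversity pi — the mean pairwise per-site proportion of
  differing residues across all unordered sequence pairs of an alignment.
  Gap handling follows the standard Nei convention of pairwise deletion:
  a column contributes to a pair only where both sequences have a real
  residue ('X' is treated as uninformative, like a gap). A switch allows
  dividing by the full alignment length instead.
* The mean branch length of a neighbor-joining tree built on the pairwise
  p-distance matrix. Branch lengths approximate substitutions per site, so
  their mean is an alternative per-group rate. Externally computed Newick
  trees can be supplied instead for parity with likelihood-based pipelines.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import AA_ALPHABET, Alignment, OrthologGroup
from . import stats_core

logger = logging.getLogger(__name__)

__all__ = [
    "DiversityError",
    "pairwise_p_distance",
    "nei_pi",
    "p_distance_matrix",
    "nj_tree",
    "mean_branch_length",
    "tree_rate",
    "alignment_from_og",
    "rate_compare",
]

_CODE = np.full(128, -1, dtype=np.int8)
for _i, _aa in enumerate(AA_ALPHABET):
    _CODE[ord(_aa)] = _i
# '-' and 'X' stay -1: incomparable


class DiversityError(ValueError):
    pass


def _encode_row(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[arr]


def _encode(alignment: Alignment) -> np.ndarray:
    return np.vstack([_encode_row(seq) for _, seq in alignment.rows])


def pairwise_p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing residues over co-ungapped columns of two
    equal-length gapped rows."""
    if len(row_a) != len(row_b):
        raise DiversityError("rows differ in length")
    a, b = _encode_row(row_a), _encode_row(row_b)
    comparable = (a >= 0) & (b >= 0)
    n = int(comparable.sum())
    if n == 0:
        raise DiversityError("no comparable (co-ungapped) columns")
    return float((a[comparable] != b[comparable]).sum()) / n


def _pair_stats(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For every unordered row pair: (n differing, n comparable)."""
    n = mat.shape[0]
    diffs = np.zeros((n, n))
    comps = np.zeros((n, n))
    valid = mat >= 0
    for i in range(n - 1):
        comparable = valid[i] & valid[i + 1 :]
        differing = comparable & (mat[i] != mat[i + 1 :])
        comps[i, i + 1 :] = comparable.sum(axis=1)
        diffs[i, i + 1 :] = differing.sum(axis=1)
    return diffs, comps


def nei_pi(alignment: Alignment, per_pair_denominator: bool = True) -> float:
    """Nei's pi: mean over all unordered pairs of the per-site difference.

    With ``per_pair_denominator`` (default) each pair is divided by its own
    number of comparable columns (pairwise deletion); otherwise by the full
    alignment length. Pairs with no comparable column are excluded; if every
    pair is excluded, pi is undefined and an error is raised.
    """
    if alignment.n_rows < 2:
        raise DiversityError("pi requires >= 2 sequences")
    mat = _encode(alignment)
    diffs, comps = _pair_stats(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    d, c = diffs[iu], comps[iu]
    usable = c > 0
    if not usable.any():
        raise DiversityError("pi undefined: no pair has comparable columns")
    if per_pair_denominator:
        return float(np.mean(d[usable] / c[usable]))
    return float(np.mean(d[usable]) / alignment.n_cols)


def p_distance_matrix(alignment: Alignment) -> tuple[np.ndarray, tuple[str, ...]]:
    """Symmetric pairwise p-distance matrix and row ids."""
    mat = _encode(alignment)
    diffs, comps = _pair_stats(mat)
    n = mat.shape[0]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if comps[i, j] == 0:
                raise DiversityError(
                    f"rows {alignment.ids[i]!r}/{alignment.ids[j]!r}: no comparable columns"
                )
            dm[i, j] = dm[j, i] = diffs[i, j] / comps[i, j]
    return dm, alignment.ids


def nj_tree(dm: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths produced by the NJ formulas are clamped to zero
    and the deficit transferred to the sibling branch, preserving the
    pairwise path length of the joined pair.
    """
    d = np.asarray(dm, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise DiversityError("nj_tree requires >= 2 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise DiversityError("distance matrix must be symmetric with zero diagonal")
    nodes = [TreeNode(name=str(i_)) for i_ in ids]
    if n == 2:
        root = TreeNode()
        for node in nodes:
            node.length = d[0, 1] / 2.0
            root.append(node)
        return root
    d = d.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        dij = sub[i_loc, j_loc]
        li = dij / 2.0 + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        gi, gj = active[i_loc], active[j_loc]
        parent = TreeNode()
        nodes[gi].length = float(li)
        nodes[gj].length = float(lj)
        parent.append(nodes[gi])
        parent.append(nodes[gj])
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (d[gi, :] + d[gj, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_d)] = new_d
        d[: len(new_d), -1] = new_d
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]
    ga, gb = active
    # attach the second remaining node under the first with the full
    # remaining distance, so terminal branch lengths are preserved exactly
    root, other = nodes[ga], nodes[gb]
    if root.is_tip():
        root, other = other, root
    other.length = float(max(d[ga, gb], 0.0))
    root.append(other)
    root.length = None
    return root


def mean_branch_length(tree: TreeNode) -> float:
    """Arithmetic mean of all edge lengths; the root edge is excluded."""
    lengths = [
        node.length if node.length is not None else 0.0
        for node in tree.traverse(include_self=False)
    ]
    if not lengths:
        raise DiversityError("tree has no edges")
    return float(np.mean(lengths))


def tree_rate(alignment: Alignment) -> float:
    """Mean branch length of the NJ tree on the alignment's p-distances."""
    dm, ids = p_distance_matrix(alignment)
    return mean_branch_length(nj_tree(dm, ids))


def alignment_from_og(og: OrthologGroup) -> Alignment:
    """Alignment view of an ortholog group whose member sequences are
    already aligned (equal length, e.g. indel-free simulation output)."""
    return Alignment(tuple((m.protein_id, m.sequence) for m in og.members))


def rate_compare(
    df: pd.DataFrame,
    value_col: str,
    group_col: str,
    groups: Sequence[str] | None = None,
    pair_col: str | None = None,
) -> dict:
    """Per-group rate summaries plus the appropriate two-group t-test.

    With ``pair_col`` (e.g. the OG id) the comparison is a paired t-test
    across complete pairs; otherwise Welch's unequal-variance test. Groups
    with fewer than 2 observations are excluded with a warning. Exactly two
    groups are required for a test; the test compares groups[0] - groups[1].
    """
    if groups is None:
        groups = sorted(df[group_col].unique())
    counts = {g: int((df[group_col] == g).sum()) for g in groups}
    kept = []
    for g in groups:
        if counts[g] < 2:
            logger.warning("group %r has %d observation(s); excluded", g, counts[g])
        else:
            kept.append(g)
    means = {
        g: float(df.loc[df[group_col] == g, value_col].mean()) for g in kept
    }
    out = {"means": means, "n": {g: counts[g] for g in kept}, "test": None}
    if len(kept) != 2:
        return out
    g0, g1 = kept
    if pair_col is not None:
        wide = df[df[group_col].isin(kept)].pivot_table(
            index=pair_col, columns=group_col, values=value_col
        ).dropna()
        out["n_pairs"] = len(wide)
        if len(wide) >= 2:
            out["test"] = stats_core.paired_t(wide[g0].to_numpy(), wide[g1].to_numpy())
    else:
        x = df.loc[df[group_col] == g0, value_col].to_numpy()
        y = df.loc[df[group_col] == g1, value_col].to_numpy()
        out["test"] = stats_core.welch_t(x, y)
    return out
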
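"""Nei's pi, NJ trees and rate comparison against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from memevo import diversity as dv
from memevo.io_formats import Alignment, ProteinRecord, TopologyAnnotation
from memevo.synthetic_data import SimulationConfig, evolve_og, generate_species_tree
from conftest import brute_force_pi, random_alignment


def aln(*rows):
    return Alignment(tuple((f"s{i}", r) for i, r in enumerate(rows)))


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("AAAA", "AAAA", 0.0),
            ("AAAA", "AAAT", 0.25),
            ("AA-A", "AATA", 0.0),  # the gapped column is skipped
            ("AXAA", "AAAA", 0.0),  # X carries no distance information
        ],
    )
    def test_cases(self, a, b, expected):
        assert dv.pairwise_p_distance(a, b) == expected

    def test_no_comparable_columns(self):
        with pytest.raises(dv.DiversityError):
            dv.pairwise_p_distance("A-", "-A")


class TestNeiPi:
    def test_identical_rows(self):
        assert dv.nei_pi(aln("ACD", "ACD", "ACD")) == 0.0

    def test_three_row_hand_value(self):
        # pair distances 0.5, 1.0, 0.5 -> mean 2/3
        assert dv.nei_pi(aln("AA", "AT", "TT")) == pytest.approx(2 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = random_alignment(rng, n_rows=int(rng.integers(3, 12)), n_cols=60)
        rows = [seq for _, seq in a.rows]
        assert dv.nei_pi(a) == pytest.approx(brute_force_pi(rows), abs=1e-12)
        assert dv.nei_pi(a, per_pair_denominator=False) == pytest.approx(
            brute_force_pi(rows, per_pair_denominator=False), abs=1e-12
        )

    def test_invariant_to_row_and_column_order(self, rng):
        a = random_alignment(rng, n_rows=6, n_cols=30)
        base = dv.nei_pi(a)
        perm_rows = Alignment(tuple(reversed(a.rows)))
        cols = rng.permutation(a.n_cols) + 1
        perm_cols = a.select_columns(list(cols))
        assert dv.nei_pi(perm_rows) == pytest.approx(base, abs=1e-12)
        assert dv.nei_pi(perm_cols) == pytest.approx(base, abs=1e-12)

    def test_aqueous_weighted_identity_gap_free(self, rng):
        """On gap-free alignments pi of concatenated slices is the exact
        column-count-weighted mean of the slice pi values."""
        inside = random_alignment(rng, n_rows=5, n_cols=12, gap_frac=0.0)
        outside = random_alignment(rng, n_rows=5, n_cols=30, gap_frac=0.0)
        merged = Alignment(
            tuple(
                (f"s{i}", inside.rows[i][1] + outside.rows[i][1]) for i in range(5)
            )
        )
        expected = (12 * dv.nei_pi(inside) + 30 * dv.nei_pi(outside)) / 42
        assert dv.nei_pi(merged) == pytest.approx(expected, abs=1e-12)

    def test_all_pairs_excluded(self):
        with pytest.raises(dv.DiversityError):
            dv.nei_pi(aln("A-", "-A"))


class TestNJTree:
    def test_two_taxa_split_evenly(self):
        tree = dv.nj_tree(np.array([[0, 0.4], [0.4, 0]]), ["a", "b"])
        lengths = sorted(t.length for t in tree.tips())
        assert lengths == pytest.approx([0.2, 0.2])

    def test_three_taxa_closed_form(self):
        dab, dac, dbc = 0.3, 0.5, 0.6
        tree = dv.nj_tree(
            np.array([[0, dab, dac], [dab, 0, dbc], [dac, 0.6, 0]]), ["A", "B", "C"]
        )
        by_name = {t.name: t.length for t in tree.tips()}
        assert by_name["A"] == pytest.approx((dab + dac - dbc) / 2)
        assert by_name["B"] == pytest.approx((dab + dbc - dac) / 2)
        assert by_name["C"] == pytest.approx((dac + dbc - dab) / 2)

    def test_additive_four_taxon_metric_recovered(self):
        # tree ((A:0.2,B:0.3):0.1,C:0.25,D:0.35) -> additive distances
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 0.5, 0.55, 0.65],
                [0.5, 0.0, 0.65, 0.75],
                [0.55, 0.65, 0.0, 0.6],
                [0.65, 0.75, 0.6, 0.0],
            ]
        )
        tree = dv.nj_tree(d, ids)
        for i in range(4):
            for j in range(i + 1, 4):
                got = tree.find(ids[i]).distance(tree.find(ids[j]))
                assert got == pytest.approx(d[i, j], abs=1e-12)

    def test_against_skbio_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 1, size=(6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(6)]
        ours = dv.nj_tree(d, ids)
        ref = skbio_nj(DistanceMatrix(d, ids))
        for i in range(6):
            for j in range(i + 1, 6):
                a = ours.find(ids[i]).distance(ours.find(ids[j]))
                b = ref.find(ids[i]).distance(ref.find(ids[j]))
                assert a == pytest.approx(b, abs=1e-9)

    def test_rejects_tiny_or_asymmetric_input(self):
        with pytest.raises(dv.DiversityError):
            dv.nj_tree(np.zeros((1, 1)), ["a"])
        with pytest.raises(dv.DiversityError):
            dv.nj_tree(np.array([[0, 1.0], [2.0, 0]]), ["a", "b"])


class TestMeanBranchLength:
    def test_two_leaf(self):
        tree = dv.nj_tree(np.array([[0, 0.4], [0.4, 0]]), ["a", "b"])
        assert dv.mean_branch_length(tree) == pytest.approx(0.2)

    def test_star(self):
        from skbio import TreeNode

        root = TreeNode(name="r")
        for name, length in (("a", 0.1), ("b", 0.2), ("c", 0.3)):
            root.append(TreeNode(name=name, length=length))
        assert dv.mean_branch_length(root) == pytest.approx(0.2)

    def test_traversal_oracle_on_nj_fixture(self, rng):
        a = random_alignment(rng, n_rows=7, n_cols=80, gap_frac=0.0)
        d, ids = dv.p_distance_matrix(a)
        tree = dv.nj_tree(d, ids)
        total, count = 0.0, 0
        stack = list(tree.children)
        while stack:
            node = stack.pop()
            total += node.length or 0.0
            count += 1
            stack.extend(node.children)
        assert dv.mean_branch_length(tree) == pytest.approx(total / count, abs=1e-12)


class TestRateMonotonicity:
    def test_pi_increases_with_generating_rate(self):
        """Mean pi tracks the simulator's substitution rate across a
        5-point ladder (50 groups per rung)."""
        from scipy.stats import spearmanr

        rates = [0.05, 0.15, 0.3, 0.5, 0.8]
        all_rates, all_pis = [], []
        means = []
        for rate in rates:
            cfg = SimulationConfig(
                n_clades=2,
                species_per_clade=3,
                n_ogs_per_class={"cytosolic_WS": 50},
                protein_length=80,
                mp_layout=(("I", 80),),
                rate_cytosolic=rate,
                loss_prob={"cytosolic_WS": 0.0},
                seed=100 + int(rate * 100),
            )
            tree, _ = generate_species_tree(cfg)
            rng = np.random.default_rng(cfg.seed)
            pis = []
            for k in range(50):
                anc = ProteinRecord(
                    f"anc{k}",
                    "ANC",
                    "".join("ACDEFGHIKL"[i % 10] for i in range(80)),
                    topology=TopologyAnnotation(()),
                )
                og = evolve_og(anc, tree, cfg, rng, "cytosolic_WS")
                pis.append(dv.nei_pi(dv.alignment_from_og(og)))
            means.append(np.mean(pis))
            all_rates += [rate] * 50
            all_pis += pis
        assert means == sorted(means)
        rho = spearmanr(all_rates, all_pis).statistic
        assert rho > 0.9


class TestRateCompare:
    def test_identical_groups_t_zero(self):
        df = pd.DataFrame(
            {
                "og": list("abcd") * 2,
                "region": ["inside"] * 4 + ["outside"] * 4,
                "pi": [0.1, 0.2, 0.3, 0.4] * 2,
            }
        )
        res = dv.rate_compare(df, "pi", "region", pair_col="og")
        assert res["test"].t == 0.0

    def test_small_group_excluded(self):
        df = pd.DataFrame(
            {"region": ["a", "a", "b"], "pi": [0.1, 0.2, 0.3]}
        )
        res = dv.rate_compare(df, "pi", "region")
        assert res["test"] is None and list(res["means"]) == ["a"]
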
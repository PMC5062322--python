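"""Dereplication, per-species spread means, group ratios, cross-domain
filtering and the spread logistic."""

import numpy as np
import pandas as pd
import pytest

from memevo import conservation_spread as cs
from memevo.io_formats import Lineage, OrthologGroup, ValidationError
from memevo.synthetic_data import SimulationConfig, generate_ogs
from memevo.topology_classify import MP, WS
from conftest import mp_protein, ws_protein


def lineage(species, domain="Bacteria", clade="CladeA", sub=None):
    return Lineage(
        species,
        (domain, "phy", "cls", "ord", clade, sub or f"{clade}.s{species}", species),
    )


class TestDereplicate:
    def _og(self, species_list):
        return OrthologGroup(
            "OG1", [ws_protein(f"p_{s}", s) for s in species_list]
        )

    def test_one_clade_collapses_to_one(self):
        og = self._og([f"S{i}" for i in range(5)])
        lineages = {f"S{i}": lineage(f"S{i}", sub="CladeA.sub0") for i in range(5)}
        out = cs.dereplicate_og(og, lineages, rng=np.random.default_rng(0))
        assert out.size == 1

    def test_three_clades_keep_three(self):
        og = self._og(["A", "B", "C"])
        lineages = {s: lineage(s, sub=f"sub_{s}") for s in "ABC"}
        out = cs.dereplicate_og(og, lineages, rng=np.random.default_rng(0))
        assert out.size == 3

    def test_deterministic_under_seed(self):
        og = self._og([f"S{i}" for i in range(6)])
        lineages = {f"S{i}": lineage(f"S{i}", sub=f"sub{i % 2}") for i in range(6)}
        picks = [
            tuple(
                m.protein_id
                for m in cs.dereplicate_og(og, lineages, rng=np.random.default_rng(4)).members
            )
            for _ in range(2)
        ]
        assert picks[0] == picks[1]

    def test_idempotent_and_never_grows(self):
        og = self._og([f"S{i}" for i in range(6)])
        lineages = {f"S{i}": lineage(f"S{i}", sub=f"sub{i % 3}") for i in range(6)}
        once = cs.dereplicate_og(og, lineages, rng=np.random.default_rng(1))
        twice = cs.dereplicate_og(once, lineages, rng=np.random.default_rng(99))
        assert [m.protein_id for m in twice.members] == [
            m.protein_id for m in once.members
        ]
        assert once.size <= og.size

    def test_preferred_species_wins(self):
        og = self._og(["S0", "S1"])
        lineages = {s: lineage(s, sub="same") for s in ("S0", "S1")}
        out = cs.dereplicate_og(
            og, lineages, rng=np.random.default_rng(0), preferred_species=("S1",)
        )
        assert out.members[0].species_id == "S1"

    def test_missing_lineage_names_species(self):
        og = self._og(["S0", "GHOST"])
        lineages = {"S0": lineage("S0")}
        with pytest.raises(ValidationError, match="GHOST"):
            cs.dereplicate_og(og, lineages, rng=np.random.default_rng(0))


class TestSpeciesMeans:
    def test_hand_means_and_sem(self):
        # species X: WS groups of sizes 4 and 6, MP group of size 2
        ogs = []
        ws_a = [ws_protein(f"a{i}", f"O{i}") for i in range(3)] + [ws_protein("aX", "X")]
        ws_b = [ws_protein(f"b{i}", f"O{i}") for i in range(5)] + [ws_protein("bX", "X")]
        mp_c = [mp_protein("cX", "X"), mp_protein("c1", "O1")]
        ogs = [
            OrthologGroup("A", ws_a),
            OrthologGroup("B", ws_b),
            OrthologGroup("C", mp_c),
        ]
        df = cs.species_mean_sizes(ogs, species=["X"])
        row = df.iloc[0]
        assert row["ws_mean"] == pytest.approx(5.0)
        assert row["mp_mean"] == pytest.approx(2.0)
        assert row["ws_sem"] == pytest.approx(1.0)  # sd(4,6)/sqrt(2) = 1

    def test_absent_species_excluded_with_warning(self, caplog):
        ogs = [OrthologGroup("A", [ws_protein("p", "S1")])]
        with caplog.at_level("WARNING"):
            df = cs.species_mean_sizes(ogs, species=["S1", "NOPE"])
        assert list(df["species_id"]) == ["S1"]
        assert "NOPE" in caplog.text

    def test_ws_exceeds_mp_for_every_species_on_default_config(self):
        ds = generate_ogs(SimulationConfig(seed=3))
        df = cs.species_mean_sizes(ds.ogs)
        assert len(df) == 24
        assert (df["ws_mean"] > df["mp_mean"]).all()


class TestGroupRatios:
    def test_hand_ratio(self):
        means = pd.DataFrame(
            [
                {"species_id": "A", "ws_mean": 5.4, "mp_mean": 2.0},
                {"species_id": "B", "ws_mean": 3.0, "mp_mean": 3.0},
            ]
        )
        df, anova = cs.group_ratios(means, {"A": "g1", "B": "g1"})
        assert df.set_index("species_id")["ratio"]["A"] == pytest.approx(2.7)
        assert df.set_index("species_id")["ratio"]["B"] == pytest.approx(1.0)

    def test_zero_mp_mean_excluded(self, caplog):
        means = pd.DataFrame(
            [
                {"species_id": "A", "ws_mean": 5.0, "mp_mean": 0.0},
                {"species_id": "B", "ws_mean": 4.0, "mp_mean": 2.0},
            ]
        )
        with caplog.at_level("WARNING"):
            df, _ = cs.group_ratios(means, {})
        assert list(df["species_id"]) == ["B"]

    def test_monotone_ratios_with_scaled_loss(self):
        """Organism groups whose membrane-loss excess scales 3:2:1 produce
        monotonically decreasing WS/MP ratios."""
        ratios = []
        for i, mp_loss in enumerate((0.45, 0.3, 0.15)):
            cfg = SimulationConfig(
                n_clades=3,
                species_per_clade=4,
                n_ogs_per_class={"cytosolic_WS": 150, "MP": 150},
                protein_length=30,
                mp_layout=(("I", 10), ("M", 10), ("O", 10)),
                loss_prob={"cytosolic_WS": 0.05, "MP": mp_loss},
                seed=30 + i,
            )
            ds = generate_ogs(cfg)
            means = cs.species_mean_sizes(ds.ogs)
            ratios.append((means["ws_mean"] / means["mp_mean"]).mean())
        assert ratios[0] > ratios[1] > ratios[2]


class TestCrossDomain:
    def test_set_logic(self):
        lineages = {
            "ECOLI": lineage("ECOLI", domain="Bacteria"),
            "HUMAN": lineage("HUMAN", domain="Eukaryota"),
            "METAC": lineage("METAC", domain="Archaea"),
        }
        only_bact = OrthologGroup("A", [ws_protein("p1", "ECOLI")])
        euk_bact = OrthologGroup(
            "B", [ws_protein("p2", "HUMAN"), ws_protein("p3", "ECOLI")]
        )
        euk_arch = OrthologGroup(
            "C", [ws_protein("p4", "HUMAN"), ws_protein("p5", "METAC")]
        )
        kept = cs.filter_cross_domain([only_bact, euk_bact, euk_arch], lineages)
        assert [g.og_id for g in kept] == ["B", "C"]

    def test_matches_brute_force_on_labelled_fixture(self, rng):
        domains = ["Bacteria", "Archaea", "Eukaryota"]
        lineages = {
            f"S{i}": lineage(f"S{i}", domain=domains[i % 3]) for i in range(12)
        }
        ogs = []
        for k in range(30):
            members = [
                ws_protein(f"g{k}_{i}", f"S{i}")
                for i in rng.choice(12, size=rng.integers(1, 6), replace=False)
            ]
            ogs.append(OrthologGroup(f"OG{k}", members))
        kept = {g.og_id for g in cs.filter_cross_domain(ogs, lineages)}
        expected = set()
        for g in ogs:
            doms = {lineages[m.species_id].domain for m in g.members}
            if "Eukaryota" in doms and doms & {"Bacteria", "Archaea"}:
                expected.add(g.og_id)
        assert kept == expected


class TestSpreadLogistic:
    def test_bins_hand_fixture(self):
        table = pd.DataFrame(
            {
                "og_id": [f"o{i}" for i in range(20)],
                "dereplicated_size": [3] * 10 + [9] * 10,
                "og_class": [MP] * 5 + [WS] * 5 + [MP] * 2 + [WS] * 8,
            }
        )
        fit, bins = cs.spread_logistic(table, max_taxa=10)
        # sizes 3/10 -> bin 4; 9/10 -> bin 10 (0.9 is included in the last bin)
        assert bins.loc[bins["bin"] == 4, "n_ogs"].item() == 10
        assert bins.loc[bins["bin"] == 4, "proportion_mp"].item() == pytest.approx(0.5)
        assert bins.loc[bins["bin"] == 10, "n_ogs"].item() == 10
        assert bins.loc[bins["bin"] == 10, "proportion_mp"].item() == pytest.approx(0.2)
        assert bins["n_ogs"].sum() == 20

    def test_min_clade_filter_applied(self):
        table = pd.DataFrame(
            {
                "og_id": ["a", "b"],
                "dereplicated_size": [2, 5],
                "og_class": [MP, WS],
            }
        )
        _, bins = cs.spread_logistic(table, max_taxa=10)
        assert bins["n_ogs"].sum() == 1

    def test_one_class_input_fits_nothing_but_bins(self):
        table = pd.DataFrame(
            {
                "og_id": [f"o{i}" for i in range(12)],
                "dereplicated_size": np.arange(3, 15),
                "og_class": [WS] * 12,
            }
        )
        fit, bins = cs.spread_logistic(table, max_taxa=15)
        assert fit is None
        assert bins["n_ogs"].sum() == 12

    def test_negative_slope_under_differential_loss(self):
        cfg = SimulationConfig(
            n_clades=6,
            species_per_clade=4,
            n_ogs_per_class={"cytosolic_WS": 150, "MP": 150},
            protein_length=30,
            mp_layout=(("I", 10), ("M", 10), ("O", 10)),
            loss_prob={"cytosolic_WS": 0.05, "MP": 0.4},
            seed=11,
        )
        ds = generate_ogs(cfg)
        table = cs.build_spread_table(ds.ogs, ds.lineages)
        fit, _ = cs.spread_logistic(
            table, max_taxa=cs.count_level_clades(ds.lineages)
        )
        assert fit is not None and fit.converged
        assert fit.slope < 0
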
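# memevo

Conservation and evolutionary-rate analysis of **membrane proteins (MP)
versus water-soluble proteins (WS)** across ortholog groups.

Membrane proteins sit at the interface between the cell and its
surroundings. Because the extracellular environment changes far more than
the homeostatic cytosol, outward-facing proteins and protein regions are
expected to evolve faster and to be lost more often as lineages change
niche. `memevo` is a toolkit for quantifying that pattern in ortholog-group
data: it measures how widely protein families are shared across a taxonomy,
how fast they diverge (overall and per topological region of a membrane
protein), and how often predicted ancestral genes have been lost within
clades of closely related species. A built-in simulator generates ortholog
groups evolving under region-specific substitution rates and class-specific
gene loss, so every analysis can be validated against known ground truth.

It is aimed at comparative genomicists working with ortholog-group exports
(OMA-style membership tables), per-residue membrane-topology annotations
(PDBTM/TMHMM-style inside/membrane/outside labels) and signal-peptide
predictions.

## What it computes

**Phylogenetic spread.** The size of an ortholog group (OG) — the number of
species with a detectable ortholog — measures how widely the family is
conserved. Groups are *dereplicated* to one representative per clade at the
sixth taxonomic level (e.g. *Escherichia* for *E. coli*, Deuterostomia for
humans) to avoid oversampling densely sequenced lineages. Per species, mean
OG size is compared between MP and WS proteins; across species the WS/MP
ratio is compared between organismal groups by one-way ANOVA with ω².
The probability that a group is membrane-bound is modelled as a
quasi-binomial logistic regression on its dereplicated size (strict-majority
census for the group's MP/WS class), with independently binned MP
proportions as a cross-check.

**Divergence rates.** Nei's sequence diversity

&nbsp;&nbsp;&nbsp;&nbsp;π = mean over all sequence pairs of the per-site
proportion of differing residues (pairwise deletion for gaps),

plus an alternative estimate: the mean branch length of a neighbor-joining
tree built on the pairwise p-distance matrix. For membrane proteins, a
reference sequence's per-residue topology is mapped onto the alignment and
the columns are *sliced* into inside-facing, membrane-spanning,
outside-facing and aqueous (inside+outside) sub-alignments, giving
region-resolved rates. Paired t-tests (with effect size
r = √(t²/(t²+df))) compare regions within groups.

**Extracellularity.** Water-soluble groups are split into cytosolic and
extracellular by a strict-majority signal-peptide census; membrane groups
are binned by the fraction of their residues that face outside. Mean OG
size per bin is regressed on the bin midpoint.

**Ancestral loss.** Within clades of ≥10 closely related species (shared
fifth-level name), groups shared by a strict majority of the clade are
inferred ancestral; missing members are counted as gene losses. Mean
sharing proportions of MP vs WS ancestral groups are compared per clade
(Welch) and across clades (paired t).

## Worked example

Run the full pipeline on a synthetic dataset of 4 clades × 10 species with
60 cytosolic-WS, 30 extracellular-WS and 60 MP ortholog groups:

```bash
cat > demo.yaml <<'EOF'
n_clades: 4
species_per_clade: 10
n_ogs_per_class: {cytosolic_WS: 60, extracellular_WS: 30, MP: 60}
EOF
memevo run-all --config demo.yaml --out demo_run --seed 7
```

Key numbers from `demo_run` (your output will be identical for the same
seed):

* `diversity/rate_comparisons.json` — whole-protein π is higher for MP
  than WS (0.474 vs 0.404; Welch t = 7.28, p = 9.0·10⁻¹¹), and within
  membrane proteins the outside-facing slices diverge much faster than the
  inside-facing ones (π 0.830 vs 0.483; paired t = 72.7 over 60 groups),
  matching the generating rates (outside 0.6 > inside 0.2 > membrane 0.1
  substitutions/site/branch).
* `loss/loss_summary.json` — ancestral MP groups are shared by a smaller
  proportion of each clade than WS groups in 4 of 4 clades (paired
  t = 13.6, p = 8.6·10⁻⁴), reflecting the simulated loss probabilities
  (MP 0.30 vs cytosolic WS 0.05).
* `spread/logistic_fit.json` — the quasi-binomial slope of membrane-ness
  on dereplicated group size is negative (−0.183, z = −1.71 at this small
  demo scale): widely shared proteins are less likely to be membrane-bound.
* `summary.md` collects these tables in one report.

Every subcommand (`simulate`, `classify`, `spread`, `pi`, `tree-rate`,
`slice`, `loss`, `stats`, `run-all`, `report`) is a thin wrapper over a
library function with identical results; see `docs/methods.md` for the
model and its assumptions.

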
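# Methods

This note documents the models, conventions and numerical choices behind
`memevo`, and what the synthetic-data generator does and does not emulate.

## Data model and coordinates

All on-disk coordinates (topology TSVs, column maps) are 1-based inclusive;
conversion to Python's 0-based half-open convention is isolated in
`io_formats`. FASTA headers use the fixed dialect `species_id|protein_id`
so sequence files join against membership and lineage tables without a
lookup table. Topology labels are I (inside-facing), M (membrane-spanning),
O (outside-facing), U (unknown); residues not covered by any interval are
implicitly U, because experimental structures frequently have unresolved
loops and an absent label carries no information.

## Classification

A protein is MP iff its topology contains at least one M interval —
mirroring topology predictors, which only assert positives; a protein with
no annotation at all is WS (with a logged warning). Group-level MP/WS and
signal-peptide calls are strict-majority censuses over members; ties
resolve to WS / negative, the conservative direction. The refined
three-way split is membrane ≻ extracellular (signal census positive)
≻ cytosolic; the membrane call takes precedence because "extracellular"
is defined as secreted *and not membrane-bound*. Signal-peptide flags are
inputs, never computed from sequence: upstream predictors are unreliable in
some taxa (e.g. archaea), and the pipeline accepts per-species missingness
(absent flag = negative).

Extracellularity bins: membrane groups are placed in ten equal-width bins
of their outside-facing residue fraction (Σ O residues / Σ lengths over MP
members); the last bin [0.9, 1.0] is closed so a fraction of exactly 1
lands in it, where forced extracellular-WS groups also go; cytosolic WS
groups are forced into the first bin. Empty bins are reported as missing
and excluded from the size-vs-midpoint regression.

## Diversity estimation

Nei's π is the mean over all unordered sequence pairs of the per-site
proportion of differing residues. Gap handling is pairwise deletion (only
co-ungapped columns count, the standard Nei convention, robust to ragged
alignment ends); 'X' residues are treated as uninformative, like gaps. The
per-pair denominator is each pair's comparable-column count, which keeps
π ≤ 1; dividing by the full alignment length instead is available via
`nei_pi(..., per_pair_denominator=False)` since the convention is genuinely
ambiguous in parts of the literature. Pairs with no comparable column are
excluded; π is undefined (an error) when every pair is excluded.

The tree-based rate is the arithmetic mean of all branch lengths (root
edge excluded) of a neighbor-joining tree built on the pairwise p-distance
matrix. NJ replaces likelihood tree inference deliberately: the analyses
only use rank agreement between π and the tree rate, which NJ preserves,
and it removes an external binary dependency. Negative NJ branch lengths
are clamped to zero with the deficit transferred to the sibling branch,
preserving the joined pair's path length. Externally computed Newick trees
(e.g. from a likelihood program) can be supplied to `tree-rate --newick`
for exact parity with likelihood-based pipelines.

## Alignment slicing

Topology annotations index the residues of a reference sequence, not
alignment columns. Slicing maps each reference residue to its column
(strictly increasing over the reference's non-gap columns), routes each
column to the slice named by its residue's label, and ignores (a) columns
where the reference is gapped and (b) columns whose residue is U or
unannotated. The column-conservation identity |inside| + |outside| +
|membrane| + |ignored reference-present| = |reference-present columns| is
asserted on every call. The aqueous slice is the inside columns followed by
the outside columns; π is column-order invariant, so the order is purely a
reproducibility convention. Proteins whose annotation lacks both an I and
an O interval are skipped entirely — an undifferentiated aqueous label
cannot support the inside/outside contrast. When several annotated
references match the same group, the one whose whole alignment has the
lowest π (best alignment) is kept, ties broken lexicographically.

In the worked 20-column toy example (see `tests/conftest.py::fig8_toy`),
one annotated membrane-list position lies beyond the example's 20 columns
and is treated as a typographic artifact; the encoded intervals cover only
in-range positions, under which the reference-residue and alignment-column
readings of the example coincide.

## Statistics

* Paired t on differences (df = n−1) and Welch's t with
  Welch–Satterthwaite df; both carry the correlation-scale effect size
  r = √(t²/(t²+df)), computed from t and df — not from raw data — so
  reported (t, df) pairs reproduce reported r values exactly.
* One-way ANOVA reports ω² = (SS_b − df_b·MS_w)/(SS_t + MS_w), clamped at
  0 (the standard small-F convention).
* The quasi-binomial logistic fit uses IRLS (logit link, relative
  tolerance 1e-8, ≤100 iterations, via statsmodels GLM) with dispersion
  estimated as Pearson χ²/(n−2) and standard errors scaled by its square
  root. Perfect or quasi-separation is reported as non-convergence with
  flagged (NaN) coefficients rather than a spuriously huge slope.
* p-values come from the t/F distributions (regularized incomplete beta
  underneath); extreme p may underflow to 0, which is acceptable since
  only t, df and r feed downstream decisions.
* Per-clade loss tests are deliberately uncorrected for multiple testing,
  matching the single-clade significance-tier convention; callers can apply
  `stats_core.benjamini_hochberg` if desired.

## Spread analyses

Dereplication keeps one member per distinct level-6 clade name, preferring
species from a configurable well-annotated list, otherwise choosing
uniformly at random under the run seed; it is idempotent and never
increases a group's size. Only groups spanning ≥3 dereplicated clades
enter the logistic fit. Binning for the fit's visual cross-check uses ten
equal-width intervals of dereplicated size divided by the total number of
level-6 clades in the dataset (the attainable maximum); the bins are
computed from the same rows but independently of the fit.

Per-species mean sizes count each group once per member species (a group
shared by several focal species contributes to each). The WS/MP ratio per
species excludes species with no or zero MP mean.

## Ancestral-loss census

Clades are maximal groups of species sharing the fifth-level lineage name
with ≥10 members. A group is ancestral to a clade when shared by strictly
more than half of the clade's species ("more than half"); the inclusive
reading (≥ half, which differs only at even clade sizes) is available via
`threshold="at_least"`. Raising the threshold can only remove groups. The
per-clade comparison is a two-sample Welch test on the sharing
*proportions*; proportions and raw counts differ only by the constant clade
size, so the choice does not affect t. Tiers: MP≥WS, MP<WS not
significant, MP<WS with p<0.05.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
real sequence evolution:

* **Tree**: a star of clade stars with unit branch lengths — `n_clades`
  clades × `species_per_clade` species. Lineages are 7 levels deep; level 5
  names the clade, level 6 subdivides it into pairs of species, and domains
  cycle Bacteria/Archaea/Eukaryota across clades (eukaryotic clades
  alternate unicellular/multicellular organism-group labels).
* **Evolution**: substitution-only. Along a branch of length ℓ each site
  substitutes with probability 1 − exp(−rate·ℓ), drawing uniformly among
  the 19 alternative residues (Jukes–Cantor-like exchangeability). The
  per-site rate is the site's region rate for MP proteins and the class
  rate for WS proteins. No indels means every group's sequences are already
  aligned, removing any external aligner from the loop, and the closed form
  for the expected p-distance enables analytic tests.
* **Loss**: applied independently at the leaves only, with class-specific
  probability; internal-branch loss is not modelled (leaf loss is
  sufficient to create the presence/absence pattern the census detects).
  Groups losing every copy keep their ground-truth row (n_extant = 0) but
  produce no sequences.

Defaults (the package's reference study conditions): 6 clades × 4 species;
200 cytosolic-WS, 100 extracellular-WS and 200 MP groups; protein length
120 with MP layout I15/M20/O15/M20/I15/M20/O15 (30 inside, 60 membrane, 30
outside residues — a typical polytopic helical topology at a tractable
length); region rates inside 0.2, membrane 0.1, outside 0.6
substitutions/site/branch (membrane-spanning cores under the strongest
packing constraint, outside-facing loops under environmental adaptation);
class rates cytosolic 0.12 and extracellular 0.22, below and near the MP
site-average of 0.25, so that whole-protein diversity orders cytosolic <
extracellular < membrane; loss probabilities cytosolic 0.05, MP 0.30,
extracellular 0.40, ordering spread cytosolic > MP > extracellular. These
orderings encode the expected biology — divergence and loss both increase
with exposure to the extracellular environment, with membrane proteins
overall fastest-diverging and extracellular proteins most often lost.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: indels and alignment error, site-rate
heterogeneity beyond the region labels, non-uniform amino-acid
exchangeabilities, horizontal gene transfer, correlated loss across
related species, taxon-sampling bias, and errors in topology or
signal-peptide prediction. Tests on synthetic data demonstrate that the
estimators recover the generating structure, not that the biological
conclusions hold.

## Problem sizes and determinism

Everything is seeded: a single run seed fans out to per-stage child seeds
by stable hashing of stage names, so stage randomness is independent of
execution order; identical config+seed reproduces byte-identical outputs.
Validation suites use deliberately modest problem sizes chosen to give the
assertions comfortable statistical margins: rate-ordering recovery uses 100
MP groups over 20 species; loss recovery uses 35 clades of 12 species with
100 groups per class per clade; the null-logistic check uses 100 runs of 6
clades × 4 species with 100 groups per class at length 60; test calibration
uses 1,000 replicates of 20-group samples over 2 clades × 3 species at
length 100.

## Known limitations

* NJ mean branch length is a relative rate proxy; it is not calibrated to
  substitutions per site under a named substitution model.
* The quasi-binomial fit reports NaN under separation instead of a
  penalized estimate; strongly separated inputs (tiny datasets with
  extreme loss differentials) need larger simulations, not a different
  flag.
* ω² from very small group counts is clamped at 0 rather than reported
  negative.
* The census attributes every absence within a clade to loss; divergence
  beyond recognition within a tight clade is assumed negligible, which is
  the analysis's stated premise rather than a tested fact.
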
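# Methods

## The model

Every computation reduces to constraint-based analysis of a stoichiometric
network at steady state: find fluxes `v` with `S v = 0` and
`lb ≤ v ≤ ub`, maximising the biomass pseudo-reaction (its flux is the
specific growth rate, h⁻¹; all other fluxes are mmol gDCW⁻¹ h⁻¹).
Exchange reactions are written as drains (metabolite → ∅), so uptake is a
negative flux; applying a medium sets each listed exchange's lower bound to
minus its uptake magnitude and closes uptake on every unlisted exchange
(minimal-medium semantics — required for single-omission auxotrophy tests
to be meaningful). The non-growth-associated maintenance (NGAM) reaction is
held at a lower bound of 1 mmol gDCW⁻¹ h⁻¹ by default (configurable).

LPs and MILPs are solved with HiGHS through scipy, which is deterministic;
feasibility tolerance 1e-9, and any flux below 1e-6 is reported as zero.
Phenotype thresholds are deliberately strict on both sides: *growth* means
rate > 0.01 h⁻¹, *auxotrophy* means rate < 0.01 h⁻¹ on omission; a rate of
exactly 0.01 is neither, and is logged as indeterminate rather than
silently classified. Because the flux vector at a degenerate FBA optimum is
solver-dependent, any question that needs a unique answer (secretion
capability, core-fluxome activity) is asked through FVA ranges rather than
a single FBA solution; the FBA-based secreted set is documented as
potentially degenerate.

## Template QC

Mass/charge balance is computed in exact rational arithmetic (coefficients
as `Fraction`s), so the report is free of float artifacts; exchange,
demand, sink and biomass reactions are exempt by construction, and any
reaction touching a pseudo-element metabolite (R-groups) is exempted with a
warning, since biomass-style pseudo-chemistry is never balanceable.
The TIC (thermodynamically infeasible cycle) check closes every exchange,
relaxes forced lower bounds (NGAM) so the all-zero flux vector is feasible,
and runs objective-free FVA; any internal reaction whose range exceeds
1e-6 — above solver noise, below any meaningful flux — can only be fed by
an internal loop. Reaction directionality is taken as given in the input
SBML; no thermodynamic re-curation is attempted.

## Strain mapping

The pipeline's contract starts at a similarity table (strain gene,
reference allele, percent identity in both search directions, mutual-best
flag); it never runs an aligner, which keeps it download-free and exactly
testable. An allele is present iff a hit is mutual-best **and** the weaker
direction reaches the threshold; 70 % is inclusive (the common BBH
convention), and ties among equally-best hits are the upstream search's
problem — the table already encodes its resolution. GPR rules are held in
disjunctive normal form because one reaction can carry several distinct
allele sets; standard SBML GPR strings cannot express this, hence the
sidecar TSV (one row per alternative, alleles semicolon-joined).

## Gapfilling

Minimal-addition repair is formulated as a MILP: continuous fluxes for the
union of the draft and all absent template reactions, one binary `y_i` per
candidate gating its bounds (`lb_i·y_i ≤ v_i ≤ ub_i·y_i`), steady state,
biomass ≥ threshold (plus a 1e-4-relative margin so the repaired optimum is
strictly above the growth threshold), minimising `Σ w_i y_i` with uniform
unit costs by default. On small instances the result is certifiably
cardinality-minimal (the tests compare against size-ordered subset search).
If the solver exceeds its time limit (60 s per strain by default) a
deterministic greedy pass adds every candidate and attempts single-reaction
removals in lexicographic order; the result is functional and set-minimal
but flagged `certified_minimal=False`. Whether the original large-scale
workflow filled to a growth threshold or to bare feasibility is not
something the inputs decide; the threshold semantics keeps one consistent
growth definition across gapfilling and phenotype calls.

## Partitioning and niche statistics

Reaction frequency is the unweighted percent of strains carrying a
reaction. Boundary semantics are literal: core is strictly *F* > 99, so
*F* = 99 is accessory, as is *F* = 15; *F* = 0 reactions form a reported
but unclassified bin. Unique reactions are exclusive to one species
regardless of how many of its strains carry them. Intra-species partitions
reuse the same thresholds over each species' strains, with percentages over
that species' observed reactome.

PERMANOVA uses squared Jaccard distances: `SS_total = Σ_{i<j} d²_ij / N`,
within-group sums analogously per group, pseudo-F =
`(SS_between/(a−1))/(SS_within/(N−a))`. When the number of distinct
labelings is ≤ 10 000 the permutation distribution is enumerated
exhaustively and the p-value is exact; otherwise 999 seeded permutations
are drawn and the p-value includes the observed labeling (so it is never
below 1/(n+1)). Enrichment is one-vs-rest over labeled strains, restricted
to niches with more than 10 strains (read strictly: ≥ 11). The odds ratio
is reported in natural log; the conventional "log-odds above five"
screening threshold is exposed as a flag since exclusive reactions are
compared on corrected cells — a Haldane–Anscombe 0.5 is added to all four
cells only when some cell is zero, without which exclusivity would give
infinite odds ratios. Fisher and chi-square go through scipy; PCA
(column-centred 0/1 values, no scaling, three components by default, signs
fixed by making each component's largest-magnitude loading positive) and
k-means (seeded) through scikit-learn. Raw p-values are reported without
multiple-testing correction.

## Validation metrics

Which phenotype is "positive" differs between assays (growth for
carbon-source tests, essentiality for auxotrophy tests), so polarity is the
caller's explicit choice when building the confusion counts. Rate metrics
are percents, F-score stays on [0, 1], and any metric with a zero
denominator is `None`, never 0. Comparisons against printed integers use
round-half-away-from-zero.

## The synthetic generator

The generator emulates, at toy scale, a family of fermentative bacteria
with a shared core pathway and species-structured accessory content. The
chemistry is artificial but strictly balanced (real element symbols, mock
metabolites), which makes yields hand-checkable:

* glycolysis analogue: glucose + ATP → G6 (kinase), an isomerase chain of
  configurable length (this is how the core is padded to `n_core_reactions`),
  and a lumped lower half F6 + 3 ADP + 2 Pi + H⁺ → 2 pyruvate + 3 ATP +
  2 H₂O — net 2 ATP per glucose;
* biomass drains 10 pyruvate + 1 of each of five mock amino acids + 20 ATP;
  with NGAM enforced, growth is exactly ATP-limited:
  `µ = uptake_glc/10 − NGAM/20`. Planting per-strain glucose-uptake scales
  in [0.5, 0.95] therefore plants an exact growth ordering, and every core
  chain reaction's maximum flux is affine in µ — the growth-correlated core
  fluxome has Pearson r = 1 by construction;
* each species carries one fermentation branch (lactate-, acetate- or
  ethanol-analogue) that disposes of overflow pyruvate; without it no
  steady state exists, which is what makes deleted reactions genuinely
  gapfillable and gives each species a distinct secretion profile;
* two-step amino-acid biosynthesis modules (pyruvate + NH₄⁺ → intermediate
  → amino acid) are deleted per the auxotrophy plan, planting exact
  auxotrophies; the ethanol branch consumes water stoichiometrically, so
  water is additionally essential for ethanol-mode species — the ground
  truth accounts for this;
* species-unique reactions, shared accessory extras and per-strain private
  reactions are dead-end isomerisations of pyruvate (they carry no flux and
  exist to shape the presence-absence matrix); one planted niche-marker
  reaction per niche is added to exactly that niche's members.

The medium mirrors a chemically defined medium: glucose 10 (a configurable
stand-in for a measured uptake), amino acids at 1 mmol gDCW⁻¹ h⁻¹ except
two "glutamate/aspartate analogues" at 2, ammonium and water at 10, NGAM 1.
Defaults are 3 species × 10 strains with two niches of 15 (niches must
exceed 10 strains to enter enrichment). Homology identities are sampled at
85–100 % for carried alleles and 30–60 % for decoys — both bands well clear
of the 70 % threshold, so recovery of the planted matrix is exact; dropout
(default 0) thins only non-essential accessory content (alternative-carbon
branches, accessory extras, unique reactions), never the core or the
fermentation branch, so dropped strains remain viable and family-core
recovery is insensitive to dropout.

What the generator does **not** emulate: realistic network scale (~80
reactions vs thousands), phylogenetic correlation between strains, partial
homology (identities near the threshold arise only in an adversarial
configuration of the identity bands), horizontal transfer, or chemistry
with cofactor/redox realism. Green tests therefore certify the pipeline's
logic and numerics, not the biology of any real family.

## Problem sizes used in the checks

Oracle suites run at sizes where exhaustive references are feasible: LP
results against vertex enumeration on 200 random networks of ≤ 8 reactions;
gapfill minimality against size-ordered subset search on 100 instances with
≤ 12 candidates; Fisher p-values against hypergeometric enumeration on all
2×2 tables with N ≤ 30; PERMANOVA null calibration on 500 seeded replicates
of 10 exchangeable points; end-to-end recovery on the default 3 × 10
population. cobra serves as an independent cross-check (SBML read-back and
FBA agreement), never as the implementation.

## Known limitations

* The FBA flux vector at a degenerate optimum is solver-dependent; only
  FVA-based statements are unique.
* The MILP's strictness margin means a model whose best achievable rate
  lies within 1e-4 (relative) of the threshold is treated as unfillable.
* PERMANOVA is one factor at a time; factors are not jointly modelled.
* The exact-enumeration PERMANOVA cost grows multinomially; the 10 000
  labeling cap keeps it bounded.
* Intra-species partitions require ≥ 2 strains per species (configurable);
  smaller species are skipped with a warning.
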
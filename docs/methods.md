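# Methods

This note documents the models, parameter choices, numerical conventions and
limitations behind `foldmech`. It complements the API docstrings; nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Fold chronology

**Model.** Genomic abundance of a domain structure is treated as a heritable,
generally increasing trait: gene duplication and amplification outpace loss,
so older structures tend to be more abundant across proteomes. Each proteome
contributes one ordered multistate phylogenetic character whose states rank
abundance, and the maximal state is declared ancestral (polarization). Under
this model the most-parsimonious rooted tree of structures places old,
abundant structures near the root, and leaf depth becomes an age proxy.

**Character coding.** Per proteome column, abundance *a* maps to
`round(ln(1+a) / ln(1+a_max) * (n_states-1))`. The logarithm tames the
heavy-tailed abundance distribution before linear binning; `n_states`
defaults to 24 (alphanumeric-style coding with states 0–9 plus letters caps
multistate codings at about this size) and is configurable from 2 to 24.
Columns whose maximum is 0 carry no signal and are dropped with a warning.

**Parsimony.** Wagner (ordered) parsimony: a character changing from state
*i* to *j* costs |i − j|. The general scorer is Sankoff dynamic programming
over states at internal nodes, with the linear-cost min-plus transform
computed by two running-minimum sweeps; it handles arbitrary rooted trees,
including polytomies. Rooting is realized by constraining the root's state
to the ancestral state *N* — score-equivalent to attaching a hypothetical
all-*N* outgroup, without an extra taxon. For strictly bifurcating trees the
search uses the Farris interval scorer (state intervals per node;
overlapping child intervals intersect at no cost, disjoint ones pay the gap),
which equals the Sankoff score on binary trees; at the polarized root each
child independently pays its interval's distance to *N*, because beyond its
minimizer interval each child's transformed cost rises with unit slope.
Both scorers are validated against exhaustive minimisation over all
internal-state assignments on small instances.

**Search.** Exhaustive enumeration of all rooted bifurcating topologies for
up to 7 taxa (at most (2·7−3)!! = 10,395 trees), guaranteeing the global
optimum there; otherwise random stepwise taxon addition followed by
nearest-neighbour-interchange hill climbing, with `n_starts` = 25 replicates
by default. Desk-scale instances (≲ 200 taxa) do not justify heavier
branch-swapping. Among equally parsimonious trees the one with the
lexicographically smallest canonical Newick string is returned; we neither
average nor build consensus trees, so outputs are deterministic for a given
seed. The canonical form sorts children recursively by subtree key.

**Ages.** For each leaf, *d* counts the internal nodes on the root-to-leaf
path (root included); *nd* = (d − d_min)/(d_max − d_min) ∈ [0, 1]. The
affine rescale makes the counting convention (root in or out) immaterial.
When every leaf is equally deep the tree carries no age signal and all *nd*
are set to 0 with a warning. The molecular clock of folds is linear:
age = 3.8 · (1 − *nd*) Ga, anchoring *nd* = 0 at the origin of proteins
(~3.8 Ga) and *nd* = 1 at the present.

## Mechanism mapping

Curation applies two rules. (1) Only domains annotated catalytic are kept;
entries left without a catalytic domain, or none of whose catalytic domains
has an age, are excluded (reason codes `no_catalytic_domain`, `no_age`) —
whole entries are dropped rather than kept partially, since partial entries
would distort per-age entry counts. (2) A step's annotations are credited to
a structure only if the structure contributed at least one residue to the
step, as "Reactant" **or** "Spectator" (no weighting by role); for
single-catalytic-domain enzymes every step belongs to the lone domain.
Steps of multi-domain enzymes with no participant record cannot be
attributed and are skipped with a log entry — the pipeline does not guess.
Steps carrying several annotations contribute each annotation independently;
repeated use within one enzyme counts once (presence, not frequency).

The default matrix granularity is one row per structure (the repertoire
view). A per-(enzyme, domain) granularity is available (`--granularity
enzyme-domain`) for pathway-style comparisons where the same structure may
appear in several enzymes with different repertoires.

## Timeline readouts

Distinct fold ages are compared after rounding *nd* to 4 decimals — the
precision at which ages are reported — so floating-point noise cannot split
one age into two timeline columns. A step type is "introduced" at the
minimum *nd* over possessing rows and is credited to *every* structure of
that age possessing it (co-credit), so per-age introduced sets are disjoint
across ages and their union is the set of types present; the cumulative
discovery curve is exactly the running union of the innovation table. For
per-age summaries a multi-domain enzyme entry is dated by its *oldest* aged
catalytic domain — the convention is open in principle; dating by the
youngest domain would systematically shift multi-domain enzymes toward the
present, while the oldest-domain convention matches the recruitment view
that late domains accessorize an older catalytic core.

## Patterns and similarity

A pattern is the exact step-type set of a row; patterns partition rows.
Pattern numbering is canonical — ascending (set size, then lexicographic
key) — because any printed numbering is dataset-specific; consumers should
match patterns by key content. Jaccard similarity J = |A∩B|/|A∪B| is always
defined (rows are nonempty by construction) and equals 1 exactly when two
rows share a pattern. Clustering is agglomerative with average linkage on
distance 1 − J (no linkage is canonical for this analysis; average linkage
is the common default for heat-map ordering). Tie-breaking is lexicographic
on cluster representative ids, and the implementation is hand-rolled
(Lance–Williams update, O(n³), trivial at these sizes) precisely so that
tie-breaking — and hence leaf order — is deterministic and invariant to
input row order; merge heights are cross-checked against SciPy's average
linkage in the tests.

## Synthetic data generator

**Census.** Domain birth times are uniform on [0, 1]. Per proteome, a
domain born at *t* starts at 1 copy and evolves for duration 1 − *t* under a
discretized birth–death count process (50 equal time slices; per slice each
copy duplicates with probability `dup_rate·dt` and dies with probability
`loss_rate·dt`). Defaults: 50 proteomes, 30 domains, duplication rate 2.0,
loss rate 0.2 — a regime where duplication clearly outpaces loss, matching
the premise that abundance grows with age, while extinction of single
lineages remains possible. `dup_rate ≤ loss_rate` is rejected. A domain
extinct in *every* proteome would be invalid downstream and is redrawn
(vanishingly rare at the defaults).

**Enzymes.** Each enzyme draws 1–4 catalytic domains with count weights
240:63:4:1 (the strong predominance of single-domain catalysis in curated
mechanism databases) and domain choice weighted by 1 − *nd* + 0.1 — a mild
age bias that keeps young structures represented. Step count is
1 + Poisson(mean_steps − 1) with `mean_steps` = 4 (typical stepwise
mechanism length). Each step samples one annotation with probability
proportional to (current usage + α), the classic preferential-attachment
urn; α defaults to 1.0 (strong reuse), and α → ∞ recovers uniform sampling
(verified by a χ² test). One participant per step is recorded, Spectator
with probability 0.2, so both residue roles are exercised. Ground truth
records birth order, each type's first user, and the full set of
(structure, type) usage pairs, against which the mapping stage is checked
for exact equivalence.

**What the generator does not emulate.** Real CATH codes and topology
strings, sequence evolution, horizontal transfer, correlated domain
histories, multi-annotation steps, curation noise, and the real-data
distributions of MACiE. Passing tests therefore demonstrate that the
pipeline's inferences are correct *under the stated model* — abundance
monotone in age, preferential reuse — not that real datasets satisfy that
model.

## Problem sizes and verification

The age-recovery experiment runs 20 seeded replicates at 50 proteomes × 12
domains (heuristic search regime, exactness cross-checked separately at ≤ 7
taxa) and requires the median Spearman correlation between true birth times
and inferred *nd* to reach 0.8; measured values are around 0.88. Exhaustive
oracles (brute-force state assignments, full topology enumeration) run on
hundreds of random instances with 4–6 taxa and 2–4 states. These sizes make
the whole suite run in about a minute while keeping every oracle exact.

## Known limitations and data caveats

- The heuristic search carries no optimality guarantee beyond 7 taxa; only
  the random-tree dominance property and the recovery experiment bound its
  quality there.
- Equally parsimonious trees are resolved by canonical string, not
  summarized; derived *nd* values are those of one optimal tree.
- The curated timeline fixture is reconstructed from printed per-structure
  innovation lists plus the aldolase repertoire; for most structures the
  full repertoire is not printed, so the fixture's sets are lower bounds on
  the real ones. Published running tallies of "types introduced by the first
  increments" disagree by one or two with a naive count over those printed
  lists (and a printed pathway-structure count of 8 corresponds to 7 listed
  rows); the fixture reproduces the printed lists, and tests assert only
  per-structure facts, never the running tallies.
- EC numbers are treated as opaque except the top-level class; CATH codes
  are opaque throughout.
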
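# Methods

## Scope and data model

`wgdplacer` takes a rooted species tree (newick; internal labels become
stable node ids, otherwise ids are auto-assigned in preorder), one gene
tree per orthogroup (leaf labels `<taxon>|<gene_id>` by default, RAxML-style
bootstrap supports as internal labels, branch lengths in Ks units), and
per-orthogroup codon alignments (FASTA). It does not infer trees or
alignments, and it does not date events in absolute time or classify
auto- vs. allopolyploidy.

## Orthogroup filtering

The cascade is fixed-order: occupancy → gaps → paralog pruning.

* **Occupancy.** An orthogroup passes if its distinct-taxon count is at
  least `floor(fraction × n_taxa)`. Floor, not round: 80% of 74 taxa
  demands 59, never 60. A `1e-9` slack guards against binary
  representation of products like `0.7 × 10`.
* **Gap fraction.** Measured over the whole alignment matrix
  (gaps / (sequences × length)) by default; a per-sequence mode (fail if
  any single sequence exceeds the bound) is available because the
  convention differs between published pipelines.
* **Paralog pruning.** In-paralogs (maximal single-taxon clades) collapse
  to one representative — the longest ungapped sequence, ties to the
  lexicographically smallest gene id, matching PhyloTreePruner's published
  behaviour. Among all clades of the collapsed tree in which no taxon
  repeats, the largest is kept (ties: closer to the root, then smallest
  leaf-label set); the orthogroup is rejected if that clade has fewer than
  `min_taxa` leaves. Correctness is checked against an exhaustive clade
  enumeration in the tests.

Duplication mapping deliberately consumes the *unpruned* trees of
orthogroups that passed occupancy + gaps: pruning removes exactly the
paralogs that carry WGD evidence.

## Duplication mapping

A gene-tree internal node is a duplication if two of its child subtrees
share at least one taxon (a polytomy counts once if any pair of children
shares a taxon). Each duplication node contributes **one** event —
pair-level counting would scale quadratically in retained copies — and is
mapped to the species-tree MRCA of all taxa below it. Tallies count events
whose duplication-node support passes the threshold (default ≥ 80);
a node without a recorded support fails a non-disabled filter
(conservative), and a stricter variant additionally requires both child
edges to pass (`support_mode: children`). Gene trees are outgroup-rooted
first: the rooting edge subtends the smallest clade containing all
outgroup leaves present (or its complement); supports are re-attached by
bipartition identity so they stay with the same unrooted split. Trees
without outgroup leaves, or whose outgroups straddle the basal polytomy,
are skipped and logged rather than guessed at.

## Ks estimation

Nei–Gojobori (1986) counting with the standard conventions:

* synonymous sites per codon = (synonymous single-base neighbours)/3,
  with stop-creating changes counted as nonsynonymous (so S + N = 3 per
  codon, the same convention as Biopython's NG86);
* differences per codon pair are averaged over all orderings of the
  single-base steps, excluding mutational paths that pass through a stop
  codon (if all are blocked, all paths are used);
* `ps = sd / S` with `S` averaged over the two sequences, corrected for
  multiple hits by Jukes–Cantor, `Ks = -(3/4) ln(1 - (4/3) ps)`. `ps ≥ 3/4`
  is beyond the correction's horizon: the value is flagged saturated and
  excluded from distributions. Codon columns with gaps or ambiguity are
  masked; fewer than 10 comparable codons is an error; stop codons are an
  error.

All 61×61 pair tables are precomputed once, so a pair's Ks is a table
gather over its codon indices. The estimator choice is a package decision:
published Ks tools rarely state their internal estimator, and NG86+JC is
fully specifiable and oracle-testable (the tests enumerate mutation paths
independently and also cross-check `Bio.codonalign.cal_dn_ds` on codon
pairs without stop-crossing paths, where the two conventions coincide).

### Distributions and mixtures

Two distribution modes mirror the two families of published tools:
*pairwise* (all within-taxon pairs; counts pairs, so one old duplication
with many retained descendants is over-represented) and *node-based* (one
value per duplication node: the median — mean by flag — over the node's
cross-subtree same-taxon pairs; counts duplications). The retention window
`[0.01, 2.0]` drops recent tandem duplicates (the peak hugging Ks 0) and
the saturated tail; both bounds are configurable and the window is a
documented default, not a claim about any particular dataset.

Mixtures are fitted on raw Ks (a log-scale option exists, off by default)
with scikit-learn's EM, k = 1..4, 10 k-means++ restarts per k, seeded.
`BIC = p ln(n) - 2 lnL` with `p = 3k - 1` (k−1 weights, k means,
k variances); minimum BIC selects k. Fewer than 20 windowed values is
"insufficient data" rather than a fit.

## Ortholog divergence and bookending

For a species pair, each orthogroup containing both taxa contributes the
minimum-Ks cross-taxon pair — a heuristic for the true ortholog pair under
duplicate retention (paralog comparisons are older, hence larger). The
divergence peak is the median of the windowed values (the 1-component
mixture mean is reported alongside). The bookending rule with margin δ
(default 0.05 Ks, configurable; peak comparisons are never treated as
exact): ortholog peak − paralog peak > δ ⇒ `not_shared`; paralog −
ortholog > δ ⇒ `shared`; otherwise `ambiguous`. A placement hypothesis at
species node v implies `shared` exactly for pairs wholly inside v's clade;
hypotheses are scored by the fraction of non-ambiguous verdicts they
match, tie-broken by the duplication tally at their node. Hypotheses with
identical implied patterns over the sampled pairs are flagged as
degenerate — bookending cannot tell one clade-wide event from independent
events at approximately the same age, so the verdict table is always
emitted for manual inspection.

## Simulator

The generator emulates the statistical structure the analysis assumes —
and nothing more:

* one gene lineage enters the species-tree root per family; along each
  branch, duplication and loss are Poisson with rates λ, μ per lineage per
  Ks unit (defaults 0.1/0.1, moderate turnover); families with < 2
  surviving leaves are discarded and resampled (budget 200 × F attempts);
* a WGD episode "at node v" duplicates every surviving lineage with
  retention probability r, **midway along the branch above v** (at the
  root itself for the root). Any position on that branch maps to v under
  MRCA mapping, whereas pinning the episode to a node would make the event
  exactly coeval with an adjacent speciation and render bookending
  degenerate by construction. Losses at the episode instant are excluded —
  retention already models them;
* gene-tree branch lengths are species-tree Ks lengths times a lognormal
  mean-1 multiplier per branch (σ default 0.1, modelling among-gene rate
  heterogeneity); the noisy lengths are the truth: a pair's true Ks is its
  path length in the emitted tree;
* codon sequences evolve down the gene tree under a synonymous-only
  substitution chain (rate 1 between synonymous single-step sense codons).
  With branch time t = Ks/3 the expected number of substitutions per
  synonymous site is exactly the branch's Ks for every codon, because a
  codon's total leaving rate is 3 × its synonymous-site count. No stop
  codon is ever reachable. Four-fold sites follow Jukes–Cantor exactly;
  two-fold sites saturate at 1/2 rather than 3/4, which leaves the NG86
  estimator a small upward bias (~+0.01 at Ks 0.4), well inside the ±0.05
  recovery tolerance asserted in the tests;
* bootstrap supports are drawn from a configured distribution (default:
  constant 100; a uniform range is available) rather than re-estimated,
  which would import a tree-inference dependency.

What a green simulation test does **not** establish: robustness to
alignment error, assembly artefacts, indels, amino-acid-level model
misspecification, incomplete lineage sorting, or non-synonymous rate
variation — none of these are generated.

### The bundled world

The default species tree has six ingroup taxa (A–F) and two outgroups,
ultrametric in Ks with root depth 0.75. The standard episode sits above
node `ab` (A+B ancestor) at Ks depth 0.2 with retention 0.5 — paralog
peak 0.4, bracketed by the A–B split at 0.3 and the (A,B)–C split at 0.5,
deliberately echoing the magnitudes reported for recent Brassicales-type
events. Scale: 300 families × 300 codons runs the whole pipeline in well
under a minute.

## Numerical and reproducibility notes

* Newick canonical form: branch lengths `%.6f`, supports `%g` as internal
  labels, child order preserved; parse→write is idempotent on the
  canonical form. The simulator emits 12 significant digits so in-memory
  truth comparisons hold to 1e-9.
* All stochastic steps (simulation, EM restarts) take explicit seeds;
  pipeline outputs are byte-identical across same-seed reruns, and the
  manifest records the config hash plus a sha256 per report.
* Gene-tree leaf uniqueness is enforced on the (taxon, gene_id) pair; the
  same gene id may recur across taxa.
* Tie-breaks are all deterministic and documented in the docstrings
  (pruning: size, then root-proximity, then label set; in-paralog
  representative: length, then gene id).
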
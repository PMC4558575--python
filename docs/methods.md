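# Methods

`cophylokit` implements the statistical core of a cophylogenetic study of
a host radiation and its species-specific parasites: how many parasite
species the sequence sample contains, whether host and parasite
phylogenies are congruent, which mix of codiversification events explains
the parasite tree, and whether the parasite's diversification rate
changed over time.  This note records the models, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Species delimitation (`delimit`)

Haplotypes (identical sequences collapsed case-insensitively) are
clustered by pairwise genetic distance against a marker-specific
divergence cut-off: 1% for nuclear ribosomal ITS (the cut-off proposed to
match morphospecies boundaries in the best-studied monogenean genus) and
2% for mitochondrial COI (the conventional barcoding threshold).  Two
haplotypes are conspecific when a chain of distances strictly below the
threshold connects them (single linkage); the species estimate is the
number of connected components of the `d < theta` graph.  Complete
linkage is available behind a flag for users who prefer "every pair must
diverge" semantics; whether published threshold counts used single or
complete grouping is rarely stated, and for samples of a few haplotypes
whose distances sit wholly on one side of the cut-off the two rules
agree, which is why the worked examples here are invariant to the choice.

Distances are uncorrected p, Jukes-Cantor (`d = -(3/4) ln(1 - 4p/3)`),
or gamma-corrected Jukes-Cantor
(`d = (3 alpha / 4) [(1 - 4p/3)^(-1/alpha) - 1]`) with marker defaults
`alpha = 0.40` (ITS) and `alpha = 0.11` (COI).  Sites containing a gap
or N in either sequence are excluded pairwise (not listwise), which
preserves short fragments and is the standard choice in distance
barcoding.  Externally computed distance matrices (TSV) are accepted,
because published distances often come from richer substitution models
whose parameters are not printed; the threshold classification, not the
distance recomputation, is the operation of record.

For diversification input, near-identical haplotypes are pruned
greedily: haplotypes are visited by decreasing multiplicity (ties by
label), each either joins the first existing representative closer than
1% or seeds a new cluster.  This keeps the most frequently sampled
variant of each cluster and focuses branching times on speciation rather
than intraspecific coalescence.

The molecular-rate calibration converts a range of between-species
pairwise divergences (d_lo, d_hi, in percent) over a dated host root (T,
in My) into a per-lineage rate `(d/2)/T` — the pairwise divergence is
split between the two diverging lineages — rounded to one decimal, the
precision at which such rates are conventionally reported.

## Event-based reconciliation (`reconcile`)

The reconciliation model maps every parasite node to a host vertex with
four event types: cospeciation (parasite node pairs with a host node,
daughters separated into distinct host daughter lineages), duplication
(within-host speciation, both daughters on the same host lineage),
host-switch (one daughter transfers to a host vertex incomparable to the
source — neither ancestral nor descendant), and sorting/loss (a host
edge crossed without a parasite event).  Given per-event costs, the
minimum-total-cost mapping is found by dynamic programming over
(parasite node, host vertex) pairs with an auxiliary "enter from above"
table that charges one sorting per host edge descended.  On binary
parasite trees the counts obey `n_cosp + n_dup + n_switch = #internal
nodes` by construction.  The DP is exact: the test suite checks it
against exhaustive enumeration of all assignments of parasite internal
nodes to host vertices on randomized small tanglegrams.

Choices that needed deciding:

* **Switch targets** are restricted to incomparable vertices.  A
  descendant target is never needed (it is expressible as duplication
  plus losses at no greater cost), and an ancestral target would make
  the parasite older than its host position.  Landing "high" on an edge
  and sorting downward is likewise never cheaper than landing at the
  final vertex, so switch landings carry no loss charge.
* **Root-to-root mapping** (default on) forces the parasite root
  lineage to enter at the host root, charging sortings down to the first
  event — the natural prior when the parasite clade is known to span the
  host clade.  It can be disabled, in which case the root maps wherever
  is cheapest.
* **Host-switches do not bill an extra duplication** by default; a flag
  restores the alternative accounting (the switch then costs
  `c_switch + c_dup`); event counts are unaffected, only the price.
* **Ties** are broken deterministically — cospeciation over duplication
  over host-switch, then host vertices in lexicographic name order — so
  identical inputs give bit-identical reports.  Internal host and
  parasite vertices are named `<smallest-leaf|clade-size>`, which is
  unique and stable across runs.
* **Polytomies** in the parasite tree are resolved greedily when
  allowed: within each polytomy the two child subtrees whose linked host
  leaves share the deepest host ancestor are joined first (the most
  congruent local arrangement), ties by leaf label; the output flags
  that resolution happened.  **Multi-host parasite leaves** are split
  into one pseudo-leaf per host (`leaf@host`) with a logged note.

### Adaptive event costs

Rather than fixing costs a priori, `estimate_costs` searches for a
scheme that is *self-consistent*: good costs should be roughly
anti-proportional to how often their events are actually used.  The
quality of a scheme `c` (normalized to sum 1) is the Euclidean distance
between `c` and the normalized inverse-frequency vector of the event
counts of the optimal reconciliation under `c`, with frequencies floored
at `0.5 / total events` so zero-count events imply a large-but-finite
ideal cost.  Quality 0 means the scheme exactly reproduces itself.  The
search draws cost vectors uniformly on the 3-simplex (default 10^4),
ranks them, polishes the best candidate of each of the leading distinct
event-count signatures by Nelder-Mead on a softmax parameterization, and
finally evaluates each polished solution's own inverse-frequency ideal
(a one-step fixed-point iteration that lands exactly on quality 0 when
the solution family is self-consistent).

Self-consistency alone is degenerate: a scheme that prices an event out
entirely can be exactly self-consistent too (zero occurrences "justify"
an extreme cost).  Two mechanisms address this.  Among quality ties the
cheaper total-cost reconciliation is preferred — a deterministic,
seed-independent tie-break.  Independently, `flag_implausible`
implements the biological sanity filter: a solution is rejected when any
event type has zero inferred occurrences while its normalized cost
exceeds 0.9, because the zero is then an artifact of the price, not
evidence about the process.  The pipeline reports the ranked solutions,
flags the implausible ones, and retains the best plausible solution.

### Chronology and topological congruence

`check_chronology` verifies that the inferred switches admit consistent
host divergence times: each switch requires its source and target host
edges to overlap in time, which (with the tree's own ancestor order)
induces ordering constraints among internal host nodes; the
reconciliation is consistent iff the combined constraint digraph is
acyclic.  Constraints whose endpoint is a pendant edge are dropped as
trivially satisfiable, since pendant edges reach the present.

`cospeciation_significance` measures topological congruence only: the
observed statistic is the cospeciation count of the optimal
reconciliation under cospeciation-favoring costs (cospeciation free,
all else unit cost), and the null regenerates both topologies uniformly
at random over labeled rooted binary trees (the
proportional-to-distinguishable model) with the links held fixed,
because the links are data, not part of the topological hypothesis.
P-values use the add-one convention `(1 + #{null >= obs}) / (1 + n)`.

## Distance-based congruence (`congruence`)

The global test embeds host and parasite distance matrices in Euclidean
space by principal coordinates (double-centering of `-D^2/2`,
eigendecomposition; axes with eigenvalue `> 1e-10 x` the largest are
kept and scaled by the root eigenvalue).  Negative eigenvalues are
dropped by default; a Cailliez correction is available for strongly
non-Euclidean inputs.  With host coordinates `B`, parasite coordinates
`C`, and binary links `A`, the statistic is the squared Frobenius norm
of the fourth-corner matrix `C'AB`; the null permutes host identities
(rows of `B`).  Each link's statistic is the drop in the global
statistic when that link alone is removed, tested under the same
permutations.  Patristic distances (path sums of branch lengths) are the
default input; any user matrix is accepted since host distances often
come from different markers than the host tree, and a codon-position
mask supports excluding saturated third positions from protein-coding
alignments.

## Diversification (`diversification`)

Branching times of an ultrametric tree (tolerance: leaf-depth spread
below 1e-6 of the root age) feed five models.  For the pure-birth family
the log-likelihood decomposes over inter-event intervals: an interval
with `k` lineages, per-lineage rate `lambda(k)` and duration `g_k`
ending in a branching contributes `ln(k lambda(k)) - k lambda(k) g_k`,
and the final interval contributes the exponential survival term only.
Because the rate scale enters linearly in the exponent, each model's
scale parameter has a closed form given its shape parameter, leaving at
most a one-dimensional numerical search:

* `pureBirth` — `lambda_hat = (n-2) / sum k g_k`, fully closed form.
* `birthDeath` — the Nee-style constant birth-death likelihood in
  `(r = b - d, a = d/b)`, optimized by Nelder-Mead from two starts (the
  pure-birth rate with small and moderate extinction fractions); its
  `a = 0` boundary reproduces the pure-birth likelihood exactly, so the
  models nest on the same scale (cross-checked against `ape::birthdeath`
  in the tests).
* `DDL` — `lambda(k) = lambda0 (1 - k/K)`, profile likelihood over
  `K > n` via a bounded search on `log(K - n)`.
* `DDX` — `lambda(k) = lambda0 k^-x`, bounded search on `x in [-5, 5]`.
* `yule2rate` — two rates with a shift searched on the grid of observed
  branching times (branchings at ages >= the shift belong to the early
  regime; among equal-likelihood shifts the earlier time wins); both
  rates closed-form per candidate.

The rate-shift statistic is `dAIC_RC = AIC(best of pureBirth,
birthDeath) - AIC(best of DDL, DDX, yule2rate)`; positive values favor
temporal rate variation.  Significance comes from recomputing the
statistic on pure-birth trees of the same tip count (branching times
simulated directly as exponential inter-event intervals; the observed
pure-birth rate sets the scale, though `dAIC_RC` is invariant to time
rescaling — the tests verify this by doubling all ages).  The model set
is configurable; these five are the conventional default set for this
test.

## Synthetic data (`simulate`)

`simulate_cophylogeny` grows a parasite tree over a given ultrametric
host tree under exactly the four-event vocabulary the reconciler
infers: one parasite lineage enters at the host root; at each host node
it cospeciates with probability `p_cosp` (follows both daughters) or is
sorted (follows one, chosen uniformly); along branches, duplication,
switching and loss are Poisson events with rates `r_dup`, `r_switch`,
`r_loss` per unit branch time.  Switch targets are drawn uniformly from
the host branches alive at the event moment, so simulated switch logs
are chronologically consistent by construction — a guaranteed-true
fixture class for `check_chronology`.  Every random decision is logged;
`replay_cophylogeny` re-runs the log and must reproduce the trees,
links and tally exactly, which the tests assert.  Defaults (`p_cosp =
0.8`, `r_dup = 0.5`, `r_switch = 0.1`, `r_loss = 0.3` on a unit-depth
host tree) emulate a cospeciation-dominated, host-specific parasite
radiation with frequent within-host speciation, rare switching, and
enough loss that several host lineages escape their parasites —
the regime the reconciliation stage is designed for.

What the generator does *not* emulate: failure-to-diverge (one parasite
persisting across a host split as a single species), multi-host parasite
lineages, within-host population structure, incomplete sampling, and
alignment artifacts (indels, rate heterogeneity across lineages beyond
the optional gamma site-rates).  Passing tests on these simulations
therefore demonstrate internal statistical correctness — calibration,
power, parameter recovery under the model's own assumptions — not
robustness to real-data violations of them.

Random topologies (`simulate_pda`) are uniform over labeled rooted
binary shapes via sequential attachment to one of the `2k - 1` edges
(uniformity is chi-square-checked against full enumeration for 3 and 4
leaves).  Pure-birth and density-dependent trees stop at the target tip
count and include the final full waiting interval, which keeps the
closed-form rate estimator unbiased (mean recovered within 10% over 100
replicates in the tests).  Sequences evolve under Jukes-Cantor with an
optional gamma distribution of site rates; the two-leaf mean p-distance
matches `(3/4)(1 - e^(-4rt/3))` within Monte-Carlo error.

## Validation problem sizes

The suite's end-to-end statistical checks run at sizes chosen to give
stable Monte-Carlo estimates while staying desk-scale: the
reconciliation DP is verified against brute force on 100 random
tanglegrams of up to 5+5 leaves; the congruence test's type-I error is
estimated from 200 independent-tree datasets (10 hosts, 10 parasites,
999 permutations) with an acceptance band of [0.01, 0.10] at nominal
0.05 (the test is known to be slightly conservative); the rate-shift
test's type-I error from 100 pure-birth 37-tip trees (200 null trees
each) with the same band, and its power from 50 strong-slowdown
replicates (`lambda0 = 1, K = 40, n = 37`, threshold 80%); event-count
recovery uses 50 cospeciation-dominated simulations on 10-host trees,
requiring Spearman rho >= 0.7 between true and inferred counts pooled
over the four event types, with inference under the default
cospeciation-favoring costs.

## Known limitations

* The adaptive cost search screens a finite sample of the simplex; on
  large tanglegrams distinct solution families may be missed at small
  `n_sets`.  The defaults (10^4 draws) are sized for trees of a few
  dozen leaves.
* The DP ignores event timing; chronological consistency is a post-hoc
  check, not a constraint during optimization (enforcing it during the
  DP is NP-hard).
* The birth-death fit assumes complete lineage sampling; no sampling
  fraction correction is implemented, and branching-time likelihoods
  condition on the root age in the usual way.
* Per-link congruence tests inherit the conservatism of the global
  permutation scheme; with few hosts the per-link power is modest.
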
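# Methods

## Scope and data model

All analyses operate on a binary fragment × sample matrix (rows =
operational taxonomic units from community fingerprinting, columns =
samples). Any strictly positive input value is treated as presence, so
abundance tables can be fed in at the cost of an implicit detection
threshold. Fragments carry a bacterial/archaeal domain label; samples carry
a core label (C1, C2, C3, C5, C8 along the flow path), a depth section, and
a scale (bulk or single particle, with a particle index 1–8 at particle
scale). Fragments detected with different restriction enzymes are treated
as separate data sets and never merged: there is no reliable cross-enzyme
fragment matching, and the analyses are defined per data set.

## Pair testing

The two-sided Fisher exact p-value of a 2×2 joint-presence table is the sum
of hypergeometric probabilities of all tables with the same margins whose
probability does not exceed that of the observed table (with the standard
1 + 1e−7 relative gate when comparing probabilities, so exact ties are
included despite floating point). The all-pairs path computes co-occurrence
counts as M·Mᵀ and groups pairs by their occupancy margins, evaluating each
margin group's hypergeometric pmf once; this is what makes 100 null
replicates over ~2·10⁵ pairs affordable. BH adjustment is the standard
step-up procedure (via statsmodels), applied across all pairs of a data
set; significance means p_adj < α with α = 0.05 by default.

## Null models

**Fixed-margin null (empirical FDR).** Each replicate conserves every row
and column sum. The default sampler is the curveball trade: pick two rows,
pool the samples held by exactly one of them, and redistribute the pool at
random between the rows, keeping each row's count; 5 × n_fragments trades
per draw. Checkerboard 2×2 swaps (4 × the number of presence cells attempts
per draw) are available as an alternative; curveball is the default because
it mixes far faster per unit work, while both conserve the margins exactly
on every draw — this is asserted in tests, not assumed. The estimated FDR
re-runs the *entire* decision pipeline (Fisher, BH, threshold) on each of
the (default 100) replicates and reports mean null significant count /
observed significant count, 0 when nothing is observed. Re-running BH per
replicate, rather than comparing raw p-values, mirrors the decision rule
whose false positives are being counted.

**Occupancy-preserving null (sign classification).** Permuting each
fragment's row independently across samples makes the null co-occurrence
count of a pair with occupancies (n_A, n_B) over S samples exactly
Hypergeometric(S, n_A, n_B); the implementation therefore samples that
distribution directly (default 1000 draws per significant pair) instead of
materializing permutations — a mathematical identity, not an approximation.
A pair is positive when the fraction of draws strictly below the observed
count, with ties counted half, exceeds 0.95; negative when the fraction
strictly above exceeds it; otherwise it stays unclassified. The half-tie
rule is a deliberate choice: whether the original procedure used ≥ or > and
how it treated ties is not derivable, and counting ties half makes the
three-way outcome (positive / negative / unclassified) well-defined and
symmetric. The null mean is reported as the expected co-occurrence and
converges to n_A·n_B/S.

## Rule mining

A confidence-1 rule A→B requires samples(A) ⊆ samples(B) with A occurring
at least once; confidence is undefined for zero-occupancy origins, which
therefore never appear as origins. With the matrix as a boolean array the
subset test for every ordered pair reduces to co[i,j] == occupancy[i] on
the M·Mᵀ product, an equivalent vectorization of the per-pair bitset scan;
mining the 620-fragment scale takes well under a second. `min_support`
(default 1, i.e. no extra filter beyond confidence 1) can be raised to
suppress rules from origins seen in very few samples, which are fragile to
single detection errors. Targets present in every sample are kept but
flagged ubiquitous, since such trivial universal supersets deserve separate
interpretation.

## Networks and topology

Significant pairs form an undirected signed graph (unclassified significant
pairs are kept as edges with sign "unclassified"); rules form a directed
simple graph. All topology metrics are computed on the undirected simple
view — reciprocal rule pairs merge into one edge, so the undirected edge
count can be below the rule count. Conventions are fixed to those of the
NetworkAnalyzer tool this panel mirrors:

- characteristic path length averages shortest-path distances over
  *connected ordered* node pairs only (disconnected pairs are excluded, not
  infinite), so modular, disconnected networks still get a finite CPL;
- local clustering of nodes with degree < 2 is defined as 0 and included in
  the mean;
- centralization is Freeman's Σ(d_max − d_i) / ((N−1)(N−2)) — 1 for a star,
  0 for a regular graph, undefined (an error) below 3 nodes;
- heterogeneity is the population coefficient of variation of the degrees.

Metrics are evaluated on the adjacency matrix (C-level BFS via
scipy.sparse.csgraph for distances, one dense matrix product for
triangles); a pure-Python BFS/triangle-counting implementation serves as
the independent oracle in the tests. The Erdős–Rényi baseline draws G(n, m)
graphs — m distinct edges uniformly among all unordered pairs — with the
network's node and edge counts and reports mean CPL and clustering over
(default) 100 draws. In this model the expected local clustering equals the
edge density, which the tests use as a convergence check.

Modularity is optimized on the positive-edge subgraph with the
deterministic fast-greedy agglomeration (networkx's CNM implementation);
the reported Q is always re-evaluated directly from
Q = Σ_c (e_cc − a_c²) on the returned membership, so the score never
depends on the optimizer's bookkeeping. Modules are numbered by decreasing
size.

Rule-network nodes are classified by role: target_only (incoming rules
only), origin_only, mixed, isolated. The top-k (default 25) lists rank
exclusive targets by in-degree and exclusive origins by out-degree, ties
broken lexicographically by fragment id. A hub's neighborhood subgraph
collects the hub, its rule-adjacent fragments, all rule edges among them,
and — as an overlay — every positive co-occurrence edge among those nodes,
which shows whether the partners predicting the hub co-occur with each
other or are alternatives.

## Spatial profiles

For each module and core, a member fragment's presence fraction is its
presence count within that core's samples divided by the core's sample
count, ignoring depth sections; the module mean is the arithmetic mean over
member fragments. Fragments outside any module are pooled in a pseudo-
module "unassigned". Cores without samples are dropped with a warning.

## Synthetic communities

The generator emulates the shape of the motivating data sets, not their
content: a bulk-like preset (280 fragments × 72 samples in five cores,
fraction archaeal 0.27) and a particle-like preset (620 fragments × 104
samples as 13 sections × 8 particles, fraction archaeal 0.48). Planted
structure, all recoverable from ground truth:

- **Modules**: blocks of fragments present with p_in (0.9 bulk / 0.85
  particle) in the samples of their associated core and p_out = 0.05
  elsewhere. Each preset module is tied to exactly one core, which mirrors
  the observed location-bound modules while keeping planted truth
  unambiguous for recovery scoring.
- **Rules**: origin fragments get small random sample sets (occupancy 6
  bulk / 5 particle — sparse, as befits taxa confined to few locations) and
  each target's set is the union of its origins' sets plus extra samples
  (12 / 10). The bulk preset plants 20 mixed-domain rules through 10 shared
  targets; the particle preset plants 150 rules from 50 archaeal origins to
  30 bacterial targets (3 targets per origin), reproducing the
  archaeum→bacterium dominance and bacterial target-only hubs at that
  scale.
- **Exclusions**: pairs covering complementary halves of the samples, hence
  disjoint, strongly negatively associated, and significant.
- **Background**: remaining fragments are i.i.d. Bernoulli(0.15) per cell.

Cell-wise i.i.d. flip noise (default rate 0.02) is applied after planting;
at rate 1 it is the deterministic complement. Because one flip can break a
confidence-1 rule, the ground truth's `surviving_rules` are recomputed from
the final matrix by direct subset check — at 2% noise only a minority of
planted rules survive, which is faithful to how brittle exceptionless rules
are, and recovery tests compare against the surviving set.

What the generator does *not* emulate: abundances and detection thresholds,
within-core depth structure, spatial autocorrelation between neighboring
particles, cross-enzyme fragment identity, and overlapping module–core
associations. Passing recovery tests therefore demonstrate that the
statistical machinery finds planted presence–absence structure at realistic
dimensions and noise, not that real communities satisfy the planted model.

## Determinism and numerics

Every stochastic step takes a seed or numpy Generator; the pipeline derives
stage seeds from its master seed by fixed offsets (+1 empirical FDR, +2
sign classification, +3 ER baselines), so full runs are bytewise
reproducible. Fisher p-values are compared to enumeration oracles at 1e−9
absolute tolerance; exact-tie handling uses the relative gate above.
Degenerate inputs fail loudly: fewer than two fragments, unknown ids,
probabilities outside [0, 1], centralization below three nodes, and CPL on
graphs without a single connected pair all raise validation errors rather
than returning conventional values.

## Problem sizes in tests and drivers

Tests run the full bulk-like (280 × 72) and particle-like (620 × 104)
presets for recovery checks, 100-draw ER baselines at the published network
sizes, exhaustive Fisher-oracle comparison for all tables up to grand total
30, and a 1000-matrix rule-mining oracle sweep at 12 × 12 — sizes chosen so
the whole suite completes in well under a minute of compute per concern
while still exercising the study-scale dimensions. The analysis drivers use
the presets at full scale with the standard replicate counts (100 FDR
replicates, 1000 sign replicates, 100 ER draws).

## Known limitations

Confidence-1 rules carry no uncertainty quantification; their count is
sensitive to single detection errors (hence `min_support`). The empirical
FDR conditions on both margin vectors, which is conservative for fragments
with extreme occupancy. Fast-greedy modularity is deterministic but can
merge small modules connected by a few noisy positive edges; no resolution
parameter is exposed. Sign classification of weakly occupied pairs is
limited by the discreteness of the hypergeometric null, which the
unclassified category absorbs.
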
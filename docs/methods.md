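# Methods

This note records the models, conventions and numerical choices behind
`nbbd`, and what the synthetic benchmark does and does not establish.

## Differential-network scoring

Two undirected, unweighted networks G₁, G₂ over the same taxa are compared
node-wise. NTPS scores a shared node by the absolute difference of one
topological property between the graphs. Conventions for degenerate cases,
chosen so the difference is always finite and both graphs use the same rule:

- betweenness is the unnormalised sum over unordered pairs
  Σ σ(u,w|v)/σ(u,w); computed per connected component when a graph is
  disconnected;
- closeness uses the reachable-set form (n_reach − 1)/Σ d(u,v); isolated
  nodes score 0;
- average neighbour degree and clustering coefficient are 0 for isolated
  nodes / nodes of degree < 2;
- node clique number is the size of the largest maximal clique containing
  the node; core number is the largest k with the node in the k-core;
- edge weights are ignored by all six properties.

Scores are defined exactly on the intersection of the vertex sets; taxa
present in only one network receive no score (and are likewise excluded,
not zero-filled, by the hybrid product).

## Resilience measures and attack sets

For an attack set S ⊆ V with C_max the order of the largest component of
G − S and ω the number of components:

    VAT(S)  = |S| / (|V−S| − C_max + 1)        S ≠ ∅
    I(S)    = |S| + C_max
    T(S)    = (|S| + C_max) / ω                ω := 1 when S = V

The graph-level value of each measure is the minimum over admissible
proper subsets. The greedy heuristic computes one removal ordering by
repeatedly deleting the node with maximal betweenness in the current
residual graph (ties broken lexicographically on taxon ID; betweenness is
recomputed over the whole residual graph, per component, after each
removal) and evaluates each measure on every prefix — sizes 1..n−1 for VAT,
0..n−1 for integrity and tenacity — returning the minimising prefix
(smallest on ties). Sharing one ordering guarantees the nesting
S_VAT ⊆ S_I ⊆ S_T.

The greedy value can exceed the true optimum. The package ships an
exhaustive oracle (≤ 16 nodes, enforced) used by the test suite; on every
connected graph with up to 7 nodes the greedy value matches the optimum for
VAT and integrity on stars and paths, but not always for tenacity: on the
5-path the tenacity optimum {v1, v3} is not a prefix of any
highest-betweenness ordering (the middle vertex is removed first), so the
greedy value is 1.5 against an optimum of 1.0. This is a structural limit
of prefix-restricted search, not an implementation artifact.

CASS feature selection intersects the two phenotype networks' attack sets.
The intersection may legitimately be empty — reported as an explicit
"no features" status, never an exception, so experiment sweeps complete.

## Network constructors

**Proxi.** Distance 1 − |Pearson r| on the taxon abundance vectors; each
taxon proposes edges to its 7 nearest neighbours, merged by union (mutual
merge available). Under the union rule every node has degree ≥ k. Distance
ties break on taxon ID, making the graph deterministic.

**SparCC.** Tables are first converted to relative abundances; the
pseudo-count (default 1.0) is applied as Dirichlet-style smoothing at a
nominal depth of 10 000 reads, f' = (f·D₀ + pc)/(D₀ + pc·m). This keeps the
estimate exactly invariant to per-sample rescaling — the defining property
of a compositional method — while retaining "one pseudo-count at
sequencing depth" semantics. Basis variances solve the sparsity-approximated
linear system from the row sums of the variation matrix; the most
correlated pair above 0.1 is excluded and the system re-solved, up to 10
iterations; a degenerate system falls back to clipped Pearson on log
fractions with a logged warning. Edges require |ρ| ≥ 0.3.

**MB.** clr-transformed abundances (pseudo-count on zeros, natural log);
per-taxon Lasso regression on all other taxa; neighbourhoods merged by OR
(default) or AND. The penalty is selected per graph as the *smallest*
λ in the grid whose merged graph has density ≤ 0.05 — i.e. the densest
graph under the cap. (The alternative reading, the largest such λ, is
degenerate: density is non-increasing in λ, so it would always pick the
grid maximum and an almost empty graph.)

**RMT.** Pearson correlations on log abundances after a 25% prevalence
filter. Thresholds are scanned ascending over 0.30–0.95 (step 0.01); at
each threshold, sub-threshold entries are zeroed, isolated rows dropped,
and the eigenvalue nearest-neighbour spacings — unfolded by a degree-5
polynomial fit to the cumulative spectral staircase — are tested against
the exponential (Poisson) law by a chi-square test at α = 0.05, with
equal-probability bins whose number adapts downward on small matrices
(target ≈ 5 expected counts per bin). The first non-rejected threshold
wins; if none is accepted the grid maximum is used with a warning. This is
a re-implementation of the random-matrix transition criterion, not a
bit-compatible port of any particular pipeline.

## Feature selection and evaluation harness

Information gain uses equal-width discretisation (10 bins) per feature and
base-2 entropies; the F statistic is the standard one-way ANOVA form with
infinite values (zero within-group variance, unequal means) capped at the
largest finite float; RFE uses an L1-penalised logistic model, dropping the
10 lowest-|coefficient| features per iteration and landing exactly on k;
RFFI is the impurity-decrease importance of a 500-tree random forest,
normalised to sum to 1. The hybrid score is the raw elementwise product of
RFFI and NTPS scores (no rescaling — both factors are nonnegative, and the
product preserves each factor's ranking when the other is constant). Top-k
selection sorts by score descending with lexicographic tie-breaks, so all
rankings are deterministic and k-nested.

The harness mirrors a nested feature-selection design: taxa are ranked on
a class-balanced subset of the training samples (the feature-selection
data set, drawn so that smaller subsets are contained in larger ones, via
prefixes of one seeded shuffle per class), the forest is trained on the
*full* training table restricted to the selected taxa, and evaluated once
on held-out data. Metrics: confusion counts at probability threshold 0.5;
MCC with the zero-denominator → 0 convention; AUC as the Mann-Whitney rank
statistic with midranks for ties (undefined, reported as missing, for a
single-class test set). RF hyperparameters beyond 500 trees are library
defaults, seed-pinned. Grid-cell failures become status rows.

The two-group Kruskal-Wallis check (tie-corrected H) is provided for
differential-abundance follow-up of selected taxa.

## Synthetic benchmark

The generator emulates a two-phenotype 16S-style study with a *known*
network difference:

1. Background graph A: Erdős–Rényi over 100 taxa with expected degree 8
   (scale-free optional).
2. Graph B: identical to A except 10 planted taxa have their incident
   edges removed and five times as many reattached to uniformly drawn
   partners (capped at 60). Planted taxa thus gain partners in the disease
   group — a disease-associated bloom engaging broadly with the community —
   and dominate degree-sensitive differential scores on the truth graphs
   by construction. Degree-preserving rewiring was rejected: it leaves
   degree-like properties unchanged in expectation, so no scoring method
   could be expected to find the planted nodes.
3. Latent correlations: precision matrix I + w·A with w = 0.3 shrunk by
   factors of 0.9 until positive definite; the inverse is rescaled to a
   correlation matrix. One shared w serves both groups (the largest
   feasible for both graphs), otherwise background edges would differ in
   strength between groups and create a spurious global signal.
4. Counts: per sample, a latent Gaussian vector is exponentiated to
   lognormal abundances, normalised, and multinomially sampled at depth
   10 000; cells are then zeroed independently with probability 0.05.
   Sampling zeros for rare taxa arise naturally from the multinomial; the
   Bernoulli layer models thin technical dropout on top (uniform dropout
   is deliberately simple — real dropout concentrates in rare taxa).
   Heavier zero inflation is available through the parameter and is
   exercised in tests at 0.9.

What the benchmark does *not* emulate: realistic taxonomies, phylogenetic
correlation, abundance heterogeneity across orders of magnitude,
abundance-dependent dropout, longitudinal structure, or strong marginal
abundance shifts. Consequently, passing tests demonstrate that the
machinery recovers *network-mediated* signal under compositional noise —
not that any particular feature count or AUC will transfer to a real
cohort.

Known quantitative limits, measured at the default conditions (100 taxa,
10 planted, 100 samples/group, 20 seeds): differential-betweenness scoring
on Proxi networks recovers planted taxa at mean precision@10 ≈ 0.44
(random: 0.10), and the hybrid score beats forest importance alone at
every feature-selection size tested. The precision ceiling is intrinsic to
the latent model: positive-definiteness caps the coupling near
1/√(max hub degree), so inferred networks jitter at n = 100 and roughly
half the top-ranked false positives are direct partners of planted hubs
(signal spillover rather than noise). Likewise, the all-features forest
baseline is hard to beat on this generator because compositional
renormalisation leaves the hubs a faint marginal footprint that 100-taxon
forests exploit.

## Numerical conventions

Natural log everywhere a log transform appears; zeros replaced by the
pseudo-count before logging. Correlations are clipped to [−1, 1]; constant
taxa get correlation 0 (logged) rather than NaN. All stochastic stages
take explicit integer seeds, and pipeline outputs are byte-reproducible
from a config file (no timestamps in artifacts). Problem sizes in the test
and acceptance runs (atlas graphs ≤ 7 nodes for exhaustive oracles, 200
random graphs ≤ 30 nodes for nesting, 20 seeds for recovery, n = 500 for
correlation null checks) were chosen as the smallest sizes at which the
respective statements are meaningful and stable.
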
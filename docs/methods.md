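# Methods

## Scope

`mergenet` integrates summary-level association data with gene annotations
and networks in three stages: marker set enrichment analysis (MSEA) scores
gene sets for enrichment of association signal; Meta-MSEA combines per-study
set-level results across studies; weighted key driver analysis (wKDA) finds
network hubs whose neighbourhoods are enriched for the disease-associated
sets. A simulation module generates all the synthetic inputs used to
calibrate and benchmark the pipeline.

## Data model and preparation

All association values live on the -log10 P scale internally; raw P-values
are converted at the file boundary. Duplicate markers keep the maximum
value, and duplicate or reciprocal network edges keep the maximum weight
(the weight encodes the reliability of an edge, so the strongest evidence
wins). Gene coordinates are 1-based inclusive and window tests use closed
intervals; strand is never consulted, so window mapping is strand-symmetric.

The default preparation order is: top-fraction filtering of the association
table (default 0.5 — weakly associated markers mostly add noise), marker-to-
gene assignment (default window 20 kb for SNPs; 50 kb is typical for
methylation sites), per-gene greedy dependency pruning (default r² < 0.5),
then merging of genes with shared markers. Pruning runs after assignment
because each gene's own marker list is the unit the permutation shuffles;
the greedy rule visits markers in descending association value, so the top
marker of every gene always survives. The shared-marker merge connects
genes whose marker-set Jaccard overlap reaches a cutoff and replaces each
connected component by a supergene (';'-joined id, union of markers). The
default cutoff 1.0 merges only identical marker sets — the least aggressive
choice, since a merge silently restructures the gene universe; lower values
are available. Whether filtering/pruning should precede or follow mapping
is genuinely open; both orders are reachable through the API, with the
above as the default.

## MSEA

For a gene set, the distinct markers of its member genes are collected and
compared against a ladder of study-wide quantile cutoffs:

    chi = sum_i (O_i - E_i) / (sqrt(E_i) + kappa)

with O_i the number of member markers at or above cutoff i (closed
threshold, for determinism under tied values), E_i = m·p_i for m distinct
member markers and background tail fraction p_i, and kappa = 1 damping the
contribution of cutoffs with small expected counts. Using quantiles of the
observed study rather than fixed P-value thresholds makes the statistic
adapt to studies of any power, and makes chi invariant under strictly
monotone transforms of the values (the scheme is rebuilt from the
transformed data; counts against interpolated quantiles depend only on
ranks).

Quantile placement: n = 10 cutoffs at upper-tail probabilities log-spaced
from 0.5 down to max(10/n_markers, 1e-4). The 0.5 anchor covers the signal
bulk; the floor keeps the smallest expected counts stable. Both n and the
ladder are overridable. Duplicate cutoffs (tied or constant data) collapse.

The null distribution is hierarchical and gene-based: each permutation
draws the same number of genes uniformly from the mapped universe, keeps
every gene's full marker list, and scores the union of distinct markers.
This preserves gene size and shared-marker structure, which a naive
marker-level shuffle would destroy (marker-label shuffling is available as
an explicit alternative). One null is simulated per distinct set size and
cached; the null hypothesis depends on the set only through its gene count,
and caching makes nperm = 10,000 (the default) tractable for large
collections. When C(universe, size) ≤ 1e5 the null enumerates all gene
sets exactly instead of sampling.

P-values: p_freq = (b+1)/(nperm+1) with b the number of null values at or
above the observation — never zero, which keeps every result convertible to
a Z-score. For an exhaustive null, p_freq = b/total is the exact
combinatorial tail probability (the observed configuration is one of the
enumerated sets, so b ≥ 1). When b = 0, the final P falls back to the upper
tail of a Gaussian fitted to the null by its sample mean and SD; the same
fit supplies the reported Z. The Gaussian is a pragmatic tail model chosen
for its direct P↔Z correspondence; heavier-tailed alternatives were left
out of scope. A degenerate null (zero variance) is scored only when the
observation equals the constant (then p_final = 1); anything else is an
error rather than a silent guess. Benjamini–Hochberg FDR is applied across
all tested sets on p_final.

Meta-MSEA converts each study's p_final to z = Phi^-1(1 - p) and combines
with Stouffer's method, z_meta = sum(w_j z_j)/sqrt(sum w_j^2) (unit weights
by default). P-values are clipped just below 1 before inversion so that
z stays finite for p_final = 1. Only sets scored in every study are
combined. Overlapping significant sets can afterwards be merged into
non-overlapping "subnetworks" at a gene-level Jaccard cutoff (default 0.2),
with enrichment typically re-run on the merged sets.

## wKDA

Hubs are nodes whose degree reaches the 0.75 quantile of the degree
distribution (ties included; a regular graph is all hubs). One adjustment
handles degenerate, minimum-dominated distributions: when the quantile
collapses onto the minimum degree while larger degrees exist (e.g. a star
graph, where 90% of nodes are leaves), the cutoff moves up to the smallest
degree above the minimum, so that low-connectivity nodes are still
excluded — the point of the screen.

Screened hubs are split into independent hubs and co-hubs by a greedy pass
in descending degree order: a hub joins the independent list only if its
neighbourhood Jaccard overlap with every accepted hub stays below 0.25;
otherwise it is recorded as a co-hub of the hub it overlaps most. Only
independent hubs enter the multiple-testing correction; co-hubs are
reported alongside their hub with their own statistic and unadjusted p.

Within a hub's neighbourhood, each neighbour's strength is the sum of its
edge weights to other neighbourhood nodes (hub included); the hub itself
receives the neighbourhood-average strength, since its raw strength is high
by construction. The observed score is the strength-weighted member share
of total strength scaled by the hub degree, O = ratio·N_k, which makes it
commensurate with the expected member count E = N_k·N_p/N (N network
order, N_p member genes on the network) under the isotropy assumption.
Random node relabelings indeed give E[O] = E exactly, which the tests
verify by Monte Carlo. The statistic is chi = (O-E)/(sqrt(E)+kappa) with
kappa = 1; a `denominator="minus"` variant ((O-E)/(sqrt(E)-kappa)) is
provided for comparison but is unstable near E = 1 and not recommended,
since kappa's purpose is to stabilise small expected counts.

Significance: node labels are permuted (equivalently, random member sets of
size N_p are drawn) with strengths and topology fixed, p = (b+1)/(nperm+1).
Correction is two-tier: within each set, independent-hub P-values are
multiplied by the number of independent hubs and values above 1 discarded
(the truncated remainder is uniform under the null); the survivors are
pooled across sets and converted to FDRs by Benjamini–Hochberg. Co-hubs of
discarded hubs are dropped with them. Directed input edges are symmetrised
at load; the analysis uses adjacency and weights only.

## Synthetic data and benchmark protocol

The generator emulates the study conditions the analyses are designed for:

- Control sets: 300 positive and 300 negative sets, 100 each of sizes 25,
  100 and 250, sampled from disjoint gene pools (the default plan; any plan
  can be supplied). Smoke-scale runs use 10+10 sets of size 25.
- Association studies: background -log10 P values from Uniform(0, 1]
  P-values (an exactly calibrated null); markers of planted genes receive
  an additive Exponential(mean = effect) bump. The uniform-plus-exponential
  law is this package's choice of "signal of a given magnitude": effect 0
  reproduces the null exactly and the planted mean shift equals the effect,
  which the tests check. The benchmark sweeps effects {0, 1, 2, 3}.
- Synthetic genome: genes carry 1 + Poisson(mean-1) markers (default mean
  3), giving the variable gene sizes that make hierarchical permutation
  meaningful.
- Networks: Barabasi–Albert (default, attachment 3) or Erdos–Renyi base
  graphs with Uniform(0.25, 1.0) weights; a planted module wires one hub to
  all members with weight 1.0. Rewiring replaces a fraction of edges either
  uniformly or by degree-preserving double-edge swaps, conserving node set,
  edge count and the weight multiset.
- Metrics: sensitivity (positives at FDR < 0.25), specificity (negatives at
  FDR ≥ 0.25), positive likelihood ratio sens/(1-spec) (infinity sentinel at
  specificity 1), ROC/AUC by threshold sweep, and key driver
  reproducibility as the Jaccard overlap of the significant (or top-k)
  independent hubs found on two networks. jaccard(∅, ∅) = 0 by convention.

What the synthetic data does not emulate: real LD block structure
(dependencies are supplied as an explicit r² table, never inferred),
population stratification, correlated markers between genes, the modular
overlap structure of curated pathway databases, and the directed, tissue-
specific character of real regulatory networks. Passing the synthetic
benchmarks therefore demonstrates internal statistical correctness
(calibration, recovery, robustness), not field performance on real GWAS.

## Numerical and testing choices

- Seeds: every stochastic routine takes a seed or Generator; per-size and
  per-set substreams are derived from the base seed so results do not
  depend on evaluation order.
- Probabilities are floored at the smallest positive float; meta-analysis
  clips P below 1 before Gaussian inversion.
- Ties: lexicographic id tie-breaks everywhere a selection could otherwise
  depend on dict/iteration order (top-fraction filter, pruning, co-hub
  ordering, output sorting).
- Null calibration checks use 200 random sets (sizes 10–40, nperm = 2000)
  and 200 hubs on an 800-node random graph (nperm = 2000); set sizes are
  spread so that the per-size null caching does not correlate the 200
  P-values through a handful of shared nulls. Recovery checks use effect 3
  with 10+10 control sets (nperm = 1000) and a 200-node network with a
  30-gene planted module (nperm = 500, medians over 5 rewiring seeds).
  These sizes keep the full suite comfortably within a desktop run while
  leaving the statistical conclusions unchanged at larger nperm.

## Limitations

- The permutation engines hold the per-gene marker index lists and, for
  wKDA, an nperm × N indicator block in memory; both are chunked but very
  large networks (N > 1e5) with nperm = 1e4 will be slow on one core.
- Edge directionality, effect directions and temporal structure are not
  modelled; the analyses use association strength and adjacency only.
- The Gaussian tail approximation can be optimistic for very skewed nulls;
  the frequency P is always reported alongside and takes precedence
  whenever any permutation reaches the observation.
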
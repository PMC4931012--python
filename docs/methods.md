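# Methods

This note records the models, conventions and numerical choices behind
`infantgut`, in the order the pipeline runs them.

## Composition profiles

The central object is a samples × taxa matrix of family-level relative
abundances. Inputs may be read counts, percentages or fractions; rows are
renormalized to probability vectors on read (an all-zero row is an error
naming the sample). Renormalization preserves within-sample ratios exactly.
Prevalence filtering for networks and heatmaps keeps taxa whose *mean*
abundance over the analysed sample subset is strictly above a threshold
(default 1%); the surviving columns are deliberately **not** renormalized,
because the filter selects variables, it does not redefine compositions. The
subset is an explicit argument — whether to filter within infants, adults or
pooled is the caller's scientific decision. Missing environment measurements
stay NaN; zero is a valid concentration and is never used as a missing code.

## Distance and clustering

Profiles are compared with the square root of the Jensen-Shannon divergence
computed with natural logarithms, so distances live in [0, sqrt(ln 2) ≈
0.8326]. Zero abundances contribute exactly 0·ln 0 = 0; no pseudocounts are
added, since JSD is finite for zeros and pseudocounts would silently perturb
every distance.

PAM is the classic two-phase algorithm. BUILD seeds greedily (first medoid
minimizes total distance; each later medoid maximizes the cost reduction).
SWAP repeatedly applies the best strictly cost-decreasing medoid/non-medoid
exchange until none exists. The algorithm is fully deterministic given the
distance matrix and its sample order: every tie — in seeding, in swap
selection, in nearest-medoid assignment — breaks toward the lowest sample
index. SWAP never increases cost, so the result is never worse than BUILD's;
it is a single-swap local optimum, which on small random instances coincides
with the exhaustive-search optimum about 95% of the time (instances exist,
even at n = 4, k = 2, where escaping the local optimum requires exchanging
two medoids at once).

The Calinski-Harabasz index is computed directly on the distance matrix via
the identity that a cluster's sum of squared deviations from its centroid
equals its sum of squared pairwise distances over twice its size:
W = Σ_c (1/2n_c) Σ_{i,j∈c} d²(i,j), T = (1/2n) Σ_{i,j} d²(i,j), B = T − W,
CH = (B/(k−1)) / (W/(n−k)). On Euclidean-embeddable distances this equals
the textbook coordinate CH to 1e-9 (tested against scikit-learn); computing
it on distances avoids committing to a truncated ordination.

### Cluster-number voting

Per trial, a uniform random subsample without replacement (default fraction
0.8) of the samples is re-clustered for every candidate k (default 2–10) and
the k with the highest CH wins the trial (CH ties go to the smaller k); the
modal winner over all trials (default 1,000) is the cluster number, and the
full vote histogram is reported. The subsample fraction and k range are
package choices, exposed and logged in every output, since reasonable
analyses may differ here. Tests and the acceptance script run 100–300 trials
rather than 1,000 — at the cohort sizes used the vote is effectively
unanimous and more trials only re-draw the same conclusion; the 1,000-trial
default stands in the library and CLI.

### Ordination and heatmap order

PCoA is classical Torgerson scaling: double-center −d²/2, eigendecompose,
scale eigenvectors by sqrt of the non-negative eigenvalues. Negative
eigenvalues (the non-Euclidean part; sqrt-JSD matrices can have small ones)
are reported but excluded from coordinates, and proportions explained are
taken over the positive spectrum. Axis signs follow the convention that each
axis's first nonzero loading is positive. Heatmap sample ordering uses
complete-linkage agglomeration via scipy; scipy's own ordering applies on
exactly tied merge heights.

## Cluster statistics

All tests are two-sided. The Mann-Whitney U statistic for the first sample
counts strict wins plus half-ties. The exact p-value enumerates the null U
distribution through the standard counting recurrence and is used when
n1+n2 ≤ 12 with no value shared across groups; otherwise (and whenever
cross-group ties occur) the normal approximation with tie and continuity
corrections applies. The approximation tracks the exact p to within 5%
relative error away from the far tail; in the far tail the continuity
correction biases it conservatively upward (absolute error stays below
0.01), which is the price of never under-stating a p-value.

The Bonferroni family is the set of cluster pairs within one variable (3
tests for 3 clusters) — the correction protects each panel's between-cluster
letters, not the whole variable collection; the family size is an explicit
argument for callers who want otherwise. Compact letter displays use
insert-and-absorb: start with one letter covering all groups, split it at
every significant pair, absorb redundant letters, and name letters in the
order of their earliest group. The emitted display always satisfies
"share a letter ⇔ not significantly different". Box summaries use type-7
(linear interpolation) quartiles — numpy's default, recorded here as the
package convention — with whiskers at the most extreme observations within
1.5 IQR of the quartiles.

## Transition dynamics

Clusters become named states via the family with the highest mean abundance
among member samples (ambiguity is an error and requires an explicit
naming); a per-sample dominance rule is available as an alternative but the
cluster route is the default. Transitions are counted between consecutive
*observed* samples per subject: missing days and not-tested samples are
bridged, and every counted transition carries its day gap in the output, so
long bridges remain auditable. No run-length smoothing is applied. The
forward fraction is the share of off-diagonal transitions moving later in
the declared S < E < B order; with no off-diagonal transitions it is
undefined and flagged rather than zero.

## Associations

Spearman correlations use average ranks for ties and the t-approximation
p = 2·P(T_{n−2} > |rho|·sqrt((n−2)/(1−rho²))); results at n < 10 are flagged
approximate (the exact permutation distribution is reserved for tests), and
constant inputs are untestable rather than zero-correlated. Network edges
require |rho| strictly above 0.3 **and** p strictly below 0.05 — a sample
rho of exactly 0.30 is excluded. Environment variables may join networks
and heatmaps as nodes/columns but never enter the 1% taxon filter, which is
about microbiota composition only. Edges use raw p-values; a Bonferroni
switch exists for callers who want multiplicity-corrected networks.

A caution the package inherits from its method: correlations among relative
abundances carry compositional closure — shares of independent raw signals
are negatively dependent (≈ −1/(k−1) for k equal shares, stronger against a
dominant stable family). The network reports what Spearman-on-shares sees;
compositionality-aware estimators are out of scope and the tests therefore
check the independence null on non-compositional variables.

## Strain screen

Growth phenotyping averages replicate OD600 curves pointwise (replicates
must share the time grid), median-smooths with a 3-point window (edge
padding — zero padding would clip a final plateau) to guard against
single-well spikes, and takes the smoothed maximum as the saturating OD.
Labels: grower above 0.7, non-grower below 0.3, indeterminate between;
indeterminate strains are excluded from the screen (and logged), never
forced into a class.

The concordance screen scans every homologous group in both orientations by
default — presence-with-growth and presence-with-non-growth — because a
discriminating absence would be equally reportable; hits are groups with at
most the tolerated number of mismatching strains, sorted by exception count
then group id for determinism, with each exception's direction listed. The
packaged 29-strain reference panel encodes the study strains' growth
phenotype and their GH29/GH95 fucosidase and FL-SBP transporter gene flags
literally from the published per-species rows; whether any strain within a
grouped row deviates on untabulated genes is not recoverable from that
source.

## Synthetic cohorts

The generator is the package's stand-in for the study data and defines the
conditions the tests assume:

* **Regimes.** Three Dirichlet regimes over 8 families, dominant
  concentration 20 against background 1 (dominant mean share ≈ 0.74).
  The cross-sectional survey adds an adult regime dominated by four
  adult-type families.
* **Dynamics.** A daily Markov chain ordered S < E < B with forward
  probability 0.15/day (S→E, E→B), backward 0.01/day (E→S, B→E), remainder
  staying. Initial distribution 0.5/0.4/0.1. These values make most
  subjects reach Bifidobacteriaceae dominance within the month with rare
  reversals, the qualitative behaviour the analysis is meant to detect.
* **Sampling.** 12 subjects, daily in week one then every other day to day
  27 (17 samples each); compositions are Dirichlet draws pushed through a
  multinomial at depth 2,000 reads and renormalized — compositional noise
  at realistic amplicon depth.
* **Environment.** acetate = 15 + 60·bifido + N(0,8) mM;
  pH = 6.8 − 1.5·bifido + N(0,0.3); residual oligosaccharide =
  30·(1 − 0.9·flu·bifido) + N(0,4) mM, truncated at 0 (pH clipped to
  (0,14)), where `flu` is a per-subject flag (P = 0.6) for colonization by
  fucosyllactose-utilizing bifidobacteria. Linear-Gaussian couplings are
  the simplest monotone stand-in for the observed associations; only the
  signs and monotonicity are scientifically meaningful.
* **Strain panels.** 29 strains, 2,000 homologous groups, background
  presence i.i.d. Bernoulli(0.5), 14 growers, one planted group equal to
  the phenotype with one flipped exception strain; logistic growth curves
  with carrying capacities in (0.9, 1.1) for growers and (0.05, 0.2) for
  non-growers, OD noise sd 0.01, two replicates over 0–40 h.

What passing on these cohorts shows — and what it does not: the pipeline
recovers planted structure under Dirichlet-multinomial compositional noise,
monotone environment couplings and Bernoulli gene backgrounds. Real cohorts
add features the generator deliberately omits: day-of-life trends within a
regime, subject-level effects beyond the regime chain and the flu flag,
sequencing error and contamination, phylogenetic correlation between gene
families, and batch structure. Results on synthetic data bound correctness,
not field performance.

## Problem sizes and determinism

Tests and the acceptance script use the study-scale cohorts (≈ 200
longitudinal samples, 49 survey samples) with 100–300 voting trials, 40–100
seeds for recovery-rate checks, and brute-force oracles up to n = 8 (PAM),
n1+n2 = 10 (Mann-Whitney) and n = 7 (Spearman permutations). Every
stochastic computation takes an explicit seed; the CLI and acceptance script
expand one run seed into per-stage streams via `numpy.random.SeedSequence`,
so stages can be reproduced in isolation and identical configurations
produce byte-identical outputs.

Recovery-rate assertions (planted k, planted gene group, transition
directionality, correlation signs) state claims about probabilities near
0.95 and are tested with a 3-sigma binomial allowance at the chosen number
of seeds, so they measure the claimed rate rather than one lucky draw.

## Known limitations

* PAM's SWAP is a single-swap local search; rare instances need multi-swap
  moves to reach the global optimum (observed even at n = 4).
* Spearman p-values are t-approximations; below n = 10 they are flagged and
  should be read qualitatively.
* The exact Mann-Whitney path declines data with cross-group ties rather
  than enumerating the conditional null with ties.
* Correlation networks on relative abundances inherit compositional
  closure; interpret negative edges accordingly.
* The subsampled voting procedure's subsample fraction and k range are
  conventions, not estimates; conclusions should be checked for robustness
  to them, which the config-and-manifest design makes cheap.
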
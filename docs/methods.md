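# Methods

This note records the models, the defaults, and the design choices made
where the procedure was genuinely open, in the order the pipeline runs.

## Nonparanormal transformation

Gaussian SEM assumes multivariate normality; bulk expression violates it.
Under a Gaussian copula each gene is a strictly monotone warp of a latent
Gaussian variable, and the rank-based transform
`z = Φ⁻¹(clip(rank/(n+1), δ, 1−δ))`, rescaled to unit sample variance,
recovers the latent scale. The truncation default is the shrunken-ECDF
rule `δ = 1/(4 n^{1/4} √(π log n))`; ties get average ranks. The transform
is applied once to the full matrix before any case/control split, so both
groups live on a common scale. Exact consequence (tested): any strictly
monotone per-gene warp of the input leaves the output bit-identical, and
zero-variance genes are a hard error rather than silently dropped.

## RICF

Acyclic path diagrams with directed (B) and bidirected (Ω) edges are
fitted to the sample covariance by residual iterative conditional fitting:
each node's incoming directed coefficients and bidirected residual
covariances are updated by a conditional regression that uses
pseudo-variables built from the other nodes' current residuals, sweeping
until the largest parameter change falls below `tol` (default 1e-6,
`max_iter` 100). On a pure DAG one sweep reproduces per-node least squares
exactly; on bidirected models the fit agrees with direct numerical ML
maximization to ~1e-4 (both are test oracles). A fit that exhausts
`max_iter` is reported `converged=False` and the pathway is excluded from
the results table instead of raising — mirroring how non-converging
pathways are reported in practice. Directed cycles in input pathway
topologies are pre-broken by removing the back-edge set of a deterministic
(sorted-order) depth-first search.

## Gene-set analysis

The group (1 = case, 0 = control) is added as an exogenous parent of every
pathway gene; RICF yields each gene's conditional group effect and an
observed-information SE from the node's conditional regression. One-sided
p-values use Student-t tails with df = n − 1 − (regressors in the node's
equation): at n ≈ 35–40 the normal tail is measurably anticonservative
(empirical type-I ≈ 0.07 at nominal 0.05 in our null simulations), while
the t correction restores ≈ 0.05.

Brown's method combines the per-gene one-sided p-values with the
Kost–McDermott moment match: `X = −2Σ ln p ~ c·χ²_f` with `E[X] = 2k` and
`Var[X] = 4k + 2Σ_{i<j} cov_ij`, `cov_ij = r(3.263 + 0.710r + 0.027r²)`
for r ≥ 0 and `r(3.246 + 0.660r)` for r < 0. The correlation proxy R for
the node statistics defaults to the **fitted residual correlation**
(Ω normalized): the node tests condition on each gene's parents, so their
dependence is the residual one, and for a well-specified DAG they are
nearly independent (Brown then reduces to Fisher). Using marginal
expression correlations instead — available via `node_corr="expression"` —
systematically overstates the dependence of conditional statistics and
drove the pathway test's type-I error to ≈ 0.005 at nominal 0.05 in null
simulations (n = 20/group, 10 correlated genes), versus ≈ 0.06 for the
residual default. The choice is therefore a calibration-driven design
decision, not a tuning knob.

Pathway verdicts: `pval = min(2·min(pNa, pNi), 1)` (a Bonferroni bound
over the two one-sided combinations; the two sides are complementary per
gene, so the bound is nearly tight), `ADJP = min(K·pval, 1)` over the K
converged pathways, status "Up" iff pNa ≤ pNi. DEGs are genes whose
two-sided p survives Benjamini–Hochberg within the pathway at α = 0.25 —
deliberately permissive, since the seed list should carry as much signal
as possible into module extraction.

## Edge weighting and Steiner tree

Per interactome edge, Pearson correlations are computed within each group
and compared by Fisher's r-to-z:
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`, two-sided normal p.
The p-value is clamped to [1e-16, 1−1e-16] before the distance
`w = 1/(−ln p)` (natural log), keeping w finite and strictly positive;
strongly rewired edges are cheap. Duplicate orientations and bidirected
tags collapse to one undirected weighted edge — orientation is re-derived
later by the DAG search.

Kou–Markowsky–Berman approximation: metric closure over seeds (Dijkstra),
MST of the closure, expansion into shortest paths, second MST, iterative
pruning of non-seed leaves. All tie-breaks (Dijkstra predecessors, Kruskal
edge order) are lexicographic, so the tree is identical across runs. The
cost is within 2(1 − 1/ℓ) of the optimum; the suite verifies the factor-2
bound against an exhaustive connector-subset oracle on 100 random
instances. Seeds missing from the graph are dropped with a warning;
seeds split across components are an error at the library level, while the
pipeline driver restricts to the component containing the most seeds.

## DAG search and SEM fitting

**Order.** The tree skeleton is oriented by the top-down
conditional-variance greedy for equal-noise linear SEMs: repeatedly append
the remaining node with the smallest residual variance given the ordered
set (lexicographic ties). This uses the data on their original scale —
per-gene standardization erases the variance signal, in which case the
orientation degrades gracefully to an arbitrary Markov-equivalent one.
The synthetic generator's equal noise SDs match this assumption, and
orientation recovery is tested (SHD ≤ 1 in ≥ 80% of replicates at
n = 1000).

**Sparsity.** Given the order, each node keeps its tree parents
unpenalized (an infinite penalty therefore returns exactly the oriented
tree) while a Lasso on the residualized remaining earlier nodes, swept
over a geometric penalty grid (default 0.01–0.5, 8 points) and scored by
BIC after an OLS refit, may add non-tree parents. Null simulations confirm
BIC rarely buys spurious edges.

**Estimation.** Models A and B standardize within their group; Model C
step 1 standardizes on the pooled sample (this, plus a shared DAG, is what
makes db = β_A − β_B an exact identity — validated both on our fits and on
the published coefficient tables, where all 10 edges reproduce the printed
db within ±0.002 rounding). De-biased node-wise estimation defaults to OLS
on the full parent set — the de-biased-Lasso limit when n comfortably
exceeds every parent set, as it does for an 11-node module with 35
samples; an explicit `alpha` enables Lasso selection with an OLS refit on
the support. SEs are observed-information; CIs are β ± 1.96·se; tests are
two-tailed z. SRMR is computed as
`√(mean lower-triangle-incl-diagonal (S_obs − S_imp)²)` with
`Σ_imp = (I−B)⁻¹ Ω (I−B)⁻ᵀ` rescaled to a correlation matrix.

**De-confounding.** The reference procedure is not fully specified; this
package reports non-adjacent node pairs whose post-fit residual
correlation exceeds a threshold (default 0.4) as candidate confounding in
`ActiveModuleDAG.confounded_pairs` rather than mutating the graph — an
deliberately transparent approximation.

## Communities and enrichment

Walk-trap (Pons–Latapy, t = 4 steps, unit weights by default) is delegated
to python-igraph and cut at maximum modularity; modularity itself is this
package's own closed form `Q = Σ_c [e_c/m − (d_c/2m)²]`, cross-checked
against networkx. Directed graphs are symmetrized; isolated nodes become
singleton communities; community ids are renumbered contiguously from 1 by
smallest member. Unit weights are the default because the published
11-gene module partition and its Q = 0.455 are reproduced exactly under
them. Enrichment is the exact hypergeometric upper tail per
(community, set) with BH across sets within a community — a standard,
reproducible substitute for service-bound empirical corrections, noted in
the result metadata.

## Synthetic data

The generator emulates the analyzed study shape: 17 cases / 18 controls by
default, continuous expression from a linear-Gaussian SEM over a random
DAG (random topological order + Bernoulli(edge_prob) forward edges), unit
noise SD, edge coefficients ~ ±U(0.3, 0.9), node perturbations as additive
group effects (default ±1.0 SD on 3 nodes) and edge perturbations as
between-group coefficient differences (default ±1.0 on 2 edges). Null
pathways use fresh genes with equal coefficients in both groups and no
group effects, so they satisfy the no-perturbation null exactly. Monotone
marginal warps (exp, cube, logistic) produce Gaussian-copula data for
testing the nonparanormal stage. What it does **not** model: counts,
library-size or dispersion effects, batch structure, identifier noise, or
dependence between pathways — so green tests certify the statistical
machinery under its stated assumptions, not robustness to raw RNA-seq
artifacts (upstream normalization is assumed done).

Problem sizes in the test suite are chosen to make each check sharp but
cheap: 1000-replicate calibration checks use one- or two-gene models,
recovery checks use n = 500–1000 with ≤ 10 nodes, and the exhaustive
Steiner oracle runs on ≤ 10-node graphs.

## Known limitations

- Pathway p-values (Table-style outputs) depend on the pathway topology
  being roughly right; RICF conditions on the declared parents.
- The causal order is a heuristic; with standardized input, orientation is
  only identified up to Markov equivalence.
- Brown's polynomial is an approximation fit for moderate correlations;
  extreme negative dependence is handled by a variance floor.
- The walk-trap dendrogram cut maximizes modularity, which has a known
  resolution limit on very small or very large graphs.
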
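# Methods

## Model family

The package implements a generative model for undirected interaction
networks in which every link is emitted by a latent *component*.  With `C`
components, `M` nodes and `N` links:

1. a component distribution `θ ~ Dirichlet(α, …, α)` over the `C`
   components;
2. per component, a node distribution `φ_z ~ Dirichlet(β, …, β)` over the
   `M` nodes;
3. each link draws its component `z ~ Multinomial(θ)` and then its two
   endpoints i.i.d. from `φ_z`.

Because links, not nodes, carry the component label, a node belongs to
every component that explains some of its links; the node-level output is
the posterior membership distribution `p(z | i)`, making the recovered
modules inherently overlapping.  Noise tolerance comes for free: an
inter-module link is simply a low-probability draw, not a constraint
violation.

Two extensions integrate gene expression:

* **Correlation links** (the "g1" variant): gene pairs whose Pearson
  correlation exceeds 0.85 become additional links, pooled with the
  physical interactions as a multiset (a pair found by both sources counts
  twice, and so carries twice the weight in the likelihood).  Strongly
  negative correlations are ignored.
* **Joint emission** (the "g2" variant): the same components also emit one
  expression profile per node.  A node datum draws its component from the
  shared `θ`, its node identity from `φ_z`, and its profile from
  `N(μ_z, σ²I)` with a conjugate prior `μ_z ~ N(μ₀, σ₀²I)`.  Covariances
  are spherical throughout, so all Gaussian updates reduce to per-dimension
  scalars.  The model is deliberately *not* constrained to assign a node's
  datum to a component its links use.

## Inference

All multinomial parameters (and the component means in the joint variant)
are integrated out analytically; collapsed Gibbs sampling updates only the
discrete assignments.  The sufficient statistics are `n_z` (links per
component), `q_zi` (endpoint/node draws of node `i` in component `z`),
and, in the joint variant, `m_z` (node data per component) and the
per-component data sums.  The held-out conditional for a link with
endpoints `(i₀, j₀)` is

    p(z₀ = z | rest) ∝ (n'_z + α) · (q'_{z,i₀} + β) · (q'_{z,j₀} + β + [i₀=j₀])
                        / ((2n'_z + Mβ) · (2n'_z + Mβ + 1))

(primes: counts without the held-out link).  In the joint variant the
component-prior counts pool links and node data (`n + m`), the node-draw
totals become `2n_z + m_z`, and a held-out node datum additionally carries
the Gaussian posterior-predictive factor `N(x_i | A'_z, (S'_z + σ²)I)` with
the conjugate update `S = 1/(1/σ₀² + m_z/σ²)`, `A = S(μ₀/σ₀² + Σx/σ²)`.
Every conditional is verified in the test suite against brute-force
enumeration of the exact collapsed joint on small instances, computed by an
independent sequential Pólya-urn/predictive construction.

Numerical conventions:

* the two endpoints of an unordered link are two sequential draws from
  `φ_z`; the constant ×2 multiplicity for distinct endpoints is omitted
  everywhere (it cancels in conditionals and shifts the joint by an
  assignment-independent constant);
* `α` is the *per-component* concentration (counts enter as `n_z + α`,
  normalizer `N + Cα`), matching the per-node use of `β`;
* the collapsed joint log-probability includes all Γ-normalization terms,
  so values are comparable across different `C`; an empty network scores
  exactly 0;
* Gaussian predictive factors are computed in log space and normalized by
  max-subtraction;
* sweeps visit links (then node data) in fixed index order — collapsed
  Gibbs is valid under any scan order, and a fixed order makes runs
  bit-reproducible (randomized scan was measured and changed nothing);
* ties in crisp assignment break to the lowest component index.

### Chain schedule and restarts

The default schedule is 19 000 burn-in sweeps followed by 20 samples at an
interval of 50; memberships are averaged over the samples without label
alignment (spaced snapshots of a single converged chain do not switch
labels in practice).  With the compiled (numba) sweep kernels this full
schedule costs about a second on a 100-node / 600-link problem, so no
reduced schedule is needed anywhere, including the test suite.

Single-site collapsed Gibbs on strongly modular networks has a known
failure mode: a small fraction of chains (≈10–15 % on the planted
benchmark below, under any scan order or initialization we tried) locks
into a minor posterior mode in which two planted modules merge and one
component remains essentially empty.  The mode is clearly identifiable —
its collapsed joint log-probability sits far below that of the dominant
mode — but is nearly absorbing at practical chain lengths.  The package
therefore provides a standard multi-restart protocol (`run_chain_best`,
`run_chain_g2_best`): run `n_init` independent chains (default 5) and keep
the one whose recorded samples have the highest mean collapsed joint
log-probability.  Selection uses only the model's own probability, never
any external reference.  All benchmark results below use this protocol.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `C` | data-dependent | number of components; fixed a priori (no model selection) |
| `α` | 10 | Dirichlet concentration per component; large values keep all components in play |
| `β` | 0.01 | Dirichlet concentration per node within a component; small values give sharply concentrated modules |
| `μ₀` | 0 | prior mean of a component's expression mean (log-ratio scale) |
| `σ₀²` | 1 | prior variance of component means: modules differ by O(1) |
| `σ²` | 0.1 | within-component observation noise |
| burn-in / samples / interval | 19000 / 20 / 50 | chain schedule |
| `n_init` | 5 | independent restarts in the best-chain protocol |
| KNN `k` | 10 | neighbours for expression imputation |
| correlation cutoff | 0.85 | strict threshold for expression links |

All defaults were fixed a priori; none is tuned per dataset.

## Synthetic benchmark

`PlantedDesign` plants 10 modules of 10 base nodes.  Links appear
independently: probability 0.9 within a module, 0.01 between modules.
Overlap: modules are arranged on a ring and, for each adjacent pair, the
first two nodes of one module are additionally wired to all base nodes of
the neighbour with the intra-module probability, making them members of
both.  This is one minimal, symmetric realization of "each module shares
two nodes with at least one other module"; the pairing rule is
configurable (`n_shared_per_pair`), and the exact wiring is a design
choice, so a specific realized link total is not a reproducible quantity
(expected ≈ 628 links; realizations vary by ±25).  Ground truth assigns
shared nodes 0.5/0.5 to their two modules and every other node 1.0 to its
own.

The expression generator draws component means from `N(μ₀, σ₀²I)`, each
node's component from its ground-truth row, and profiles from `N(μ_z,
σ²I)` — exactly the joint model's own process, which is what makes
parameter-recovery tests meaningful.

What the generator does *not* emulate about real PPI/expression data:
degree heterogeneity (hubs), assortative noise in interaction screens,
correlated conditions and batch structure in expression, and missing
values (missingness is exercised separately in the imputation tests).
Passing benchmarks here demonstrate correctness of the inference
machinery, not performance on real screens.

## Evaluation statistics

* **Membership distance**: mean over nodes of the Euclidean distance
  between estimated and ground-truth membership rows.  Distance is not
  invariant to component relabeling, so estimated components are first
  aligned to truth by maximum-agreement (Hungarian) matching on column dot
  products.  One scalar per run; runs are averaged.  The binarized variant
  first collapses each row to its argmax indicator, reproducing what a
  hard-assignment method would report (a shared node then always
  contributes √2/2 ≈ 0.707 to the sum, so with 20 shared nodes among 100
  the binarized statistic cannot fall below ≈ 0.141).
* **Perplexity**: `exp(−(1/N) Σ log p(c_l | m_l))` over a cluster × class
  confusion table with row-normalized empirical conditionals.  1 means
  class-pure clusters; the number of classes is the upper bound.  The
  plug-in estimate is upward-biased at small `N`; comparisons are only made
  at equal `N`.
* **Standard classes from a term DAG**: descending from the root(s),
  annotation counts (restricted to the evaluation universe) shrink; where a
  child's count drops below the cutoff the parent is emitted as a class.  A
  term at/above the cutoff with no child at/above it is its branch's
  frontier and emits itself.  Classes with more than 300 genes are
  dropped; children are visited in lexicographic order for determinism.
* **Enrichment sweep**: one-sided hypergeometric (Fisher exact) p-value per
  (module, class) pair over the clustered-gene universe; counts of enriched
  modules/classes at cutoffs 10⁻¹ … 10⁻¹⁰.  No multiple-testing correction
  by default (the cutoff sweep plays that role); Benjamini–Hochberg is
  available as an option.
* **Complex coverage**: per complex, the largest fraction of its proteins
  (those present in the clustered dataset — the denominator deliberately
  excludes proteins absent from the data) captured by a single module;
  reported as a histogram (default: ten equal bins on (0, 1]).

## Problem sizes used in the shipped analyses

The planted benchmark (100 nodes, ≈ 630 links, C = 10, 10 independent
runs, 5 restarts each, full 19000/20/50 schedule) is the reference
experiment for both the distance statistics and parameter recovery; it
completes in well under a minute per 10-run experiment.  Enumeration
oracles use instances of ≤ 6 items (links + node data) with C = 2, the
largest size for which exact summation over all assignments is practical.

## Known limitations

* The number of components is fixed a priori; no Dirichlet-process or
  information-criterion selection is provided.
* There is no explicit noise component for inter-module links; such links
  are only absorbed as low-probability draws.
* Component means are global across conditions in the joint variant;
  condition-specific structure is not modelled.
* Memberships are averaged across MCMC samples without label alignment;
  this is safe for well-separated modes but would blur genuinely
  label-switching chains.
* The merged-module minor mode is handled by restarts, not by split–merge
  moves; pathologically multimodal posteriors may need more than the
  default five initializations.
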
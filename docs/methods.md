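# Methods

## Model

P-values from a differential-expression analysis are modelled as a
two-component beta-uniform mixture (BUM): null p-values are
Uniform(0,1); signal p-values follow Beta(a,1) with shape 0 < a < 1,
which concentrates density near zero. The mixture density is
f(x|a,λ) = λ + (1−λ) a x^(a−1) with mixing weight λ on the uniform
component. The model assumes p-values are independent draws from this
mixture; correlation between genes (co-regulation, shared probes) is
ignored, as is any deviation of the null from uniformity (e.g. from a
misspecified test).

Because the uniform density is a boundary case of the beta family, the
model is **not identifiable at the no-signal limit**: a → 1 with any λ
and λ → 1 with any a describe the same flat density. The identifiable
summary is π̂ = λ + (1−λ)a, the upper bound on the null proportion.
`fit_bum` therefore breaks near-exact likelihood ties (within 1e-4 log
units) toward larger λ — the conservative reading that attributes the
flat component to the null — but on genuinely uniform data the
unconstrained MLE can still land on the a-ridge; downstream quantities
(π̂, τ, scores) are insensitive to which ridge parameterisation is
returned.

## Scoring

From a fit, the significance threshold controlling the estimated FDR
upper bound at level α is τ = ((π̂ − αλ)/(α(1−λ)))^(1/(a−1)). The
per-gene score is S(x) = (a−1)(log x − log τ), natural log: zero at τ,
positive below, strictly decreasing in x. When α > π̂ the formula gives
τ > 1; τ is clipped to 1 with a warning (every gene scores ≥ 0). The
precondition αλ < π̂ cannot fail for a valid fit (π̂ > λ ≥ αλ when
α < 1); it is checked only to reject malformed parameter sets.

Exact zero p-values are clamped to 1e-300 (configurable) before fitting
and scoring, since the density diverges at the origin; p = 1 is kept.

## Optimisation problem

For a module A (a set of nodes inducing a subgraph of the network):

* activity S_A = Σ_{x∈A} S(x), to maximise;
* coverage R_A = number of pathways with cover rate
  R_i = |V_i ∩ V_A|/|V_i| **strictly** greater than R_ratio, to
  maximise;
* constraint: the induced subgraph must be connected.

Connectivity is decided through the algebraic connectivity (Fiedler
value), the second-smallest eigenvalue of L = D − A of the induced
subgraph, computed with a dense symmetric eigensolver (modules are
small relative to the network, so sparse iterative machinery is
unnecessary). A value above 1e-8 counts as positive, absorbing
floating-point noise; tests cross-check against traversal connectivity
on hundreds of random graphs. Single-node modules are connected by
convention (a 1×1 Laplacian has no second eigenvalue); empty modules
are infeasible.

The cover-rate denominator |V_i| is the full annotated pathway by
default, even when some members are absent from the network; the
alternative (restrict pathways to network nodes) is available via
`restrict_to_network` / `--restrict-pathways-to-network`. The default
is the stricter reading: a pathway does not become easier to cover just
because the network misses half of it.

## Search engine

A modified NSGA-II over binary membership vectors of length |V|. The
node order is lexicographic by gene id, fixed at load time and recorded
in the output — crossover semantics depend on the ordering, so it must
be deterministic. Internally both objectives are negated
(minimisation); all reports use the maximisation scale.

* **Initialisation**: the `population_size` nodes with the highest
  scores (ties by gene id) seed one module each — every node, if the
  population exceeds the network — and each seed immediately absorbs
  its positive-scoring neighbours, so initial modules are connected.
* **Parent selection**: binary tournament under constrained dominance
  (feasible beats infeasible, then lower rank, then larger crowding,
  then a coin flip). When the fraction of duplicated selections exceeds
  `tournament_skip_dup_fraction` (default 0.5) the step is skipped and
  the whole population reproduces — relieving selection pressure once
  the population has converged.
* **Crossover**: single-point on the bit vectors, cut uniform in
  1..|V|−1 (rate 0.9). Offspring may be disconnected; they are not
  repaired — the constraint handles them.
* **Mutation**: growth only — add `mutation_additions` (default 1)
  uniformly drawn neighbours of the module that have positive score or
  belong to ≥ 1 pathway. Adding only neighbours preserves
  connectivity; there is no deletion operator, so module shrinkage
  arises only from crossover. Restricting the pathway clause to
  neighbours (rather than arbitrary pathway genes) keeps the operator
  connectedness-preserving.
* **Clearing**: all but the first copy of each duplicated selection are
  marked infeasible and disappear at replacement, preventing replica
  pile-up near optima.
* **Replacement**: parents + offspring (2N) are sorted by constrained
  fast non-dominated sorting with crowding distance; the best N
  survive. Extreme points of a front carry infinite crowding, so the
  best feasible S_A (and R_A) ever found is never truncated — elitism,
  asserted from the per-generation history in tests.
* **Stopping**: a fixed generation count (default 200); the method has
  no natural convergence criterion.

The run is bit-reproducible from `rng_seed`: one seeded PCG64 generator
drives every stochastic choice and all tie-breaks are deterministic.

For reporting, the front's **extreme points** are the max-S_A and
max-R_A members, and the **knee** is the member with maximum
perpendicular distance from the line joining the extremes after min-max
normalising both objectives (degenerate fronts — fewer than three
members or a flat objective — fall back to the max-S_A extreme).

## Network construction

`build_network` implements the interactome filter: keep exactly the
interactions with at least one endpoint whose adjusted p-value is
≤ 0.05 (default), then take the graph on nodes incident to kept edges —
retaining indirect interactions through one non-significant partner.
Input graphs are simplified on load (self-loops and duplicate edges
dropped with a logged count), covering multi-evidence interaction
databases that repeat edges.

## Synthetic benchmark

The generator emulates the data the method expects. Defaults: a
300-node Barabási–Albert graph (m = 2; heavy-tailed degrees, as in
interactome data), a planted connected module of 25 nodes grown by
seeded breadth-first expansion, signal p ~ Beta(0.1, 1) by inverse
transform u^(1/a), background p ~ Uniform(0,1), and 20 pathways of
10–30 genes of which 5 draw ≥ 80% of their members from the planted
module. It does **not** mimic gene–gene correlation, probe-level noise,
or the exact degree sequence of any real interactome, so passing
recovery tests demonstrates correctness of the machinery under the
model's own assumptions, not performance on real microarray data.

The default search configuration uses α = 0.05 (the conventional FDR
level; with ~8% signal genes this yields τ ≈ 2–3 × 10⁻³ and a
manageable positive-score set). Stringent levels such as 10⁻⁴ are
appropriate when most of a network is significant and module size needs
reining in — both presets for R_ratio (0.6 and 0.8) are exposed the
same way.

Recovery is scored by Jaccard/precision/recall of each front member
against the planted truth. At these settings the max-S_A member
typically reaches Jaccard ≈ 0.55–0.75: the planted module contains
genuinely weak-signal nodes (Beta(0.1,1) puts ~20% of signal p-values
above 0.1) that an activity-maximising module rightly omits.

## Numerical choices

* MLE: L-BFGS-B on the box [1e-6, 1−1e-6]², restarted from the five
  best points of a 10×10 grid plus one high-λ start; objective
  tolerance 1e-8. Tests require the optimum to match a 100×100 grid
  oracle within 1e-3 log-likelihood units.
* Quadrature check: the density integrates to 1 within 1e-6 for random
  parameter draws.
* Coverage counting uses a dense pathway-by-node indicator matrix; at
  desk scale (≤ a few thousand nodes) this is faster and simpler than
  sparse structures.
* Problem sizes in the test suite (300-node benchmark, population 50,
  200 generations, three seeds) complete in seconds and were chosen as
  the smallest instances at which planted-module recovery is stable.

## Limitations

* Single-point crossover on a lexicographic node order has no spatial
  meaning on the graph; most crossover offspring of dissimilar parents
  are disconnected and rejected by the constraint, so search progress
  leans on mutation and on crossover between similar parents. This is
  inherent to the bit-vector representation.
* No deletion operator: a spuriously added node can only leave a
  lineage via crossover.
* The Pareto front depends in principle on the node ordering and seed;
  only the front's invariants (connectivity, mutual non-domination,
  elitism) are guaranteed, not a particular solution count.
* Gene identifiers are matched verbatim; no namespace mapping between
  network, p-value table and pathway files.
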
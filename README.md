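# pamod — prior-knowledge-guided active module identification

`pamod` finds **active modules**: connected regions of a molecular
interaction network whose genes show coordinated, significant changes in
expression. Instead of optimising activity alone, it treats module
identification as a **two-objective** problem — maximising the module's
activity score *and* its coverage of known pathways — and returns a
Pareto front of connected modules spanning the trade-off between
data-driven novelty and prior knowledge. It is aimed at systems-biology
analysts who have (1) a network (e.g. protein–protein interactions),
(2) per-gene differential-expression p-values, and (3) a pathway
collection in GMT format.

## Method

**Node scoring.** The p-value distribution is modelled as a
beta-uniform mixture (BUM): nulls are Uniform(0,1), signals Beta(a,1),

> f(x | a, λ) = λ + (1 − λ) a x^(a−1),  0 < a, λ < 1,

fitted by maximum likelihood. With π̂ = λ + (1 − λ)a (an upper bound on
the null proportion), the threshold that controls the estimated FDR at
level α is

> τ = ((π̂ − αλ) / (α(1 − λ)))^(1/(a−1)),

and each gene gets the additive score
S(x) = (a − 1)(log x − log τ): zero at τ, positive below it.

**Objectives.** For a module A: the activity score S_A = Σ_{x∈A} S(x),
and the pathway coverage count R_A = |{i : R_i > R_ratio}| where
R_i = |V_i ∩ V_A| / |V_i| is the fraction of pathway i inside A.

**Search.** A modified NSGA-II over binary membership vectors:
seeded initialisation from top-scoring nodes, single-point crossover,
growth mutation (adding a neighbouring node with positive score or
pathway membership), a clearing step that marks duplicated solutions
infeasible, and a connectivity constraint — a module is feasible only if
its induced subgraph has positive **algebraic connectivity** (the
second-smallest eigenvalue of the Laplacian L = D − A). Feasible
solutions dominate infeasible ones; fast non-dominated sorting and
crowding distance drive elitist replacement.

## Worked example

Generate a synthetic benchmark (300-node scale-free network with a
planted 25-node active module and 20 pathways, 5 of which overlap the
module), fit the mixture, and search:

```bash
pamod generate --out demo --seed 7
pamod fit-bum --pvalues demo/pvalues.tsv --alpha 0.05 --out demo/fit.json
pamod search --network demo/edges.tsv --pvalues demo/pvalues.tsv \
             --gmt demo/pathways.gmt --seed 7 --out demo/run
pamod report --run demo/run --network demo/edges.tsv \
             --pvalues demo/pvalues.tsv --gmt demo/pathways.gmt
```

Output of the run above:

```
n=300  a=0.08435  lambda=0.9362  pi_hat=0.9416  tau=0.002121  loglik=117.3615
6 Pareto module(s) written to demo/run
module  size  s_a         r_a  labels
0       13    112.715347  0    max-S_A
1       16    105.894735  1    knee
2       18    103.366931  2
3       19    101.348803  3
4       20    99.345274   4
5       20    97.710345   5    max-R_A
```

The fit reads ~94% of genes as null (π̂ = 0.94) and sets the
significance threshold at τ ≈ 2.1 × 10⁻³. The front spans the trade-off:
module 0 is the most active (S_A = 112.7) but covers no pathway beyond
the 60% threshold; module 5 sacrifices activity to cover 5 pathways;
the knee (module 1) is the balanced compromise. Each `module_<id>.txt`
is a plain gene list ready to paste into a GO enrichment web tool, and
`run.json` records the configuration, input checksums and
per-generation history needed to re-run the search bit-identically.

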
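# formulanet

Network pharmacology for multi-herb formulas. A traditional prescription
pools hundreds of compounds acting on overlapping target sets; the question
is which targets carry the formula's pharmacology, how close those targets
sit to disease genes in the interactome, and what each herb contributes.
`formulanet` implements that analysis as a reusable, tested pipeline, with
synthetic-data generators (planted ground truth) so every stage can be
validated without database downloads.

The pipeline, stage by stage:

1. **Drug-likeness screening** — QED, the weighted geometric mean of eight
   desirability-transformed descriptors (MW, ALOGP, HBA, HBD, PSA, ROTB,
   AROM, ALERTS):
   `QED = exp( Σᵢ wᵢ ln dᵢ(xᵢ) / Σᵢ wᵢ )`, compounds kept at QED > 0.25.
2. **Target prioritisation** — a target hit by *k* of *n* compounds is
   tested against `P(X ≥ k)` for `X ~ Binomial(n, g/n)` (*g* = mean
   compounds per target), BH-adjusted; the gene score is
   `GS = −log₁₀(P_adj) / rank(P_adj)` when `P_adj ≤ 0.05`, else 0, and a
   compound's score CS is the mean GS over its targets. Genes with GS > 0
   are the formula's **core targets**.
3. **Multilayer networks** — for a query gene set on a PPI: the core net
   (CN, induced subgraph), the shortest-path-extending net (SPEN, adds all
   intermediates of shortest paths ≤ 3 edges between query pairs) and the
   neighbor-extending net (NEN, adds direct neighbors); node overlap
   between two networks is `|N_A ∩ N_B| / min(|N_A|, |N_B|)`.
4. **Enrichment** — hypergeometric over-representation against GMT
   collections, BH-adjusted at 0.01, with common-term cumulative curves and
   trapezoidal AUCC to rank diseases.
5. **Proximity** — mean shortest-path distance (SPD) and random walk with
   restart, `x_{t+1} = (1−γ) M x_t + γ x₀` (γ = 0.7, seeds = disease
   genes), scored as 1000 × mean stationary probability over the targets;
   significance by uniform permutation of the disease-sized seed set
   (empirical and normal-tail parametric p).
6. **Modules** — partitions scored by `MS = Q + BHI` (modularity plus the
   biological homogeneity index); greedy-modularity and density-expansion
   detectors are bundled and external partitions can be ingested and scored.
7. **Herb roles** — per-herb GS-ranked targets, cumulative RWR-score curves
   against a disease, AUCC ranking of herbs.

## Worked example

Everything below is synthetic with planted ground truth:

```python
from formulanet import pipeline

cfg = pipeline.simulate_inputs("demo", seed=5, n_nodes=300, n_compounds=400,
                               n_core=30, n_modules=4, module_size=10)
cfg.n_perm = 200
summary = pipeline.run_pipeline(cfg)
```

This writes every stage's table under `demo/results/`. With this seed the
screen keeps 320 of 400 compounds (the generator planted an 80% drug-like
fraction), recovers all 30 planted core targets (`n_core = 30`), and the
proximity stage prints:

```
disease method     type  average_score  p_empirical  p_parametric
   near    SPD original       2.849333     0.039801      0.027420
   near    SPD shuffled       2.976733          NaN           NaN
   near    RWR original       7.342634     0.004975      0.000278
   near    RWR shuffled       2.964940          NaN           NaN
 random    SPD original       3.096000     0.955224      0.950606
 random    SPD shuffled       2.977940          NaN           NaN
 random    RWR original       2.742697     0.507463      0.559082
 random    RWR shuffled       2.939167          NaN           NaN
```

Reading it: the disease set planted *near* the core targets sits closer
than chance (SPD 2.85 vs 2.98 shuffled) and receives ~2.5× the random-walk
mass (RWR 7.34 vs 2.96, parametric p ≈ 3×10⁻⁴), while the uniform-random
control set is indistinguishable from its permutation null — exactly the
contrast the proximity stage is meant to detect. The module stage ranks the
greedy partition (Q 0.398 + BHI 0.152 = MS 0.549) above the density
detector's (MS 0.376) on the formula's SPEN.

The same stages are exposed as subcommands:

```sh
formulanet simulate --out demo --seed 5
formulanet screen --descriptors demo/descriptors.tsv --cutoff 0.25 --out qed.tsv
formulanet score-targets --interactions demo/interactions.tsv --out scores
formulanet proximity --ppi demo/ppi.tsv --targets demo/results/core_targets.txt \
    --disease demo/disease_near.txt --nperm 2000 --seed 1 --out proximity.tsv
```

A bundled worked-example dataset (the published 140-gene core-target list
of the seven-herb Ban-Xia-Xie-Xin-Tang formula, its approved-drug target
rows for colitis / diabetes mellitus / gastric cancer, the printed
module-detector Q/BHI panel, and the 8-gene toy network that illustrates
the layer constructions) is available through `formulanet.datasets`.

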
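# Methods

This note records the models the package implements, the conventions chosen
where the underlying methodology leaves room, and what the synthetic-data
experiments do and do not demonstrate.

## Drug-likeness screening (QED)

QED maps each of eight physicochemical descriptors through an asymmetric
double-sigmoid desirability function `d_i` and combines them as a weighted
geometric mean, `QED = exp(Σ w_i ln d_i(x_i) / Σ w_i) ∈ (0, 1]`. The
desirability coefficients and weights are the published values of Bickerton
et al. (2012), stored as data in `data/qed_params.yaml` so alternative
parameterisations can be swapped without code changes. Two conventions are
the package's own choices:

* **Weighting variant.** The mean-information-content weights (QED_w,mo)
  are the default. The max-weight and unit-weight variants of the original
  publication can be supplied via a user parameter file.
* **Desirability floor.** Desirabilities are floored at 1e-6 before the
  logarithm so that a pathological descriptor yields a very small QED
  rather than −∞. The floor only affects compounds that fail any sensible
  cutoff regardless.

Descriptors are taken as tabular input (TSV); computing them from SMILES is
deliberately out of scope, since descriptor generation belongs to dedicated
chemistry tooling. PCA summaries z-score the descriptors first — the
descriptors mix units and molecular mass would otherwise dominate every
component.

## Binomial target prioritisation

For a profile of `n` compounds in which gene `t` is hit by `k` compounds,
the null is `X ~ Binomial(n, g/n)` with `g` the mean number of compounds
per target, and the p-value is the upper tail `P(X ≥ k)` (computed via the
survival function, never by naive factorials). Conventions:

* **Significance gate.** Both the gate and the GS numerator use the
  BH-adjusted p-value at α = 0.05 (`gs_pvalue="raw"` switches both to the
  raw tail). Adjusting before interpretation is the standard guard against
  the hundreds of genes tested per profile.
* **Rank.** 1-based competition (min) rank over the gating p-values,
  computed across *all* profiled genes. Since BH adjustment is monotone,
  ranking by adjusted or raw p gives the same order; the choice only
  matters for the numerator, which follows the gate.
* **Logarithm base.** Base 10, the convention for −log p in this field;
  configurable.
* **Ties.** CS ties break lexicographically by compound id so that the
  representative-compound prefix is reproducible. The prefix is a ranked
  prefix, not a minimal set cover: compounds inside the prefix that add no
  new coverage stay in it.

## Multilayer networks

Path lengths count edges; "paths no longer than 3" means ≤ 3 edges, so a
SPEN path contributes at most two intermediates. *All* shortest paths
between a qualifying query pair are harvested (a node `v` is on a shortest
a–b path iff `d(a,v) + d(v,b) = d(a,b)`), which makes the construction
deterministic and avoids path-enumeration blowup. Query genes absent from
the PPI are dropped with a warning rather than raised — partial mapping is
the norm for curated gene lists. Edges with confidence score 0 are dropped
at PPI load time (threshold configurable).

Network statistics report both the mean local clustering coefficient and
the global transitivity, because on sparse graphs the two differ sharply
and published panels rarely say which was used; diameter and mean shortest
path are computed over connected pairs only, with isolated nodes counted
separately.

## Proximity (SPD and RWR)

The random walk with restart iterates `x_{t+1} = (1−γ) M x_t + γ x₀` with
γ = 0.7, `M` the column-degree-normalised adjacency (uniform transition to
neighbors; degree-0 columns become self-loops so the matrix stays
stochastic), and `x₀` uniform over the seed genes. Seeds are the *disease*
genes; scores are read at the formula targets. Convergence is an L1 change
below 1e-10. `x₀` is normalised to sum to 1 so the stationary vector is a
probability distribution; the reported score is `1000 × mean(x over
targets)`, under which a random target set on an N-node network scores
about 1000/N (≈ 0.06 at the 16.5k-gene scale of a full human interactome,
matching the published shuffled baseline for that scale).

The permutation test holds the targets fixed and redraws disease-sized
seed sets uniformly from the network (no degree matching — matching the
stated randomisation of the original analysis). Alongside the empirical
`(1 + extreme)/(n_perm + 1)` p-value, a parametric normal-tail p from the
permutation moments is reported: published proximity p-values far below
the 1/(n_perm+1) floor imply such an approximation. Internally one adjoint
fixed point `y = (1−γ) Mᵀ y + γ e_T` replaces a full RWR solve per draw
(each permutation then costs O(|seed set|) lookups), and SPD draws reuse a
precomputed target-distance matrix; tests assert both shortcuts equal the
naive compositions.

Herb curves: one RWR seeded by the disease; each herb's curve cumulates
the scaled stationary probability of its GS-ranked targets (running sum by
default, running mean available), and herbs are ranked by trapezoidal AUCC.

## Module scoring

`MS = Q + BHI`. Q is Newman–Girvan modularity computed over all ordered
node pairs; overlapping partitions are first hard-assigned (each gene goes
to the module holding most of its edges; ties to the smaller module, then
the lower index), and uncovered nodes count as singleton communities —
Eq-style modularity presumes a hard assignment, and this reduction
reproduces standard Q exactly on non-overlapping covers. BHI averages, over
all K modules, the fraction of ordered pairs of pathway-annotated genes
sharing at least one pathway; modules with fewer than two annotated genes
contribute zero rather than NaN.

Two reference detectors are bundled: greedy (Clauset–Newman–Moore)
modularity agglomeration, and a seeded local-density expansion in the
spirit of molecular-complex detection (seeds ordered by clustering ×
degree; greedy neighbor absorption while density ≥ threshold; minimum
size 4). Published detectors with bespoke algorithms (MOfinder, NeMo,
IPCA) are supported through partition-file ingestion and scored with the
same MS, which is the comparison the score exists for.

## Enrichment

Hypergeometric upper tail with universe N = all genes annotated in the
collection (not the genome): the collection defines the reference space.
Terms with zero query overlap are not tested — they cannot be significant
and would only dilute the BH correction. GO/KEGG are treated as flat GMT
term → gene-set maps; DAG propagation is out of scope. Common-term curves
use the query's terms sorted ascending by adjusted p (ties by term id) and
the percentage denominator at position N is N itself.

## Synthetic data: what it emulates and what it does not

* **PPI**: preferential-attachment backbone (heavy-tailed degrees, as real
  interactomes show) with planted dense blocks (internal edge probability
  0.65, connectivity enforced) for the module analysis. It does not model
  date-hub structure, edge confidence distributions, or protein complexes
  beyond density.
* **Compound–target profile**: independent Bernoulli links at base rate
  0.01 — chosen to match the link density of real formula-scale profiles
  (a few thousand interactions across ~200 compounds × ~2000 targets) —
  with planted core targets linked at 8× that rate. Real profiles have
  correlated chemistry (similar compounds share targets); the generator
  does not.
* **Disease genes**: the "near" mode samples within 2 hops of an anchor
  set, stratified over hop distance (weights 0.3/0.4/0.3, intended mean
  hop ≈ 1, recorded in the truth object). The 0-hop stratum mirrors the
  overlap real disease gene sets show with formula targets. On small-world
  graphs the plain 2-hop ball of a large anchor set covers most of the
  network, so an unstratified "near" would be indistinguishable from
  uniform — the stratification is what makes proximity a controlled,
  plantable condition. The "random" mode is the matched null.
* **Descriptors**: the drug-like class is sampled near the QED
  desirability maxima, the non-drug-like class in the penalised tails
  (mass ≈ 950 Da, ≥ 3 structural alerts, PSA ≈ 260 Å²), which guarantees
  the two classes separate at the 0.25 cutoff. No attempt is made to mimic
  real chemical-space structure.
* **Annotations**: one term per planted module (± small noise) plus random
  noise terms.

Because every generator draws from one explicit seed, all outputs are
byte-identical across runs. Passing tests on these data demonstrate the
statistical machinery (calibration under the null, recovery under planted
signal, oracle equivalence of the numerics); they do not certify
performance on real interactomes, whose correlation structure the
generators deliberately omit.

## Problem sizes and numerical choices

The planted-recovery study uses 200 compounds × 1000 targets with 50
planted at lift 8; the proximity calibration uses a 500-node PPI, 50
anchors, disease sets of 25, 100 runs × 200 permutations; the scaling
baseline uses a 16503-node graph with 140-gene target sets. These sizes
are chosen so the full suite and the acceptance script run comfortably on
a laptop-class single CPU while each check retains clear statistical
power. RWR convergence: L1 tolerance 1e-10, iteration cap 10 000 (a
restart probability of 0.7 contracts the residual by 0.3 per step, so
convergence takes ~25 iterations in practice). Binomial and hypergeometric
tails go through scipy survival functions and are verified against
exact-rational enumeration to 1e-12 in the tests.

## Known limitations

* Gene identity is plain upper-cased symbol matching; no identifier
  mapping (a user-supplied mapping table can be applied upstream).
* Q is unweighted; edge confidence scores only gate edge inclusion.
* The parametric permutation p assumes approximate normality of the
  permutation distribution; for tiny networks or tiny disease sets the
  empirical p is the safer quantity.
* The representative-compound prefix depends on the CS tie-break order;
  equal-CS reorderings of the input change nothing, but CS perturbations
  smaller than rounding can.
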
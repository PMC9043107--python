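# Methods

## Model

The predictor treats lncRNA–disease association inference as label
propagation on a heterogeneous network: a bipartite association network
bridging an lncRNA similarity network and a disease similarity network. It
assumes (i) functionally similar lncRNAs associate with semantically similar
diseases, so similarity neighbourhoods carry predictive signal, and (ii) the
absence of a recorded association is an unlabelled pair, not a negative —
the method never uses negative training examples.

Scores come from two complementary mechanisms averaged into one iteration:

* a **network-consistency projection** restart term, `(A + NCP)/sum(A + NCP)`,
  where the projection score of a pair is the scalar projection of the
  entity's similarity vector onto the partner's association profile. It is
  parameter-free and injects topology information even for entities with a
  single known link;
* a **bi-random walk** diffusion term, `NLS·S` on the lncRNA side and
  `S·NDS` on the disease side, which spreads scores through the normalized
  similarity networks for up to `r1` / `r2` iterations per side.

The iteration is Jacobi-style: both sides read `S(t−1)` and the update is
their average. With the default `r1 = r2 = 1` the final scores have the
closed form

```
S = ½ [ β·NLS·S(0) + β·S(0)·NDS + (1−β)·((A+LSNCP)/c1 + (A+DSNCP)/c2) ]
```

with `c1`, `c2` the grand totals of the restart numerators.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `beta` | 0.8 | decay factor; weight of diffusion vs projection restart (dimensionless, in [0, 1]) |
| `r1`, `r2` | 1, 1 | per-side iteration caps; `r1 > r2` weights the lncRNA network more |
| `gamma_prime_l/d` | 1.0 | GIP bandwidth scale; the effective bandwidth is `γ′` divided by the mean squared profile norm, so kernels adapt to matrix density |
| `delta` | 0.5 | per-generation semantic decay in the disease-DAG contribution model |
| `normalization_variant` | `literal` | similarity normalization, see below |
| `mode` | `full` | `ncp_only` and `birw_only` ablations available |
| `k`, `seed` | 5, required | cross-validation folds and RNG seed; the seed is always explicit and logged |

The `beta = 0.8`, `r1 = r2 = 1` operating point is the default because a
cross-validated grid search (`grid_search`, sweeping `beta` 0.1–0.9 in steps
of 0.1 and both caps over 1–5, 225 cells) selects it on the curated-database
scale this tool targets; the sweep is re-runnable on any dataset.

## Numerical choices

* **GIP bandwidth convention.** The bandwidth definition is implemented as
  division by the mean squared profile norm (`divide`), the normalized-
  bandwidth convention of the GIP-kernel literature; a `multiply` switch is
  provided for the multiplicative reading. With binary profiles and `γ′=1`
  the two coincide only when the mean squared norm is 1.
* **Similarity normalization.** The `literal` variant divides each entry by
  (row sum × column sum). This does not bound entries by 1 — the `sqrt`
  variant (divide by the square root of the product, i.e. symmetric
  normalization) is the one that does — so both ship; `literal` is the
  default. Entries with a zero row or column sum map to 0.
* **Degenerate inputs.** All-zero similarity profiles would make the GIP
  bandwidth undefined; the kernel then returns the identity with a warning.
  Zero-norm association rows/columns (entities with no training links, which
  fold masking routinely produces) get projection score 0 rather than an
  error. An all-zero association matrix is rejected: the walk's initial
  matrix is undefined.
* **Exhausted walks.** When `r1 ≠ r2` and one side's cap is passed, the
  default (`freeze`) lets the exhausted side contribute `S(t−1)` to the
  average; the `active` policy averages only the still-iterating side. The
  choice only matters for asymmetric caps, which the default grid explores.
* **Ties and determinism.** Ranked-prediction ties break by lexicographic
  lncRNA id; ROC curves sweep all distinct scores and integrate
  trapezoidally, so tied scores earn half credit and the AUC equals the
  midrank Mann–Whitney statistic (asserted against scipy and scikit-learn
  in the tests). Every code path is deterministic given inputs and seed;
  CLI outputs are byte-reproducible.
* **Floating point.** Double precision throughout; similarity matrices are
  symmetrized by averaging with their transpose and checked to 1e-10;
  kernels and walk steps agree with naive per-entry loop oracles to 1e-12
  in the tests.
* **Empty-profile functional similarity.** A lncRNA with no associated
  diseases has undefined best-match similarity; it is assigned 0 to every
  lncRNA including itself, and the zero then gates the integration so `LS`
  falls back to the GIP kernel for such rows.
* **Diseases without a DAG** get semantic similarity 0 to everything
  (diagonal 1), equivalent to an isolated singleton DAG, with a warning; the
  rarity term uses the vocabulary actually supplied in the counts file, not
  the full MeSH thesaurus.

## Cross-validation design

Known pairs are split into k near-equal folds. Each fold's positives are
masked to zero in a training copy and **everything downstream of the
association matrix is recomputed from the training copy** — both GIP
kernels, the functional similarity, the integrations, the projections and
the walk's initial matrix. This is the only leakage-free reading of
"train on k−1 parts": the kernels would otherwise memorise the held-out
links. Held-out positives are ranked against candidate pairs (zero in the
*original* matrix); training positives are excluded from the ranking. The
AUC is reported both pooled over all folds' scores and as the mean of
fold-level AUCs; the two rarely differ by more than the fold-to-fold spread.

## Synthetic benchmark

`simulate_dataset` plants co-clusters: lncRNAs and diseases are partitioned
into `n_blocks` groups, pairs inside a co-cluster are associated with
probability 0.43 and outside with 0.002, giving ~700 expected associations
in the default 82 × 157 matrix (~5.4% density, matching curated resources).
Each disease's DAG is a chain of `dag_depth = 3` ancestors shared by its
block, so semantic similarity is high exactly within blocks, and
`dag_counts` are exact membership counts over the generated forest.
`shuffle_labels` scatters the same number of 1s uniformly, preserving
sparsity while destroying the signal — the chance-level control.

What the generator does **not** emulate: multi-parent and variable-depth
MeSH topology, hub lncRNAs with many associations, and literature-curation
bias. Passing the planted-recovery test therefore shows the pipeline
recovers block-structured signal through honest cross-validation; it does
not certify performance on real curated databases, which must be evaluated
by feeding the real TSV inputs through `cv`.

A consequence of the planted design, visible in the acceptance script's
output: the block structure is so well captured by the projection scores
alone that the `ncp_only` ablation matches — and can marginally exceed — the
full hybrid on this benchmark, while `birw_only` trails clearly. The
hybrid's advantage over the projection is expected to come from real-data
similarity structure that a block model does not reproduce.

## File formats

* associations: two-column TSV `lncrna_id <TAB> disease_id`, one row per
  known pair; duplicates collapse with a logged count; entity order is
  first appearance.
* DAG edges: TSV `disease_id <TAB> parent_id <TAB> child_id` listing each
  disease's ancestor-closure edges; a row with empty parent/child declares a
  disease with no ancestors.
* DAG counts: TSV `node_id <TAB> dag_count`, optionally preceded by
  `# total_diseases=<D>`.
* matrices: dense TSV with a header row and an index column; CLI outputs
  carry `#` comment headers with the tool version and resolved parameters.

## Known limitations

* Cold-start entities (no known associations at all) receive only
  GIP-kernel-identity similarity and zero projection scores; the method has
  no side-information channel (expression, sequence) to rescue them.
* The score scale is not a probability; only the ranking is meaningful.
* The semantic similarity model requires externally prepared DAG files; raw
  MeSH descriptor parsing is out of scope.
* Dense matrix algebra throughout: appropriate for hundreds of entities,
  not for genome-scale matrices.
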
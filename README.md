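# ncpbirw

Prediction of long non-coding RNA (lncRNA)–disease associations by
**network-consistency projection** (NCP) combined with a **bi-random walk**
(BiRW) over fused similarity networks.

Experimentally validating which lncRNAs are involved in which diseases is
slow and expensive, so the catalogue of known associations is sparse
(typically ~5% of all lncRNA–disease pairs). This package scores every
unobserved pair by propagating the known associations through lncRNA-side
and disease-side similarity networks, for researchers who want a ranked list
of candidate lncRNAs for a disease of interest, and a cross-validation
harness to quantify how well that ranking recovers held-out associations.

## The method

Let `A` be the binary `n_l × n_d` lncRNA × disease incidence matrix.

1. **Similarity networks.** Gaussian interaction-profile kernels over rows
   and columns of `A`,

   `KL(i,j) = exp(−γ_l ‖A_i· − A_j·‖²)`, with bandwidth
   `γ_l = γ′_l / (mean_i ‖A_i·‖²)` (likewise `KD` over columns); disease
   semantic similarity `SV` from MeSH-style ancestor DAGs, where an ancestor
   `s` contributes `D_d(s) = max_{s′∈children(s)} (Δ + P_s)·D_d(s′)`
   (`D_d(d)=1`, decay `Δ=0.5`, rarity bonus
   `P_s = (max_k dags(k) − dags(s))/D`), and
   `SV(d_i,d_j) = Σ_{s∈N(d_i)∩N(d_j)} (D_{d_i}(s)+D_{d_j}(s)) / (DV(d_i)+DV(d_j))`;
   lncRNA functional similarity `FL` as the best-match average of `SV`
   between the two lncRNAs' disease sets. The integrated networks are
   `LS = (KL+FL)/2` where `FL ≠ 0` (else `KL`) and `DS = (KD+SV)/2` where
   `SV ≠ 0` (else `KD`).

2. **Network-consistency projection.** Space-projection scores
   `LSNCP(i,j) = (LS_i · A_j)/‖A_j‖` and
   `DSNCP(i,j) = (A_i · DS_j)/‖A_i‖` — the closer a lncRNA's similarity
   vector is in angle to a disease's association profile, the higher the
   score. The step has no free parameters.

3. **Bi-random walk.** With normalized networks `NLS`, `NDS`, initial matrix
   `S(0) = A/sum(A)`, and for `t = 1 … max(r1, r2)`:

   ```
   RL = β·NLS·S(t−1) + (1−β)·(A + LSNCP)/sum(A + LSNCP)     (while t ≤ r1)
   RD = β·S(t−1)·NDS + (1−β)·(A + DSNCP)/sum(A + DSNCP)     (while t ≤ r2)
   S(t) = (RL + RD)/2
   ```

   The decay factor `β` balances diffusion against the projection-based
   restart term. Defaults: `β = 0.8`, `r1 = r2 = 1`. Ablation modes
   `ncp_only` (restart terms alone) and `birw_only` (walk without
   projection) are built in, as are both readings of the similarity
   normalization (`literal` product form and its `sqrt` variant).

## Worked example

```python
from ncpbirw import NCPBiRW, SyntheticConfig, simulate_dataset

A, dags = simulate_dataset(SyntheticConfig(seed=0))   # planted benchmark
model = NCPBiRW(A, dags, beta=0.8, r1=1, r2=1)
res = model.fit()
print(res.summary())
print(res.top_predictions("D012", n=5).to_string(index=False))
print(model.cross_validate(k=5, seed=1).summary())
```

prints

```
             NCP-BiRW association prediction
==========================================================
lncRNAs:                            82
diseases:                          157
known associations:                718
matrix density:                 0.0558
diseases with a DAG:               157
----------------------------------------------------------
mode:                             full
decay factor beta:                0.80
iteration caps r1, r2:            1, 1
normalization:                 literal
GIP gamma-prime (l, d):           1, 1
----------------------------------------------------------
score min / max:             7.481e-06 / 1.166e-04
score grand total:              0.2381
==========================================================
ncpbirw 0.1.0

 rank lncrna_id disease_id    score  known
    1      L008       D012 0.000047  False
    2      L004       D012 0.000042  False
    3      L002       D012 0.000039  False
    4      L011       D012 0.000038  False
    5      L009       D012 0.000038  False

5-fold cross-validation (seed 1)
  walk: beta=0.8 r1=1 r2=1 mode=full
  pooled AUC : 0.9502
  mean AUC   : 0.9503
  fold AUCs  : 0.9345 0.9557 0.9636 0.9590 0.9390
```

The summary describes the data (a planted-block synthetic matrix at the
scale of a curated lncRNA–disease database) and the operating point; the
ranked table lists the five strongest novel candidates for disease `D012`
(known associations are excluded, so `known` is always False here); the
cross-validation block shows that held-out associations are ranked far above
chance (pooled AUC 0.95) when each fold is masked and the entire pipeline is
recomputed from the training matrix.

The same pipeline is available from the shell:

```
ncpbirw simulate --seed 0 --out-dir data/
ncpbirw predict --associations data/associations.tsv \
    --dag-edges data/dag_edges.tsv --dag-counts data/dag_counts.tsv \
    --out scores.tsv
ncpbirw rank --scores scores.tsv --associations data/associations.tsv \
    --disease D012 --top-n 10 --out top10.tsv
ncpbirw cv --associations data/associations.tsv \
    --dag-edges data/dag_edges.tsv --dag-counts data/dag_counts.tsv \
    --k 5 --seed 1 --out cv.json
```

To run on real data, supply your own edge list and MeSH-derived DAG files in
the same three TSV formats (see `docs/methods.md`).

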
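# nbbd — network-based biomarker discovery for microbiome data

`nbbd` identifies candidate microbial biomarkers from case/control OTU
abundance tables by comparing the *ecological networks* of the two
phenotypes rather than (only) the marginal abundances of individual taxa.
It is aimed at microbiome researchers who have a samples-by-taxa table with
a binary phenotype label (e.g. IBD vs healthy) and want a ranked list of
taxa whose community role differs between the groups, plus an honest
classifier-based assessment of how discriminative those taxa are.

## The method

Given a labeled OTU table, the pipeline:

1. **splits** the samples by phenotype and infers one microbial ecology
   network per group, with taxa as nodes, using any of four constructors:
   - **Proxi** — k-nearest-neighbour graph under the distance
     d(u,v) = 1 − |r(u,v)| (Pearson), k = 7;
   - **SparCC** — basis correlations for compositional data from the
     log-ratio variation matrix t(u,v) = var log(x_u/x_v), with iterative
     exclusion of strongly correlated pairs; edge if |ρ| ≥ 0.3;
   - **MB** — neighbourhood selection: L1-penalised regression of each
     taxon's clr abundance on all others; OR/AND merge of neighbourhoods;
   - **RMT** — hard correlation threshold chosen automatically as the
     smallest cutoff at which the nearest-neighbour eigenvalue spacing
     distribution of the thresholded matrix is consistent with the Poisson
     law (random-matrix criterion).

2. **scores** each shared node v. Two scoring families are provided:
   - **NTPS** (node topological property scoring):
     score_P(v) = | f_P(v, G₁) − f_P(v, G₂) |
     for P ∈ {betweenness `btw`, closeness `cls`, average neighbour degree
     `and`, clustering coefficient `cc`, node clique number `ncn`, core
     number `cn`};
   - **CASS** (critical attack set scoring): minimise a node resilience
     measure — vertex attack tolerance VAT(S) = |S| / (|V−S| − C_max(V−S) + 1),
     integrity I(S) = |S| + C_max(V−S), or tenacity
     T(S) = (|S| + C_max(V−S)) / ω(V−S) — over prefixes of the greedy
     highest-betweenness removal ordering, and select the taxa shared by
     both networks' attack sets. The feature count is data-driven.

3. **selects** the top-k taxa (optionally fusing NTPS with random-forest
   feature importance via an elementwise product — the *hybrid* score) and
   **evaluates** them by training a 500-tree random forest on the full
   training table restricted to those taxa, reporting ACC, Sn, Sp, MCC and
   AUC on held-out samples. The experiment grid sweeps nested
   feature-selection subset sizes × methods × k.

A synthetic benchmark generator with planted differential nodes (known
ground truth) makes the whole chain testable end to end; see
`docs/methods.md` for the model and its limitations.

## Worked example

```bash
python examples/03_score_nodes.py
```

builds the default benchmark (200 samples × 100 taxa, 10 planted taxa),
infers one Proxi network per phenotype and ranks taxa by each NTPS
property:

```
property  top taxon  precision@10
btw       OTU_003             0.5
cls       OTU_003             0.5
and       OTU_024             0.2
cc        OTU_080             0.1
ncn       OTU_038             0.3
cn        OTU_000             0.2

precision@10 = fraction of the 10 top-scored taxa that are truly planted
(random guessing: 0.1)
```

Here differential betweenness recovers 5 of the 10 planted taxa in its
top 10 — five times the random baseline — while purely local properties
(`cc`) see little of the planted hub signal. `examples/01`–`05` walk
through generation, network inference, attack sets and the full
classifier harness; each prints a short interpretation of its numbers.

The same pipeline runs from the shell:

```bash
nbbd simulate --n-taxa 100 --n-planted 10 --n-per-group 100 --seed 7 --out-dir bench/
nbbd build-net --table bench/table.tsv --metadata bench/metadata.tsv \
               --method proxi --group IBD --out ibd.tsv
nbbd run --config config.yaml     # whole pipeline, deterministic per config
```

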
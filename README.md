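# metadeg

Prognostic gene discovery from expression differentiation between
metastatic stages of a staged tumour cohort.

## The problem

Classical differential-expression screens contrast normal tissue with
tumour tissue — the two extremes of carcinogenesis — and miss the subtle
dysregulation that happens *during* specific steps such as lymph-node
invasion. `metadeg` implements a transition-centric alternative for
cohorts whose primary tumours can be staged as **confined** (no nodal or
distant spread), **lymphnode** (nodal spread only) and **metastasis**
(distant spread), with paired adjacent-normal tissue where available.
It is written for computational biologists who want the full chain — from
a log2 expression matrix, a clinical annotation table and one or more
protein-interaction edge lists down to a validated prognostic gene
module — as tested, reusable library code with a thin CLI.

## The method

For a transition (an ordered pair of sample groups) each gene *i* gets a
**differential score**

```
D_i = log2(FC_i) · (−log10 P_i)
```

where `log2(FC_i)` is the difference of group means on the log2 scale and
`P_i` is the two-sided Wilcoxon p-value (signed-rank for paired designs,
rank-sum otherwise). A normal distribution is fitted to the scores by
moments (the Kolmogorov–Smirnov statistic of that fit is reported), and
significant up-/down-regulated genes are called from the one-sided tails
at level α.

Survival relevance of a transition is quantified by the **AACCV**: every
gene is z-scored and fitted in a univariate Cox proportional-hazards model
(Breslow ties), and the average absolute Cox coefficient of the top-N
genes by differential score is compared between transitions with a
rank-sum test. Significant DEGs are projected onto a merged
protein-interaction network; the largest connected component of the
induced subgraph is the candidate **module**, validated by splitting
patients at the median of the module's first principal component (PC1)
and comparing the two arms with Kaplan–Meier / log-rank and a stepwise
Cox table over clinical covariates (univariate screen at p < 0.05, then
one joint multivariate fit).

Preprocessing mirrors common expression practice: genes missing in more
than half of any subgroup are dropped, gaps are filled by gene-wise k-NN
imputation, and between-sample intensity trends are removed by pairwise
cyclic loess on MA coordinates.

A synthetic-data generator (`metadeg.synthetic`) produces cohorts with
planted differential genes, proportional-hazards survival tied to a gene
signature, and a random interaction network with a planted connected
module, so every stage is testable without external downloads.

## Worked example

```python
from metadeg import (SimulationConfig, TransitionSpec, simulate_all,
                     filter_missing_genes, impute_knn,
                     differential_table, fit_score_normal, call_degs,
                     biggest_connected_deg_module, pc1_split, km_logrank)

cfg = SimulationConfig(seed=3)                   # 1200 genes, 77 samples
expr, ann, truth, net = simulate_all(cfg)
expr = impute_knn(filter_missing_genes(expr, ann), k=10)

tab = differential_table(expr, ann, TransitionSpec("confined", "lymphnode"))
fit = fit_score_normal(tab["d_score"].to_numpy())
calls = call_degs(tab["d_score"], fit, alpha=0.05)
print(f"KS D = {fit.ks_D:.3f}, called {int(calls['significant'].sum())} DEGs")

module = biggest_connected_deg_module(net, set(calls.index[calls["significant"]]))
cancer = ann[ann.group != "normal"].index
res = pc1_split(expr[cancer], module)
km = km_logrank(ann, res.group)
print(f"module of {len(module)} genes, log-rank p = {km.logrank_p:.2e}")
```

prints

```
KS D = 0.299, called 75 DEGs
module of 7 genes, log-rank p = 1.49e-02
```

— the score distribution is visibly heavier-tailed than normal (the KS
statistic quantifies this), 75 genes fall in the 5% one-sided tails, and
the connected module they form splits the cohort into arms with different
survival at the 5% level. (The full pipeline additionally applies
cyclic-loess normalisation before scoring; `metadeg run` below.)

The same flow runs end-to-end from the shell:

```bash
metadeg run --config pipeline.yaml      # writes TSV/JSON artifacts + manifest
metadeg simulate --out data --seed 7    # just the synthetic input bundle
```

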
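# netomics

Integrative multi-omics classification with network-informed feature
expansion, for two-class case/control studies that measure several
molecular layers (methylation arrays, RNA-seq counts, proteomic
intensities) on the same cohort.

The pipeline mirrors a common systems-biology study design:

1. **Block-wise preprocessing** — M-value coding for methylation,
   median-of-ratios (DESeq2-style) size factors and low-count filtering
   for expression, log2 + per-sample median centering for proteomics,
   variance-based feature reduction, and train-fitted z-scoring.
2. **Sparse PLS-DA and multiblock integration.** Per component h,
   single-block sparse PLS-DA finds a unit loading u_h with exactly
   keepX_h nonzeros maximizing cov(X u_h, Y v_h) against the centered
   class indicator Y. The multiblock (DIABLO-style) model couples
   blocks X⁽¹⁾…X⁽ᴮ⁾ through a symmetric design matrix C, maximizing
   Σ_{i<j} c_ij cov(X⁽ⁱ⁾u_i, X⁽ʲ⁾u_j) with the outcome as an extra
   block (c_{i,Y} = 1, block–block weight 0.1 by default) by block
   coordinate ascent with soft-thresholding.
3. **Tuning by balanced error rate (BER)** — repeated stratified
   five-fold cross-validation; component count and per-component keepX
   chosen by a one-standard-error rule; selection reproducibility by
   stratified bootstrap (selection frequency over B refits).
4. **Interactome seed expansion** — the selected signature seeds two
   prioritizations on a protein-interaction network: Hidden Nodes
   (upper-tail hypergeometric over-connectivity of each candidate's
   neighbourhood to the seed set, BH-adjusted) and network propagation
   (random walk with restart; empirical p-values from degree-matched
   permuted seed sets; top 1% retained). Scores are −log10(adjusted p).
5. **Four-pillar network stability** — LCC robustness under random node
   removal, node criticality via global-efficiency drop, structural
   metrics (average path length, clustering, modularity Q, degree and
   betweenness centralization), and regulator degree/betweenness
   statistics.
6. **Gradient-boosted classification** — XGBoost models on the
   multi-omics signature (MO), the topological regulators (TR) and
   their union (MO-TR); stratified 80/20 split, 5-fold grid search on
   the training data only, and held-out evaluation with 95%
   percentile-bootstrap confidence intervals; external validation by
   exact-ID feature intersection and refitting.

A fully parameterized synthetic-data module generates two-class
multi-omics cohorts (shared class-linked latent components, block
specific sparse signatures, negative-binomial counts with library-size
factors) and scale-free interaction networks with planted over-connected
regulators, so every stage is testable without any data download.

## Worked example

```python
import numpy as np, pandas as pd
from netomics import SimConfig, NetSimConfig, gen_multiomics, gen_network, \
    diablo_fit, select_features
from netomics.nettopo import hidden_nodes, regulator_stats
from netomics.classify import stratified_split, grid_search_gbt, fit_eval
from netomics.preprocess import zscore_fit, zscore_apply

ds = gen_multiomics(SimConfig(n_samples=300, seed=42))
net = gen_network(NetSimConfig(n_nodes=800, seed=42), ds.truth["expression"])

blocks = {b.name: (np.log2(b.data + 1) if b.name == "expression" else b.data)
          for b in ds.blocks}
plan = stratified_split(ds.labels, test_frac=0.2, seed=42)
y_train = ds.labels.loc[plan.train].to_numpy()

model = diablo_fit({n: X.loc[plan.train] for n, X in blocks.items()},
                   y_train, ncomp=2, keepX=[[20, 20]] * 3)
sig = select_features(model)

seeds = set(sig.features("expression")) & set(net.graph.nodes())
hn = hidden_nodes(net, seeds)
regs = list(hn.loc[hn["significant"], "node"])

mo = pd.concat([blocks[b][sig.features(b)] for b in blocks], axis=1)
scaler = zscore_fit(mo.loc[plan.train])
Xtr, Xte = zscore_apply(scaler, mo.loc[plan.train]), zscore_apply(scaler, mo.loc[plan.test])
best, _ = grid_search_gbt(Xtr, y_train, seed=42)
rep, _ = fit_eval(Xtr, y_train, Xte, ds.labels.loc[plan.test].to_numpy(),
                  params=best, seed=42)
```

Output:

```
cohort: {'case': 210, 'control': 90}
split: 240 train / 60 test
signature sizes: {'methylation': 20, 'expression': 20, 'proteomics': 20}
HN regulators: 96  planted recovered: 15 / 15
degree ratio: 1.12
auc          0.981 (95% CI 0.950-1.000)
accuracy     0.917 (95% CI 0.850-0.983)
sensitivity  0.929 (95% CI 0.833-1.000)
specificity  0.889 (95% CI 0.722-1.000)
f1           0.940 (95% CI 0.886-0.988)
```

The multiblock fit selects 20 features per block per component whose
union recovers the planted signature; the hypergeometric expansion
flags all 15 planted regulators among its significant nodes; and the
MO classifier separates the held-out samples far above chance because
the simulated effect (delta = 1.5 on the latent scores) is strong.

The same analysis is available from the shell:

```sh
netomics simulate --seed 42 --out fixture/
netomics nettopo --edges fixture/edges.tsv --seeds seeds.txt --out topo/
netomics run --config pipeline.yaml --seed 42 --out run/
```

`netomics run` consumes a YAML config naming the block matrices, label
table and edge list, executes every stage with per-stage seeds derived
from the global seed, and writes TSV/JSON reports plus a manifest with
input hashes and parameters.

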
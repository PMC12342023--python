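# dynanet

Dynamic network analysis of longitudinal inflammatory-mediator panels.

Serial measurements of cytokines, chemokines and DAMPs — a serum panel
sampled daily across the course of pediatric acute liver failure (PALF),
or hepatocyte supernatants sampled over 1–48 h of acetaminophen toxicity —
carry information not just in each mediator's level but in how mediators
move together and drive one another over time.  `dynanet` implements the
computational toolchain for that question, for bioinformaticians and
systems-biology groups working with small-cohort multiplex panels:

* **DyNA** — interval-wise signed correlation networks: mediators are
  connected within a time window (d0–d1, d1–d2, …) when |Pearson r| ≥ 0.85
  (inclusive, configurable), black/positive vs red/negative.  Per-interval
  network complexity is `(N₁ + … + Nₙ)/(n − 1) = 2E/(n − 1)` over the
  analysed panel of n mediators, and the total number of connections sums
  edges across all intervals — the headline contrast between outcome
  subgroups.
* **DyBN** — lag-1 dynamic Bayesian network inference with the BGe
  (Bayesian Gaussian with score equivalence) marginal-likelihood score and
  node-specific changepoints, sampled by Metropolis–Hastings over parent
  sets and segmentations.  Posterior edge probabilities are thresholded
  into a consensus digraph; nodes with a self-loop plus other connections
  are *central/high-feedback* candidates.
* **Biomarker statistics** — Mann-Whitney rank-sum (exact for small
  samples), Spearman vs age (exact permutation p for n ≤ 10), ROC/AUC with
  Youden-J optimal cutoff, and volcano classification at fold change ≥ 2.0
  and P < 0.05.
* **Synthetic studies** — a generator with known ground truth (subgroup
  fold changes, AR self-feedback, cross-couplings, planted interval
  correlations, changepoints, missingness) emulating the PALF serum design
  (28 mediators, survivors n=14 vs non-survivors n=7, d0–d7) and the mouse
  hepatocyte design (23 mediators, genotype × treatment, 1–48 h), so every
  inference stage is validated end to end without any external data.

The two inference engines are scikit-learn-style estimators
(`DynamicNetworkAnalysis`, `DynamicBayesianNetwork`: constructor
parameters, `fit(dataset, subgroup=...)`, fitted `*_` attributes,
`get_params`/`set_params`), with plain functions beneath them.
See `docs/methods.md` for the models, priors and design decisions.

## Worked example

```python
from dynanet import (DynamicNetworkAnalysis, DynamicBayesianNetwork,
                     generate, palf_preset)
from dynanet.stats import roc_auc, volcano

ds, truth = generate(palf_preset(seed=1))   # 21 subjects x 8 days x 28 mediators

dyna_ns = DynamicNetworkAnalysis(threshold=0.85).fit(ds, subgroup="NS")
dyna_s = DynamicNetworkAnalysis(threshold=0.85).fit(ds, subgroup="S")
print("total connections NS:", dyna_ns.total_connections_,
      "S:", dyna_s.total_connections_)

vol = volcano(ds, "S", "NS")                # NS relative to S
print(vol.table.head(3).round(3).to_string(index=False))

frame = ds.frame
gdf = frame[frame.mediator == "GDF-15"].dropna(subset=["value"])
print("GDF-15 AUC:", round(roc_auc(gdf.value, gdf.subgroup).auc, 3))

dybn = DynamicBayesianNetwork(random_state=1).fit(ds, subgroup="S")
print("self-feedback:", dybn.self_feedback_[:4], "... central:", len(dybn.central_))
```

Output:

```
total connections NS: 14 S: 5
mediator  log2_fc  p_value class
    IL-6    1.238      0.0    up
     MIG   -1.072      0.0  down
  GDF-15    1.260      0.0    up
GDF-15 AUC: 0.727
self-feedback: ['GDF-15', 'GM-CSF', 'IL-8', 'IL-12p40'] ... central: 8
```

The non-survivor subgroup carries the denser dynamic network (14 vs 5
total connections — the planted contrast), GDF-15 rises >2-fold in
non-survivors with a discriminating AUC while MIG falls, and the DyBN
recovers the self-feedback loops planted on GDF-15 and HMGB1 together
with the survivor-only MIG→GDF-15 coupling.

A command-line interface mirrors the library:

```sh
dynanet simulate --preset palf --seed 1 --out sim/
dynanet dyna --in sim/dataset.csv --subgroup NS --threshold 0.85 --out dyna_ns/
dynanet dybn --in sim/dataset.csv --subgroup S --iterations 20000 --seed 1 --out dybn_s/
dynanet stats volcano --in sim/dataset.csv --groups S,NS --out stats/
dynanet run-all --preset palf --seed 1 --out run/
```

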
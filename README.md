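# taskcomm

Task-state functional-connectivity community analysis: beta-series networks
per task condition, multi-threshold consensus community detection,
fragmentation / NMI / node-role metrics, mover-node identification, and
network-similarity → behavior models — with a synthetic-data generator that
plants ground truth for every stage.

## The problem

During a cognitive task, the brain's functional network reorganizes: most
regions keep a stable community ("module") affiliation across task states,
while a minority — *mover* nodes — switch allegiance between communities as
the task changes (e.g. encoding vs. retrieval of spatial vs. temporal
context in episodic memory).  Quantifying this reorganization, relating it
to canonical resting-state networks (RSNs), and asking whether it predicts
behavior requires a long pipeline:

1. **Beta series** — a GLM with one boxcar ⊛ HRF regressor per trial
   (plus motion nuisance and intercept) yields per-trial amplitude
   estimates β̂ for each node; trials overlapping framewise displacement
   > 0.55 mm are excluded and series lengths equalized across conditions.
2. **Connectivity** — Pearson correlation between node beta series,
   Fisher-transformed (z = artanh r), with negative edges and edges
   between nodes < 20 mm apart set to zero; optional wiring-cost
   thresholding removes the weakest fraction of edges; group networks
   average individual z matrices.
3. **Consensus communities** — Louvain modularity maximization
   (Q(γ) = (1/2W) Σᵢⱼ [wᵢⱼ − γ sᵢsⱼ/2W] δ(cᵢ,cⱼ), γ = 1.25) run 100×
   per cost; the co-assignment matrix is thresholded at 0.5 and
   re-clustered to a fixed point; a second consensus across the cost grid
   {0.01, 0.11, …, 0.91} gives each condition's final partition.
4. **Stability and movers** — the meet of the four condition partitions
   separates stable modules (cells ≥ 5 nodes) from mover nodes.
5. **Metrics** — within-module degree z-score
   zᵢ = (kᵢ(mᵢ) − k̄(mᵢ))/σ_k(mᵢ), participation coefficient
   PCᵢ = 1 − Σₘ (kᵢ(m)/kᵢ)², node identities from the sign pair
   (zᵢ, z-scored PC): connector (+,+), provincial (+,−), satellite (−,+),
   peripheral (−,−); fragmentation of an RSN, F = 1 − C/T, where C is the
   largest count of the RSN's T nodes sharing one data-driven module;
   NMI between partitions and its area under the NMI-vs-cost curve.
6. **Brain–behavior** — network similarity (Pearson r of the vectorized
   upper triangles of two condition matrices, whole-network or per
   subnetwork) correlated with behavioral performance (Bonferroni over the
   six condition pairs, swept over costs), multiple regression on
   subnetwork similarities with adjusted R²/AIC comparison, and a lasso
   path identifying the last-surviving predictor.

Because every stage is exercised on synthetic data with planted structure
(block-correlated beta series, movers with condition-dependent blocks,
HRF-convolved BOLD, motion spikes, behavior linearly coupled to network
dissimilarity), the package tests recovery of known ground truth end to
end.

## Worked example

```python
import taskcomm as tc

truth  = tc.make_ground_truth(seed=0)        # 100 nodes, 4 blocks, 12 movers
nodes  = tc.make_node_table(100, [f"RSN{k}" for k in range(10)], seed=0)
series = tc.plant_beta_series(truth, n_trials=40, seed=1)

net  = tc.series_to_network(series["space_encoding"], nodes)
part = tc.multiscale_consensus(net, tc.CommunityConfig(seed=2))
print(part.n_modules, part.module_sizes)       # 4 [25 25 25 25]
print(tc.nmi(part, truth.labels("space_encoding")))  # 1.000

parts = {c: tc.multiscale_consensus(tc.series_to_network(series[c], nodes),
                                    tc.CommunityConfig(seed=2))
         for c in truth.conditions}
stable, movers = tc.stable_modules_and_movers(parts, min_stable_size=5)
print([len(s) for s in stable], movers)
# [22, 22, 22, 22] [88 89 90 91 92 93 94 95 96 97 98 99]

cohort = tc.simulate_similarity_cohort(n_subjects=18, slope=-0.5, seed=3)
res = tc.similarity_performance_correlation(cohort.similarities, cohort.performance)
print(f"r = {res.r:.2f}, Bonferroni p = {res.p_adjusted:.2e}")
# r = -0.96, Bonferroni p = 1.21e-09
```

The consensus partition recovers the four planted blocks exactly (NMI = 1),
the meet across the four conditions isolates precisely the 12 planted mover
nodes, and the planted negative similarity→performance slope is detected as
a strongly negative correlation.

A `taskcomm` command-line interface wraps the same stages
(`taskcomm simulate | betas | connect | communities | metrics |
fragmentation | similarity | behavior`); run `taskcomm --help`.

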
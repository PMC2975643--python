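# boolcore

Inference and dynamical analysis of Boolean **core** gene regulatory
networks from gene-deletion / overexpression expression data.

Large-scale perturbation screens (knock out or overexpress one gene,
measure everything else on arrays) carry enough signal to reconstruct a
functional regulatory network and — because the perturbations also pin
down each interaction's sign — the Boolean *logic* of every gene. This
package implements that reconstruction and the downstream question it
enables: do the wiring and the logic of the reconstructed network favor
the propagation of information between genes, compared to chance?

It is aimed at systems biologists working with perturbation expression
compendia and at researchers studying criticality and information flow in
Boolean network models.

## What it computes

* **Inference** — gene j is a direct input of gene G if perturbing j
  changes G at least a threshold fold (default 3.32-fold, calibrated so
  the core's mean connectivity K matches an external estimate such as
  5.6). The *core* is the maximal subnetwork in which every gene has both
  inputs and outputs. Each core gene's transfer function comes from
  perturbation weights `W(G, j, x) = sign(r)·10^|r|` (r the log10 ratio of
  G when j is deleted, x = 0, or overexpressed, x = 1): the summed weight
  over an input state sets the truth-table entry (positive → 1, negative
  → 0, zero → seeded deterministic tie-break).
* **Topology** — mean connectivity K, mean directed path length L over
  connected ordered pairs, cluster (weakly connected component) count, and
  the generalized clustering coefficient C_p for loops of p nodes (C_3
  equals the classical Watts–Strogatz coefficient).
* **Logic** — per-function p-bias (fraction of input states mapping to 1)
  and average sensitivity s^f; the network mean S = ⟨s^f⟩ locates the
  dynamics relative to the critical point S = 1, with the analytic
  estimate S = 2·K·p·(1−p) for bias-p random functions.
* **Information propagation** — temporal pairwise mutual information
  I_ij = H(s_i) + H(s_j) − H(s_ij) between node i at t and node j at
  t + 1, estimated from transients: 100 random initial states × length-10
  trajectories, pooled into 900 transitions per ordered pair (plug-in
  estimator, bits).
* **Null models** — "Random 2" uniform topologies with a fixed edge count,
  dressed with random truth tables whose biases are either drawn from a
  fitted Beta distribution (Rand-Beta) or fixed at the empirical mean
  (Rand-p-bias).
* **Self-consistency** — Monte-Carlo agreement of the inferred network's
  one-step predictions with the binarized measurements it was inferred
  from, against a shuffled baseline.
* **Synthetic data** — ground-truth networks plus simulated perturbation
  tables in the same dialect, with controlled effect size and noise, so
  the whole pipeline is testable end to end.

See `docs/methods.md` for definitions, conventions and design decisions.

## Worked example

Infer a network from simulated perturbation data and characterize it:

```python
from boolcore import (generate_truth, simulate_perturbation_dataset,
                      infer_network, network_sensitivity, mean_transient_I,
                      topology_summary, analytic_sensitivity)

truth = generate_truth(40, 3.0, seed=1, noise_sd=0.05)   # 40 genes, K=3
ds = simulate_perturbation_dataset(truth)                # 80 experiments
net = infer_network(ds, threshold=3.32, seed=0)
bn = net.to_boolean_network()

topo = topology_summary(net.topology, max_p=4)
S = network_sensitivity(bn).network_S
info = mean_transient_I(bn, n_starts=100, transient_length=10, seed=2)
print(f"core: {topo.N} genes, K = {topo.K:.2f}")
print(f"mean p-bias   = {bn.mean_pbias():.3f}")
print(f"sensitivity S = {S:.3f}  (2Kp(1-p) estimate: "
      f"{analytic_sensitivity(topo.K, bn.mean_pbias()):.3f})")
print(f"path length L = {topo.L:.2f}, clusters = {topo.n_clusters}")
print(f"mean transient I = {info.mean_I:.5f} bits")
```

prints

```
core: 36 genes, K = 2.94
mean p-bias   = 0.493
sensitivity S = 1.347  (2Kp(1-p) estimate: 1.472)
path length L = 3.09, clusters = 1
mean transient I = 0.03328 bits
```

Reading it: four of the 40 genes lacked inputs or outputs above threshold
and fell out of the core. The exact network sensitivity (1.35) sits near
its random-table estimate, slightly above the critical value 1, and the
pooled-transient mutual information (0.033 bits averaged over all ordered
gene pairs) quantifies how much one gene's state tells about any gene's
state one step later.

The same steps are available from the shell:

```sh
boolcore synth --genes 40 --k 3 --noise 0.05 --seed 1 \
    --out data.tsv --meta-out data.meta.tsv
boolcore infer --data data.tsv --meta data.meta.tsv \
    --threshold 3.32 --out net/
boolcore metrics --net net/ --out metrics.json
boolcore mi --net net/ --starts 100 --length 10 --seed 2
boolcore table2 --reps 30 --seed 0 --out table2.tsv   # null-model table
```

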
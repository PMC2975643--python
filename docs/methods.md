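# Methods

`boolcore` infers a Boolean "core" gene regulatory network from
perturbation expression measurements and characterizes how well its
topology and logic propagate information, by comparison with random null
models. This note records the model, the procedure, the parameters that
matter, and the design choices made where the design was genuinely open.

## Model and assumptions

Genes are binary (`1` expressing, `0` not) and update synchronously and
deterministically: each gene's next state is a Boolean transfer function of
the current states of its input genes. This is the standard random-Boolean-
network (RBN) abstraction; it ignores stochasticity, graded expression and
asynchronous timing, but it is tractable at the hundreds-of-genes scale and
captures the propagation of discrete expression changes, which is the
quantity of interest here. Knockouts and overexpressions are modeled as
*clamps*: the perturbed gene is held at 0 or 1 at every step including
t = 0, so a deleted gene is never observed ON.

Two quantities organize the analysis:

* the **average sensitivity** `s^f` of a transfer function — the expected
  number of single-input flips that change its output, with inputs weighted
  uniformly. The network mean `S` is an order parameter: `S < 1` ordered,
  `S ≈ 1` critical, `S > 1` chaotic. For truth tables filled i.i.d.
  Bernoulli(p) at mean connectivity K, `S ≈ 2·K·p·(1−p)`.
* the **temporal pairwise mutual information** `I_ij` between node i at
  time t and node j at t + 1, a measure of information propagated in one
  step (possibly via common ancestors); the network mean `I` summarizes
  propagation.

## Inference from perturbation data

Input data are tab-separated tables of log10 expression ratios (perturbed
vs wild type), one column per experiment, plus a sidecar naming each
column's perturbation kind (deletion or overexpression). The pipeline:

1. **Edges.** Gene j is a direct input of G if some perturbation of j
   changes G at least `threshold`-fold in either direction (inclusive).
   The default threshold of 3.32-fold is the value calibrated so the
   resulting core's mean connectivity matches an external estimate of
   K = 5.6 from binding-interaction databases for the yeast core;
   `calibrate_threshold` recalibrates for any dataset by sweeping the
   observed fold magnitudes (the candidate grid on which K(t) is piecewise
   constant) and picking the threshold with mean core K closest to the
   target. Post-core-extraction K is matched by default; a flag matches
   the raw network.
2. **Core extraction.** The core is the maximal induced subgraph in which
   every gene has at least one input and one output — only such genes can
   both receive and forward information. Violating nodes are removed
   iteratively to a fixed point (a single pass is not enough: removals
   create new violations); the fixed point is order-independent.
3. **Transfer functions.** The weight of input j in state x on gene G is
   the signed fold change `W = sign(r)·10^|r|` where r is G's log10 ratio
   in the experiment putting j in state x (deletion → x = 0,
   overexpression → x = 1); `W = 0` when no measurement exists. For each
   input state the summed weight V decides the truth-table entry (positive
   → 1, negative → 0). `V = 0` entries are undecidable from the data and
   are set by a keyed hash of (gene, state index, seed) — deterministic
   given the seed, identical between the explicit and implicit
   representations, and reproducible without materializing 2^n entries.
   With every input measured at least once and generic (noise-perturbed)
   weight magnitudes the tied fraction is at most 2^−n, and in practice 0;
   exact cancellations of equal-magnitude weights can exceed that bound on
   degenerate data, and the tied count always equals the number of V = 0
   states.

**Self-measurements are masked by default**: the expression change of the
perturbed gene in its own experiment reflects the perturbation itself, not
regulation, so self-edges are unidentifiable from this design. A flag
(`allow_self`) restores them for sensitivity analyses.

Functions with more than `explicit_cap = 20` inputs keep the implicit
weight representation; their p-bias and sensitivity are estimated by seeded
Monte-Carlo sampling (10,000 states by default), all other functions are
evaluated exactly over their 2^n states.

## Topology statistics

* **L** — mean shortest directed path length over ordered pairs (i ≠ j)
  that have a path; unreachable pairs are excluded. Reported as NaN when
  no pair is connected. Because L silently ignores disconnected parts, the
  number of **clusters** (weakly connected components) is reported with it.
* **C_p** — generalized clustering coefficient for loops through p nodes.
  `C_1` is the fraction of genes with a self-input; `C_2` the mean fraction
  of a gene's (undirected) connections that are bidirectional (a node with
  three connections, one bidirectional, contributes 1/3). For p ≥ 3,
  shells of nodes at undirected shortest-path distance r from node i are
  formed (distances strictly positive, i excluded) and C_p averages the
  ratio of realized to possible connections between shells r and p−r−1
  over r = 1..p−2. With this convention `C_3` reduces exactly to the
  classical Watts–Strogatz clustering coefficient on undirected graphs,
  which fixes the otherwise open choice of directed vs undirected shells;
  a directed variant sits behind a flag. Nodes with no possible
  connections (zero denominator) are excluded from the average rather than
  counted as 0 — counting them as 0 would conflate sparse neighborhoods
  with unclustered ones. A single scalar aggregate of C_1..C_P (default
  P = 8) is configurable (mean/sum/max) since different summaries are
  defensible; the vector is always reported.

## Transient mutual information protocol

`mean_transient_I` draws `n_starts = 100` uniform random initial states,
runs each for `transient_length = 10` synchronous steps, and pools all
100 × 9 = 900 transitions into a single joint table per ordered node pair.
MI is computed per pair from the pooled table with the plug-in
(maximum-likelihood) estimator and averaged over all ordered pairs,
including i = j by default (a flag excludes self-pairs; the difference is
O(1/N)). Transients rather than attractors are measured deliberately: the
object of interest is the response to perturbations, not long-term cycles.
Per-transient MI would be spurious at length 10; pooling is essential.

Estimator notes. Marginals are taken from the same pooled transitions
(node i over times 0..8, node j over 1..9), which makes the plug-in MI
nonnegative by construction. No bias correction is applied: the positive
small-sample floor (≈ 1/(2·T·ln 2) bits per pair at T = 900 for
full-entropy nodes) is part of the measured quantity and identical across
the networks being compared, so it cancels in contrasts. MI is returned in
bits (base-2 entropies); multiplying by ln 2 converts to natural-log
units, the scale on which the reference tabulations of this protocol are
reported — `scripts/acceptance.py` performs that conversion.

## Null models

Topologies follow the "Random 2" construction: exactly m ordered pairs
(u, v), self-pairs allowed, drawn uniformly without replacement from the
n² possibilities; m = round(K·n) realizes a target mean connectivity
(1837 edges for K = 5.6, n = 328). In/out-degrees are then Binomial(n,
m/n²).

* **Rand-Beta** draws each node's truth-table bias from
  Beta(α = 0.3467, β = 0.4350) — the maximum-likelihood fit to the yeast
  core's strongly U-shaped p-bias sample — and fills the table i.i.d.
  Bernoulli(bias). It preserves the p-bias *distribution* but randomizes
  the local structure (C_p).
* **Rand-p-bias** fixes every bias at 0.41, the yeast core's mean p-bias,
  preserving the mean but destroying the spread; at K = 5.6 this puts the
  ensemble deep in the chaotic regime (S ≈ 2.7), whereas the U-shaped
  biases keep Rand-Beta near critical (S ≈ 1.2).

Nodes that receive no inputs get a constant function drawn Bernoulli(bias)
so every node participates in the dynamics. `EmpiricalBias` resamples an
explicit p-bias list instead of the fitted Beta, for when an empirical
sample is available. Beta fitting clips values to [ε, 1−ε] (exact 0/1
biases arise from constant functions and have infinite log-density under
shapes < 1); the natural per-function resolution 1/(2·2^n) is the
recommended clip when fitting realized p-biases.

## Synthetic data generator

The generator produces the measurement design the inference expects: for
each gene and each perturbation kind, one experiment reporting log10
ratios for every gene. Targets of a true edge j → G respond with
`±effect_scale` (sign from j's regulatory sign on G, flipped for
deletions); all other cells are additive Gaussian noise on the log10 scale
(`noise_sd`). The regulatory sign of an input is the majority vote of the
truth-table differences over the other inputs' states, ties counting as
activation — the same aggregate a perturbation weight encodes. Defaults:
`effect_scale = 1.0` (a 10-fold change, a strong and clearly detectable
regulatory response, comfortably above the 3.32-fold threshold) and
`noise_sd = 0.1` (typical log10-scale ratio-microarray variability).
Ground-truth topologies plant no self-loops, matching their
unidentifiability from this design.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: indirect cascade effects (each cell reflects
only direct edges, while a real perturbation propagates downstream),
probe-level artifacts, dye bias, correlated noise across genes, and
incomplete measurement coverage. Edge recovery is exact at zero noise by
construction; the informative tests are the monotone degradation with
noise and the end-to-end determinism.

## Self-consistency check

`self_consistency` draws a random network state and a random measured
experiment, optionally clamps the experiment's perturbation, advances one
step (horizon configurable), and compares each gene's predicted state with
its binarized measured response (changes of at least the threshold fold;
smaller changes are undetermined and excluded). The perturbed gene itself
is excluded — its state is forced, not predicted. Note a structural
ceiling: a multi-input target's summed weight can be dominated by inputs
other than the perturbed one, so pooled agreement stays below 1 even on
noise-free synthetic data; the meaningful comparison is against a
shuffled-measurement baseline (≈ 0.5). Default `n_runs = 10^5`; the
estimator is unbiased at any run count.

## Numerical choices

* Threshold comparisons are inclusive, with a 1e−12 slack on the log10
  scale to make "exactly at threshold" robust to float rounding.
* `V = 0` detection is exact float equality: ties are meant to capture
  exact cancellations (including the common all-equal-magnitude case), not
  near-cancellations.
* Duplicate experiments for the same (gene, kind) are merged by averaging
  log-ratios gene-wise, with a warning; missing cells are configurable as
  hard errors or as "no data" (weight 0).
* All randomness flows through numpy Generators seeded explicitly;
  tie-breaks use a keyed blake2b hash so they survive serialization
  round-trips. Full pipelines are bit-reproducible given their seeds.

## Problem sizes

Ensemble statistics in the test suite and in `scripts/acceptance.py` use
30 replicates at the reference scale (n = 328, m = 1837) with the
100-start × length-10 transient protocol; these sizes give ensemble
standard errors well below the reference uncertainties (e.g. ±0.02 on S,
±0.0003 on I) while keeping a full run under a minute on one CPU.

## Known limitations

* The Boolean, synchronous, noiseless dynamics are a coarse abstraction;
  conclusions about information propagation are relative statements
  between networks under the same dynamics.
* The single-threshold binarization treats all genes alike; gene-specific
  thresholds are not supported.
* Mean L excludes unreachable pairs and so can rank a fragmented network
  "shorter" than a connected one; always read it together with the cluster
  count.
* Self-regulation is invisible to the perturbation design (see masking
  above); C_1 of an inferred network is therefore 0 unless `allow_self`
  is set.
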
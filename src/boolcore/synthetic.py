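"""Synthetic ground-truth networks and simulated perturbation datasets.

The generator emulates the measurement design the inference expects: one
experiment per (gene, perturbation kind), reporting log10 expression ratios
of every gene versus wild type.  Genes downstream of a true regulatory edge
respond with a signed effect of controlled magnitude; all other cells are
pure noise (additive Gaussian on the log10 scale, the standard model for
ratio microarrays).

Ground-truth topologies exclude self-loops: a perturbation experiment
cannot distinguish a gene's autoregulation from the perturbation itself, so
self-edges are unidentifiable from this data and the generator does not
plant them.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._util import as_rng
from .functions import TransferFunction
from .io import Kind, PerturbationDataset, PerturbationExperiment
from .network import BooleanNetwork
from .nullmodels import FixedBias, CORE_MEAN_PBIAS, edges_for_mean_k


@dataclass
class SyntheticGroundTruth:
    """A known Boolean network plus the effect/noise scales used to write
    its simulated perturbation measurements."""

    net: BooleanNetwork
    effect_scale: float  # log10 fold change of a true regulatory effect
    noise_sd: float      # SD of additive log10 noise on every cell
    seed: int

    def __post_init__(self):
        if self.effect_scale <= 0:
            raise ValueError("effect_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _random_topology_no_self(n: int, m: int, rng) -> nx.DiGraph:
    """Uniform m distinct ordered pairs with u != v (no self-loops)."""
    if m > n * (n - 1):
        raise ValueError(f"m={m} exceeds n*(n-1)={n * (n - 1)}")
    flat = rng.choice(n * (n - 1), size=m, replace=False)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for f in flat:
        u, r = divmod(int(f), n - 1)
        v = r if r < u else r + 1
        g.add_edge(u, v)
    return g


def generate_truth(n_genes: int, mean_k: float,
                   bias_mode=FixedBias(CORE_MEAN_PBIAS), seed: int = 0,
                   effect_scale: float = 1.0,
                   noise_sd: float = 0.1) -> SyntheticGroundTruth:
    """Random ground-truth network with named genes.

    Topology: round(mean_k * n_genes) uniformly random directed edges
    without self-loops.  Functions: truth tables filled i.i.d. Bernoulli(b)
    with b drawn per node from ``bias_mode``.  The default effect scale of
    1.0 (a 10-fold change) models a strong, clearly detectable regulatory
    response; the default noise SD of 0.1 on the log10 scale is typical
    cell-to-cell variability of ratio microarrays.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = as_rng(seed)
    m = edges_for_mean_k(n_genes, mean_k)
    width = len(str(n_genes))
    names = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    topo = _random_topology_no_self(n_genes, m, rng)
    functions = {}
    for i, name in enumerate(names):
        inputs = tuple(names[j] for j in sorted(topo.predecessors(i)))
        b = bias_mode.draw(rng)
        table = (rng.random(2 ** len(inputs)) < b).astype(np.uint8)
        functions[name] = TransferFunction.from_table(name, inputs, table)
    net = BooleanNetwork(names, functions)
    return SyntheticGroundTruth(net=net, effect_scale=float(effect_scale),
                                noise_sd=float(noise_sd), seed=int(seed))


def regulatory_sign(f: TransferFunction, input_index: int) -> int:
    """+1 if the input predominantly activates, -1 if it represses.

    Majority vote of f(..x_j=1..) - f(..x_j=0..) over all states of the
    other inputs; ties count as activation (+1).
    """
    table = f.to_explicit()
    n = f.n
    if not 0 <= input_index < n:
        raise IndexError("input_index out of range")
    idx = np.arange(2 ** n, dtype=np.int64)
    low = idx[(idx >> input_index) & 1 == 0]
    diff = table[low | (1 << input_index)].astype(int) - table[low].astype(int)
    return 1 if diff.sum() >= 0 else -1


def simulate_perturbation_dataset(truth: SyntheticGroundTruth,
                                  kinds=(Kind.DELETION, Kind.OVEREXPRESSION)
                                  ) -> PerturbationDataset:
    """One simulated experiment per (gene, kind) of the ground truth.

    A target G of a true edge j -> G responds with log-ratio
    s * effect_scale + noise, where s flips with the regulatory sign of j on
    G and with the kind (deleting an activator lowers G; overexpressing it
    raises G).  Non-targets receive pure noise.  The perturbed gene's own
    cell reflects the perturbation itself (down for deletion, up for
    overexpression).
    """
    net = truth.net
    rng = as_rng([truth.seed, 0xD47A])
    # per-target regulatory sign of each true edge
    sign: dict[tuple, int] = {}
    for G in net.nodes:
        f = net.functions[G]
        for pos, j in enumerate(f.inputs):
            sign[(j, G)] = regulatory_sign(f, pos)
    experiments = []
    for j in net.nodes:
        for kind in kinds:
            flip = 1 if kind is Kind.OVEREXPRESSION else -1
            ratios = {}
            for G in net.nodes:
                noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd \
                    else 0.0
                if G == j:
                    ratios[G] = flip * truth.effect_scale + noise
                elif (j, G) in sign:
                    ratios[G] = flip * sign[(j, G)] * truth.effect_scale \
                        + noise
                else:
                    ratios[G] = noise
            experiments.append(PerturbationExperiment(j, kind, ratios))
    return PerturbationDataset.from_experiments(experiments, list(net.nodes))
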
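"""Random null-model networks and Beta fits to p-bias samples.

Two null ensembles share a uniformly random directed topology with a fixed
edge count ("Random 2" wiring: m distinct ordered node pairs, self-pairs
allowed, drawn uniformly without replacement from [1, n]^2):

* **Rand-Beta** — each node's truth-table bias b is drawn from the Beta
  distribution fitted to an empirical p-bias sample (for the yeast core,
  alpha = 0.3467, beta = 0.4350); outputs are i.i.d. Bernoulli(b).
* **Rand-p-bias** — every node uses the same fixed bias (0.41 for the yeast
  core), destroying the spread of the p-bias distribution while keeping its
  mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from ._util import as_rng
from .functions import TransferFunction
from .network import BooleanNetwork

#: Beta parameters fitted to the yeast core p-bias sample
CORE_BETA_ALPHA = 0.3467
CORE_BETA_BETA = 0.4350
#: mean p-bias of the yeast core transfer functions
CORE_MEAN_PBIAS = 0.41


@dataclass(frozen=True)
class FixedBias:
    """Every function gets the same bias p."""

    p: float

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValueError("fixed bias must lie in [0, 1]")

    def draw(self, rng: np.random.Generator) -> float:
        return self.p


@dataclass(frozen=True)
class BetaBias:
    """Biases drawn i.i.d. from Beta(alpha, beta)."""

    alpha: float = CORE_BETA_ALPHA
    beta: float = CORE_BETA_BETA

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shapes must be positive")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))


@dataclass(frozen=True)
class EmpiricalBias:
    """Biases resampled (with replacement) from an empirical p-bias list."""

    sample: tuple

    def draw(self, rng: np.random.Generator) -> float:
        return float(self.sample[rng.integers(len(self.sample))])


@dataclass
class NullModelConfig:
    """Size, wiring density and bias mode of one null ensemble member."""

    n_nodes: int
    n_edges: int
    bias_mode: object  # FixedBias | BetaBias | EmpiricalBias
    seed: int = 0

    def __post_init__(self):
        if self.n_edges > self.n_nodes ** 2:
            raise ValueError("n_edges cannot exceed n_nodes**2")


@dataclass
class BetaFit:
    """Maximum-likelihood Beta(alpha, beta) fit to a [0, 1] sample."""

    alpha: float
    beta: float
    loglik: float


def random2_topology(n: int, m: int, seed) -> nx.DiGraph:
    """Uniformly random directed graph with exactly m distinct edges.

    Edges are m ordered pairs (u, v) in [0, n)^2 — self-pairs allowed —
    drawn uniformly without replacement.
    """
    if m > n * n:
        raise ValueError(f"m={m} exceeds n**2={n * n}")
    rng = as_rng(seed)
    flat = rng.choice(n * n, size=m, replace=False)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(flat // n, flat % n))
    return g


def make_null_network(config: NullModelConfig) -> BooleanNetwork:
    """Random topology plus bias-driven random truth tables.

    Per node (in index order): draw a bias b from the config's bias mode,
    then fill the truth table over its inputs with i.i.d. Bernoulli(b)
    entries, independently of all other output states.  Nodes that receive
    no inputs get a constant function drawn Bernoulli(b) so every node
    participates in the dynamics.
    """
    rng = as_rng(config.seed)
    topo = random2_topology(config.n_nodes, config.n_edges, rng)
    functions = {}
    for node in range(config.n_nodes):
        inputs = tuple(sorted(topo.predecessors(node)))
        b = config.bias_mode.draw(rng)
        table = (rng.random(2 ** len(inputs)) < b).astype(np.uint8)
        functions[node] = TransferFunction.from_table(node, inputs, table)
    return BooleanNetwork(range(config.n_nodes), functions)


def rand_beta_network(n: int = 328, m: int = 1837,
                      alpha: float = CORE_BETA_ALPHA,
                      beta: float = CORE_BETA_BETA, seed=0) -> BooleanNetwork:
    """One Rand-Beta null network (random wiring, Beta-distributed biases)."""
    return make_null_network(
        NullModelConfig(n, m, BetaBias(alpha, beta), seed))


def rand_pbias_network(n: int = 328, m: int = 1837,
                       p: float = CORE_MEAN_PBIAS, seed=0) -> BooleanNetwork:
    """One Rand-p-bias null network (random wiring, one fixed bias)."""
    return make_null_network(NullModelConfig(n, m, FixedBias(p), seed))


def edges_for_mean_k(n: int, mean_k: float) -> int:
    """Edge count realizing a target mean connectivity: m = round(K * n)."""
    return int(round(mean_k * n))


def fit_beta(pbias_sample, eps: float = 1e-6) -> BetaFit:
    """Maximum-likelihood two-parameter Beta fit to a p-bias sample.

    Values are clipped to [eps, 1 - eps] first: exact 0/1 biases occur for
    constant functions and have infinite log-density under any Beta with
    shape < 1.  An all-identical sample has a degenerate likelihood and is
    rejected.
    """
    x = np.clip(np.asarray(pbias_sample, dtype=float), eps, 1 - eps)
    if x.size < 2:
        raise ValueError("need at least two p-bias values to fit")
    if np.all(x == x[0]):
        raise ValueError("degenerate (all-identical) p-bias sample")
    alpha, beta, _, _ = stats.beta.fit(x, floc=0, fscale=1)
    loglik = float(stats.beta.logpdf(x, alpha, beta).sum())
    return BetaFit(alpha=float(alpha), beta=float(beta), loglik=loglik)
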
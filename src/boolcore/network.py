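"""Synchronous Boolean network model with clamped perturbations.

All nodes update simultaneously and deterministically; a clamp holds a node
at a forced value (0 for a deletion, 1 for an overexpression) at every time
step *including* t = 0, so a deleted gene is never observed ON.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from ._util import as_rng
from .functions import TransferFunction


@dataclass(frozen=True)
class ClampSpec:
    """Nodes held at forced values throughout a simulation."""

    clamps: Mapping = field(default_factory=dict)

    @classmethod
    def deletion(cls, *genes) -> "ClampSpec":
        return cls({g: 0 for g in genes})

    @classmethod
    def overexpression(cls, *genes) -> "ClampSpec":
        return cls({g: 1 for g in genes})

    def __bool__(self):
        return bool(self.clamps)


class BooleanNetwork:
    """Ordered gene list plus one transfer function per gene."""

    def __init__(self, nodes, functions: Mapping):
        self.nodes = list(nodes)
        self.functions = dict(functions)
        self._index = {g: i for i, g in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        missing = [g for g in self.nodes if g not in self.functions]
        if missing:
            raise ValueError(f"nodes without a transfer function: {missing[:5]}")
        self._in_idx = {}
        for g in self.nodes:
            f = self.functions[g]
            try:
                self._in_idx[g] = np.array(
                    [self._index[j] for j in f.inputs], dtype=np.int64)
            except KeyError as e:
                raise ValueError(
                    f"function of {g!r} uses unknown input {e.args[0]!r}")

    @property
    def N(self) -> int:
        return len(self.nodes)

    def topology(self) -> nx.DiGraph:
        """Directed graph with an edge j -> G for each input j of G."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for node in self.nodes:
            for j in self.functions[node].inputs:
                g.add_edge(j, node)
        return g

    # -- dynamics -----------------------------------------------------

    def _clamp_cols(self, clamp: ClampSpec | None):
        if not clamp:
            return None, None
        try:
            cols = np.array([self._index[g] for g in clamp.clamps], dtype=int)
        except KeyError as e:
            raise KeyError(f"clamp references unknown node {e.args[0]!r}")
        vals = np.array([int(v) for v in clamp.clamps.values()], dtype=np.uint8)
        return cols, vals

    def apply_clamp(self, states: np.ndarray, clamp: ClampSpec | None
                    ) -> np.ndarray:
        cols, vals = self._clamp_cols(clamp)
        states = np.array(states, dtype=np.uint8, copy=True)
        if cols is not None:
            states[..., cols] = vals
        return states

    def step_batch(self, states: np.ndarray, clamp: ClampSpec | None = None
                   ) -> np.ndarray:
        """Synchronous update of a ``(B, N)`` batch of states."""
        states = np.asarray(states, dtype=np.uint8)
        if states.ndim != 2 or states.shape[1] != self.N:
            raise ValueError(f"expected (B, {self.N}) state array")
        nxt = np.empty_like(states)
        for i, g in enumerate(self.nodes):
            nxt[:, i] = self.functions[g].eval_batch(
                states[:, self._in_idx[g]])
        return self.apply_clamp(nxt, clamp)

    def step(self, state, clamp: ClampSpec | None = None) -> np.ndarray:
        """Single synchronous update of one state vector."""
        return self.step_batch(np.atleast_2d(np.asarray(state)), clamp)[0]

    def transient_batch(self, initials: np.ndarray, length: int,
                        clamp: ClampSpec | None = None) -> np.ndarray:
        """``(B, length, N)`` trajectories from a batch of initial states.

        A trajectory of ``length`` states contains ``length - 1``
        transitions; clamps are imposed on the initial state as well.
        """
        if length < 1:
            raise ValueError("length must be >= 1")
        initials = np.atleast_2d(np.asarray(initials, dtype=np.uint8))
        traj = np.empty((initials.shape[0], length, self.N), dtype=np.uint8)
        traj[:, 0] = self.apply_clamp(initials, clamp)
        for t in range(1, length):
            traj[:, t] = self.step_batch(traj[:, t - 1], clamp)
        return traj

    def transient(self, initial, length: int,
                  clamp: ClampSpec | None = None) -> np.ndarray:
        """``(length, N)`` trajectory from one initial state."""
        return self.transient_batch(np.atleast_2d(np.asarray(initial)),
                                    length, clamp)[0]

    def random_states(self, n: int, seed) -> np.ndarray:
        """Uniform random states, ``(n, N)``, from a dedicated seed stream."""
        rng = as_rng(seed)
        return rng.integers(0, 2, size=(n, self.N), dtype=np.uint8)

    def mean_pbias(self) -> float:
        return float(np.mean([self.functions[g].pbias for g in self.nodes]))

    def __repr__(self):  # pragma: no cover
        return f"BooleanNetwork(N={self.N})"
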
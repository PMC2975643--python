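"""Temporal pairwise mutual information from pooled transient dynamics.

For an ordered node pair (i, j), I_ij = H(s_i) + H(s_j) - H(s_ij), where s_i
is node i's state at time t, s_j node j's state at t + 1, and s_ij their
joint.  Probabilities are plug-in (maximum-likelihood) estimates pooled over
all observed transitions — by default 100 random initial states, transients
of length 10, hence 900 transitions.  Short pooled series give the plug-in
estimator a small positive bias; that bias floor is part of the measured
quantity and is deliberately not corrected.

The network-level statistic I is the mean of I_ij over ordered pairs,
including i = j by default (a flag excludes self-pairs; the difference is
O(1/N)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._util import as_rng
from .network import BooleanNetwork, ClampSpec


def _plogp(p: np.ndarray) -> np.ndarray:
    """Elementwise -p*log2(p) with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    mask = p > 0
    out[mask] = -p[mask] * np.log2(p[mask])
    return out


def entropy(p0: float, p1: float) -> float:
    """Shannon entropy (bits) of a binary process with P(0)=p0, P(1)=p1."""
    if p0 < 0 or p1 < 0:
        raise ValueError("probabilities must be nonnegative")
    if abs(p0 + p1 - 1.0) > 1e-8:
        raise ValueError("p0 + p1 must equal 1")
    return float(_plogp(np.array([p0, p1])).sum())


@dataclass
class TransitionCounts:
    """Pooled (state at t, state at t+1) counts for every ordered node pair.

    ``c11[i, j]`` counts transitions with node i ON at t and node j ON at
    t + 1, and so on; marginals are taken from the same pooled transitions
    (node i over times 0..L-2, node j over 1..L-1 of each transient), so the
    plug-in mutual information is nonnegative by construction.
    """

    nodes: list
    n_transitions: int
    c00: np.ndarray
    c01: np.ndarray
    c10: np.ndarray
    c11: np.ndarray
    px1: np.ndarray  # P(node ON at t)
    py1: np.ndarray  # P(node ON at t+1)

    @classmethod
    def from_transitions(cls, X: np.ndarray, Y: np.ndarray,
                         nodes) -> "TransitionCounts":
        """Build from aligned (T, N) arrays of states at t and t + 1."""
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if X.shape != Y.shape or X.ndim != 2:
            raise ValueError("X and Y must be equal-shape (T, N) arrays")
        T = X.shape[0]
        if T < 1:
            raise ValueError("at least one transition is required")
        return cls(
            nodes=list(nodes),
            n_transitions=T,
            c11=X.T @ Y,
            c10=X.T @ (1 - Y),
            c01=(1 - X).T @ Y,
            c00=(1 - X).T @ (1 - Y),
            px1=X.mean(axis=0),
            py1=Y.mean(axis=0),
        )

    @classmethod
    def from_trajectories(cls, traj: np.ndarray, nodes) -> "TransitionCounts":
        """Pool the transitions of a (B, L, N) batch of trajectories."""
        traj = np.asarray(traj)
        if traj.ndim != 3:
            raise ValueError("expected a (B, L, N) trajectory array")
        N = traj.shape[2]
        X = traj[:, :-1, :].reshape(-1, N)
        Y = traj[:, 1:, :].reshape(-1, N)
        return cls.from_transitions(X, Y, nodes)


def mi_matrix(counts: TransitionCounts) -> np.ndarray:
    """I_ij (bits) for every ordered pair; row = node at t, col = at t+1."""
    T = counts.n_transitions
    hx = _plogp(counts.px1) + _plogp(1 - counts.px1)
    hy = _plogp(counts.py1) + _plogp(1 - counts.py1)
    hxy = sum(_plogp(c / T)
              for c in (counts.c00, counts.c01, counts.c10, counts.c11))
    mi = hx[:, None] + hy[None, :] - hxy
    return np.clip(mi, 0.0, None)


def pairwise_mi(counts: TransitionCounts, i, j) -> float:
    """I_ij in bits for one ordered pair (node labels or indices)."""
    if counts.n_transitions < 1:
        raise ValueError("at least one transition is required")
    ii = i if isinstance(i, (int, np.integer)) and i not in counts.nodes \
        else counts.nodes.index(i)
    jj = j if isinstance(j, (int, np.integer)) and j not in counts.nodes \
        else counts.nodes.index(j)
    return float(mi_matrix(counts)[ii, jj])


@dataclass
class InfoReport:
    """Pairwise MI matrix and its network-level means."""

    nodes: list
    I_matrix: np.ndarray
    mean_I: float           # over all ordered pairs, incl. i = j
    mean_I_no_self: float   # over ordered pairs with i != j
    protocol: dict

    def bound_ok(self, counts: TransitionCounts, atol: float = 1e-9) -> bool:
        """Check I_ij <= min(H(s_i), H(s_j)) for every pair."""
        hx = _plogp(counts.px1) + _plogp(1 - counts.px1)
        hy = _plogp(counts.py1) + _plogp(1 - counts.py1)
        bound = np.minimum(hx[:, None], hy[None, :])
        return bool(np.all(self.I_matrix <= bound + atol))


def mean_transient_I(net: BooleanNetwork, n_starts: int = 100,
                     transient_length: int = 10, seed=0,
                     clamp: ClampSpec | None = None,
                     return_counts: bool = False):
    """Mean temporal pairwise MI over transients from random initial states.

    ``n_starts`` uniform random initial states are each run for
    ``transient_length`` synchronous steps; the
    ``n_starts * (transient_length - 1)`` transitions are pooled into a
    single probability table per node pair (not averaged per transient,
    which would be spurious at this length).  Defaults reproduce the
    900-transition protocol.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if transient_length < 2:
        raise ValueError("transient_length must be >= 2")
    rng = as_rng(seed)
    initials = net.random_states(n_starts, rng)
    traj = net.transient_batch(initials, transient_length, clamp)
    counts = TransitionCounts.from_trajectories(traj, net.nodes)
    mi = mi_matrix(counts)
    n = net.N
    mean_all = float(mi.mean())
    mean_ns = float((mi.sum() - np.trace(mi)) / (n * n - n)) if n > 1 \
        else math.nan
    report = InfoReport(
        nodes=list(net.nodes),
        I_matrix=mi,
        mean_I=mean_all,
        mean_I_no_self=mean_ns,
        protocol={"n_starts": n_starts, "transient_length": transient_length,
                  "n_transitions": counts.n_transitions},
    )
    if return_counts:
        return report, counts
    return report
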
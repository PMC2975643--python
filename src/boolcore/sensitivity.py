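"""Average sensitivity of Boolean functions and networks.

The sensitivity of a function f on input x is the number of Hamming
neighbors of x on which f differs from f(x); the average sensitivity s^f is
its expectation over uniformly distributed inputs.  The network mean S (the
unweighted mean of s^f over all transfer functions) is an order parameter of
Boolean dynamics: S < 1 ordered, S = 1 critical, S > 1 chaotic.  For truth
tables filled i.i.d. Bernoulli(p) over K-input functions the analytic
estimate is S = 2 K p (1 - p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import stable_u32
from .functions import DEFAULT_EXPLICIT_CAP, DEFAULT_N_SAMPLES, TransferFunction
from .network import BooleanNetwork


@dataclass
class SensitivityReport:
    """Per-function and network-mean average sensitivities."""

    per_function: dict
    network_S: float
    method: str  # "exact", "sampled" or "mixed"
    n_samples: int | None = None


def function_sensitivity(f: TransferFunction, mode: str = "exact",
                         n_samples: int = DEFAULT_N_SAMPLES, seed: int = 0,
                         return_se: bool = False):
    """Average sensitivity of one transfer function.

    ``exact`` enumerates all 2**n inputs (requires an explicit table or
    n <= the explicit cap); ``sampled`` is an unbiased Monte-Carlo estimate
    over uniform input states, optionally with its standard error.
    """
    n = f.n
    if n == 0:
        return (0.0, 0.0) if return_se else 0.0
    if mode == "exact":
        table = f.to_explicit()
        idx = np.arange(2 ** n, dtype=np.int64)
        flips = np.zeros(2 ** n)
        for l in range(n):
            flips += table[idx ^ (1 << l)] != table
        s = float(flips.mean())
        return (s, 0.0) if return_se else s
    if mode != "sampled":
        raise ValueError("mode must be 'exact' or 'sampled'")
    if n_samples <= 0:
        raise ValueError("sampled mode requires n_samples >= 1")
    bits = f.sample_states(n_samples, seed=[seed, stable_u32(str(f.gene))])
    fx = f.eval_batch(bits)
    flips = np.zeros(n_samples)
    for l in range(n):
        nb = bits.copy()
        nb[:, l] ^= 1
        flips += f.eval_batch(nb) != fx
    s = float(flips.mean())
    if return_se:
        return s, float(flips.std(ddof=1) / np.sqrt(n_samples))
    return s


def network_sensitivity(net: BooleanNetwork, mode: str = "auto",
                        explicit_cap: int = DEFAULT_EXPLICIT_CAP,
                        n_samples: int = DEFAULT_N_SAMPLES,
                        seed: int = 0) -> SensitivityReport:
    """Unweighted mean of per-function average sensitivities.

    ``auto`` evaluates exactly whenever a function has at most
    ``explicit_cap`` inputs and falls back to seeded Monte-Carlo sampling
    for larger (implicit) functions.
    """
    per = {}
    methods = set()
    for g in net.nodes:
        f = net.functions[g]
        if mode == "auto":
            use = "exact" if (f.explicit or f.n <= explicit_cap) else "sampled"
        else:
            use = mode
        per[g] = function_sensitivity(f, mode=use, n_samples=n_samples,
                                      seed=seed)
        methods.add(use)
    method = methods.pop() if len(methods) == 1 else "mixed"
    return SensitivityReport(
        per_function=per,
        network_S=float(np.mean(list(per.values()))),
        method=method,
        n_samples=n_samples if method != "exact" else None,
    )


def analytic_sensitivity(K: float, p: float) -> float:
    """Estimate S = 2 K p (1 - p) for bias-p random functions at mean
    connectivity K."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if K < 0:
        raise ValueError("K must be nonnegative")
    return 2.0 * K * p * (1.0 - p)
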
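"""Self-consistency of an inferred network against its source measurements.

Protocol: repeatedly draw a uniform random network state and a random
measured experiment; advance the network one synchronous step (optionally
clamping the experiment's perturbed gene to its forced value, 0 for a
deletion, 1 for an overexpression); compare each gene's predicted next
state with its binarized measured response under that experiment.  Only
genes whose measured change reaches the binarization threshold contribute
("determined" responses); the perturbed gene itself is excluded, since its
state is fixed by the perturbation rather than predicted.  The report pools
agreement over all runs and determined genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import as_rng
from .inference import InferredNetwork
from .io import Kind, PerturbationDataset, binarize_response
from .network import BooleanNetwork


@dataclass
class ConsistencyReport:
    """Pooled agreement fractions of predictions with measurements."""

    agreement_free: float | None
    agreement_clamped: float | None
    n_runs: int
    n_comparisons: int


def _binarization_matrix(experiments, genes, threshold):
    """(E, N) int8 matrix of binarized responses; -1 = undetermined."""
    idx = {g: i for i, g in enumerate(genes)}
    B = np.full((len(experiments), len(genes)), -1, dtype=np.int8)
    for e_i, exp in enumerate(experiments):
        for g, r in exp.ratios.items():
            if g not in idx:
                continue
            b = binarize_response(r, threshold)
            if b is not None:
                B[e_i, idx[g]] = b
    return B


def self_consistency(net, dataset: PerturbationDataset,
                     n_runs: int = 100_000, clamp_mode: str = "both",
                     seed: int = 0, threshold: float | None = None,
                     horizon: int = 1,
                     batch_size: int = 50_000) -> ConsistencyReport:
    """Monte-Carlo agreement of one-step predictions with measurements.

    Parameters
    ----------
    net:
        An :class:`InferredNetwork` (its calibrated threshold is reused for
        binarization) or a plain :class:`BooleanNetwork` (pass
        ``threshold``).
    clamp_mode:
        ``"free"`` — random initial states only; ``"clamped"`` — each run
        additionally clamps the drawn experiment's perturbation;
        ``"both"`` — compute both agreement fractions on the same seeds.
    horizon:
        Number of synchronous steps before comparing (default 1).
    """
    if isinstance(net, InferredNetwork):
        bn = net.to_boolean_network()
        threshold = net.threshold if threshold is None else threshold
    else:
        bn = net
        if threshold is None:
            raise ValueError("a binarization threshold is required for a "
                             "plain BooleanNetwork")
    if clamp_mode not in ("free", "clamped", "both"):
        raise ValueError("clamp_mode must be 'free', 'clamped' or 'both'")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    genes = bn.nodes
    gene_idx = {g: i for i, g in enumerate(genes)}
    missing = [g for g in genes if g not in set(dataset.genes)]
    if missing:
        raise ValueError(f"network genes absent from dataset: {missing[:5]}")
    experiments = [e for e in dataset.experiments
                   if e.perturbed_gene in gene_idx]
    if not experiments:
        raise ValueError("no experiment perturbs a network gene")
    B = _binarization_matrix(experiments, genes, threshold)
    if not (B >= 0).any():
        raise ValueError("no measured response reaches the binarization "
                         "threshold; nothing to compare")
    pert_col = np.array([gene_idx[e.perturbed_gene] for e in experiments])
    forced = np.array([e.kind.forced_value for e in experiments],
                      dtype=np.uint8)

    rng = as_rng(seed)
    agree = {"free": 0, "clamped": 0}
    total = {"free": 0, "clamped": 0}
    modes = ("free", "clamped") if clamp_mode == "both" else (clamp_mode,)
    done = 0
    while done < n_runs:
        r = min(batch_size, n_runs - done)
        done += r
        states = rng.integers(0, 2, size=(r, bn.N), dtype=np.uint8)
        exp_i = rng.integers(0, len(experiments), size=r)
        Bx = B[exp_i]                       # (r, N) measured responses
        mask = Bx >= 0
        mask[np.arange(r), pert_col[exp_i]] = False
        for mode in modes:
            cur = states.copy()
            if mode == "clamped":
                cur[np.arange(r), pert_col[exp_i]] = forced[exp_i]
            for _ in range(horizon):
                cur = bn.step_batch(cur)
                if mode == "clamped":
                    cur[np.arange(r), pert_col[exp_i]] = forced[exp_i]
            agree[mode] += int(((cur == Bx) & mask).sum())
            total[mode] += int(mask.sum())

    def frac(mode):
        if mode not in modes:
            return None
        return agree[mode] / total[mode] if total[mode] else None

    return ConsistencyReport(
        agreement_free=frac("free"),
        agreement_clamped=frac("clamped"),
        n_runs=n_runs,
        n_comparisons=sum(total[m] for m in modes),
    )
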
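"""Boolean transfer functions.

A transfer function maps a binary state of its ordered inputs to the next
binary state of its gene.  Two representations are supported:

* **explicit** — a truth table of ``2**n`` output bits, used when the number
  of inputs ``n`` does not exceed ``explicit_cap``;
* **implicit** — the signed perturbation weights ``(w0, w1)`` per input
  (weight of the input being OFF / ON) plus a tie-break seed; the output for
  a state is recomputed on demand.  This avoids materializing huge tables
  for highly connected genes.

State-index convention: the bit vector ``(x_1, ..., x_n)`` aligned with
``inputs`` maps to the integer ``sum_j x_j * 2**j``, i.e. ``inputs[0]`` is
the least-significant bit of the truth-table index.

When the summed weight of a state is exactly zero the output is undecidable
from the data and is set pseudo-randomly, but *deterministically*: the bit is
a keyed hash of ``(gene, state index, seed)``, so explicit and implicit
representations of the same function agree bit-for-bit.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np

from ._util import as_rng, stable_u32

#: inputs beyond this count keep the implicit weight representation
DEFAULT_EXPLICIT_CAP = 20

#: Monte-Carlo sample size for p-bias / sensitivity of implicit functions
DEFAULT_N_SAMPLES = 10_000


def tie_break_bit(gene, state_index: int, seed: int) -> int:
    """Deterministic pseudo-random bit for a zero-weight truth-table entry."""
    key = f"{gene}|{int(state_index)}|{int(seed)}".encode()
    return hashlib.blake2b(key, digest_size=1).digest()[0] & 1


class TransferFunction:
    """Boolean rule of one gene over an ordered tuple of input genes."""

    __slots__ = ("gene", "inputs", "table", "w0", "w1", "seed",
                 "n_tie_states", "_pbias")

    def __init__(self, gene, inputs: Sequence, *, table=None, w0=None,
                 w1=None, seed: int = 0, n_tie_states: int = 0):
        self.gene = gene
        self.inputs = tuple(inputs)
        self.seed = int(seed)
        self.n_tie_states = int(n_tie_states)
        self._pbias = None
        if table is not None:
            table = np.asarray(table, dtype=np.uint8)
            if table.shape != (2 ** len(self.inputs),):
                raise ValueError(
                    f"truth table for {gene!r} has {table.size} entries, "
                    f"expected {2 ** len(self.inputs)}")
            self.table, self.w0, self.w1 = table, None, None
        elif w0 is not None and w1 is not None:
            self.table = None
            self.w0 = np.asarray(w0, dtype=float)
            self.w1 = np.asarray(w1, dtype=float)
            if self.w0.shape != (self.n,) or self.w1.shape != (self.n,):
                raise ValueError("weight arrays must match the input count")
        else:
            raise ValueError("provide either a truth table or weights")

    # -- construction -------------------------------------------------

    @classmethod
    def from_table(cls, gene, inputs, table) -> "TransferFunction":
        return cls(gene, inputs, table=table)

    @classmethod
    def constant(cls, gene, value: int) -> "TransferFunction":
        """Zero-input function pinned at ``value``."""
        return cls(gene, (), table=[int(value)])

    @classmethod
    def from_weights(cls, gene, inputs, w0, w1, seed: int = 0,
                     explicit_cap: int = DEFAULT_EXPLICIT_CAP
                     ) -> "TransferFunction":
        """Build from signed perturbation weights.

        ``w0[j]`` / ``w1[j]`` is the weight of input ``j`` being OFF / ON
        (from deletion / overexpression experiments respectively).  For
        ``n <= explicit_cap`` the full truth table is materialized; larger
        functions stay implicit and are evaluated lazily.
        """
        n = len(inputs)
        if n == 0:
            raise ValueError(f"gene {gene!r} has no inputs")
        f = cls(gene, inputs, w0=w0, w1=w1, seed=seed)
        if n <= explicit_cap:
            table, n_ties = f._materialize()
            return cls(gene, inputs, table=table, seed=seed,
                       n_tie_states=n_ties)
        # count of tie states is unknown without enumeration; leave implicit
        return f

    def _materialize(self):
        n = self.n
        idx = np.arange(2 ** n, dtype=np.int64)
        bits = (idx[:, None] >> np.arange(n)) & 1
        v = bits @ self.w1 + (1 - bits) @ self.w0
        table = (v > 0).astype(np.uint8)
        ties = np.flatnonzero(v == 0.0)
        for t in ties:
            table[t] = tie_break_bit(self.gene, int(t), self.seed)
        return table, len(ties)

    # -- basic queries ------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.inputs)

    @property
    def explicit(self) -> bool:
        return self.table is not None

    def to_explicit(self, explicit_cap: int = DEFAULT_EXPLICIT_CAP
                    ) -> np.ndarray:
        """Truth table as an array; errors for implicit functions above cap."""
        if self.table is not None:
            return self.table
        if self.n > explicit_cap:
            raise ValueError(
                f"function of {self.gene!r} has {self.n} inputs; refusing "
                f"to materialize 2**{self.n} entries")
        return self._materialize()[0]

    # -- evaluation ---------------------------------------------------

    def eval_batch(self, bits: np.ndarray) -> np.ndarray:
        """Evaluate on a ``(B, n)`` array of input bits; returns ``(B,)``."""
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.ndim != 2 or bits.shape[1] != self.n:
            raise ValueError(f"expected (B, {self.n}) bit array")
        if self.table is not None:
            if self.n == 0:
                return np.full(bits.shape[0], self.table[0], dtype=np.uint8)
            idx = bits @ (1 << np.arange(self.n, dtype=np.int64))
            return self.table[idx]
        v = bits @ self.w1 + (1 - bits) @ self.w0
        out = (v > 0).astype(np.uint8)
        for row in np.flatnonzero(v == 0.0):
            state_index = int(sum(int(b) << j for j, b in enumerate(bits[row])))
            out[row] = tie_break_bit(self.gene, state_index, self.seed)
        return out

    def __call__(self, bits) -> int:
        return int(self.eval_batch(np.atleast_2d(np.asarray(bits)))[0])

    def sample_states(self, n_samples: int, seed=None) -> np.ndarray:
        """Seeded uniform sample of input states (for implicit estimates)."""
        if seed is None:
            seed = [self.seed, stable_u32(str(self.gene))]
        rng = as_rng(seed)
        return rng.integers(0, 2, size=(n_samples, self.n), dtype=np.uint8)

    @property
    def pbias(self) -> float:
        """Fraction of input states mapped to 1.

        Exact for explicit tables; a seeded Monte-Carlo estimate
        (``DEFAULT_N_SAMPLES`` states) for implicit functions.
        """
        if self._pbias is None:
            if self.table is not None:
                self._pbias = float(self.table.mean())
            else:
                bits = self.sample_states(DEFAULT_N_SAMPLES)
                self._pbias = float(self.eval_batch(bits).mean())
        return self._pbias

    def __repr__(self):  # pragma: no cover - debugging aid
        rep = "explicit" if self.explicit else "implicit"
        return (f"TransferFunction(gene={self.gene!r}, n={self.n}, "
                f"{rep}, pbias={self.pbias:.3f})")
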
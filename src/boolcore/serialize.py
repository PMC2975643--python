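"""Text serialization of Boolean networks.

A network directory contains:

* ``topology.txt`` — the input-matrix dialect (output gene + tab-separated
  input genes per line);
* ``functions.json`` — per gene, the ordered input list and either the
  truth table as a bit string (``inputs[0]`` = least-significant index bit)
  or, for implicit functions, the weight arrays and tie-break seed;
* ``meta.json`` — provenance (threshold, seeds, configuration hash...).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .functions import TransferFunction
from .network import BooleanNetwork
from .inference import InferredNetwork
from .io import write_input_matrix


def save_network(net, outdir, meta: dict | None = None) -> Path:
    """Write a BooleanNetwork or InferredNetwork to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dict(meta or {})
    if isinstance(net, InferredNetwork):
        meta.setdefault("threshold", net.threshold)
        meta.update({k: v for k, v in net.provenance.items()
                     if k not in meta})
        bn = net.to_boolean_network()
    else:
        bn = net
    write_input_matrix(bn.topology(), outdir / "topology.txt")
    funcs = {}
    for g in bn.nodes:
        f = bn.functions[g]
        entry: dict = {"inputs": [str(j) for j in f.inputs]}
        if f.explicit:
            entry["table"] = "".join(map(str, f.table.tolist()))
        else:
            entry["w0"] = f.w0.tolist()
            entry["w1"] = f.w1.tolist()
            entry["seed"] = f.seed
        funcs[str(g)] = entry
    with open(outdir / "functions.json", "w") as fh:
        json.dump({"nodes": [str(g) for g in bn.nodes],
                   "functions": funcs}, fh, indent=1)
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    return outdir


def load_network(netdir) -> tuple[BooleanNetwork, dict]:
    """Load a network directory; returns (network, metadata)."""
    netdir = Path(netdir)
    with open(netdir / "functions.json") as fh:
        doc = json.load(fh)
    functions = {}
    for g, entry in doc["functions"].items():
        inputs = tuple(entry["inputs"])
        if "table" in entry:
            table = np.frombuffer(entry["table"].encode(), dtype=np.uint8) \
                - ord("0")
            functions[g] = TransferFunction.from_table(g, inputs, table)
        else:
            functions[g] = TransferFunction(
                g, inputs, w0=entry["w0"], w1=entry["w1"],
                seed=entry.get("seed", 0))
    meta_path = netdir / "meta.json"
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    return BooleanNetwork(doc["nodes"], functions), meta
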
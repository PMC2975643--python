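"""Reading and writing perturbation expression tables and core input matrices.

Two text dialects are supported:

* **perturbation table** — tab-separated; first column gene identifiers,
  each remaining column one perturbation experiment with header
  ``WT/{gene}`` naming the perturbed gene; cells are log10 ratios of mutant
  to wild-type expression.  The header does not encode whether the
  perturbation was a deletion or an overexpression, so the reader accepts a
  sidecar metadata table and otherwise defaults to deletion with a warning.
* **input matrix** — one line per output gene: the output gene name followed
  by a tab-separated list of its input genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Structural problem with a file (headers, duplicate lines...)."""


class ParseError(ValueError):
    """A cell could not be interpreted; the message names row and column."""


class Kind(str, Enum):
    """Perturbation kind: the forced state of the perturbed gene."""

    DELETION = "deletion"
    OVEREXPRESSION = "overexpression"

    @property
    def forced_value(self) -> int:
        return 0 if self is Kind.DELETION else 1


#: cell tokens treated as "no measurement" under the ``nodata`` policy
NA_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}


@dataclass(frozen=True)
class PerturbationExperiment:
    """Log10 expression ratios of all measured genes in one perturbation.

    ``ratios`` holds only measured, finite values; a gene absent from the
    mapping has no data for this experiment (its weight downstream is 0).
    """

    perturbed_gene: str
    kind: Kind
    ratios: Mapping[str, float]

    def __post_init__(self):
        for g, v in self.ratios.items():
            if not math.isfinite(v):
                raise ValueError(
                    f"non-finite ratio {v!r} for gene {g!r} in experiment "
                    f"perturbing {self.perturbed_gene!r}")


@dataclass
class PerturbationDataset:
    """All perturbation experiments over an ordered gene universe."""

    experiments: list[PerturbationExperiment]
    genes: list[str]

    def __post_init__(self):
        universe = set(self.genes)
        keys = set()
        for e in self.experiments:
            key = (e.perturbed_gene, e.kind)
            if key in keys:
                raise ValueError(f"duplicate experiment {key} after merging")
            keys.add(key)
            if e.perturbed_gene not in universe:
                raise ValueError(
                    f"perturbed gene {e.perturbed_gene!r} not in gene universe")
            unknown = set(e.ratios) - universe
            if unknown:
                raise ValueError(
                    f"experiment {key} references unknown genes: "
                    f"{sorted(unknown)[:5]}")

    @classmethod
    def from_experiments(cls, experiments: Sequence[PerturbationExperiment],
                         genes: Sequence[str] | None = None
                         ) -> "PerturbationDataset":
        """Build a dataset, merging duplicate (gene, kind) experiments.

        Duplicates are averaged gene-wise on the log scale, with a warning.
        """
        groups: dict[tuple, list[PerturbationExperiment]] = {}
        order: list[tuple] = []
        for e in experiments:
            key = (e.perturbed_gene, e.kind)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(e)
        merged = []
        for key in order:
            group = groups[key]
            if len(group) == 1:
                merged.append(group[0])
                continue
            warnings.warn(f"merging {len(group)} duplicate experiments for "
                          f"{key} by averaging log-ratios")
            pooled: dict[str, list[float]] = {}
            for e in group:
                for g, v in e.ratios.items():
                    pooled.setdefault(g, []).append(v)
            merged.append(PerturbationExperiment(
                key[0], key[1], {g: float(np.mean(v))
                                 for g, v in pooled.items()}))
        if genes is None:
            seen: dict[str, None] = {}
            for e in merged:
                seen.setdefault(e.perturbed_gene)
                for g in e.ratios:
                    seen.setdefault(g)
            genes = list(seen)
        return cls(merged, list(genes))

    def get(self, gene: str, kind: Kind) -> PerturbationExperiment | None:
        for e in self.experiments:
            if e.perturbed_gene == gene and e.kind == kind:
                return e
        return None

    def perturbed_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.experiments:
            seen.setdefault(e.perturbed_gene)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Genes x experiments frame of log10 ratios (NaN = no data)."""
        cols = {}
        for i, e in enumerate(self.experiments):
            cols[i] = pd.Series(dict(e.ratios), dtype=float)
        frame = pd.DataFrame(cols).reindex(self.genes)
        frame.columns = [f"WT/{e.perturbed_gene}" for e in self.experiments]
        return frame


@dataclass
class InputMatrix:
    """Topology as rows of (output gene, ordered list of input genes)."""

    rows: dict[str, list[str]]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for out, inputs in self.rows.items():
            seen.setdefault(out)
            for g in inputs:
                seen.setdefault(g)
        return list(seen)

    @property
    def mean_connectivity(self) -> float:
        """Total inputs over the number of output rows.

        In a core network every gene has at least one input, so rows and
        gene universe coincide and this is the mean in-degree K.
        """
        if not self.rows:
            raise ValueError("empty input matrix")
        return sum(len(v) for v in self.rows.values()) / len(self.rows)

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for out, inputs in self.rows.items():
            for j in inputs:
                g.add_edge(j, out)
        return g


# ---------------------------------------------------------------------------
# perturbation tables
# ---------------------------------------------------------------------------

def _load_kind_metadata(meta) -> tuple[dict[int, Kind], dict[str, Kind]]:
    """Sidecar metadata: per-column and/or per-gene perturbation kinds.

    Accepts a path to a TSV with columns (``gene``, ``kind``) and optionally
    ``column`` (1-based data-column index), or a mapping gene -> kind.
    """
    by_col: dict[int, Kind] = {}
    by_gene: dict[str, Kind] = {}
    if meta is None:
        return by_col, by_gene
    if isinstance(meta, Mapping):
        for g, k in meta.items():
            by_gene[str(g)] = Kind(k)
        return by_col, by_gene
    frame = pd.read_csv(meta, sep="\t", dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "kind" not in frame.columns:
        raise FormatError(f"metadata file {meta} lacks a 'kind' column")
    for _, row in frame.iterrows():
        kind = Kind(row["kind"].strip().lower())
        if "column" in frame.columns and not pd.isna(row.get("column")):
            by_col[int(row["column"])] = kind
        elif "gene" in frame.columns:
            by_gene[str(row["gene"]).strip()] = kind
    return by_col, by_gene


def read_perturbation_table(path, meta=None, missing: str = "error",
                            default_kind: Kind = Kind.DELETION
                            ) -> PerturbationDataset:
    """Read a tab-separated perturbation expression table.

    Parameters
    ----------
    path:
        Table with header ``GENE\\tWT/{g1}\\tWT/{g2}...`` and log10-ratio
        cells.
    meta:
        Optional sidecar assigning a perturbation kind to each column (by
        1-based data-column index) or to each perturbed gene; see
        :func:`_load_kind_metadata`.  Columns without metadata default to
        ``default_kind`` with a warning.
    missing:
        ``"error"`` — a non-numeric cell raises :class:`ParseError` naming
        row and column; ``"nodata"`` — such cells are treated as "no
        measurement" and excluded (their weight downstream is 0).
    """
    if missing not in ("error", "nodata"):
        raise ValueError("missing must be 'error' or 'nodata'")
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header has no experiment columns")
    perturbed = []
    for col, title in enumerate(header[1:], start=1):
        title = title.strip()
        if not title.startswith("WT/") or len(title) <= 3:
            raise FormatError(
                f"{path}: column {col + 1} header {title!r} is not of the "
                f"form 'WT/{{gene}}'")
        perturbed.append(title[3:])

    by_col, by_gene = _load_kind_metadata(meta)
    kinds = []
    defaulted = 0
    for col, gene in enumerate(perturbed, start=1):
        if col in by_col:
            kinds.append(by_col[col])
        elif gene in by_gene:
            kinds.append(by_gene[gene])
        else:
            kinds.append(default_kind)
            defaulted += 1
    if defaulted and (by_col or by_gene or default_kind is Kind.DELETION):
        if defaulted == len(perturbed) and not (by_col or by_gene):
            warnings.warn(
                f"{path}: no perturbation-kind metadata; assuming all "
                f"{defaulted} columns are {default_kind.value} experiments")
        elif by_col or by_gene:
            warnings.warn(f"{path}: {defaulted} columns lack kind metadata; "
                          f"defaulting to {default_kind.value}")

    genes: list[str] = []
    ratios: list[dict[str, float]] = [{} for _ in perturbed]
    seen_genes = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        gene = cells[0].strip()
        if not gene:
            raise FormatError(f"{path}:{lineno}: missing gene identifier")
        if gene in seen_genes:
            raise FormatError(f"{path}:{lineno}: duplicate gene row {gene!r}")
        seen_genes.add(gene)
        genes.append(gene)
        if len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, "
                f"got {len(cells)}")
        for col, cell in enumerate(cells[1:]):
            token = cell.strip()
            if token.lower() in NA_TOKENS:
                value = None
            else:
                try:
                    value = float(token)
                except ValueError:
                    value = None
                    if missing == "error":
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric cell {token!r} in "
                            f"column {header[col + 1]!r} (gene {gene!r})")
                else:
                    if not math.isfinite(value):
                        value = None
            if value is None:
                if missing == "error" and token.lower() in NA_TOKENS:
                    raise ParseError(
                        f"{path}:{lineno}: missing value in column "
                        f"{header[col + 1]!r} (gene {gene!r})")
                continue
            ratios[col][gene] = value

    experiments = [
        PerturbationExperiment(g, k, r)
        for g, k, r in zip(perturbed, kinds, ratios)
    ]
    # perturbed genes may be absent from the row universe (e.g. probe sets
    # not covering them); extend the universe so the invariant holds
    universe = list(genes)
    known = set(universe)
    for g in perturbed:
        if g not in known:
            universe.append(g)
            known.add(g)
    return PerturbationDataset.from_experiments(experiments, universe)


def write_perturbation_table(dataset: PerturbationDataset, path,
                             meta_path=None) -> None:
    """Write a dataset in the perturbation-table dialect.

    Cells are written with full ``repr`` precision so a read round-trips
    bit-exactly.  If ``meta_path`` is given, a sidecar TSV with columns
    (column, gene, kind) records each column's perturbation kind.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("GENE")
        for e in dataset.experiments:
            fh.write(f"\tWT/{e.perturbed_gene}")
        fh.write("\n")
        for g in dataset.genes:
            fh.write(g)
            for e in dataset.experiments:
                v = e.ratios.get(g)
                fh.write("\t" if v is None else f"\t{v!r}")
            fh.write("\n")
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            fh.write("column\tgene\tkind\n")
            for i, e in enumerate(dataset.experiments, start=1):
                fh.write(f"{i}\t{e.perturbed_gene}\t{e.kind.value}\n")


# ---------------------------------------------------------------------------
# input matrices
# ---------------------------------------------------------------------------

def read_input_matrix(path) -> InputMatrix:
    """Read a core-network input matrix (one output gene + inputs per line)."""
    path = Path(path)
    rows: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tokens = [t.strip() for t in line.split("\t") if t.strip()]
            out, inputs = tokens[0], tokens[1:]
            if out in rows:
                raise FormatError(
                    f"{path}:{lineno}: duplicate output gene {out!r}")
            deduped = list(dict.fromkeys(inputs))
            if len(deduped) != len(inputs):
                warnings.warn(f"{path}:{lineno}: duplicate inputs for "
                              f"{out!r} removed")
            rows[out] = deduped
    if not rows:
        raise FormatError(f"{path}: empty input matrix")
    return InputMatrix(rows)


def write_input_matrix(obj, path) -> None:
    """Write an :class:`InputMatrix` or directed graph to the dialect.

    For a graph, each node with at least one input becomes a row listing
    its predecessors.
    """
    if isinstance(obj, InputMatrix):
        rows = obj.rows
    else:
        rows = {n: sorted(obj.predecessors(n), key=str) for n in obj.nodes
                if obj.in_degree(n) > 0}
    with open(path, "w") as fh:
        for out, inputs in rows.items():
            fh.write("\t".join(str(t) for t in [out, *inputs]) + "\n")


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarize_response(ratio: float, threshold: float = 3.32) -> int | None:
    """Binary expression call from a log10 ratio, or None if undetermined.

    A change of at least ``threshold``-fold (inclusive) in either direction
    is called 1 (up) or 0 (down); smaller changes are undetermined and are
    excluded from agreement counts.
    """
    if not math.isfinite(ratio):
        raise ValueError(f"non-finite ratio {ratio!r}")
    if threshold <= 1:
        raise ValueError("threshold must exceed 1 (fold change)")
    if abs(ratio) >= math.log10(threshold) - 1e-12:
        return 1 if ratio > 0 else 0
    return None
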
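"""Bipartite reaction networks and Block Decomposition Method complexity.

The community reaction network is bipartite: compound nodes (substrates and
products) and reaction nodes carrying their percent energy yield, with
directed substrate->reaction and reaction->product edges.

Network complexity C is estimated with the Block Decomposition Method (BDM):
the adjacency matrix — canonical node ordering: compounds then reactions,
each lexicographic by id — is partitioned into ``block_size`` x ``block_size``
blocks (zero-padded at the edges), and

    C = sum over unique block patterns ( kappa(block) + log2(multiplicity) )

where kappa is a pluggable per-block algorithmic-complexity lookup.  The
default kappa is a Shannon block-entropy surrogate,

    kappa(u) = block_size**2 * H(bit frequency of u) + 1,

which preserves the BDM aggregation structure without external lookup tables;
a Coding-Theorem-Method (CTM) table can be loaded from TSV instead.

Each reaction node's contribution to the network's complexity is
DeltaC(v) = C(G) - C(G with v and its incident edges removed); the node is
restored after each measurement, so DeltaC values are independent of
evaluation order.  Positive DeltaC means removing the reaction lowers
complexity (the reaction contributes structure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import pandas as pd

from ._tsv import read_tsv, write_tsv
from .geochem import CatabolicReaction, EnergyLandscape

KappaFn = Callable[[np.ndarray], float]


class DataError(ValueError):
    pass


class ParameterError(ValueError):
    pass


@dataclass
class ComplexityReport:
    total_complexity: float
    table: pd.DataFrame  # reaction, percent_yield, delta_c
    block_size: int
    kappa_mode: str


def build_reaction_network(reactions: Iterable[CatabolicReaction],
                           landscape: EnergyLandscape) -> nx.DiGraph:
    """Bipartite substrate/reaction network with percent-yield attributes.

    Compound nodes are deduplicated across reactions; each reaction node
    carries its percent energy yield from the landscape (water and protons are
    part of the stoichiometry and appear as compounds like any other species).
    """
    graph = nx.DiGraph()
    for rxn in reactions:
        substrates = [s for s, nu in rxn.stoichiometry.items() if nu < 0]
        products = [s for s, nu in rxn.stoichiometry.items() if nu > 0]
        if not substrates:
            raise DataError(f"{rxn.id}: empty substrate set")
        yield_pct = float(landscape.table.loc[
            landscape.table["reaction"] == rxn.id, "percent_yield"].iloc[0])
        graph.add_node(rxn.id, kind="reaction", percent_yield=yield_pct)
        for s in substrates:
            graph.add_node(s, kind="compound")
            graph.add_edge(s, rxn.id)
        for s in products:
            graph.add_node(s, kind="compound")
            graph.add_edge(rxn.id, s)
    return graph


def canonical_adjacency(network: nx.DiGraph) -> np.ndarray:
    """Binary adjacency matrix in the canonical ordering (compounds then
    reactions, each lexicographic by id)."""
    compounds = sorted(n for n, d in network.nodes(data=True)
                       if d.get("kind") != "reaction")
    reactions = sorted(n for n, d in network.nodes(data=True)
                       if d.get("kind") == "reaction")
    order = compounds + reactions
    return nx.to_numpy_array(network, nodelist=order, dtype=float) > 0


def kappa_entropy(block: np.ndarray) -> float:
    """Shannon block-entropy surrogate for per-block algorithmic complexity."""
    s = block.size
    p = float(block.sum()) / s
    if p in (0.0, 1.0):
        h = 0.0
    else:
        h = -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
    return s * h + 1.0


def load_ctm_kappa(path) -> KappaFn:
    """Load a CTM lookup table (TSV columns: pattern, k) as a kappa function.

    ``pattern`` is the block flattened row-major into a 0/1 string.
    """
    df = read_tsv(path, dtype={"pattern": str})
    lookup = dict(zip(df["pattern"], df["k"].astype(float)))

    def kappa(block: np.ndarray) -> float:
        key = "".join("1" if v else "0" for v in block.ravel())
        try:
            return lookup[key]
        except KeyError:
            raise DataError(f"CTM table lacks pattern {key}") from None

    return kappa


def bdm_matrix(matrix: np.ndarray, block_size: int = 4,
               kappa: KappaFn = kappa_entropy) -> float:
    """BDM complexity of a binary matrix (zero-padded to full blocks)."""
    if block_size not in (2, 3, 4):
        raise ParameterError("block_size must be 2, 3, or 4")
    m = np.asarray(matrix, dtype=bool)
    if m.size == 0:
        return 0.0
    n_rows = -(-m.shape[0] // block_size) * block_size
    n_cols = -(-m.shape[1] // block_size) * block_size
    padded = np.zeros((n_rows, n_cols), dtype=bool)
    padded[:m.shape[0], :m.shape[1]] = m
    counts: dict[bytes, tuple[int, float]] = {}
    for i in range(0, n_rows, block_size):
        for j in range(0, n_cols, block_size):
            block = padded[i:i + block_size, j:j + block_size]
            key = np.packbits(block).tobytes()
            if key in counts:
                n, k = counts[key]
                counts[key] = (n + 1, k)
            else:
                counts[key] = (1, kappa(block))
    return float(sum(k + math.log2(n) for n, k in counts.values()))


def bdm_complexity(network: nx.DiGraph, block_size: int = 4,
                   kappa: KappaFn = kappa_entropy) -> float:
    """BDM complexity of a reaction network's canonical adjacency matrix."""
    if network.number_of_nodes() == 0:
        return 0.0
    return bdm_matrix(canonical_adjacency(network), block_size, kappa)


def node_delta_complexity(network: nx.DiGraph, block_size: int = 4,
                          kappa: KappaFn = kappa_entropy,
                          kappa_mode: str = "entropy") -> ComplexityReport:
    """DeltaC(v) = C(G) - C(G minus v) for every reaction node.

    Each reaction node (with its incident edges) is removed, the complexity of
    the reduced network recomputed from scratch, and the node restored, so
    results do not depend on evaluation order.
    """
    reactions = sorted(n for n, d in network.nodes(data=True)
                       if d.get("kind") == "reaction")
    if not reactions:
        raise DataError("network has no reaction nodes")
    c_full = bdm_complexity(network, block_size, kappa)
    rows = []
    for v in reactions:
        reduced = network.copy()
        reduced.remove_node(v)
        delta = c_full - bdm_complexity(reduced, block_size, kappa)
        rows.append({"reaction": v,
                     "percent_yield": network.nodes[v].get("percent_yield", np.nan),
                     "delta_c": delta})
    return ComplexityReport(total_complexity=c_full,
                            table=pd.DataFrame(rows),
                            block_size=block_size, kappa_mode=kappa_mode)


# ---------------------------------------------------------------------------
# serialization


def write_network(network: nx.DiGraph, path) -> None:
    rows = [{"source": u, "target": v} for u, v in network.edges()]
    write_tsv(pd.DataFrame(rows, columns=["source", "target"]), path)


def write_network_graphml(network: nx.DiGraph, path) -> None:
    nx.write_graphml(network, str(path))


def write_report(report: ComplexityReport, path) -> None:
    df = report.table.copy()
    df.insert(0, "block_size", report.block_size)
    df.insert(0, "total_complexity", report.total_complexity)
    write_tsv(df, path)
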
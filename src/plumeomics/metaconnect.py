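"""Metabolic connectivity: MW-scores and functional co-occurrence networks.

The MW-score (metabolic weight score) measures how much a metabolic or
biogeochemical cycling step contributes to community-level metabolism: steps
that are encoded by more genomes *and* carried by more abundant, more deeply
covered genomes score higher.  Given a MAG x function table with incidence
g_m(F), per-(MAG, function) gene coverage a_m(F), and MAG relative abundance
A_m, the default scoring is

    w(F)  = sum_m A_m * g_m(F) * a_m(F)          (abundance weight)
    s(F)  = #MAGs encoding F / #MAGs             (sharedness)
    MW(F) = 100 * s(F) w(F) / sum_G s(G) w(G)    (percent, sums to 100)

The scoring function is pluggable so an alternative community-metabolism
scorer can be swapped in without touching the network code.

The functional network has one node per function (node size = total gene
coverage of the function) and an undirected edge between two functions
whenever at least one genome encodes both (genome co-occurrence reading of
connectivity; a shared-compound variant is available via ``edge_mode``), with
edge weight equal to the mean of the two node sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._tsv import read_tsv, write_tsv


class ParameterError(ValueError):
    pass


@dataclass
class FunctionTable:
    """MAG x function incidence/coverage with MAG relative abundances.

    Invariants: coverage > 0 implies incidence; sum of abundances <= 1.
    """

    incidence: pd.DataFrame   # bool, mags x functions
    coverage: pd.DataFrame    # float >= 0, same shape
    mag_abundance: pd.Series  # indexed by mag

    def __post_init__(self) -> None:
        if not self.incidence.index.equals(self.coverage.index) \
                or not self.incidence.columns.equals(self.coverage.columns):
            raise ParameterError("incidence and coverage must share axes")
        if ((self.coverage > 0) & ~self.incidence.astype(bool)).any().any():
            raise ParameterError("coverage > 0 at a (MAG, function) not encoded")
        if (self.coverage < 0).any().any():
            raise ParameterError("negative coverage")
        if self.mag_abundance.sum() > 1 + 1e-9:
            raise ParameterError("MAG abundances sum to more than 1")

    @property
    def mags(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def functions(self) -> list[str]:
        return list(self.incidence.columns)

    def node_size(self, function: str) -> float:
        return float(self.coverage[function].sum())


def default_mw_weight(table: FunctionTable) -> pd.Series:
    """Abundance weight w(F) = sum_m A_m g_m(F) a_m(F)."""
    weighted = table.coverage.mul(table.incidence.astype(float)) \
        .mul(table.mag_abundance, axis=0)
    return weighted.sum(axis=0)


def compute_mw_scores(table: FunctionTable,
                      weight_fn: Callable[[FunctionTable], pd.Series] = default_mw_weight,
                      ) -> pd.DataFrame:
    """MW-score per function (percent; sums to 100 when any function is present)."""
    if table.incidence.empty:
        raise ParameterError("empty function table")
    sharedness = table.incidence.astype(float).mean(axis=0)
    weight = weight_fn(table)
    raw = sharedness * weight
    total = raw.sum()
    scores = 100.0 * raw / total if total > 0 else raw * 0.0
    return pd.DataFrame({
        "function": table.functions,
        "sharedness": sharedness.values,
        "weight": weight.values,
        "mw_score": scores.values,
    })


def build_functional_network(table: FunctionTable,
                             selected_functions: Sequence[str] | None = None,
                             edge_mode: str = "cooccurrence",
                             function_compounds: Mapping[str, Iterable[str]] | None = None,
                             ) -> nx.Graph:
    """Functional network over the selected functions.

    ``edge_mode="cooccurrence"`` (default) connects two functions co-encoded
    in at least one MAG; ``edge_mode="shared_compound"`` connects functions
    whose compound sets (``function_compounds``) intersect.  Node attribute
    ``size`` is the function's total gene coverage; edge ``weight`` is the
    mean of the two node sizes.
    """
    functions = list(selected_functions) if selected_functions is not None \
        else table.functions
    unknown = set(functions) - set(table.functions)
    if unknown:
        raise ParameterError(f"unknown functions: {sorted(unknown)}")
    if edge_mode not in ("cooccurrence", "shared_compound"):
        raise ParameterError("edge_mode must be 'cooccurrence' or 'shared_compound'")
    if edge_mode == "shared_compound" and function_compounds is None:
        raise ParameterError("shared_compound mode needs function_compounds")
    graph = nx.Graph()
    for f in functions:
        graph.add_node(f, size=table.node_size(f))
    for i, f in enumerate(functions):
        for g in functions[i + 1:]:
            if edge_mode == "cooccurrence":
                connected = bool((table.incidence[f] & table.incidence[g]).any())
            else:
                connected = bool(set(function_compounds[f])
                                 & set(function_compounds[g]))
            if connected:
                weight = (graph.nodes[f]["size"] + graph.nodes[g]["size"]) / 2.0
                graph.add_edge(f, g, weight=weight)
    return graph


# ---------------------------------------------------------------------------
# serialization


def write_function_table(table: FunctionTable, path) -> None:
    rows = []
    for mag in table.mags:
        for func in table.functions:
            rows.append({"mag": mag, "function": func,
                         "present": int(table.incidence.loc[mag, func]),
                         "coverage": table.coverage.loc[mag, func],
                         "mag_abundance": table.mag_abundance[mag]})
    write_tsv(pd.DataFrame(rows), path)


def read_function_table(path) -> FunctionTable:
    df = read_tsv(path)
    incidence = df.pivot(index="mag", columns="function", values="present") \
        .astype(bool)
    coverage = df.pivot(index="mag", columns="function", values="coverage") \
        .astype(float)
    abundance = df.drop_duplicates("mag").set_index("mag")["mag_abundance"]
    return FunctionTable(incidence=incidence, coverage=coverage,
                         mag_abundance=abundance.astype(float))


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [{"source": u, "target": v, "weight": d.get("weight", 1.0)}
            for u, v, d in graph.edges(data=True)]
    write_tsv(pd.DataFrame(rows, columns=["source", "target", "weight"]), path)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))
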
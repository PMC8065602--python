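"""Risk-gene-anchored TOM subnetworks and hub identification.

Starting from a module's TOM, the subnetwork keeps the module's risk
genes plus every gene connected to at least one risk gene with TOM at or
above the cutoff (0.1 by default); edges are all intra-node pairs meeting
the same cutoff.  Hubs are genes that are simultaneously high-degree
within the subnetwork and strongly correlated with the module eigengene
(high kME).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .coexnet import KmeTable, TOMatrix
from .riskgenes import RiskGeneSet

__all__ = ["SubNetwork", "HubReport", "extract_subnetwork", "rank_hubs",
           "annotate_nodes"]


@dataclass
class SubNetwork:
    nodes: pd.DataFrame   # index gene; columns: degree, is_risk, + flags
    edges: pd.DataFrame   # columns: gene_i, gene_j, tom  (i < j, unique)
    cutoff: float
    module: str = ""

    def __post_init__(self) -> None:
        if len(self.edges):
            swapped = self.edges["gene_i"] >= self.edges["gene_j"]
            if swapped.any():
                raise ValueError("edges must satisfy gene_i < gene_j")
            if self.edges.duplicated(["gene_i", "gene_j"]).any():
                raise ValueError("duplicate edges")
        counts = pd.concat([self.edges["gene_i"], self.edges["gene_j"]]) \
            .value_counts() if len(self.edges) else pd.Series(dtype=int)
        recomputed = counts.reindex(self.nodes.index, fill_value=0)
        if not (recomputed == self.nodes["degree"]).all():
            raise ValueError("stored degrees inconsistent with the edge list")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for gene, row in self.nodes.iterrows():
            g.add_node(gene, **{k: _graphml_safe(v) for k, v in row.items()})
        for e in self.edges.itertuples():
            g.add_edge(e.gene_i, e.gene_j, tom=float(e.tom))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def _graphml_safe(v):
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, np.integer):
        return int(v)
    if isinstance(v, np.floating):
        return float(v)
    return v


@dataclass
class HubReport:
    table: pd.DataFrame   # index gene; degree, kme, is_hub, is_risk + flags
    degree_threshold: float
    kme_min: float

    def hubs(self) -> list[str]:
        return list(self.table.index[self.table["is_hub"]])


def extract_subnetwork(tom: TOMatrix, module_genes, riskset: RiskGeneSet,
                       cutoff: float = 0.1, module: str = "") -> SubNetwork:
    """Genes connected to at least one risk gene at TOM >= cutoff.

    Anchoring is strictly risk-gene based: a gene joins only through a
    risk-gene connection, never transitively through another non-risk
    node.  Edges are then all pairs among the kept nodes with TOM >=
    cutoff.
    """
    module_genes = list(dict.fromkeys(module_genes))
    gidx = {g: i for i, g in enumerate(tom.genes)}
    risk = [g for g in riskset.genes if g in set(module_genes) and g in gidx]
    if not risk:
        warnings.warn(f"no {riskset.disorder} risk gene inside the module; "
                      "empty subnetwork", stacklevel=2)
        nodes = pd.DataFrame(columns=["degree", "is_risk"])
        edges = pd.DataFrame(columns=["gene_i", "gene_j", "tom"])
        return SubNetwork(nodes, edges, cutoff, module)

    pool = [g for g in module_genes if g in gidx]
    risk_rows = np.array([gidx[g] for g in risk])
    pool_rows = np.array([gidx[g] for g in pool])
    sub = tom.values[np.ix_(pool_rows, risk_rows)].copy()
    for i, g in enumerate(pool):  # self-similarity must not anchor a risk gene
        for j, r in enumerate(risk):
            if g == r:
                sub[i, j] = 0.0
    keep_mask = sub.max(axis=1) >= cutoff
    node_list = sorted(set(risk) | {g for g, k in zip(pool, keep_mask) if k})

    rows = np.array([gidx[g] for g in node_list])
    block = tom.values[np.ix_(rows, rows)]
    edges = []
    for i in range(len(node_list)):
        for j in range(i + 1, len(node_list)):
            if block[i, j] >= cutoff:
                edges.append((node_list[i], node_list[j], float(block[i, j])))
    edges_df = pd.DataFrame(edges, columns=["gene_i", "gene_j", "tom"])
    degree = pd.concat([edges_df["gene_i"], edges_df["gene_j"]]).value_counts() \
        if len(edges_df) else pd.Series(dtype=int)
    nodes_df = pd.DataFrame({
        "degree": degree.reindex(node_list, fill_value=0).astype(int),
        "is_risk": [g in set(risk) for g in node_list],
    }, index=pd.Index(node_list, name="gene"))
    return SubNetwork(nodes_df, edges_df, cutoff, module)


def rank_hubs(net: SubNetwork, kme: KmeTable, module: str | None = None,
              degree_quantile: float = 0.9, kme_min: float = 0.8) -> HubReport:
    """Hubs = genes above the degree quantile AND at/above the kME floor.

    Ranked by degree, kME breaking ties.  The report keeps every node with
    its annotations so near-hub genes (high kME but moderate degree, risk
    or DEG flags) remain visible.
    """
    if net.n_nodes == 0:
        raise ValueError("empty subnetwork")
    module = module or net.module
    if module not in kme.values.columns:
        raise ValueError(f"kME table has no module column {module!r}")
    tab = net.nodes.copy()
    tab["kme"] = kme.values[module].reindex(tab.index).fillna(0.0)
    thr = float(np.quantile(tab["degree"], degree_quantile))
    tab["is_hub"] = (tab["degree"] >= thr) & (tab["kme"] >= kme_min)
    tab = tab.sort_values(["degree", "kme"], ascending=False, kind="stable")
    return HubReport(table=tab, degree_threshold=thr, kme_min=kme_min)


def annotate_nodes(net: SubNetwork, annotations: dict[str, list[str]]
                   ) -> SubNetwork:
    """Add boolean membership flags (DEG lists, gene sets) to the nodes."""
    nodes = net.nodes.copy()
    for name, genes in annotations.items():
        members = set(genes)
        nodes[name] = [g in members for g in nodes.index]
    return SubNetwork(nodes, net.edges.copy(), net.cutoff, net.module)
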
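"""Directed TF -> gene regulatory network assembly and inverted-edge PageRank.

Source nodes are TFs whose binding motifs are enriched in the ranked peak
list (FDR < 0.05) and whose own gene passes the RNA detection filter.
An edge TF -> gene exists when some peak assigned to the gene carries a
retained footprint with the TF's motif, and the peak is differentially
accessible or the gene differentially expressed. Node importance is
PageRank computed on the edge-inverted graph, so TFs that (directly or
indirectly) influence many genes score highly; per network, nodes above
the 99th percentile of all node values are the key TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class RegulatoryNetwork:
    """Directed TF -> gene graph with optional per-node PageRank."""

    graph: nx.DiGraph
    pagerank: dict[str, float] | None = None

    @property
    def sources(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "tf"}

    @property
    def targets(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene"}


def select_sources(
    enrichment: pd.DataFrame,
    expressed: Iterable[str],
    fdr_cutoff: float = 0.05,
    tf_gene: Mapping[str, str] | None = None,
) -> set[str]:
    """TFs enriched at FDR < cutoff whose own gene is detectably expressed.

    ``tf_gene`` maps TF identifiers to gene identifiers; by default the TF
    identifier is its gene.
    """
    expressed = set(expressed)
    out = set()
    for tf, row in enrichment.iterrows():
        gene = tf_gene.get(str(tf), str(tf)) if tf_gene else str(tf)
        if row["fdr"] < fdr_cutoff and gene in expressed:
            out.add(str(tf))
    return out


def select_targets(
    peak_gene: Mapping[str, str],
    dar_peaks: Iterable[str],
    deg_genes: Iterable[str],
    hits: pd.DataFrame,
    sources: Iterable[str],
) -> pd.DataFrame:
    """Edge list (source TF, target gene, evidence peaks).

    An edge exists iff (i) a peak assigned to the gene carries a motif hit
    of the source TF (hits must already be restricted to retained
    footprints) and (ii) that peak is a DAR or the gene is a DEG. Multiple
    supporting peaks collapse into one edge carrying the evidence list.
    Peaks without a gene assignment contribute nothing.
    """
    dar = set(dar_peaks)
    deg = set(deg_genes)
    src = set(sources)
    evidence: dict[tuple[str, str], set[str]] = {}
    for tf, peak in hits[["tf", "peak"]].itertuples(index=False):
        if tf not in src:
            continue
        gene = peak_gene.get(peak)
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            continue
        if peak in dar or gene in deg:
            evidence.setdefault((str(tf), str(gene)), set()).add(str(peak))
    rows = [
        (tf, gene, ",".join(sorted(peaks)))
        for (tf, gene), peaks in sorted(evidence.items())
    ]
    return pd.DataFrame(rows, columns=["source", "target", "evidence"])


def build_network(edges: pd.DataFrame) -> RegulatoryNetwork:
    """Assemble a RegulatoryNetwork from a (source, target, evidence) table."""
    g = nx.DiGraph()
    ordered = edges.sort_values(["source", "target"])
    for src in ordered["source"]:
        g.add_node(src, kind="tf")
    for row in ordered.itertuples(index=False):
        if not g.has_node(row.target):  # a TF can also be a target; tf label wins
            g.add_node(row.target, kind="gene")
        g.add_edge(row.source, row.target, evidence=getattr(row, "evidence", ""))
    return RegulatoryNetwork(graph=g)


def inverted_pagerank(
    network: RegulatoryNetwork | nx.DiGraph,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """PageRank on the edge-inverted graph (uniform teleport, dangling mass
    redistributed uniformly), by sparse power iteration to L1 tolerance.

    Inverting the edges only for this computation makes a TF's importance
    grow with the number of genes it regulates, directly or through other
    TFs. The original graph is left untouched. Values are strictly
    positive for damping < 1 and sum to 1.
    """
    graph = network.graph if isinstance(network, RegulatoryNetwork) else network
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    index = {node: i for i, node in enumerate(nodes)}
    # inverted edge v<-u becomes u->v in the walk matrix
    rows, cols = [], []
    for u, v in graph.edges:
        rows.append(index[u])  # walk goes v -> u on the inverted graph
        cols.append(index[v])
    out_deg = np.zeros(n)
    for c in cols:
        out_deg[c] += 1
    data = [1.0 / out_deg[c] for c in cols]
    walk = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    dangling = out_deg == 0

    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        mass = x[dangling].sum()
        y = damping * (walk @ x + mass / n) + (1.0 - damping) / n
        if np.abs(y - x).sum() < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError(f"PageRank did not converge in {max_iter} iterations")
    result = {node: float(x[i]) for node, i in index.items()}
    if isinstance(network, RegulatoryNetwork):
        network.pagerank = result
    return result


def key_tfs(
    network_a: RegulatoryNetwork,
    network_b: RegulatoryNetwork,
    percentile: float = 99.0,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Select and compare high-PageRank nodes across two networks.

    Per network, nodes with PageRank strictly above the given percentile
    (linear interpolation) of that network's node values are selected. The
    table reports every selected node's value in both networks, with 0 for
    nodes absent from a network, and flags nodes specific to one network
    (nonzero in one, 0 in the other).
    """
    la, lb = labels

    def _pr(network: RegulatoryNetwork) -> dict[str, float]:
        if network.pagerank is not None:
            return network.pagerank
        if network.graph.number_of_nodes() == 0:
            return {}
        return inverted_pagerank(network)

    pr_a, pr_b = _pr(network_a), _pr(network_b)

    def _selected(pr: dict[str, float]) -> set[str]:
        if not pr:
            return set()
        cut = np.percentile(list(pr.values()), percentile)
        return {node for node, v in pr.items() if v > cut}

    sel_a, sel_b = _selected(pr_a), _selected(pr_b)
    rows = []
    for node in sorted(sel_a | sel_b):
        va = pr_a.get(node, 0.0)
        vb = pr_b.get(node, 0.0)
        selected_in = (
            "both" if node in sel_a and node in sel_b else (la if node in sel_a else lb)
        )
        specific = la if vb == 0 else (lb if va == 0 else "")
        rows.append((node, va, vb, selected_in, specific))
    return pd.DataFrame(
        rows,
        columns=["node", f"pagerank_{la}", f"pagerank_{lb}", "selected_in", "specific_to"],
    ).set_index("node")


def co_target_counts(network: RegulatoryNetwork) -> pd.DataFrame:
    """TF x TF matrix of shared target counts (simple cobinding summary)."""
    tfs = sorted(network.sources)
    targets = {tf: set(network.graph.successors(tf)) for tf in tfs}
    mat = [[len(targets[a] & targets[b]) for b in tfs] for a in tfs]
    return pd.DataFrame(mat, index=tfs, columns=tfs)


def write_graphml(network: RegulatoryNetwork, path) -> None:
    g = network.graph.copy()
    if network.pagerank:
        nx.set_node_attributes(g, network.pagerank, "pagerank")
    nx.write_graphml(g, path)
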
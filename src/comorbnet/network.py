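"""Thresholded comorbidity network construction and Gephi-ready export.

Nodes are comorbid diseases whose cohort prevalence exceeds a minimum
(default 1%, strict); edges join pairs whose relative risk exceeds a
threshold (default 1.0, strict) with both endpoints retained.  Edge weight
is the raw co-occurrence count C_AB; the relative risk rides along as an
edge annotation.  The index disease is never a node.  Diseases that pass
the prevalence cut but have no significant partner remain as isolated
nodes: node and edge inclusion are independent criteria.
"""

from __future__ import annotations

import pandas as pd
import networkx as nx
from lxml import etree

from .stats import PrevalenceTable

GEXF_12_NS = "http://www.gexf.net/1.2draft"


def build_network(
    pair_stats: pd.DataFrame,
    prevalence: PrevalenceTable,
    min_prevalence: float = 0.01,
    rr_threshold: float = 1.0,
) -> nx.Graph:
    """Build the weighted undirected comorbidity network.

    Parameters
    ----------
    pair_stats
        Output of :func:`comorbnet.stats.relative_risk`.
    prevalence
        Marginal prevalence table from the same cohort.
    min_prevalence
        Node retention: prevalence strictly greater than this fraction.
    rr_threshold
        Edge retention: relative risk strictly greater than this ratio.
    """
    g = nx.Graph(
        min_prevalence=float(min_prevalence),
        rr_threshold=float(rr_threshold),
        cohort_n=int(prevalence.cohort_n),
    )
    n = prevalence.cohort_n
    for row in prevalence.table.itertuples(index=False):
        if n and row.count / n > min_prevalence:
            g.add_node(
                row.disease,
                label=row.disease,
                prevalence=float(row.count / n),
                carrier_count=int(row.count),
            )
    for row in pair_stats.itertuples(index=False):
        if (
            row.disease_a in g
            and row.disease_b in g
            and row.rr > rr_threshold
        ):
            g.add_edge(
                row.disease_a,
                row.disease_b,
                weight=int(row.co_count),
                rr=float(row.rr),
            )
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    return g


def total_edge_weight(g: nx.Graph) -> float:
    """m = sum of edge weights (each undirected edge counted once)."""
    return float(sum(d.get("weight", 1.0) for _, _, d in g.edges(data=True)))


def degree_table(g: nx.Graph) -> pd.DataFrame:
    """Per-node unweighted and weighted degree, ranked descending.

    Weighted degree is the sum of incident co-occurrence counts; hubs
    (high-degree diseases) sort first, ties broken by code.
    """
    rows = [
        {
            "disease": node,
            "degree": g.degree(node),
            "weighted_degree": float(g.degree(node, weight="weight")) if g.degree(node) else 0.0,
            "prevalence": g.nodes[node].get("prevalence", float("nan")),
        }
        for node in g.nodes
    ]
    df = pd.DataFrame(rows, columns=["disease", "degree", "weighted_degree", "prevalence"])
    return df.sort_values(
        ["degree", "weighted_degree", "disease"], ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)


def _with_viz(g: nx.Graph) -> nx.Graph:
    """Attach Gephi viz hints: node size ~ prevalence, grey level ~ degree."""
    h = g.copy()
    max_deg = max((d for _, d in h.degree()), default=1) or 1
    for node in h.nodes:
        prev = h.nodes[node].get("prevalence", 0.0)
        deg = h.degree(node)
        shade = int(40 + 180 * (1 - deg / max_deg))
        h.nodes[node]["viz"] = {
            "size": 10.0 + 90.0 * float(prev),
            "color": {"r": shade, "g": shade, "b": max(shade, 120)},
        }
    return h


def export_network(g: nx.Graph, path, format: str = "gexf") -> None:
    """Write the network as GEXF 1.2draft, GraphML, or a delimited edge list.

    All three formats round-trip through :func:`import_network` with node
    and edge attributes preserved.
    """
    if format == "gexf":
        nx.write_gexf(_with_viz(g), path, version="1.2draft")
    elif format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edgelist":
        rows = [
            {
                "disease_a": min(a, b),
                "disease_b": max(a, b),
                "weight": d.get("weight", 1),
                "rr": d.get("rr", float("nan")),
            }
            for a, b, d in g.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["disease_a", "disease_b", "weight", "rr"])
        df = df.sort_values(["disease_a", "disease_b"], kind="stable")
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format {format!r}; use gexf|graphml|edgelist")


def import_network(path, format: str = "gexf") -> nx.Graph:
    """Read a network previously written by :func:`export_network`."""
    if format == "gexf":
        g = nx.read_gexf(path)
    elif format == "graphml":
        g = nx.read_graphml(path)
    elif format == "edgelist":
        df = pd.read_csv(path)
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.disease_a, row.disease_b, weight=int(row.weight), rr=float(row.rr))
    else:
        raise ValueError(f"unknown import format {format!r}; use gexf|graphml|edgelist")
    out = nx.Graph(**{k: v for k, v in g.graph.items() if k in
                      ("min_prevalence", "rr_threshold", "cohort_n")})
    for node, data in g.nodes(data=True):
        keep = {k: data[k] for k in ("label", "prevalence", "carrier_count", "degree")
                if k in data}
        if "carrier_count" in keep:
            keep["carrier_count"] = int(keep["carrier_count"])
        if "degree" in keep:
            keep["degree"] = int(keep["degree"])
        out.add_node(node, **keep)
    for a, b, data in g.edges(data=True):
        out.add_edge(a, b, weight=int(data.get("weight", 1)), rr=float(data.get("rr", 1.0)))
    return out


def validate_gexf(path) -> None:
    """Structural validation of a GEXF 1.2 file.

    Checks the document namespace and version, the graph mode/default edge
    type, that every edge references a declared node, and that every
    attvalue references a declared attribute.  Raises ``ValueError`` on the
    first violation.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != f"{{{GEXF_12_NS}}}gexf":
        raise ValueError(f"root element {root.tag!r} is not a GEXF 1.2draft <gexf>")
    if root.get("version") != "1.2":
        raise ValueError(f"gexf version {root.get('version')!r} != '1.2'")
    ns = {"g": GEXF_12_NS}
    graphs = root.findall("g:graph", ns)
    if len(graphs) != 1:
        raise ValueError("expected exactly one <graph> element")
    graph = graphs[0]
    if graph.get("defaultedgetype", "undirected") != "undirected":
        raise ValueError("comorbidity networks must be undirected")
    declared_attrs = {
        a.get("id") for a in graph.findall("g:attributes/g:attribute", ns)
    }
    node_ids = set()
    for node in graph.findall("g:nodes/g:node", ns):
        nid = node.get("id")
        if nid is None:
            raise ValueError("node without id")
        if nid in node_ids:
            raise ValueError(f"duplicate node id {nid!r}")
        node_ids.add(nid)
        for av in node.findall("g:attvalues/g:attvalue", ns):
            if av.get("for") not in declared_attrs:
                raise ValueError(f"attvalue references undeclared attribute {av.get('for')!r}")
    for edge in graph.findall("g:edges/g:edge", ns):
        src, tgt = edge.get("source"), edge.get("target")
        if src not in node_ids or tgt not in node_ids:
            raise ValueError(f"edge {src!r}->{tgt!r} references an undeclared node")
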
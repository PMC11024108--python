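"""Cross-link protein-protein network: construction, filtering, ranking
and first-tier coverage.

Nodes are protein accessions; an edge joins two proteins connected by at
least one inter-protein cross-link and carries the number of unique
residue pairs between them as its weight.  Intra-protein links never
become edges.  Filtering drops isolated proteins and small disconnected
clusters, leaving the well-connected interactome on which localization
inference operates.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .errors import ConfigError, InputError
from .io import CrossLink

logger = logging.getLogger("clasp")

#: The cross-link network is a plain networkx graph with ``weight`` edge
#: attributes and optional ``is_lm`` / ``compartment`` node attributes.
XLNetwork = nx.Graph


def build_network(crosslinks: Iterable[CrossLink]) -> XLNetwork:
    """One node per protein, one edge per protein pair with >= 1
    inter-protein unique residue pair; weight = number of such pairs."""
    g = nx.Graph()
    for xl in crosslinks:
        g.add_node(xl.protein_a)
        g.add_node(xl.protein_b)
        if xl.is_intra:
            continue
        if g.has_edge(xl.protein_a, xl.protein_b):
            g[xl.protein_a][xl.protein_b]["weight"] += 1
        else:
            g.add_edge(xl.protein_a, xl.protein_b, weight=1)
    return g


def filter_network(net: XLNetwork, min_component_size: int = 3) -> Tuple[XLNetwork, dict]:
    """Remove isolated nodes and connected components smaller than
    ``min_component_size`` proteins.

    Returns the filtered copy together with a report of what was removed.
    The operation is idempotent.
    """
    if min_component_size < 2:
        raise ConfigError("min_component_size must be at least 2")
    isolated = sorted(n for n, d in net.degree() if d == 0)
    g = net.copy()
    g.remove_nodes_from(isolated)
    removed_components: List[List[str]] = []
    for comp in nx.connected_components(g):
        if len(comp) < min_component_size:
            removed_components.append(sorted(comp))
    for comp in removed_components:
        g.remove_nodes_from(comp)
    report = {
        "min_component_size": min_component_size,
        "removed_isolated": isolated,
        "removed_components": sorted(removed_components),
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
    return g, report


def rank_connectivity(net: XLNetwork, top_n: int | None = None) -> List[str]:
    """Accessions in descending degree order; ties break on accession
    string order for reproducibility."""
    ranked = sorted(net.nodes(), key=lambda n: (-net.degree(n), n))
    if top_n is None:
        return ranked
    if top_n > len(ranked):
        logger.warning("top_n=%d exceeds node count %d; returning all", top_n, len(ranked))
        return ranked
    return ranked[:top_n]


def first_tier(net: XLNetwork, lms: Iterable[str]) -> Set[str]:
    """All non-marker proteins directly cross-linked to >= 1 marker."""
    lm_set = set(lms)
    missing = lm_set - set(net.nodes())
    if missing:
        logger.warning("%d marker(s) not present in the network: %s",
                       len(missing), ", ".join(sorted(missing)[:5]))
    tier: Set[str] = set()
    for lm in lm_set & set(net.nodes()):
        tier.update(net.neighbors(lm))
    return tier - lm_set


def coverage(net: XLNetwork, lms: Iterable[str]) -> float:
    """Percentage of network proteins that are markers or first-tier
    interactors of markers (the proteins amenable to localization
    inference)."""
    n = net.number_of_nodes()
    if n == 0:
        raise InputError("coverage is undefined on an empty network")
    lm_in = set(lms) & set(net.nodes())
    covered = lm_in | first_tier(net, lm_in)
    return 100.0 * len(covered) / n
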
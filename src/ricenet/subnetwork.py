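"""Guide-gene subnetwork extraction.

The vicinity of a guide set is every gene within a fixed number of steps
(graph distance, default 2) of any guide over the thresholded co-expression
edges, together with the *induced* edge set: connections among any two
reached genes are kept even when neither endpoint is adjacent to a guide,
matching how published subnetwork figures display interconnections among
non-guide nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .coexpression import CoexpressionNetwork
from .expression_io import GuideSet

logger = logging.getLogger("ricenet")


class SubnetworkError(ValueError):
    pass


@dataclass
class Subnetwork:
    """Induced subgraph around a guide set with per-node annotations."""

    graph: nx.Graph
    guide_ids: tuple[str, ...]      # guides present in the parent network
    missing_guides: tuple[str, ...]  # requested guides absent from it
    steps: int
    label: str = ""
    distances: dict[str, int] | None = None  # node -> distance to nearest guide

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def node_label(self, node: str) -> str:
        return "guide" if node in set(self.guide_ids) else "other"

    def node_table(self) -> pd.DataFrame:
        comp_of = {}
        for cid, (_, members) in enumerate(self._components(), start=1):
            for n in members:
                comp_of[n] = cid
        rows = [
            (n, self.node_label(n), comp_of[n],
             self.distances.get(n) if self.distances else None)
            for n in sorted(self.graph.nodes)
        ]
        return pd.DataFrame(
            rows, columns=["node", "label", "component", "distance_to_guide"]
        )

    def _components(self) -> list[tuple[int, list[str]]]:
        comps = [sorted(c) for c in nx.connected_components(self.graph)]
        comps.sort(key=lambda c: (-len(c), c))
        return [(len(c), c) for c in comps]

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{u}\tco\t{v}\n")

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for n in g.nodes:
            g.nodes[n]["label"] = self.node_label(n)
            if self.distances:
                g.nodes[n]["distance_to_guide"] = int(self.distances[n])
        nx.write_graphml(g, path)

    def write_node_attributes(self, path) -> None:
        self.node_table().to_csv(path, sep="\t", index=False)


def extract_subnetwork(
    network: CoexpressionNetwork,
    guides: GuideSet,
    steps: int = 2,
) -> Subnetwork:
    """All genes within graph distance <= ``steps`` of any guide, induced.

    Breadth-first search over the undirected thresholded edge set from every
    resolvable guide; guides absent from the network are reported (an error
    only if none resolves).
    """
    if steps < 0:
        raise SubnetworkError("steps must be >= 0")
    g = network.graph
    present, missing = guides.resolve(g.nodes)
    if not present:
        raise SubnetworkError(
            f"no guide present in the network; missing: {list(guides.guide_ids)}"
        )
    dist: dict[str, int] = {}
    for guide in present:
        for node, d in nx.single_source_shortest_path_length(
            g, guide, cutoff=steps
        ).items():
            if node not in dist or d < dist[node]:
                dist[node] = d
    sub = g.subgraph(dist).copy()
    out = Subnetwork(
        graph=sub,
        guide_ids=tuple(present),
        missing_guides=tuple(missing),
        steps=steps,
        label=guides.label,
        distances=dist,
    )
    n_comp = nx.number_connected_components(sub) if sub.number_of_nodes() else 0
    logger.info(
        "subnetwork %r: %d nodes, %d edges, %d component(s) within %d step(s) "
        "of %d guide(s)",
        guides.label, out.node_count, out.edge_count, n_comp, steps, len(present),
    )
    return out


def component_summary(sub: Subnetwork) -> list[tuple[int, int, list[str]]]:
    """Connected components sorted by size descending.

    Returns ``(component_id, node_count, guide_members)`` tuples; component
    ids are 1-based in size order (ties broken by member gene order).
    """
    guides = set(sub.guide_ids)
    out = []
    for cid, (size, members) in enumerate(sub._components(), start=1):
        out.append((cid, size, [g for g in members if g in guides]))
    return out
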
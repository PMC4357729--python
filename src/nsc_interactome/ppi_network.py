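"""Physical-interaction filtering and first-neighbor subnetwork extraction.

The interaction sources mix physical binding with regulatory links;
non-physical edge types (by default 'transcription regulation' and
'transport', matched case-insensitively) are discarded before network
analysis.  The subnetwork around a seed set (here: proteins enriched in
the NSC pull-downs) is the subgraph induced by the seeds present in the
graph plus every node adjacent to a seed — neighbor-neighbor edges are
kept.  Seeds absent from the edge list are reported, not silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .iotables import EdgeList, write_edges

DEFAULT_EXCLUDED_TYPES = frozenset({"transcription regulation", "transport"})


@dataclass
class InteractionGraph:
    """A typed PPI subnetwork around a seed set.

    ``edges`` are the retained typed edges (both endpoints inside
    seeds + neighbors); ``seeds`` are the seed proteins present in the
    input graph, ``neighbors`` the non-seed nodes adjacent to a seed,
    ``missing_seeds`` the requested seeds absent from the graph.
    """

    edges: EdgeList
    seeds: set[str]
    neighbors: set[str]
    missing_seeds: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return self.seeds | self.neighbors

    def node_roles(self) -> pd.DataFrame:
        rows = [{"node": n, "role": "seed"} for n in sorted(self.seeds)]
        rows += [{"node": n, "role": "neighbor"} for n in sorted(self.neighbors)]
        return pd.DataFrame(rows, columns=["node", "role"])

    def write(self, sif_path: str | Path, attrs_path: str | Path) -> None:
        """Write the subnetwork as SIF plus a node-role attribute TSV."""
        write_edges(self.edges, sif_path)
        self.node_roles().to_csv(attrs_path, sep="\t", index=False)


def filter_physical_edges(edges: EdgeList,
                          excluded_types: Iterable[str] = DEFAULT_EXCLUDED_TYPES,
                          ) -> EdgeList:
    """Drop edges whose interaction type is in ``excluded_types``.

    Matching is case-insensitive on the verbatim type label; unknown
    labels are treated as physical and kept.
    """
    excluded = {t.lower() for t in excluded_types}
    return EdgeList([e for e in edges.edges if e[1].lower() not in excluded])


def first_neighbor_subnetwork(edges: EdgeList, seeds: Iterable[str]) -> InteractionGraph:
    """Subgraph induced by the seeds present in the graph plus their first neighbors.

    ``edges`` should already be filtered to physical interaction types.
    Every neighbor is at graph distance exactly 1 from some seed; edges
    between two neighbors are retained.
    """
    seeds = set(seeds)
    g = nx.Graph()
    for a, _, b in edges.edges:
        g.add_edge(a, b)
    present = seeds & set(g.nodes)
    missing = seeds - present
    neighbors: set[str] = set()
    for s in present:
        neighbors.update(g.neighbors(s))
    neighbors -= seeds
    keep = present | neighbors
    sub = EdgeList([e for e in edges.edges if e[0] in keep and e[2] in keep])
    return InteractionGraph(edges=sub, seeds=present, neighbors=neighbors,
                            missing_seeds=missing)
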
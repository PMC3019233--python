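"""The broken-read contig graph and its (bi-)connected components.

A "broken read" is a single sequencing read that the assembler split
into placements in two or more contigs.  Contigs sharing broken reads
are biologically related: divergent alleles of one gene, recent gene
duplicates, or exons joined by alternative splicing.  Nodes are contigs;
an edge between two contigs is weighted by the number of distinct base
read names placed in both.

Connected components (CCs) group everything reachable through broken
reads.  Bi-connected components (BCCs) are the stronger signal: a BCC is
a subgraph that no single edge removal disconnects, so it needs at least
three contigs linked by *independent* sets of broken reads -- a topology
that chimeric reads are vanishingly unlikely to fake.

Two biconnectivity semantics are offered.  ``mode="edge"`` (the default)
takes the definition literally: maximal 2-edge-connected subgraphs,
computed by deleting bridges.  ``mode="vertex"`` gives classical
articulation-point blocks.  Parallel broken reads between one contig
pair collapse to a single weighted edge for connectivity purposes;
otherwise any two contigs sharing two reads would count as
"biconnected", defeating the three-node minimum.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .assembly_io import Assembly, DEFAULT_NAME_PATTERN, base_read_name

__all__ = [
    "BrokenReadGraph",
    "BiconnectedComponent",
    "ComponentSet",
    "build_graph",
    "connected_components",
    "biconnected_components",
    "write_edges_tsv",
    "write_components_tsv",
]


@dataclass
class BrokenReadGraph:
    """Contigs as nodes; unordered contig pairs -> the broken reads joining them."""

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def multiplicity(self, a: str, b: str) -> int:
        return len(self.edges.get(_key(a, b), ()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), names in self.edges.items():
            g.add_edge(a, b, multiplicity=len(names), read_names=names)
        return g


@dataclass
class BiconnectedComponent:
    nodes: set[str]
    edges: set[tuple[str, str]]
    total_broken_reads: int
    min_edge_multiplicity: int


@dataclass
class ComponentSet:
    connected: list[set[str]]
    biconnected: list[BiconnectedComponent]


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_graph(
    assembly: Assembly,
    pattern: str = DEFAULT_NAME_PATTERN,
    min_multiplicity: int = 1,
) -> BrokenReadGraph:
    """Build the broken-read graph from an assembly.

    Every base read name placed in k >= 2 distinct contigs contributes
    that name to each of the k*(k-1)/2 contig-pair edges.  Edges whose
    multiplicity falls below ``min_multiplicity`` are dropped; all
    contigs remain as (possibly isolated) nodes.
    """
    placed_in: dict[str, set[str]] = {}
    graph = BrokenReadGraph()
    for contig in assembly.contigs:
        graph.nodes.add(contig.contig_id)
        for p in contig.placements:
            name = base_read_name(p.read_id, pattern)
            placed_in.setdefault(name, set()).add(contig.contig_id)
    for name, contigs in placed_in.items():
        if len(contigs) < 2:
            continue
        ordered = sorted(contigs)
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                graph.edges.setdefault(_key(ordered[i], ordered[j]), set()).add(name)
    if min_multiplicity > 1:
        graph.edges = {
            k: v for k, v in graph.edges.items() if len(v) >= min_multiplicity
        }
    return graph


def connected_components(graph: BrokenReadGraph) -> list[set[str]]:
    """Connected components with at least one edge (>= 2 nodes).

    Isolated contigs are not reported: a component of one node carries
    no broken-read evidence.
    """
    g = graph.to_networkx()
    comps = [set(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: sorted(c)[0])
    return comps


def biconnected_components(graph: BrokenReadGraph, mode: str = "edge") -> ComponentSet:
    """Extract bi-connected components of the broken-read graph.

    mode="edge": maximal 2-edge-connected subgraphs (no single edge
    removal disconnects them), obtained by removing bridges.
    mode="vertex": classical biconnected blocks (no articulation point).
    Only components with >= 3 nodes are reported.
    """
    if mode not in ("edge", "vertex"):
        raise ValueError(f"mode must be 'edge' or 'vertex', got {mode!r}")
    g = graph.to_networkx()
    node_sets: list[set[str]]
    if mode == "edge":
        h = g.copy()
        h.remove_edges_from(list(nx.bridges(g)))
        node_sets = [set(c) for c in nx.connected_components(h) if len(c) >= 3]
    else:
        node_sets = [set(c) for c in nx.biconnected_components(g) if len(c) >= 3]
    bccs = []
    for nodes in sorted(node_sets, key=lambda c: sorted(c)[0]):
        if mode == "edge":
            edges = {_key(a, b) for a, b in g.subgraph(nodes).edges()}
        else:
            # a vertex-block may share articulation nodes with others; keep
            # only edges internal to this block's node set
            edges = {_key(a, b) for a, b in g.subgraph(nodes).edges()}
        mults = [len(graph.edges[e]) for e in edges]
        bccs.append(
            BiconnectedComponent(
                nodes=nodes,
                edges=edges,
                total_broken_reads=sum(mults),
                min_edge_multiplicity=min(mults),
            )
        )
    return ComponentSet(connected=connected_components(graph), biconnected=bccs)


def write_edges_tsv(graph: BrokenReadGraph, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["contig_a", "contig_b", "multiplicity", "read_names"])
        for (a, b), names in sorted(graph.edges.items()):
            w.writerow([a, b, len(names), ",".join(sorted(names))])


def write_components_tsv(components: ComponentSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["kind", "component_id", "n_nodes", "members",
                    "total_broken_reads", "min_edge_multiplicity"])
        for i, cc in enumerate(components.connected):
            w.writerow(["CC", f"cc{i}", len(cc), ",".join(sorted(cc)), "", ""])
        for i, bcc in enumerate(components.biconnected):
            w.writerow(["BCC", f"bcc{i}", len(bcc.nodes), ",".join(sorted(bcc.nodes)),
                        bcc.total_broken_reads, bcc.min_edge_multiplicity])
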
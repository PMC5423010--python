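"""Integration of the sponge, PPI and lncRNA-target layers and enumeration of
the two 4-node sponge-co-regulation-of-PPI motif types.

Motif semantics
---------------
A "link" from a sponge node s to a protein p depends on the sponge's kind:
for an lncRNA sponge it is an lnc_target edge; for an mRNA sponge the sponge
node *is* its protein, so links are its own ppi edges. This keeps both motif
types at exactly 4 nodes for mixed sponge kinds.

Type A: sponge(s1, s2); link(s1, p1); link(s2, p2); ppi(p1, p2) — the two
sponges each touch a different party of one PPI.

Type B: sponge(s1, s2); link(s1, p); link(s2, p); ppi(p, q) — the sponges
share one protein which itself has a PPI partner q; each distinct q yields a
distinct match.

All four nodes are pairwise distinct in both types. A match is reported once
per unordered realization: sponge pairs are canonicalized s1 < s2 (in type A
p1 is the protein linked to s1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .datamodel import EdgeList, GeneList, TypedNetwork, canonical_edge

logger = logging.getLogger("mirscoppi")


class TypeConflictError(ValueError):
    """A symbol's layer memberships imply contradictory node kinds."""


@dataclass(frozen=True)
class MotifMatch:
    """One 4-node motif instance.

    ``proteins`` is (p1, p2) for type A and (p, q) for type B. ``edges`` are
    the four realizing typed edges; ``kinds`` records each node's kind so
    matches can be merged back into a typed network.
    """

    motif_type: str  # "A" or "B"
    sponge_pair: tuple[str, str]
    proteins: tuple[str, str]
    edges: tuple[tuple[str, str, str], ...]
    kinds: tuple[tuple[str, str], ...]

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.sponge_pair) | frozenset(self.proteins)


def integrate_networks(
    sponge: EdgeList,
    ppi: EdgeList,
    lnc_target: EdgeList,
    lncrna_ids: GeneList,
) -> TypedNetwork:
    """Merge the three layers into one typed graph.

    Identical symbols across layers map to the same node (an mRNA sponge and
    its protein are one node). Kinds: lncRNA if declared in ``lncrna_ids``;
    otherwise mRNA_protein for sponge endpoints and protein for the rest.
    """
    lnc = lncrna_ids.symbols
    conflict = sorted(lnc & ppi.nodes())
    if conflict:
        raise TypeConflictError(
            f"symbols declared lncRNA but present as PPI endpoints: {conflict}"
        )
    sponge_nodes = sponge.nodes()

    def kind_of(node: str) -> str:
        if node in lnc:
            return "lncRNA"
        if node in sponge_nodes:
            return "mRNA_protein"
        return "protein"

    net = TypedNetwork()
    for edge_list, etype in ((sponge, "sponge"), (ppi, "ppi"),
                             (lnc_target, "lnc_target")):
        for a, b in edge_list.edges:
            net.add_edge(a, b, etype, kind_of(a), kind_of(b))
    for a, b in lnc_target.edges:
        if a not in lnc and b not in lnc:
            raise TypeConflictError(
                f"lnc_target edge ({a}, {b}) has no lncRNA endpoint"
            )
    logger.info("integrated network: %d nodes, %s", net.n_nodes,
                net.edge_type_counts())
    return net


def _adjacency(net: TypedNetwork, edge_type: str) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b, t in net.edges:
        if t == edge_type:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    return adj


def enumerate_motifs(net: TypedNetwork) -> list[MotifMatch]:
    """Every distinct type-A and type-B match, in deterministic sorted order."""
    sponge_adj = _adjacency(net, "sponge")
    ppi_adj = _adjacency(net, "ppi")
    lnc_adj = _adjacency(net, "lnc_target")

    def links(s: str) -> set[str]:
        if net.kind(s) == "lncRNA":
            return lnc_adj.get(s, set())
        return ppi_adj.get(s, set())

    def link_edge(s: str, p: str) -> tuple[str, str, str]:
        etype = "lnc_target" if net.kind(s) == "lncRNA" else "ppi"
        a, b = canonical_edge(s, p)
        return (a, b, etype)

    matches: list[MotifMatch] = []
    sponge_edges = sorted((a, b) for a, b, t in net.edges if t == "sponge")
    for s1, s2 in sponge_edges:  # s1 < s2 canonical
        l1 = links(s1) - {s1, s2}
        l2 = links(s2) - {s1, s2}
        sponge_edge = (s1, s2, "sponge")
        # type A: distinct parties of one PPI
        for p1 in l1:
            for p2 in ppi_adj.get(p1, set()) & l2:
                if p2 == p1 or p2 in (s1, s2) or p1 in (s1, s2):
                    continue
                nodes = (s1, s2, p1, p2)
                matches.append(MotifMatch(
                    "A", (s1, s2), (p1, p2),
                    edges=(sponge_edge, link_edge(s1, p1), link_edge(s2, p2),
                           canonical_edge(p1, p2) + ("ppi",)),
                    kinds=tuple((n, net.kind(n)) for n in nodes),
                ))
        # type B: shared protein with a PPI partner q
        for p in l1 & l2:
            for q in ppi_adj.get(p, set()):
                if q in (s1, s2, p):
                    continue
                nodes = (s1, s2, p, q)
                matches.append(MotifMatch(
                    "B", (s1, s2), (p, q),
                    edges=(sponge_edge, link_edge(s1, p), link_edge(s2, p),
                           canonical_edge(p, q) + ("ppi",)),
                    kinds=tuple((n, net.kind(n)) for n in nodes),
                ))
    matches.sort(key=lambda m: (m.motif_type, m.sponge_pair, m.proteins))
    logger.info("motif search: %d type-A, %d type-B match(es)",
                sum(m.motif_type == "A" for m in matches),
                sum(m.motif_type == "B" for m in matches))
    return matches


def build_coreg_network(matches: list[MotifMatch]) -> TypedNetwork:
    """Union of all nodes and typed edges across matches (the merged network)."""
    net = TypedNetwork()
    for m in matches:
        for node, kind in m.kinds:
            net.add_node(node, kind)
        for a, b, t in m.edges:
            net.edges.add((a, b, t))
    counts = net.edge_type_counts()
    logger.info("co-regulation network: %d nodes; %s", net.n_nodes,
                ", ".join(f"{t}={n}" for t, n in sorted(counts.items())) or "empty")
    return net
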
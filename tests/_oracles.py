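"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: exact combinatorial
enumeration for the hypergeometric tail, brute-force 4-node-subset scanning
for motif matching, and a random typed-network generator with kind-consistent
edge layers.
"""

from __future__ import annotations

import itertools
import random
from fractions import Fraction
from math import comb

from mirscoppi.datamodel import TypedNetwork, canonical_edge


def hypergeom_upper_tail_exact(M: int, N: int, K: int, x: int) -> float:
    """P(X >= x) by exact enumeration of the hypergeometric pmf."""
    total = Fraction(0)
    denom = comb(M, K)
    for i in range(x, min(N, K) + 1):
        if K - i <= M - N:
            total += Fraction(comb(N, i) * comb(M - N, K - i), denom)
    return float(total)


def brute_force_motifs(net: TypedNetwork) -> set[tuple]:
    """All motif matches by checking every 4-node subset against the patterns.

    Match identity mirrors the implementation's canonical form:
    ("A", (s1, s2), (p1, p2)) with s1 < s2 and p1 the protein linked to s1;
    ("B", (s1, s2), (p, q)) with s1 < s2.
    """
    sponge = net.edges_of_type("sponge")
    ppi = net.edges_of_type("ppi")
    lnc = net.edges_of_type("lnc_target")

    def has(edges: set, a: str, b: str) -> bool:
        return canonical_edge(a, b) in edges

    def link(s: str, p: str) -> bool:
        if net.kind(s) == "lncRNA":
            return has(lnc, s, p)
        return has(ppi, s, p)

    found: set[tuple] = set()
    nodes = sorted(net.nodes)
    for quad in itertools.combinations(nodes, 4):
        for s1, s2 in itertools.combinations(quad, 2):  # s1 < s2 by construction
            if not has(sponge, s1, s2):
                continue
            u, v = [n for n in quad if n not in (s1, s2)]
            for p1, p2 in ((u, v), (v, u)):
                if link(s1, p1) and link(s2, p2) and has(ppi, p1, p2):
                    found.add(("A", (s1, s2), (p1, p2)))
            for p, q in ((u, v), (v, u)):
                if link(s1, p) and link(s2, p) and has(ppi, p, q):
                    found.add(("B", (s1, s2), (p, q)))
    return found


def random_typed_network(rng: random.Random, n_nodes: int) -> TypedNetwork:
    """A random kind-consistent typed network (for motif-oracle comparisons)."""
    net = TypedNetwork()
    names = [f"n{i:02d}" for i in range(n_nodes)]
    kinds = {}
    for name in names:
        kinds[name] = rng.choice(["lncRNA", "mRNA_protein", "protein"])
        net.add_node(name, kinds[name])
    sponge_ok = [n for n in names if kinds[n] != "protein"]
    ppi_ok = [n for n in names if kinds[n] != "lncRNA"]
    lncs = [n for n in names if kinds[n] == "lncRNA"]

    def add_some(candidates_a, candidates_b, etype, n_edges):
        for _ in range(n_edges):
            if not candidates_a or not candidates_b:
                return
            a = rng.choice(candidates_a)
            b = rng.choice(candidates_b)
            if a != b:
                net.add_edge(a, b, etype)

    add_some(sponge_ok, sponge_ok, "sponge", max(2, n_nodes // 2))
    add_some(ppi_ok, ppi_ok, "ppi", max(3, n_nodes))
    add_some(lncs, ppi_ok, "lnc_target", max(2, n_nodes // 2))
    return net
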
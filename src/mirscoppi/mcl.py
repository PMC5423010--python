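"""Markov clustering (MCL) of the co-regulation network and module extraction.

Native dense-matrix MCL: start from the unweighted adjacency matrix with unit
self-loops, column-normalize, then alternate expansion (matrix power) and
inflation (elementwise power followed by re-normalization), pruning tiny
entries, until the matrix stops changing. Clusters are read off as
attractor-connected components; nodes attracted by several systems go to the
lowest-index attractor. The procedure is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import TypedNetwork

logger = logging.getLogger("mirscoppi")


@dataclass
class ModulePartition:
    """Modules numbered 1..n in decreasing size order (ties by member names)."""

    modules: list[set[str]]
    module_ids: list[int]

    def __len__(self) -> int:
        return len(self.modules)

    def items(self):
        return zip(self.module_ids, self.modules)


def mcl_cluster(
    net: TypedNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    prune_threshold: float = 1e-5,
    tol: float = 1e-6,
) -> list[set[str]]:
    """Cluster the network (edge types ignored, weight 1) with MCL.

    Returns disjoint node sets covering every node.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    if net.n_nodes == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, _ in net.edges:
        m[index[a], index[b]] = 1.0
        m[index[b], index[a]] = 1.0
    np.fill_diagonal(m, 1.0)  # self-loops
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        last = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        m[m < prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        dead = colsum[0] == 0.0
        if dead.any():  # fully pruned column: park the node on itself
            m[np.where(dead)[0], dead] = 1.0
            colsum = m.sum(axis=0, keepdims=True)
        m /= colsum
        if np.max(np.abs(m - last)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; "
                       "clusters taken from the final state", max_iter)

    # attractors: nodes with positive return probability (nonzero diagonal)
    attractors = [i for i in range(n) if m[i, i] > 0.0]
    members = {i: set(np.nonzero(m[i])[0]) for i in attractors}
    # merge attractor systems with overlapping support (union-find)
    parent = {i: i for i in attractors}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in attractors:
        for j in attractors:
            if j <= i:
                continue
            if members[i] & members[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, set[int]] = {}
    for i in attractors:
        clusters.setdefault(find(i), set()).update(members[i])
    assigned: dict[int, int] = {}
    for root in sorted(clusters):
        for node in clusters[root]:
            if node not in assigned:  # lowest-index attractor system wins
                assigned[node] = root
    result: dict[int, set[str]] = {}
    for node, root in assigned.items():
        result.setdefault(root, set()).add(nodes[node])
    for i in range(n):  # never-attracted nodes become singletons
        if i not in assigned:
            result[n + i] = {nodes[i]}
    out = [result[k] for k in sorted(result)]
    logger.info("MCL: %d cluster(s) from %d node(s)", len(out), n)
    return out


def extract_modules(clusters: list[set[str]], min_size: int) -> ModulePartition:
    """Drop clusters below ``min_size`` and number survivors by size."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    seen: set[str] = set()
    for c in clusters:
        if seen & c:
            raise ValueError("clusters are not disjoint")
        seen |= c
    kept = [c for c in clusters if len(c) >= min_size]
    dropped = len(clusters) - len(kept)
    if dropped:
        logger.info("dropped %d cluster(s) below the minimum module size %d",
                    dropped, min_size)
    kept.sort(key=lambda c: (-len(c), sorted(c)))
    return ModulePartition(kept, list(range(1, len(kept) + 1)))


def write_modules(partition: ModulePartition, path) -> None:
    """Two-column TSV: module_id, member."""
    with open(path, "w") as fh:
        fh.write("module_id\tmember\n")
        for mid, members in partition.items():
            for member in sorted(members):
                fh.write(f"{mid}\t{member}\n")


def read_modules(path) -> ModulePartition:
    modules: dict[int, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("module_id\t"):
            raise ValueError(f"{path}: missing module_id/member header")
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            mid, member = line.split("\t")[:2]
            modules.setdefault(int(mid), set()).add(member)
    ids = sorted(modules)
    return ModulePartition([modules[i] for i in ids], ids)
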
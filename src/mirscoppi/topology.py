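"""Topology analytics: degree distribution, characteristic path length,
log-log power-law fits, per-sponge-edge motif statistics and hub selection.

Edges are treated as undirected and untyped throughout; power-law goodness of
fit is the R-squared of an ordinary least-squares line on the log10 frequency
spectrum (the convention behind reporting a single R^2 for a scale-free
claim), not a maximum-likelihood exponent fit.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .datamodel import TypedNetwork, canonical_edge
from .motifs import MotifMatch
from .sponge import SpongeCandidate, pearson_with_pvalue

logger = logging.getLogger("mirscoppi")


class InsufficientDataError(ValueError):
    pass


@dataclass
class DistributionFit:
    xs: list[int]
    freqs: list[int]
    slope: float
    intercept: float
    r_squared: float


@dataclass
class EdgeStatistics:
    """Per-sponge-edge motif and shared-miRNA counts plus their correlation.

    ``corr`` is None (flagged) when either count vector is constant.
    """

    edges: list[tuple[str, str]]
    motif_counts: list[int]
    shared_mirna_counts: list[int]
    corr: float | None
    corr_defined: bool


def degree_distribution(net: TypedNetwork) -> dict[int, int]:
    """Mapping degree -> number of nodes; frequencies sum to the node count."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return dict(Counter(net.degree().values()))


def characteristic_path_length(net: TypedNetwork) -> float:
    """Mean shortest-path length over unordered reachable node pairs.

    Unreachable pairs are excluded (their count is logged), so the value is
    finite on multi-component graphs.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    g = net.to_networkx()
    total = 0
    reachable = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                reachable += 1
    reachable //= 2
    total //= 2
    n = net.n_nodes
    unreachable = n * (n - 1) // 2 - reachable
    if unreachable:
        logger.info("characteristic path length: %d unreachable pair(s) excluded",
                    unreachable)
    if reachable == 0:
        raise ValueError("no reachable node pair; path length undefined")
    return total / reachable


def power_law_r2(distribution: dict[int, int]) -> DistributionFit:
    """OLS fit of log10(frequency) on log10(value).

    Zero frequencies are skipped; a value <= 0 is a domain error; fewer than
    3 usable points is an insufficient-data error. A flat (constant-frequency)
    spectrum returns slope 0 with R^2 = 0.
    """
    points = sorted((v, f) for v, f in distribution.items() if f > 0)
    if any(v <= 0 for v, _ in points):
        raise ValueError("power-law fit requires strictly positive values")
    if len(points) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct values with positive frequency, got {len(points)}"
        )
    xs = [v for v, _ in points]
    freqs = [f for _, f in points]
    lx = np.log10(xs)
    ly = np.log10(freqs)
    if np.ptp(ly) == 0.0:
        return DistributionFit(xs, freqs, 0.0, float(ly[0]), 0.0)
    res = stats.linregress(lx, ly)
    return DistributionFit(xs, freqs, float(res.slope), float(res.intercept),
                           float(res.rvalue) ** 2)


def edge_statistics(
    coreg: TypedNetwork,
    matches: list[MotifMatch],
    candidates: list[SpongeCandidate],
) -> EdgeStatistics:
    """Motif count and shared-miRNA count per sponge edge, with their Pearson r."""
    by_pair = {c.pair: c for c in candidates}
    motif_count = Counter(m.sponge_pair for m in matches)
    edges = sorted(coreg.edges_of_type("sponge"))
    motifs: list[int] = []
    shared: list[int] = []
    for a, b in edges:
        pair = canonical_edge(a, b)
        if pair not in by_pair:
            raise ValueError(f"sponge edge {pair} has no candidate record")
        motifs.append(motif_count.get(pair, 0))
        shared.append(by_pair[pair].stat.x)
    corr: float | None = None
    defined = (len(edges) >= 3
               and len(set(motifs)) > 1 and len(set(shared)) > 1)
    if defined:
        corr, _ = pearson_with_pvalue(np.array(motifs, float),
                                      np.array(shared, float))
    else:
        logger.info("motif/shared-miRNA correlation undefined "
                    "(constant counts or < 3 sponge edges)")
    return EdgeStatistics(edges, motifs, shared, corr, defined)


def select_hubs(net: TypedNetwork, fraction: float) -> list[str]:
    """Top ceil(fraction * n) nodes by degree (ties broken lexicographically)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if net.n_nodes == 0:
        raise ValueError("empty network")
    deg = net.degree()
    ordered = sorted(deg, key=lambda n: (-deg[n], n))
    k = math.ceil(fraction * net.n_nodes)
    return ordered[:k]
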
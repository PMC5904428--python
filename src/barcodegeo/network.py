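"""Statistical-parsimony (TCS-style) haplotype networks.

Observed haplotypes are connected by chains of unit-mutation edges, with
anonymous median nodes standing in for unsampled intermediates, up to a
parsimony connection limit J: the largest number of mutational steps for
which the connection is non-homoplasious with probability >= alpha
(default 0.95).

The connection-probability model used for J treats substitutions at each
site as Poisson with a common per-site mean over the path joining the pair,
under Jukes-Cantor state symmetry.  Given j observed differences out of L
sites, the per-site mean lambda is the JC-inverted divergence
lambda = -(3/4) ln(1 - 4j/(3L)), and

  P(parsimony) = P(single hit | site differs)^j
                 * P(no hidden change | site identical)^(L-j)

with P(single|diff) = lambda e^-lambda / ((3/4)(1 - e^(-4 lambda/3))) and
P(none|same) = e^-lambda / (1/4 + (3/4) e^(-4 lambda/3)).  J is the largest
j with P >= alpha; it grows with L at fixed alpha and without bound as
alpha -> 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .haplotypes import HaplotypeTable

__all__ = [
    "ParsimonyLimit",
    "pairwise_steps",
    "parsimony_probability",
    "parsimony_limit",
    "build_tcs_network",
    "export_network",
    "read_network",
]


def pairwise_steps(table: HaplotypeTable) -> np.ndarray:
    """Hamming distances between haplotype representatives (retained sites)."""
    seqs = [s for _, s, _ in table.haplotypes]
    mat = np.array([list(s) for s in seqs], dtype="U1")
    n = len(seqs)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        out[i, i + 1 :] = (mat[i + 1 :] != mat[i]).sum(axis=1)
    return out + out.T


def parsimony_probability(j: int, L: int) -> float:
    """Probability that j observed differences over L sites are parsimonious."""
    if j < 0 or L < 1:
        raise ValueError("need j >= 0 and L >= 1")
    if j == 0:
        return 1.0
    x = 1.0 - 4.0 * j / (3.0 * L)
    if x <= 0.0:  # beyond JC saturation: multiple hits effectively certain
        return 0.0
    lam = -0.75 * math.log(x)
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * lam / 3.0))
    p_single_given_diff = lam * math.exp(-lam) / p_diff
    p_same = 1.0 - p_diff
    p_none_given_same = math.exp(-lam) / p_same
    return p_single_given_diff**j * p_none_given_same ** (L - j)


@dataclass(frozen=True)
class ParsimonyLimit:
    J: int
    alpha: float
    L: int


def parsimony_limit(L: int, alpha: float = 0.95) -> ParsimonyLimit:
    """Largest step count J with connection probability >= alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if L < 1:
        raise ValueError("L must be >= 1")
    j = 0
    while j + 1 <= math.floor(3 * L / 4) and parsimony_probability(j + 1, L) >= alpha:
        j += 1
    return ParsimonyLimit(J=max(j, 1), alpha=alpha, L=L)


def build_tcs_network(
    table: HaplotypeTable,
    limit: ParsimonyLimit | int,
    region_counts: pd.DataFrame | None = None,
) -> nx.Graph:
    """Agglomerative statistical-parsimony network.

    Haplotype pairs are processed in order of increasing step count (ties
    broken by lexicographic ID pair).  A pair within the limit is connected
    through a fresh chain of step-1 median nodes when the two haplotypes are
    in different components, or when the direct chain is strictly shorter
    than the current graph distance between them (this retains genuine
    alternative-path loops while never duplicating an existing
    minimum-length path).  Pairs beyond the limit stay unconnected, so the
    result may have several components.

    Nodes carry ``kind`` ('haplotype'/'median'), ``abundance`` (0 for
    medians) and optional per-region counts.
    """
    J = limit.J if isinstance(limit, ParsimonyLimit) else int(limit)
    g = nx.Graph()
    for hap, _, members in table.haplotypes:
        attrs = {"kind": "haplotype", "abundance": len(members)}
        if region_counts is not None and hap in region_counts.index:
            attrs["regions"] = dict(region_counts.loc[hap].astype(int))
        g.add_node(hap, **attrs)
    steps = pairwise_steps(table)
    ids = table.ids
    pairs = sorted(
        (
            (int(steps[i, j]), ids[i], ids[j])
            for i, j in itertools.combinations(range(len(ids)), 2)
        ),
        key=lambda t: (t[0], t[1], t[2]),
    )
    median_counter = 0
    for d, a, b in pairs:
        if d == 0 or d > J:
            continue
        try:
            current = nx.shortest_path_length(g, a, b)
        except nx.NetworkXNoPath:
            current = None
        if current is not None and current <= d:
            continue
        chain = [a]
        for _ in range(d - 1):
            median_counter += 1
            m = f"m{median_counter}"
            g.add_node(m, kind="median", abundance=0)
            chain.append(m)
        chain.append(b)
        for u, v in zip(chain, chain[1:]):
            g.add_edge(u, v, steps=1)
    return g


def export_network(net: nx.Graph, edge_path: str | Path, graphml_path: str | Path | None = None) -> None:
    """Write a TSV edge list (and optionally GraphML) for the network."""
    rows = [
        {"source": u, "target": v}
        for u, v in sorted(net.edges())
    ]
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if graphml_path is not None:
        g = net.copy()
        for _, attrs in g.nodes(data=True):
            if isinstance(attrs.get("regions"), dict):
                attrs["regions"] = ",".join(
                    f"{k}:{v}" for k, v in sorted(attrs["regions"].items())
                )
        nx.write_graphml(g, str(graphml_path))


def read_network(graphml_path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(graphml_path))
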
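"""Signed, thresholded trait-correlation network.

Edges follow the hard-limit adjacency H(r_ij) = 1/2*(sgn(|r_ij| - rho) + 1):
1 above the limit, 0 below, and literally 1/2 on the boundary, which is
recorded as a "boundary" edge and treated as connected.  Display tiers flag
edges whose |r| reaches each cut-off (conventionally 0.3 and 0.7); positive
and negative correlations carry a sign attribute for green/red rendering
downstream.  Node positions come from a Fruchterman-Reingold force layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ValidityError

log = logging.getLogger(__name__)


def adjacency(R: pd.DataFrame, rho: float = 0.0) -> pd.DataFrame:
    """Hard-limit adjacency: 1 if |r| > rho, 0 if |r| < rho, 1/2 at |r| = rho."""
    if rho < 0:
        raise ValidityError("rho must be non-negative")
    A = 0.5 * (np.sign(np.abs(np.asarray(R, dtype=float)) - rho) + 1.0)
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=R.index, columns=R.columns)


@dataclass(frozen=True)
class CorrelationGraph:
    graph: nx.Graph
    rho: float
    display_cutoffs: tuple[float, ...]

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self, cutoff: float | None = None) -> list[tuple[str, str, dict]]:
        out = []
        for u, v, attrs in self.graph.edges(data=True):
            if cutoff is None or attrs["displayed"].get(cutoff, False):
                out.append((u, v, attrs))
        return out


def build_graph(
    R: pd.DataFrame,
    rho: float = 0.0,
    display_cutoffs: tuple[float, ...] = (0.3, 0.7),
) -> CorrelationGraph:
    """Correlation graph with sign, weight and display-tier attributes."""
    for c in display_cutoffs:
        if not 0 <= c <= 1:
            raise ValidityError("display cutoffs must lie in [0, 1]")
    A = adjacency(R, rho)
    G = nx.Graph()
    G.add_nodes_from(str(c) for c in R.columns)
    cols = list(R.columns)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            h = A.iloc[i, j]
            r = float(R.iloc[i, j])
            if h == 0 or r == 0:   # exactly-zero correlations carry no edge
                continue
            G.add_edge(
                str(a), str(b),
                r=r,
                weight=abs(r),
                sign="positive" if r >= 0 else "negative",
                boundary=bool(h == 0.5),
                displayed={c: bool(abs(r) >= c) for c in display_cutoffs},
            )
    log.info("correlation graph: %d nodes, %d edges (rho=%.2f)",
             G.number_of_nodes(), G.number_of_edges(), rho)
    return CorrelationGraph(G, rho, tuple(display_cutoffs))


# --------------------------------------------------------------------------
# Fruchterman-Reingold layout
#
# Hand-rolled so the cooling schedule and the force terms (repulsion k^2/d,
# attraction d^2/k weighted by |r|, linear cooling, k = sqrt(area/n)) are
# explicit and the potential-energy trajectory is observable in tests.

def fr_energy(positions: dict[str, np.ndarray], graph: nx.Graph, k: float) -> float:
    """Potential whose gradients are the FR forces (for diagnostics)."""
    nodes = list(positions)
    e = 0.0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            d = float(np.linalg.norm(positions[u] - positions[v])) or 1e-9
            e += k * k * np.log(1.0 / d)  # repulsive potential
            if graph.has_edge(u, v):
                w = graph[u][v].get("weight", 1.0)
                e += w * d ** 3 / (3.0 * k)  # attractive potential
    return e


def layout_fruchterman_reingold(
    cg: CorrelationGraph,
    iterations: int = 100,
    seed: int = 0,
    area: float = 1.0,
    return_trajectory: bool = False,
):
    """Deterministic force-directed node coordinates.

    Returns ``{node: (x, y)}``; with ``return_trajectory=True`` also the
    per-iteration potential energy (which should decrease or plateau).
    """
    if iterations < 1:
        raise ValidityError("iterations must be >= 1")
    G = cg.graph
    nodes = list(G.nodes)
    n = len(nodes)
    if n == 0:
        return ({}, []) if return_trajectory else {}
    rng = np.random.default_rng(seed)
    if n == 1:
        pos = {nodes[0]: np.zeros(2)}
        traj = [fr_energy(pos, G, 1.0)]
        out = {nodes[0]: (0.0, 0.0)}
        return (out, traj) if return_trajectory else out

    k = float(np.sqrt(area / n))
    side = float(np.sqrt(area))
    P = rng.uniform(-side / 2, side / 2, size=(n, 2))
    idx = {u: i for i, u in enumerate(nodes)}
    t0 = side / 10.0
    energies: list[float] = []
    for it in range(iterations):
        disp = np.zeros_like(P)
        for i in range(n):
            delta = P[i] - P
            dist = np.linalg.norm(delta, axis=1)
            dist[i] = np.inf
            dist = np.maximum(dist, 1e-9)
            disp[i] += ((delta.T / dist) * (k * k / dist)).T.sum(axis=0)
        for u, v, attrs in G.edges(data=True):
            i, j = idx[u], idx[v]
            delta = P[i] - P[j]
            dist = max(float(np.linalg.norm(delta)), 1e-9)
            f = attrs.get("weight", 1.0) * dist * dist / k
            step = delta / dist * f
            disp[i] -= step
            disp[j] += step
        t = t0 * (1.0 - it / iterations)  # linear cooling
        lengths = np.maximum(np.linalg.norm(disp, axis=1), 1e-9)
        P += (disp.T / lengths).T * np.minimum(lengths, t)[:, None]
        energies.append(fr_energy({u: P[idx[u]] for u in nodes}, G, k))
    out = {u: (float(P[idx[u], 0]), float(P[idx[u], 1])) for u in nodes}
    return (out, energies) if return_trajectory else out


# --------------------------------------------------------------------------
# Export

def export_graph(
    cg: CorrelationGraph,
    layout: dict[str, tuple[float, float]] | None = None,
    format: str = "graphml",
) -> str:
    """Serialize to GraphML or DOT with weight/sign/tier/coordinate attributes."""
    G = nx.Graph()
    G.add_nodes_from(cg.nodes)
    if layout:
        for u, (x, y) in layout.items():
            G.nodes[u]["x"] = float(x)
            G.nodes[u]["y"] = float(y)
    for u, v, attrs in cg.graph.edges(data=True):
        flat = {
            "r": attrs["r"],
            "weight": attrs["weight"],
            "sign": attrs["sign"],
            "boundary": attrs["boundary"],
        }
        for c, shown in attrs["displayed"].items():
            flat[f"displayed_{c}"] = shown
        G.add_edge(u, v, **flat)
    if format == "graphml":
        return "\n".join(nx.generate_graphml(G))
    if format == "dot":
        lines = ["graph correlation {"]
        for u, data in G.nodes(data=True):
            coord = f' [pos="{data["x"]:.4f},{data["y"]:.4f}"]' if "x" in data else ""
            lines.append(f'  "{u}"{coord};')
        for u, v, data in G.edges(data=True):
            color = "green" if data["sign"] == "positive" else "red"
            lines.append(
                f'  "{u}" -- "{v}" [weight={data["weight"]:.4f}, color={color}];'
            )
        lines.append("}")
        return "\n".join(lines)
    raise ValidityError(f"unknown format {format!r}")
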
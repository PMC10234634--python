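"""Kirchhoff flow solves on contracting vein networks.

Flows are driven by vein volume changes: a vein whose cross-section shrinks
expels fluid into the network through its two endpoints.  Node pressures
follow from conservation of fluid volume (Kirchhoff's current law on the
conductance-weighted graph Laplacian); they are defined up to an additive
constant and reported mean-zero per connected component.

Also provides the electrical-analogy reductions used by the adaptation model:
two-terminal effective resistance, relative resistance R/R_net, and the
Norton-equivalent flow through a single contracting vein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import UM, VeinNetwork, shear_from_flow

__all__ = [
    "FlowSolution",
    "NortonEquivalent",
    "solve_flows",
    "timeseries_fields",
    "effective_resistance",
    "graph_effective_resistance",
    "relative_resistance",
    "graph_relative_resistance",
    "norton_flow",
    "norton_equivalent",
]


@dataclass
class FlowSolution:
    """Per-snapshot Kirchhoff solution.

    pressures are gauge-fixed (mean zero per connected component), flows are
    signed with respect to each vein's stored orientation (node_a -> node_b
    positive), shear rates are τ = 4|Q|/(πa³).
    """

    time_s: float
    pressures: dict[str, float]          # node id -> Pa
    flows: dict[str, float]              # vein id -> m³/s
    shear: dict[str, float]              # vein id -> 1/s
    residual: float                      # max node conservation residual, m³/s

    def vein_pressure(self, network: VeinNetwork, vein_id: str) -> float:
        """Mean of the two endpoint node pressures, in Pa."""
        v = network.veins[vein_id]
        return 0.5 * (self.pressures[v.node_a] + self.pressures[v.node_b])


@dataclass
class NortonEquivalent:
    """One vein seen against the rest of the network as a two-resistor circuit."""

    vein_id: str
    resistance: float                    # R, Pa·s·m⁻³
    network_resistance: float | None     # R_net, Pa·s·m⁻³ (None if undefined)
    inflow: float                        # Q_in, m³/s


# ---------------------------------------------------------------------------
# Kirchhoff solver
# ---------------------------------------------------------------------------

def _solve_component(G: nx.MultiGraph, nodes: list[str],
                     source: Mapping[str, float],
                     open_nodes: set[str]) -> dict[str, float]:
    """Solve L P = s on one connected component; returns node pressures."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, k, data in G.edges(nodes, keys=True, data=True):
        if u not in idx or v not in idx:
            continue
        g = 1.0 / data["resistance"]
        i, j = idx[u], idx[v]
        rows += [i, j, i, j]
        cols += [i, j, j, i]
        vals += [g, g, -g, -g]
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    s = np.array([source.get(nd, 0.0) for nd in nodes])

    pinned = [idx[nd] for nd in nodes if nd in open_nodes]
    if not pinned:
        # closed component: absorb any net excess uniformly (the unmodelled
        # remainder of the organism), then pin one node and re-gauge
        s = s - s.sum() / n
        pinned = [0]
        dirichlet = False
    else:
        dirichlet = True

    L = L.tolil()
    for i in pinned:
        L.rows[i], L.data[i] = [i], [1.0]
        s[i] = 0.0
    if n == 1:
        P = np.zeros(1)
    else:
        P = spla.spsolve(L.tocsr(), s)
    if not dirichlet:
        P = P - P.mean()
    else:
        # gauge: open nodes sit at the external reference pressure (0)
        pass
    return {nd: float(P[idx[nd]]) for nd in nodes}


def solve_flows(network: VeinNetwork,
                radii_um: Mapping[str, float],
                dvdt_m3_s: Mapping[str, float] | None = None,
                open_nodes: Iterable[str] = (),
                node_sources_m3_s: Mapping[str, float] | None = None,
                time_s: float = 0.0) -> FlowSolution:
    """Solve one Kirchhoff snapshot.

    Parameters
    ----------
    radii_um : instantaneous radius per vein id (μm), used for resistances
        and shear rates.
    dvdt_m3_s : volume change rate L·d(πa²)/dt per vein id (m³/s).  A vein's
        rate is split half-and-half onto its endpoints as fluid sources
        (contraction, dV/dt < 0, expels fluid into the network).
    open_nodes : reservoir nodes held at the reference pressure; if a closed
        component's sources do not balance, the excess is absorbed uniformly.
    node_sources_m3_s : explicit node injections (m³/s) added on top of the
        lumped vein sources; used e.g. for the time-averaged pumping problem
        where a vein injects +Q_in / -Q_in at its endpoints.
    """
    for vid, a in radii_um.items():
        if a <= 0:
            raise ValueError(f"vein {vid}: radius must be positive")
    G = network.resistance_graph(radii_um)
    open_set = set(open_nodes)

    source: dict[str, float] = {n: 0.0 for n in network.nodes}
    if dvdt_m3_s is not None:
        for vid, v in network.veins.items():
            s = -float(dvdt_m3_s.get(vid, 0.0))   # contraction -> outflow
            source[v.node_a] += 0.5 * s
            source[v.node_b] += 0.5 * s
    if node_sources_m3_s is not None:
        for nid, s in node_sources_m3_s.items():
            source[nid] += float(s)

    pressures: dict[str, float] = {}
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        if len(nodes) == 1 and G.degree(nodes[0]) == 0:
            if abs(source.get(nodes[0], 0.0)) > 0:
                raise ValueError(
                    f"isolated node {nodes[0]!r} carries a nonzero source")
            pressures[nodes[0]] = 0.0
            continue
        pressures.update(_solve_component(G, nodes, source, open_set))

    flows: dict[str, float] = {}
    shear: dict[str, float] = {}
    for vid, v in network.veins.items():
        R = G.edges[v.node_a, v.node_b, vid]["resistance"]
        Q = (pressures[v.node_a] - pressures[v.node_b]) / R
        flows[vid] = Q
        shear[vid] = shear_from_flow(Q, radii_um[vid] * UM)

    # conservation residual (exclude open nodes, which exchange freely)
    residual = 0.0
    net_in = {n: 0.0 for n in network.nodes}
    for vid, v in network.veins.items():
        net_in[v.node_a] -= flows[vid]
        net_in[v.node_b] += flows[vid]
    # uniform absorption per closed component
    for comp in nx.connected_components(G):
        nodes = [n for n in comp]
        if open_set & set(nodes):
            continue
        excess = sum(source[n] for n in nodes) / len(nodes)
        for n in nodes:
            residual = max(residual, abs(net_in[n] + source[n] - excess))
    return FlowSolution(time_s=time_s, pressures=pressures, flows=flows,
                        shear=shear, residual=residual)


def _area_rate(times: np.ndarray, radii_um: np.ndarray) -> np.ndarray:
    """d(πa²)/dt in m²/s by central differences (one-sided at the ends)."""
    area = math.pi * (radii_um * UM) ** 2
    return np.gradient(area, times)


def timeseries_fields(network: VeinNetwork,
                      open_nodes: Iterable[str] = ()
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-snapshot Kirchhoff fields over the common radius-series grid.

    Returns ``(vein_df, node_df)``: long-format frames with columns
    ``vein_id, time_s, Q_m3_per_s, tau_per_s, P_Pa`` (vein pressure = mean of
    its endpoint pressures) and ``node_id, time_s, P_Pa``.
    """
    times = network.common_time_grid()
    rates = {vid: v.length_um * UM * _area_rate(times, v.radii.radii)
             for vid, v in network.veins.items()}
    radii = {vid: v.radii.radii for vid, v in network.veins.items()}

    vein_rows, node_rows = [], []
    for i, t in enumerate(times):
        sol = solve_flows(network,
                          {vid: radii[vid][i] for vid in radii},
                          {vid: rates[vid][i] for vid in rates},
                          open_nodes=open_nodes, time_s=float(t))
        for vid in network.veins:
            vein_rows.append((vid, float(t), sol.flows[vid], sol.shear[vid],
                              sol.vein_pressure(network, vid)))
        for nid, P in sol.pressures.items():
            node_rows.append((nid, float(t), P))
    vein_df = pd.DataFrame(
        vein_rows, columns=["vein_id", "time_s", "Q_m3_per_s", "tau_per_s",
                            "P_Pa"])
    node_df = pd.DataFrame(node_rows, columns=["node_id", "time_s", "P_Pa"])
    return vein_df, node_df


# ---------------------------------------------------------------------------
# effective / relative resistance and Norton reduction
# ---------------------------------------------------------------------------

def time_averaged_shear(network: VeinNetwork,
                        radii_um: Mapping[str, float] | None = None
                        ) -> dict[str, float]:
    """Time-averaged shear rate ⟨τ⟩ per vein from its own pumping, by full
    Kirchhoff solves.

    Each vein's contraction generates a net flow Q_in = 8πLε⟨a⟩²/T exchanged
    with the network; solving Kirchhoff's laws with +Q_in / -Q_in injected at
    the vein's endpoints (all resistors present, the vein's included) yields
    the flow through the vein.  By Norton's theorem this equals
    Q_in / (1 + R/R_net) for interior veins and Q_in for dangling ends and
    bridges (the only route), so one scheme covers every topology.
    """
    from .network import contraction_inflow

    if radii_um is None:
        radii_um = {vid: v.mean_radius_um() for vid, v in network.veins.items()}
    out: dict[str, float] = {}
    for vid, v in network.veins.items():
        Q_in = contraction_inflow(v.length_um, radii_um[vid], v.eps, v.period_s)
        if Q_in == 0.0:
            out[vid] = 0.0
            continue
        sol = solve_flows(network, radii_um,
                          node_sources_m3_s={v.node_a: Q_in, v.node_b: -Q_in})
        out[vid] = sol.shear[vid]
    return out


def graph_effective_resistance(G: nx.MultiGraph, u, v,
                               weight: str = "resistance") -> float | None:
    """Two-terminal effective resistance of a resistor multigraph.

    Returns None if u and v are not connected.  Solved by injecting a unit
    flow at u and withdrawing it at v (grounded Laplacian solve).
    """
    if u == v:
        return 0.0
    if u not in G or v not in G or not nx.has_path(G, u, v):
        return None
    comp = nx.node_connected_component(G, u)
    nodes = sorted(comp)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for a, b, k, data in G.edges(nodes, keys=True, data=True):
        g = 1.0 / data[weight]
        i, j = idx[a], idx[b]
        rows += [i, j, i, j]
        cols += [i, j, j, i]
        vals += [g, g, -g, -g]
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n)).tolil()
    s = np.zeros(n)
    s[idx[u]], s[idx[v]] = 1.0, -1.0
    ground = idx[v]
    L.rows[ground], L.data[ground] = [ground], [1.0]
    s[ground] = 0.0
    P = spla.spsolve(L.tocsr(), s)
    return float(P[idx[u]] - P[idx[v]])


def effective_resistance(network: VeinNetwork, node_pair: tuple[str, str],
                         radii_um: Mapping[str, float] | None = None
                         ) -> float | None:
    """Effective resistance between two nodes of the vein network (SI).

    Each vein contributes its Poiseuille resistance at its (supplied or
    time-averaged) radius.  None if the nodes are disconnected.
    """
    u, v = node_pair
    return graph_effective_resistance(network.resistance_graph(radii_um), u, v)


def graph_relative_resistance(G: nx.MultiGraph, key) -> float | None:
    """R/R_net for one edge of a resistor multigraph, None when undefined.

    R_net is the effective resistance between the edge's endpoints with the
    edge removed.  Undefined for dangling ends (an endpoint of degree 1) and
    bridges (removal disconnects the endpoints).
    """
    edge = None
    for u, v, k, data in G.edges(keys=True, data=True):
        if k == key:
            edge = (u, v, data)
            break
    if edge is None:
        raise KeyError(f"no edge with key {key!r}")
    u, v, data = edge
    if G.degree(u) == 1 or G.degree(v) == 1:
        return None
    H = G.copy()
    H.remove_edge(u, v, key)
    R_net = graph_effective_resistance(H, u, v)
    if R_net is None:
        return None
    return data["resistance"] / R_net


def relative_resistance(network: VeinNetwork, vein_id: str,
                        radii_um: Mapping[str, float] | None = None
                        ) -> float | None:
    """Relative resistance R/R_net of a vein; None for bridges/dangling ends."""
    if vein_id not in network.veins:
        raise KeyError(f"unknown vein {vein_id!r}")
    return graph_relative_resistance(network.resistance_graph(radii_um),
                                     vein_id)


def norton_flow(resistance: float, network_resistance: float,
                inflow: float) -> float:
    """Flow through a vein in its Norton-reduced circuit.

    The vein (resistance R, contraction source Q_in) sits in parallel with
    the rest of the network (R_net, source -Q_in); Kirchhoff's second law
    gives Q = Q_in / (1 + R/R_net).
    """
    if resistance <= 0 or network_resistance <= 0:
        raise ValueError("norton_flow requires positive resistances")
    return inflow / (1.0 + resistance / network_resistance)


def norton_equivalent(network: VeinNetwork, vein_id: str,
                      radii_um: Mapping[str, float] | None = None
                      ) -> NortonEquivalent:
    """Reduce the network, seen from one vein, to its Norton equivalent."""
    from .network import contraction_inflow

    v = network.veins[vein_id]
    a = radii_um[vein_id] if radii_um is not None else v.mean_radius_um()
    G = network.resistance_graph(radii_um)
    R = G.edges[v.node_a, v.node_b, vein_id]["resistance"]
    H = G.copy()
    H.remove_edge(v.node_a, v.node_b, vein_id)
    if G.degree(v.node_a) == 1 or G.degree(v.node_b) == 1:
        R_net = None
    else:
        R_net = graph_effective_resistance(H, v.node_a, v.node_b)
    Q_in = contraction_inflow(v.length_um, a, v.eps, v.period_s)
    return NortonEquivalent(vein_id=vein_id, resistance=R,
                            network_resistance=R_net, inflow=Q_in)
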
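"""Structural pruning cascades driven by relative resistance.

A vein whose resistance exceeds the effective resistance of the rest of the
network between its endpoints (R/R_net > 1) is energetically unfavourable:
rerouting its flow through the remaining network dissipates less.  Removing
it frees its endpoints; veins meeting in series at a freed degree-2 node
coalesce into one longer — hence higher-resistance — vein, which can push
*its* relative resistance above threshold.  Iterating removal + merging
produces the avalanches in which whole network regions vanish.

Operates on ``networkx.MultiGraph`` objects whose edges carry a
``resistance`` attribute (plus optional ``length_um``, ``radius_um``,
``eps``, ``period_s``, ``frozen``).  Use ``VeinNetwork.resistance_graph()``
to obtain one from a vein network; edges marked ``frozen=True`` (e.g. the
abstract rest-of-network resistor of the region fixture) are never removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import networkx as nx

from .hydraulics import graph_relative_resistance

__all__ = [
    "CascadeRecord",
    "RegionFixtureParams",
    "relative_resistance_map",
    "prune_step",
    "merge_series",
    "run_cascade",
    "region_fixture",
]


@dataclass
class CascadeRecord:
    """Ordered log of one pruning cascade.

    events : list of (step index, removed vein id, its R/R_net at removal).
    ratio_maps : per step (before each removal, plus a final map), every
        vein's R/R_net (None where undefined).
    final : the surviving network.
    """

    events: list[tuple[int, str, float]] = field(default_factory=list)
    ratio_maps: list[dict[str, float | None]] = field(default_factory=list)
    final: nx.MultiGraph | None = None


@dataclass
class RegionFixtureParams:
    """Parameters of the minimal avalanche region.

    r : resistance of each region vein (arbitrary units).
    rest_ratio : r / R_rest, region-vein resistance relative to the
        rest-of-network equivalent resistor (default 0.1).
    perturbation : factor applied to the perturbed vein's resistance
        (default 2, i.e. a slightly shrunken vein).
    """

    r: float = 1.0
    rest_ratio: float = 0.1
    perturbation: float = 2.0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.rest_ratio <= 0:
            raise ValueError("resistances must be positive")
        if self.perturbation <= 0:
            raise ValueError("perturbation factor must be positive")


def relative_resistance_map(G: nx.MultiGraph) -> dict[str, float | None]:
    """R/R_net for every edge (None for bridges and dangling ends)."""
    return {k: graph_relative_resistance(G, k)
            for _, _, k in G.edges(keys=True)}


def _prune_candidate(G: nx.MultiGraph) -> tuple[str, str, str, float] | None:
    """(key, u, v, ratio) of the vein prune_step would remove, or None."""
    best: tuple[float, str, str, str] | None = None
    for u, v, k, data in G.edges(keys=True, data=True):
        if data.get("frozen"):
            continue
        ratio = graph_relative_resistance(G, k)
        if ratio is None or ratio <= 1.0:
            continue
        if best is None or ratio > best[0] or \
                (ratio == best[0] and str(k) < str(best[1])):
            best = (ratio, k, u, v)
    if best is None:
        return None
    ratio, key, u, v = best
    return key, u, v, ratio


def prune_step(G: nx.MultiGraph) -> tuple[str | None, float | None]:
    """Remove the single most unstable vein, if any.

    Computes R/R_net for every non-bridge, non-dangling, non-frozen vein;
    if any ratio exceeds 1 the vein with the largest ratio (ties: smallest
    vein id) is removed in place and ``(vein_id, ratio)`` is returned,
    else ``(None, None)``.
    """
    cand = _prune_candidate(G)
    if cand is None:
        return None, None
    key, u, v, ratio = cand
    G.remove_edge(u, v, key)
    return key, ratio


def _merged_attrs(d1: dict, d2: dict) -> dict:
    """Series-merge two vein attribute dicts: R and L add; the effective
    radius follows from inverting R = 8μL/(πa⁴) (viscosity cancels);
    ε and T are length-weighted means."""
    R = d1["resistance"] + d2["resistance"]
    out = {"resistance": R}
    L1, L2 = d1.get("length_um"), d2.get("length_um")
    if L1 is not None and L2 is not None:
        L = L1 + L2
        out["length_um"] = L
        a1, a2 = d1.get("radius_um"), d2.get("radius_um")
        if a1 is not None and a2 is not None:
            out["radius_um"] = (L / (L1 / a1**4 + L2 / a2**4)) ** 0.25
        for key in ("eps", "period_s"):
            if key in d1 and key in d2:
                out[key] = (L1 * d1[key] + L2 * d2[key]) / L
    return out


def merge_series(G: nx.MultiGraph, node,
                 new_key: str | None = None) -> str | None:
    """Collapse the two veins meeting at a degree-2 node into one.

    No-op (returns None) unless ``node`` has degree exactly 2 with two
    distinct incident veins.  If both veins connect the same outer node the
    merge would create a self-loop; both veins are removed instead and
    ``"<removed>"`` is returned.  Otherwise the merged vein (summed length
    and resistance, back-computed radius) replaces the pair, the node is
    deleted, and the new vein id is returned.
    """
    if node not in G or G.degree(node) != 2:
        return None
    incident = list(G.edges(node, keys=True, data=True))
    if len(incident) != 2:
        return None  # a self-loop counts degree 2 with one edge
    (u1, v1, k1, d1), (u2, v2, k2, d2) = incident
    if d1.get("frozen") or d2.get("frozen"):
        return None  # abstract rest-of-network resistors never merge
    outer1 = v1 if u1 == node else u1
    outer2 = v2 if u2 == node else u2
    G.remove_edge(u1, v1, k1)
    G.remove_edge(u2, v2, k2)
    G.remove_node(node)
    if outer1 == outer2:
        return "<removed>"
    key = new_key if new_key is not None else f"{k1}+{k2}"
    G.add_edge(outer1, outer2, key=key, **_merged_attrs(d1, d2))
    return key


def merge_series_network(network, node, radii_um: dict, tau_s: dict,
                         pmap: dict) -> str | None:
    """Series-merge on a VeinNetwork plus simulation state (used by the
    network-coupled adaptation simulator).  Returns the merged vein id."""
    from .network import VeinSegment

    incident = [v for v in network.veins.values() if node in v.endpoints]
    if len(incident) != 2:
        return None
    v1, v2 = incident
    o1 = v1.node_b if v1.node_a == node else v1.node_a
    o2 = v2.node_b if v2.node_a == node else v2.node_a
    for v in (v1, v2):
        network.veins.pop(v.vein_id)
    network.nodes.pop(node, None)
    a1, a2 = radii_um.pop(v1.vein_id), radii_um.pop(v2.vein_id)
    ts1, ts2 = tau_s.pop(v1.vein_id), tau_s.pop(v2.vein_id)
    p1 = pmap.pop(v1.vein_id)
    p2 = pmap.pop(v2.vein_id)
    if o1 == o2:
        return None
    L = v1.length_um + v2.length_um
    a = (L / (v1.length_um / a1**4 + v2.length_um / a2**4)) ** 0.25
    key = f"{v1.vein_id}+{v2.vein_id}"
    seg = VeinSegment(
        vein_id=key, node_a=o1, node_b=o2, length_um=L,
        eps=(v1.length_um * v1.eps + v2.length_um * v2.eps) / L,
        period_s=(v1.length_um * v1.period_s + v2.length_um * v2.period_s) / L)
    network.veins[key] = seg
    radii_um[key] = a
    tau_s[key] = 0.5 * (ts1 + ts2)
    pmap[key] = p1 if p1.t_adapt_s <= p2.t_adapt_s else p2
    return key


def run_cascade(G: nx.MultiGraph) -> CascadeRecord:
    """Alternate prune_step and series merging until no vein is unstable.

    The input graph is not modified.  Each step's full R/R_net map is logged
    before the removal; termination is guaranteed since every step removes
    at least one vein.
    """
    G = G.copy()
    rec = CascadeRecord()
    step = 0
    while True:
        rec.ratio_maps.append(relative_resistance_map(G))
        cand = _prune_candidate(G)
        if cand is None:
            break
        key, u, v, ratio = cand
        G.remove_edge(u, v, key)
        rec.events.append((step, key, ratio))
        for node in (u, v):          # series-merge only at the freed nodes
            merge_series(G, node)
        step += 1
    rec.final = G
    return rec


def region_fixture(params: RegionFixtureParams | None = None,
                   perturb: bool = True) -> nx.MultiGraph:
    """The minimal avalanche region: a few similar veins against a backbone.

    Deterministic construction.  Nodes A, B anchor the region to the rest of
    the network, abstracted as a frozen resistor R_rest = r/rest_ratio
    between them.  The region between A and B::

        A --b1-- n1 --X-- n2 --b2-- B        (chain of r-veins)
             n1 --y1-- m --y2-- n2           (2-vein chain parallel to X)
        A --------V(1.2 r)-------- m         (shortcut closing a loop)

    X is a member of a parallel *path* pair (X vs the y-chain); doubling its
    resistance (``perturb=True``) drives its R/R_net above 1 while every
    unperturbed region vein sits strictly below 1.  The removal of X frees
    degree-2 nodes; the merged b1+y1 vein lands in parallel with V and turns
    unstable in turn — the avalanche mechanism in miniature.

    Raises ValueError if the stated guarantees fail for the given params.
    """
    p = params if params is not None else RegionFixtureParams()
    r = p.r
    G = nx.MultiGraph()
    G.add_edge("A", "n1", key="b1", resistance=r)
    G.add_edge("n2", "B", key="b2", resistance=r)
    G.add_edge("n1", "n2", key="X",
               resistance=r * (p.perturbation if perturb else 1.0))
    G.add_edge("n1", "m", key="y1", resistance=r)
    G.add_edge("m", "n2", key="y2", resistance=r)
    G.add_edge("A", "m", key="V", resistance=1.2 * r)
    G.add_edge("A", "B", key="Rrest", resistance=r / p.rest_ratio,
               frozen=True)

    ratios = {k: v for k, v in relative_resistance_map(G).items()
              if k != "Rrest"}
    if perturb:
        others = {k: v for k, v in ratios.items() if k != "X"}
        if ratios["X"] is None or ratios["X"] <= 1.0:
            raise ValueError(
                f"region fixture guarantee violated: perturbed vein ratio "
                f"{ratios['X']} is not > 1 for {p}")
        if any(v is not None and v > 1.0 for v in others.values()):
            raise ValueError(
                f"region fixture guarantee violated: unperturbed vein above "
                f"threshold for {p}: {others}")
    else:
        if any(v is not None and v >= 1.0 for v in ratios.values()):
            raise ValueError(
                f"region fixture guarantee violated: ratios {ratios} not all "
                f"< 1 for {p}")
    return G
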
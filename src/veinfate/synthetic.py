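"""Synthetic contractile networks and radius time series.

Emulates the statistical structure of bright-field-derived vein data so the
whole analysis pipeline is testable without any download: planar-ish
multigraphs (with loops, dangling ends and parallel vein pairs), vein radii
log-uniform in 5–70 μm, peristaltic oscillations of relative amplitude ε and
period T ≈ 100 s sampled at ≈ 6 s cadence, plus additive Gaussian
measurement noise.  Contraction phases are independent per vein; travelling
phase coordination is deliberately not modelled (the time-averaged analyses
downstream are insensitive to it).

All randomness flows from the integer ``seed`` in :class:`SynthConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .adaptation import AdaptationParams, ReducedSystem, simulate_vein
from .network import RadiusSeries, VeinNetwork, VeinSegment

__all__ = [
    "SynthConfig",
    "generate_network",
    "generate_dynamics",
    "generate_vein_benchmark",
]


@dataclass
class SynthConfig:
    """Generation parameters; defaults mirror the observation conditions.

    radius bounds 5–70 μm; contraction period 100 s with relative amplitude
    0.05; cadence 6 s; duration one hour; 1 % multiplicative-scale noise.
    """

    n_nodes: int = 16
    topology: Literal["lattice_with_loops", "random_planar"] = \
        "lattice_with_loops"
    radius_bounds_um: tuple[float, float] = (5.0, 70.0)
    period_s: float = 100.0
    eps: float = 0.05
    cadence_s: float = 6.0
    duration_s: float = 3600.0
    noise_std: float = 0.01          # fraction of the mean radius
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.radius_bounds_um
        if not 0 < lo < hi:
            raise ValueError("radius bounds must be ordered and positive")
        if self.cadence_s >= self.period_s / 4:
            raise ValueError("cadence must resolve the contraction "
                             "(cadence < T/4)")


def _draw_radius(rng: np.random.Generator, cfg: SynthConfig) -> float:
    lo, hi = cfg.radius_bounds_um
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_network(config: SynthConfig) -> VeinNetwork:
    """Random connected multigraph with the observed motif inventory.

    Nodes sit on a jittered grid (spacing ~500 μm); edges connect grid
    neighbours with random thinning that keeps the graph connected and
    loopy.  For ≥ 12 nodes the result is guaranteed to contain at least one
    loop, one dangling end and one true parallel vein pair.  Radii are
    i.i.d. log-uniform within the configured bounds; lengths follow from
    node geometry.  Same seed, same network.
    """
    cfg = config
    if cfg.n_nodes < 4:
        raise ValueError("need at least 4 nodes")
    rng = np.random.default_rng(cfg.seed)
    side = max(2, int(math.ceil(math.sqrt(cfg.n_nodes))))
    spacing = 500.0

    net = VeinNetwork()
    grid: dict[tuple[int, int], str] = {}
    count = 0
    for j in range(side):
        for i in range(side):
            if count >= cfg.n_nodes:
                break
            nid = f"n{count}"
            x = i * spacing + rng.uniform(-0.2, 0.2) * spacing
            y = j * spacing + rng.uniform(-0.2, 0.2) * spacing
            net.add_node(nid, x, y)
            grid[(i, j)] = nid
            count += 1

    def dist(a: str, b: str) -> float:
        (x1, y1), (x2, y2) = net.nodes[a], net.nodes[b]
        return math.hypot(x1 - x2, y1 - y2)

    vid = 0

    def add(u: str, v: str) -> str:
        nonlocal vid
        key = f"v{vid}"
        vid += 1
        net.add_vein(VeinSegment(
            vein_id=key, node_a=u, node_b=v, length_um=max(dist(u, v), 1.0),
            eps=cfg.eps, period_s=cfg.period_s))
        return key

    # grid edges with thinning; a random spanning tree keeps connectivity
    candidates = []
    for (i, j), u in grid.items():
        for di, dj in ((1, 0), (0, 1)):
            vtx = grid.get((i + di, j + dj))
            if vtx is not None:
                candidates.append((u, vtx))
    order = rng.permutation(len(candidates))
    parent = {n: n for n in net.nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    extra = []
    for idx in order:
        u, v = candidates[idx]
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            add(u, v)
        else:
            extra.append((u, v))
    # keep ~60 % of the surplus edges: loops
    keep = rng.random(len(extra)) < 0.6
    n_loops = 0
    for (u, v), k in zip(extra, keep):
        if k or n_loops == 0:
            add(u, v)
            n_loops += 1

    if cfg.n_nodes >= 12:
        # guarantee motifs: one parallel pair, one dangling end
        u, v = extra[0] if extra else candidates[0]
        add(u, v)  # duplicate an existing connection -> parallel pair
        tip = f"n{cfg.n_nodes}"
        anchor = rng.choice(sorted(net.nodes))
        ax, ay = net.nodes[anchor]
        net.add_node(tip, ax + 0.6 * spacing, ay + 0.6 * spacing)
        add(anchor, tip)

    # radii
    rng2 = np.random.default_rng(cfg.seed + 1)
    for v in net.veins.values():
        a = _draw_radius(rng2, cfg)
        n = max(2, int(round(cfg.duration_s / cfg.cadence_s)) + 1)
        # placeholder constant series; generate_dynamics overwrites
        v.radii = RadiusSeries(
            np.arange(2) * cfg.cadence_s, np.full(2, a))
    return net


def generate_dynamics(network: VeinNetwork, config: SynthConfig,
                      mean_radii_um: dict[str, np.ndarray] | None = None
                      ) -> VeinNetwork:
    """Attach peristaltic radius series to every vein (in place).

    a_i(t) = ⟨a_i⟩(t) · (1 + ε sin(2πt/T + φ_i)) + η(t), with i.i.d. uniform
    phases φ_i and additive Gaussian noise of standard deviation
    ``noise_std × mean radius``.  ⟨a_i⟩(t) is the vein's current mean radius
    unless a slowly-varying trend is supplied per vein id.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 2)
    n = int(round(cfg.duration_s / cfg.cadence_s)) + 1
    t = np.arange(n) * cfg.cadence_s
    for vid, v in network.veins.items():
        base = v.radii.mean_radius if v.radii is not None else 20.0
        if mean_radii_um is not None and vid in mean_radii_um:
            mean = np.asarray(mean_radii_um[vid], dtype=float)
            if mean.shape != t.shape:
                raise ValueError(f"mean radius trend for {vid} is off-grid")
        else:
            mean = np.full(n, base)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        a = mean * (1.0 + cfg.eps * np.sin(2 * math.pi * t / cfg.period_s
                                           + phase))
        a = a + rng.normal(0.0, cfg.noise_std * mean.mean(), size=n)
        a = np.maximum(a, 1e-3)
        v.radii = RadiusSeries(t, a)
    return network


def generate_vein_benchmark(params: AdaptationParams,
                            reduced: ReducedSystem | None = None,
                            seed: int = 0,
                            mode: Literal["driven", "autonomous"] = "driven",
                            variant: str = "midvein",
                            a0: float = 20.0,
                            tau_s0: float | None = None,
                            cadence_s: float = 6.0,
                            duration_s: float = 10800.0,
                            drive_amplitude: float = 0.1,
                            drive_period_s: float = 3600.0,
                            noise_std_a: float = 0.002,
                            noise_std_tau: float = 0.005,
                            transient_discard_s: float = 900.0) -> dict:
    """Ground-truth (⟨a⟩(t), ⟨τ⟩(t)) pair for benchmarking the estimators.

    ``driven`` (default): the fluid shear is an exogenous slow modulation
    ⟨τ⟩(t) = τ0 (1 + A sin(2πt/T_drive + φ)) around the target shear —
    emulating the slow biological variability that keeps real veins excited
    — filtered through the sensing equation and integrated to ⟨a⟩(t).  The
    drive period (default 1 h) is long against the sensing delay, so the
    cross-correlation lag of the generated pair is the generating t_delay
    to within a cadence step.  The first ``transient_discard_s`` seconds
    (sensing filter transient) are dropped from the returned series.

    ``autonomous``: the closed-loop system (network closure from
    ``reduced``) integrated by :func:`simulate_vein` — decaying spirals or
    shrinkage, depending on the initial state.

    Fractional Gaussian noise is added to both series.  Returns a dict with
    ``times, a, tau`` and the generating ``params``.
    """
    rng = np.random.default_rng(seed)
    if mode == "driven":
        from .fitting import forward_model

        t = np.arange(0.0, duration_s + cadence_s / 2, cadence_s)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        tau = params.tau0 * (1.0 + drive_amplitude
                             * np.sin(2 * math.pi * t / drive_period_s
                                      + phase))
        a = forward_model(t, tau, params, a0, tau_s0=tau_s0)
    elif mode == "autonomous":
        if reduced is None:
            raise ValueError("autonomous mode requires a reduced system")
        traj = simulate_vein(variant, reduced, params, a0=a0, tau_s0=tau_s0,
                             duration=duration_s, a_min=1e-12 * a0)
        t = np.arange(0.0, duration_s + cadence_s / 2, cadence_s)
        t = t[t <= traj["t"].iloc[-1]]
        a = np.interp(t, traj["t"], traj["a"])
        tau = np.interp(t, traj["t"], traj["tau_fluid"])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if noise_std_a > 0:
        a = a * (1.0 + rng.normal(0.0, noise_std_a, size=a.size))
    if noise_std_tau > 0:
        tau = tau * (1.0 + rng.normal(0.0, noise_std_tau, size=tau.size))
    keep = t >= transient_discard_s
    return {"times": t[keep] - t[keep][0], "a": a[keep], "tau": tau[keep],
            "params": params, "reduced": reduced}
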
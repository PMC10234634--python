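"""Delayed shear-feedback adaptation dynamics of contractile veins.

The model couples two ordinary differential equations per vein:

* radius adaptation  d⟨a⟩/dt = (⟨a⟩/t_adapt) (τs²/τ0² − 1), a quadratic
  shear response whose zero τs = τ0 is Murray's constant-shear steady state;
* shear sensing      dτs/dt = −(τs − ⟨τ⟩)/t_delay, a first-order relaxation
  of the sensed shear rate τs toward the fluid shear rate ⟨τ⟩ with sensing
  delay t_delay (≈ minutes, well below the adaptation time t_adapt).

The fluid shear ⟨τ⟩ closes the loop through the network: for a vein embedded
in a network reduced to its Norton equivalent (rest-of-network resistance
R_net), ⟨τ⟩ = 32 L ε ⟨a⟩³ / (T (⟨a⟩⁴ + c)) with coupling c = 8μL/(π R_net);
for a dangling end ⟨τ⟩ = 32 L ε / (⟨a⟩ T).

Fixed points of the reduced (τs, ⟨a⟩) system are (0, 0) plus the positive
roots of the quartic a⁴ − β a³ + c = 0, β = 32 L ε / (T τ0): two positive
roots (a saddle and a stable spiral) exist iff c < 27 β⁴ / 256.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import UM, MPAS, VeinNetwork
from . import hydraulics

__all__ = [
    "AdaptationParams",
    "ReducedSystem",
    "FixedPoint",
    "adaptation_rhs",
    "sensing_rhs",
    "midvein_shear",
    "dangling_shear",
    "target_shear_from_pressure",
    "reduced_fixed_points",
    "simulate_vein",
    "simulate_network",
]


@dataclass
class AdaptationParams:
    """Per-vein model constants.

    t_adapt_s : vein-wall growth/disassembly timescale (s), order 10-100 min.
    tau0 : target (Murray) shear rate (1/s).
    t_delay_s : shear sensing delay (s), order 1-3 min.
    tau_active : active-stress shear scale σ_active/μ (1/s), used when τ0 is
        derived from the local pressure; optional.
    a_min_um : absorbing vanish threshold on the radius (μm).
    growth_cap_factor : dangling ends stop integrating at this multiple of
        the initial radius (the model has no large-radius attractor there).
    """

    t_adapt_s: float
    tau0: float
    t_delay_s: float
    tau_active: float | None = None
    a_min_um: float = 0.5
    growth_cap_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.t_adapt_s <= 0 or self.t_delay_s <= 0:
            raise ValueError("t_adapt and t_delay must be positive")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if self.a_min_um <= 0:
            raise ValueError("a_min must be positive")


@dataclass
class ReducedSystem:
    """Geometry and network coupling of one vein after Norton reduction.

    Plain numbers in any consistent unit system (SI internally when built
    from a network; dimensionless in phase-plane studies):
    length L, contraction amplitude eps, period T, and the coupling
    c = 8 μ L / (π R_net) with dimension length⁴.  c -> 0 is the
    short-circuit (R ≪ R_net, dangling-like) limit.
    """

    length: float
    eps: float
    period: float
    coupling: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.period <= 0:
            raise ValueError("length and period must be positive")
        if self.eps < 0 or self.coupling < 0:
            raise ValueError("eps and coupling must be non-negative")

    def beta(self, tau0: float) -> float:
        """β = 32 L ε / (T τ0), the quartic's cubic coefficient (length)."""
        return 32.0 * self.length * self.eps / (self.period * tau0)

    @classmethod
    def from_vein(cls, network: VeinNetwork, vein_id: str,
                  radii_um: Mapping[str, float] | None = None
                  ) -> "ReducedSystem":
        """Build the SI reduced system for one vein of a network.

        Raises if R_net is undefined (dangling end or bridge).
        """
        eq = hydraulics.norton_equivalent(network, vein_id, radii_um)
        if eq.network_resistance is None:
            raise ValueError(
                f"vein {vein_id!r} has no defined R_net (dangling or bridge)")
        v = network.veins[vein_id]
        mu = network.viscosity_mPas * MPAS
        c = 8.0 * mu * (v.length_um * UM) / (math.pi * eq.network_resistance)
        return cls(length=v.length_um * UM, eps=v.eps, period=v.period_s,
                   coupling=c)


@dataclass
class FixedPoint:
    """A fixed point of the reduced (τs, ⟨a⟩) system with its stability."""

    tau_s: float
    radius: float
    stability: Literal["stable", "unstable"]
    eigenvalues: tuple[complex, complex]


# ---------------------------------------------------------------------------
# right-hand sides and shear closures
# ---------------------------------------------------------------------------

def adaptation_rhs(a: float, tau_s: float, params: AdaptationParams) -> float:
    """d⟨a⟩/dt = (⟨a⟩/t_adapt)(τs²/τ0² − 1)."""
    return (a / params.t_adapt_s) * ((tau_s / params.tau0) ** 2 - 1.0)


def sensing_rhs(tau_s: float, tau_fluid: float, t_delay_s: float) -> float:
    """dτs/dt = −(τs − ⟨τ⟩)/t_delay."""
    if t_delay_s <= 0:
        raise ValueError("t_delay must be positive")
    return -(tau_s - tau_fluid) / t_delay_s


def midvein_shear(a, reduced: ReducedSystem):
    """⟨τ⟩ = 32 L ε a³ / (T (a⁴ + c)) for a vein inside the network.

    Equivalent to composing Q_in = 8πLεa²/T, R = 8μL/(πa⁴), the Norton flow
    Q = Q_in/(1 + R/R_net) and τ = 4|Q|/(πa³).  Vectorised over a.
    """
    a = np.asarray(a, dtype=float)
    out = (32.0 * reduced.length * reduced.eps * a**3
           / (reduced.period * (a**4 + reduced.coupling)))
    return float(out) if out.ndim == 0 else out


def _midvein_shear_da(a: float, reduced: ReducedSystem) -> float:
    """d⟨τ⟩/da of the mid-vein closure (for Jacobians)."""
    c = reduced.coupling
    pref = 32.0 * reduced.length * reduced.eps / reduced.period
    return pref * a**2 * (3.0 * c - a**4) / (a**4 + c) ** 2


def dangling_shear(a, length: float, eps: float, period: float):
    """⟨τ⟩ ≃ 32 L ε / (a T): shear in a dangling end, where all of Q_in
    traverses the single attachment."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("dangling_shear requires a > 0")
    out = 32.0 * length * eps / (a * period)
    return float(out) if out.ndim == 0 else out


def target_shear_from_pressure(tau_active: float, p_mean_Pa: float,
                               p0_Pa: float, viscosity_mPas: float,
                               prefactor: float = 1.0
                               ) -> tuple[float, bool]:
    """Target shear τ0 ≈ τ_active − ⟨P − P0⟩/μ from the local fluid pressure.

    A larger local pressure lowers the shear threshold a vein needs to
    sustain itself (high-pressure dangling ends grow).  Returns
    ``(tau0, clipped)``; τ0 is clipped below at 0 and the flag reports it.
    The proportionality is implemented as equality times ``prefactor``.
    """
    if viscosity_mPas <= 0:
        raise ValueError("viscosity must be positive")
    tau0 = prefactor * (tau_active
                        - (p_mean_Pa - p0_Pa) / (viscosity_mPas * MPAS))
    if tau0 < 0:
        return 0.0, True
    return tau0, False


# ---------------------------------------------------------------------------
# fixed points of the reduced system
# ---------------------------------------------------------------------------

def _jacobian(a: float, tau_s: float, reduced: ReducedSystem,
              params: AdaptationParams) -> np.ndarray:
    """Jacobian of (da/dt, dτs/dt) at (a, τs) for the mid-vein closure."""
    t0 = params.tau0
    J = np.empty((2, 2))
    J[0, 0] = ((tau_s / t0) ** 2 - 1.0) / params.t_adapt_s
    J[0, 1] = 2.0 * a * tau_s / (t0**2 * params.t_adapt_s)
    J[1, 0] = _midvein_shear_da(a, reduced) / params.t_delay_s
    J[1, 1] = -1.0 / params.t_delay_s
    return J


def reduced_fixed_points(reduced: ReducedSystem,
                         params: AdaptationParams,
                         tol: float = 1e-9) -> list[FixedPoint]:
    """All fixed points of the reduced (τs, ⟨a⟩) system, with stability.

    Always contains (0, 0) (vanished vein, stable).  Nonzero fixed points
    have τs* = τ0 and radii at the positive roots of a⁴ − βa³ + c = 0; when
    two exist the smaller is a saddle (unstable) and the larger a stable,
    typically spiralling, point.
    """
    beta = reduced.beta(params.tau0)
    c = reduced.coupling
    out: list[FixedPoint] = []

    # origin: da/dt -> -a/t_adapt, dτs/dt -> -τs/t_delay near (0, 0)
    out.append(FixedPoint(
        tau_s=0.0, radius=0.0, stability="stable",
        eigenvalues=(-1.0 / params.t_adapt_s, -1.0 / params.t_delay_s)))

    roots = np.roots([1.0, -beta, 0.0, 0.0, c])
    scale = max(beta, c**0.25, 1e-300)
    pos = sorted(r.real for r in roots
                 if abs(r.imag) < 1e-9 * scale and r.real > tol * scale)
    for a_star in pos:
        ev = np.linalg.eigvals(_jacobian(a_star, params.tau0, reduced, params))
        stable = bool(np.all(ev.real < tol / params.t_delay_s))
        out.append(FixedPoint(
            tau_s=params.tau0, radius=float(a_star),
            stability="stable" if stable else "unstable",
            eigenvalues=(complex(ev[0]), complex(ev[1]))))
    return out


# ---------------------------------------------------------------------------
# single-vein simulation
# ---------------------------------------------------------------------------

def simulate_vein(variant: Literal["midvein", "dangling"],
                  reduced: ReducedSystem,
                  params: AdaptationParams,
                  a0: float,
                  tau_s0: float | None = None,
                  duration: float = 6000.0,
                  dt: float | None = None,
                  a_min: float | None = None) -> pd.DataFrame:
    """Integrate the two-equation system for one vein.

    ``reduced`` supplies geometry (L, ε, T) and, for the midvein variant,
    the coupling c; the dangling variant ignores c.  Integration stops early
    when the radius crosses a_min (vanished) or, for dangling growth, the
    cap ``growth_cap_factor × a0``.  Adaptive RK45, max step t_delay/10.

    Returns a DataFrame with columns t, a, tau_s, tau_fluid and attrs
    ``outcome`` ∈ {completed, vanished, grew_to_cap}.
    """
    if variant not in ("midvein", "dangling"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "midvein":
        shear: Callable[[float], float] = lambda a: midvein_shear(a, reduced)
    else:
        shear = lambda a: dangling_shear(a, reduced.length, reduced.eps,
                                         reduced.period)
    if tau_s0 is None:
        tau_s0 = shear(a0)
    a_cap = params.growth_cap_factor * a0
    if a_min is None:
        # default assumes SI lengths (reduced built from a network); pass
        # a_min explicitly when working in nondimensional variables
        a_min = params.a_min_um * UM

    def rhs(t, y):
        a, ts = y
        return (adaptation_rhs(a, ts, params),
                sensing_rhs(ts, shear(a), params.t_delay_s))

    def hit_min(t, y):
        return y[0] - a_min
    hit_min.terminal = True
    hit_min.direction = -1

    def hit_cap(t, y):
        return y[0] - a_cap
    hit_cap.terminal = True
    hit_cap.direction = 1

    max_step = params.t_delay_s / 10.0
    t_eval = None
    if dt is not None:
        if dt > params.t_delay_s / 10.0 + 1e-12:
            raise ValueError("dt must be <= t_delay/10")
        t_eval = np.arange(0.0, duration + dt / 2, dt)
    sol = solve_ivp(rhs, (0.0, duration), [a0, tau_s0], method="RK45",
                    max_step=max_step, rtol=1e-7, atol=1e-9,
                    events=[hit_min, hit_cap], t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"integrator failed: {sol.message}")
    a = sol.y[0]
    ts = sol.y[1]
    df = pd.DataFrame({
        "t": sol.t, "a": a, "tau_s": ts,
        "tau_fluid": [shear(x) for x in a],
    })
    if sol.t_events[0].size:
        df.attrs["outcome"] = "vanished"
    elif sol.t_events[1].size:
        df.attrs["outcome"] = "grew_to_cap"
    else:
        df.attrs["outcome"] = "completed"
    return df


# ---------------------------------------------------------------------------
# network-coupled simulation
# ---------------------------------------------------------------------------

def simulate_network(network: VeinNetwork,
                     params: Mapping[str, AdaptationParams] | AdaptationParams,
                     duration: float,
                     dt: float,
                     initial_radii_um: Mapping[str, float] | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate the time-averaged adaptation of every vein at once.

    At each step every vein's fluid shear ⟨τ⟩ is recomputed from full
    Kirchhoff solves of the time-averaged problem, as the sum of two
    contributions living on separate timescales:

    * the vein's own peristaltic pumping, Q_in injected at its endpoints
      (one solve per vein; exact where the two-resistor Norton reduction
      is exact only for a single perturbed vein), and
    * the slow flow driven by every vein's adaptation-timescale volume
      change L·d(π⟨a⟩²)/dt, lumped half-and-half onto endpoints — the mass
      redistribution that boosts shear in the outer segments of a shrinking
      loop and in the survivor of a vanishing parallel pair.

    ⟨a⟩ and τs then advance one explicit RK2 step.  Veins crossing a_min
    are removed (event ``vanished``) and freed degree-2 nodes are
    series-merged (event ``merged``, handled by the pruning machinery).

    Returns ``(trajectories, events)``: long-format trajectory frame
    ``vein_id, time_s, a_um, tau_s_per_s, tau_fluid_per_s`` and an event log
    ``time_s, vein_id, event``.
    """
    from . import avalanche as _av

    if isinstance(params, AdaptationParams):
        params = {vid: params for vid in network.veins}
    pmap = dict(params)
    for vid, p in pmap.items():
        if dt > p.t_delay_s / 10.0 + 1e-12:
            raise ValueError("dt must be <= t_delay/10 for every vein")

    # mutable copy of the network topology
    net = VeinNetwork(nodes=dict(network.nodes),
                      veins=dict(network.veins),
                      viscosity_mPas=network.viscosity_mPas)
    radii: dict[str, float] = (
        dict(initial_radii_um) if initial_radii_um is not None
        else {vid: v.mean_radius_um() for vid, v in net.veins.items()})

    def fluid_shear(tau_s_now: Mapping[str, float] | None) -> dict[str, float]:
        tau = hydraulics.time_averaged_shear(net, radii)
        if tau_s_now is None:
            return tau
        # slow adaptation-driven redistribution: each vein's current volume
        # change rate acts as a source; its |Q| adds to the pumping shear
        dvdt = {}
        for vid, v in net.veins.items():
            dadt = adaptation_rhs(radii[vid], tau_s_now[vid], pmap[vid])
            dvdt[vid] = (v.length_um * UM) * 2.0 * math.pi \
                * (radii[vid] * UM) * (dadt * UM)
        if any(abs(s) > 0 for s in dvdt.values()):
            sol = hydraulics.solve_flows(net, radii, dvdt_m3_s=dvdt)
            for vid in tau:
                tau[vid] = tau[vid] + sol.shear[vid]
        return tau

    tau_fluid = fluid_shear(None)
    tau_s: dict[str, float] = {vid: tau_fluid[vid] for vid in net.veins}

    rows, events = [], []
    n_steps = int(round(duration / dt))
    t = 0.0
    for step in range(n_steps + 1):
        tau_fluid = fluid_shear(tau_s)
        for vid in net.veins:
            rows.append((vid, t, radii[vid], tau_s[vid], tau_fluid[vid]))
        if step == n_steps:
            break

        # explicit midpoint (RK2) step per vein, shear field frozen over dt
        for vid in list(net.veins):
            p = pmap[vid]
            a, ts = radii[vid], tau_s[vid]
            ka1 = adaptation_rhs(a, ts, p)
            ks1 = sensing_rhs(ts, tau_fluid[vid], p.t_delay_s)
            a_mid, ts_mid = a + 0.5 * dt * ka1, ts + 0.5 * dt * ks1
            ka2 = adaptation_rhs(a_mid, ts_mid, p)
            ks2 = sensing_rhs(ts_mid, tau_fluid[vid], p.t_delay_s)
            radii[vid] = a + dt * ka2
            tau_s[vid] = ts + dt * ks2
        t += dt

        # removal + series merging
        vanished = [vid for vid, a in radii.items()
                    if a < pmap[vid].a_min_um]
        for vid in vanished:
            v = net.veins.pop(vid)
            radii.pop(vid)
            tau_s.pop(vid)
            pmap.pop(vid)
            events.append((t, vid, "vanished"))
            for node in v.endpoints:
                merged = _av.merge_series_network(net, node, radii, tau_s,
                                                  pmap)
                if merged is not None:
                    events.append((t, merged, "merged"))

    traj = pd.DataFrame(rows, columns=["vein_id", "time_s", "a_um",
                                       "tau_s_per_s", "tau_fluid_per_s"])
    ev = pd.DataFrame(events, columns=["time_s", "vein_id", "event"])
    return traj, ev
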
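"""Contractile vein-network data model, elementary hydraulic formulas, and I/O.

A :class:`VeinNetwork` is a planar-ish multigraph: nodes carry 2-D positions
(in micrometres), veins are cylindrical segments with a length, a radius time
series, a peristaltic contraction amplitude and period.  Parallel veins between
the same node pair are first-class citizens and survive I/O round trips.

Unit conventions
----------------
Public inputs use the scales the data is reported on: micrometres for lengths
and radii, seconds for times, mPa·s for the fluid viscosity.  All hydraulic
quantities (resistance, flow, pressure) are computed and returned in SI.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

UM = 1e-6          # micrometre -> metre
MPAS = 1e-3        # mPa·s -> Pa·s

__all__ = [
    "RadiusSeries",
    "VeinSegment",
    "VeinNetwork",
    "NetworkFormatError",
    "poiseuille_resistance",
    "shear_from_flow",
    "contraction_inflow",
    "read_network",
    "write_network",
]


class NetworkFormatError(ValueError):
    """Raised when a network file violates the tabular schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RadiusSeries:
    """Sampled vein radius trajectory a(t), near-uniform cadence.

    times are seconds (strictly increasing, cadence jitter < 10 %), radii are
    micrometres (strictly positive).
    """

    times: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.times.shape != self.radii.shape or self.times.ndim != 1:
            raise ValueError("times and radii must be 1-D arrays of equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            jitter = (dt.max() - dt.min()) / np.median(dt)
            if jitter > 0.10:
                raise ValueError(
                    f"radius series cadence varies by {jitter:.1%} (> 10%); "
                    "resample upstream"
                )
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")

    @property
    def cadence(self) -> float:
        """Median sampling interval in seconds."""
        if self.times.size < 2:
            raise ValueError("cadence undefined for a single sample")
        return float(np.median(np.diff(self.times)))

    @property
    def mean_radius(self) -> float:
        return float(self.radii.mean())

    def __len__(self) -> int:
        return self.times.size


@dataclass
class VeinSegment:
    """One cylindrical vein: endpoints, length, contraction, radius data."""

    vein_id: str
    node_a: str
    node_b: str
    length_um: float
    eps: float = 0.0
    period_s: float = 100.0
    radii: RadiusSeries | None = None

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError(f"vein {self.vein_id}: length must be > 0")
        if self.eps < 0:
            raise ValueError(f"vein {self.vein_id}: eps must be >= 0")
        if self.period_s <= 0:
            raise ValueError(f"vein {self.vein_id}: period must be > 0")
        if self.node_a == self.node_b:
            raise ValueError(f"vein {self.vein_id}: endpoints must be distinct")

    @property
    def endpoints(self) -> tuple[str, str]:
        return (self.node_a, self.node_b)

    def mean_radius_um(self) -> float:
        if self.radii is None:
            raise ValueError(f"vein {self.vein_id} has no radius series")
        return self.radii.mean_radius


@dataclass
class VeinNetwork:
    """Multigraph of veins; node positions in μm, one fluid-wide viscosity.

    The default viscosity (1.5 mPa·s) is of the order of cytoplasmic
    endoplasm; it only matters for pressure maps, never for shear rates,
    and is configurable.
    """

    nodes: dict[str, tuple[float, float]] = field(default_factory=dict)
    veins: dict[str, VeinSegment] = field(default_factory=dict)
    viscosity_mPas: float = 1.5

    def add_node(self, node_id: str, x_um: float, y_um: float) -> None:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id!r}")
        self.nodes[node_id] = (float(x_um), float(y_um))

    def add_vein(self, vein: VeinSegment) -> None:
        if vein.vein_id in self.veins:
            raise ValueError(f"duplicate vein id {vein.vein_id!r}")
        for n in vein.endpoints:
            if n not in self.nodes:
                raise ValueError(f"vein {vein.vein_id}: unknown node {n!r}")
        self.veins[vein.vein_id] = vein

    def graph(self):
        """The underlying networkx.MultiGraph (edge key = vein id)."""
        import networkx as nx

        G = nx.MultiGraph()
        for nid, (x, y) in self.nodes.items():
            G.add_node(nid, pos=(x, y))
        for vid, v in self.veins.items():
            G.add_edge(v.node_a, v.node_b, key=vid, vein=v)
        return G

    def resistance_graph(self, radii_um: Mapping[str, float] | None = None):
        """MultiGraph with per-edge Poiseuille 'resistance' (SI) attributes.

        radii_um overrides the stored time-averaged radii (per vein id).
        """
        import networkx as nx

        G = nx.MultiGraph()
        G.add_nodes_from(self.nodes)
        for vid, v in self.veins.items():
            a = radii_um[vid] if radii_um is not None else v.mean_radius_um()
            R = poiseuille_resistance(v.length_um, a, self.viscosity_mPas)
            G.add_edge(v.node_a, v.node_b, key=vid, resistance=R,
                       length_um=v.length_um, radius_um=a,
                       eps=v.eps, period_s=v.period_s)
        return G

    def common_time_grid(self) -> np.ndarray:
        """Shared sampling grid of all radius series; error if they differ."""
        grids = [v.radii.times for v in self.veins.values() if v.radii is not None]
        if not grids:
            raise ValueError("network carries no radius series")
        ref = grids[0]
        for g in grids[1:]:
            if g.shape != ref.shape or not np.allclose(g, ref):
                raise ValueError("radius series do not share a common time grid")
        return ref

    def validate(self) -> None:
        for vid, v in self.veins.items():
            for n in v.endpoints:
                if n not in self.nodes:
                    raise ValueError(f"vein {vid}: unknown node {n!r}")


# ---------------------------------------------------------------------------
# elementary formulas
# ---------------------------------------------------------------------------

def poiseuille_resistance(length_um: float, radius_um: float,
                          viscosity_mPas: float) -> float:
    """Hydraulic resistance R = 8 μ L / (π a⁴) of a cylindrical vein, in
    Pa·s·m⁻³.

    Inputs are in μm / mPa·s; pass ``length_um=1, radius_um=1`` with
    ``viscosity_mPas`` scaled accordingly only if you want unit tricks —
    normally give physical values.
    """
    if length_um <= 0 or radius_um <= 0 or viscosity_mPas <= 0:
        raise ValueError("poiseuille_resistance requires positive L, a, mu")
    L = length_um * UM
    a = radius_um * UM
    mu = viscosity_mPas * MPAS
    return 8.0 * mu * L / (math.pi * a**4)


def shear_from_flow(flow_m3_s, radius_m):
    """Wall shear rate τ = 4 |Q| / (π a³) of laminar pipe flow, in s⁻¹.

    SI inputs; even in Q (flow direction does not matter for the magnitude
    of the wall velocity gradient).  Vectorised over Q.
    """
    radius_m = np.asarray(radius_m, dtype=float)
    if np.any(radius_m <= 0):
        raise ValueError("shear_from_flow requires a > 0")
    out = 4.0 * np.abs(flow_m3_s) / (math.pi * radius_m**3)
    return float(out) if np.ndim(out) == 0 else out


def contraction_inflow(length_um: float, mean_radius_um: float, eps: float,
                       period_s: float) -> float:
    """Time-averaged net flow Q_in ≃ 8π L ε ⟨a⟩² / T pumped by peristaltic
    contraction of a single vein, in m³/s.

    This is the period average of |L d(πa²)/dt| for
    a(t) = ⟨a⟩(1 + ε sin(2πt/T)), to first order in ε.
    """
    if length_um <= 0 or mean_radius_um <= 0 or period_s <= 0:
        raise ValueError("contraction_inflow requires positive L, a, T")
    if eps < 0:
        raise ValueError("contraction_inflow requires eps >= 0")
    L = length_um * UM
    a = mean_radius_um * UM
    return 8.0 * math.pi * L * eps * a**2 / period_s


# ---------------------------------------------------------------------------
# I/O  (nodes.csv / veins.csv / radii.csv|radii.h5 + meta.json|yaml sidecar)
# ---------------------------------------------------------------------------

_NODE_COLS = ["node_id", "x_um", "y_um"]
_VEIN_COLS = ["vein_id", "node_a", "node_b", "length_um", "eps", "period_s"]
_RADII_COLS = ["vein_id", "time_s", "radius_um"]


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise NetworkFormatError(
            f"{path}: missing column(s) {missing}; expected header {cols}")


def _check_unique(df: pd.DataFrame, col: str, path: Path) -> None:
    dup = df[col][df[col].duplicated()]
    if len(dup):
        first = dup.iloc[0]
        line = int(df.index[df[col] == first][1]) + 2  # header + 1-based
        raise NetworkFormatError(
            f"{path}: line {line}: duplicate {col} {first!r}")


def read_network(path: str | Path) -> VeinNetwork:
    """Load a VeinNetwork from a directory of CSV files.

    Expects ``nodes.csv`` and ``veins.csv``; optionally ``radii.csv`` (long
    format) or ``radii.h5`` (one dataset per vein, columns time_s/radius_um),
    and a ``meta.json`` or ``meta.yaml`` sidecar with the viscosity.
    """
    d = Path(path)
    nodes_path, veins_path = d / "nodes.csv", d / "veins.csv"
    for p in (nodes_path, veins_path):
        if not p.exists():
            raise NetworkFormatError(f"{p}: file not found")

    nodes = pd.read_csv(nodes_path, dtype={"node_id": str})
    _require_columns(nodes, _NODE_COLS, nodes_path)
    _check_unique(nodes, "node_id", nodes_path)

    veins = pd.read_csv(veins_path,
                        dtype={"vein_id": str, "node_a": str, "node_b": str})
    _require_columns(veins, _VEIN_COLS, veins_path)
    _check_unique(veins, "vein_id", veins_path)

    viscosity = 1.5
    meta_json, meta_yaml = d / "meta.json", d / "meta.yaml"
    if meta_json.exists():
        viscosity = float(json.loads(meta_json.read_text())["viscosity_mPas"])
    elif meta_yaml.exists():
        import yaml

        viscosity = float(yaml.safe_load(meta_yaml.read_text())["viscosity_mPas"])

    net = VeinNetwork(viscosity_mPas=viscosity)
    for i, row in nodes.iterrows():
        try:
            net.add_node(row["node_id"], float(row["x_um"]), float(row["y_um"]))
        except (TypeError, ValueError) as e:
            raise NetworkFormatError(
                f"{nodes_path}: line {i + 2}: {e}") from e

    radii_by_vein: dict[str, RadiusSeries] = {}
    radii_csv, radii_h5 = d / "radii.csv", d / "radii.h5"
    if radii_csv.exists():
        rad = pd.read_csv(radii_csv, dtype={"vein_id": str})
        _require_columns(rad, _RADII_COLS, radii_csv)
        for vid, grp in rad.groupby("vein_id", sort=False):
            grp = grp.sort_values("time_s")
            radii_by_vein[str(vid)] = RadiusSeries(
                grp["time_s"].to_numpy(), grp["radius_um"].to_numpy())
    elif radii_h5.exists():
        import h5py

        with h5py.File(radii_h5, "r") as f:
            for vid in f:
                ds = f[vid][...]
                radii_by_vein[str(vid)] = RadiusSeries(ds[:, 0], ds[:, 1])

    for i, row in veins.iterrows():
        try:
            seg = VeinSegment(
                vein_id=row["vein_id"], node_a=row["node_a"],
                node_b=row["node_b"], length_um=float(row["length_um"]),
                eps=float(row["eps"]), period_s=float(row["period_s"]),
                radii=radii_by_vein.get(row["vein_id"]))
            net.add_vein(seg)
        except (TypeError, ValueError) as e:
            raise NetworkFormatError(
                f"{veins_path}: line {i + 2}: field error: {e}") from e
    return net


def write_network(network: VeinNetwork, path: str | Path) -> None:
    """Write a VeinNetwork to a directory (inverse of :func:`read_network`)."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(nid, x, y) for nid, (x, y) in network.nodes.items()],
        columns=_NODE_COLS,
    ).to_csv(d / "nodes.csv", index=False)
    pd.DataFrame(
        [(v.vein_id, v.node_a, v.node_b, v.length_um, v.eps, v.period_s)
         for v in network.veins.values()],
        columns=_VEIN_COLS,
    ).to_csv(d / "veins.csv", index=False)
    rows: list[pd.DataFrame] = []
    for v in network.veins.values():
        if v.radii is not None:
            rows.append(pd.DataFrame({
                "vein_id": v.vein_id,
                "time_s": v.radii.times,
                "radius_um": v.radii.radii,
            }))
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(d / "radii.csv", index=False)
    (d / "meta.json").write_text(
        json.dumps({"viscosity_mPas": network.viscosity_mPas}) + "\n")
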
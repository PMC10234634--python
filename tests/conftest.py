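"""Shared fixtures: small deterministic networks and reference systems."""

import numpy as np
import pytest

import veinfate as vf


@pytest.fixture
def two_node_net():
    """Single vein between two nodes."""
    net = vf.VeinNetwork()
    net.add_node("u", 0.0, 0.0)
    net.add_node("v", 100.0, 0.0)
    net.add_vein(vf.VeinSegment("e1", "u", "v", 100.0, eps=0.05,
                                period_s=100.0))
    return net


@pytest.fixture
def triangle_net():
    """Equal-resistance triangle (equal lengths, equal radii)."""
    net = vf.VeinNetwork()
    for i, (x, y) in enumerate([(0, 0), (100, 0), (50, 80)]):
        net.add_node(f"n{i}", float(x), float(y))
    for i, (a, b) in enumerate([("n0", "n1"), ("n1", "n2"), ("n2", "n0")]):
        net.add_vein(vf.VeinSegment(f"e{i}", a, b, 100.0))
    return net


@pytest.fixture
def nondim_reduced():
    """Reduced system with beta = 2.5 (at tau0 = 1) and c = 1 in
    dimensionless units: the two-positive-root reference case."""
    return vf.ReducedSystem(length=1.0, eps=1.0, period=32.0 / 2.5,
                            coupling=1.0)


def make_random_net(seed: int, n: int = 10, m: int = 15) -> tuple:
    """Random connected multigraph with constant radius series."""
    r = np.random.default_rng(seed)
    net = vf.VeinNetwork()
    for i in range(n):
        x, y = r.uniform(0, 1000, 2)
        net.add_node(f"n{i}", float(x), float(y))
    ids = list(net.nodes)
    for i in range(1, n):
        j = int(r.integers(0, i))
        net.add_vein(vf.VeinSegment(f"e{i - 1}", ids[i], ids[j],
                                    float(r.uniform(50, 500)),
                                    eps=0.05, period_s=100.0))
    k = n - 1
    while k < m:
        i, j = (int(x) for x in r.integers(0, n, 2))
        if i == j:
            continue
        net.add_vein(vf.VeinSegment(f"e{k}", ids[i], ids[j],
                                    float(r.uniform(50, 500)),
                                    eps=0.05, period_s=100.0))
        k += 1
    radii = {vid: float(r.uniform(5, 70)) for vid in net.veins}
    for vid, v in net.veins.items():
        v.radii = vf.RadiusSeries(np.array([0.0, 6.0]),
                                  np.full(2, radii[vid]))
    return net, radii
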
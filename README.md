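# veinfate

Flow-based, time-delayed vein adaptation analysis for contractile vascular
networks.

Vascular networks — blood vasculature, leaf venation, and the vein networks
that make up the slime mould *Physarum polycephalum* — continuously remodel:
individual veins grow, shrink, stabilise or vanish. The classical picture
(Murray) is that wall shear stress feeds back on vein radius, but shear
alone cannot explain why veins with near-identical shear and radius suffer
opposite fates. `veinfate` implements a quantitative framework in which a
vein's fate is decided by flow physics that *integrates the whole network's
architecture*: the sensing delay between shear and adaptation, the local
fluid pressure, and the vein's resistance relative to the rest of the
network.

The package is aimed at quantitative biologists and physicists analysing
vein-radius time series from whole-network imaging, and at modellers
studying adaptive flow networks. It needs no experimental data to run: a
synthetic-data module generates contracting networks with the statistical
structure of bright-field-derived measurements (radii 5–70 μm, peristaltic
contractions with period T ≈ 100 s, 6 s sampling cadence, measurement
noise), and every analysis stage is exercised against it.

## The model

Each vein is a cylindrical segment of length L and (time-averaged) radius
⟨a⟩ carrying laminar Poiseuille flow, with

- hydraulic resistance R = 8μL/(π⟨a⟩⁴),
- wall shear rate τ = 4|Q|/(π⟨a⟩³),
- peristaltic pumping Q_in = ⟨|L d(πa²)/dt|⟩ ≃ 8πLε⟨a⟩²/T for relative
  contraction amplitude ε.

Flows follow from conservation of fluid volume (Kirchhoff's laws) on the
conductance-weighted network; pressures are defined up to a gauge constant.
Reducing the rest of the network, seen from one vein, to its Norton
equivalent (resistance R_net) gives the vein's time-averaged shear

    ⟨τ⟩ = (4 Q_in / π⟨a⟩³) · 1/(1 + R/R_net) = 32 L ε ⟨a⟩³ / (T (⟨a⟩⁴ + c)),

with coupling c = 8μL/(πR_net). Radius adaptation responds to a *sensed*
shear τs that tracks ⟨τ⟩ with a first-order delay:

    d⟨a⟩/dt = (⟨a⟩/t_adapt) (τs²/τ0² − 1),
    dτs/dt  = −(τs − ⟨τ⟩)/t_delay,

where t_adapt (tens of minutes) is the wall growth/disassembly timescale,
t_delay (minutes) the sensing delay, and τ0 the target shear of Murray's
constant-shear steady state; τ0 is tied to the local pressure through
τ0 ≈ τ_active − ⟨P−P0⟩/μ. Fixed points of the reduced (τs, ⟨a⟩) system are
(0, 0) plus the positive roots of a⁴ − βa³ + c = 0 with β = 32Lε/(Tτ0):
below the saddle-node boundary c = 27β⁴/256 there are exactly two stable
fixed points and one saddle, and trajectories near the finite-radius
attractor spiral clockwise in the (⟨a⟩, τ) plane.

On top of the dynamics, the package provides the analysis stages used on
(real or synthetic) radius time series: trend extraction, contraction-period
estimation, cross-correlation inference of t_delay (lag of ⟨τ⟩(t − Δ)
against d⟨a⟩/dt, significance threshold 0.5), trajectory classification
(stable / shrinking monotonic / non-monotonic / unclassifiable, with loop
orientation), L1 model fitting of (t_adapt, τ0), and the structural pruning
rule R/R_net > 1 whose removal-plus-merging iteration produces avalanches of
vanishing veins.

## Worked example

Generate a synthetic vein under reference conditions (t_adapt = 37 min,
τ0 = 1.1 s⁻¹, t_delay = 2 min, 1 % measurement noise), infer the sensing
delay, and fit the model:

```python
import veinfate as vf
from veinfate.synthetic import generate_vein_benchmark

p_true = vf.AdaptationParams(t_adapt_s=37 * 60, tau0=1.1, t_delay_s=120)
bench = generate_vein_benchmark(p_true, seed=1,
                                noise_std_a=0.01, noise_std_tau=0.01)

a_tr = vf.trend(bench["times"], bench["a"], 300.0)
tau_tr = vf.trend(bench["times"], bench["tau"], 300.0)
est = vf.estimate_delay(bench["times"], tau_tr, a_tr, max_lag_s=900.0,
                        derivative_smooth_s=300.0)
print(f"inferred sensing delay: {est.t_delay_s:.0f} s "
      f"(peak correlation {est.peak_correlation:.2f})")

model = vf.DelayedAdaptationModel(bench["times"], bench["a"], bench["tau"],
                                  delay_mode=est.t_delay_s)
res = model.fit()
print(res.summary())
```

which prints

```
inferred sensing delay: 120 s (peak correlation 0.99)
Delayed adaptation model fit
============================================
n obs                                   1651
duration [min]                         165.0
delay mode                             fixed
--------------------------------------------
t_adapt [min]                          37.75
tau0 [1/s]                             1.099
t_delay [min]                           2.00
eps_err                             0.008543
converged                               True
============================================
```

The cross-correlation recovers the 2-minute sensing delay to the sampling
cadence, and the fit recovers the generating t_adapt and τ0 to ≈ 2 % and
≈ 0.1 % with relative L1 error ε_err ≈ 0.009.

A command-line interface wires the stages into a pipeline:

```sh
veinfate synth --out net --nodes 16 --duration 3600 --seed 1
veinfate flows --network net --out flows
veinfate analyze-delays --network net --out delays
veinfate fit --network net --out fits --delay-mode 120
veinfate avalanche --network net --out cascade
```

## Layout

- `src/veinfate/network.py` — vein-network data model, hydraulic formulas, CSV I/O
- `src/veinfate/hydraulics.py` — Kirchhoff solver, effective/relative resistance, Norton reduction
- `src/veinfate/adaptation.py` — the delayed adaptation ODEs, fixed points, simulators
- `src/veinfate/timeseries.py` — trends, period and delay estimation, classification
- `src/veinfate/fitting.py` — `DelayedAdaptationModel` / `DelayedAdaptationResults`
- `src/veinfate/avalanche.py` — pruning rule, series merging, cascade tracking
- `src/veinfate/synthetic.py` — synthetic networks, dynamics and benchmarks
- `src/veinfate/cli.py` — the `veinfate` command
- `docs/methods.md` — modelling assumptions, numerical choices, limitations
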
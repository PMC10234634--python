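# Methods

This note records the modelling assumptions, parameter conventions,
numerical choices and known limitations behind `veinfate`. It documents
what the code computes and why the open design choices were resolved the
way they were; every empirical statement below is one the test suite or
`scripts/acceptance.py` actually computes.

## Hydraulics

**Units.** Public inputs are in the scales the data is reported on
(μm, s, mPa·s); all hydraulic quantities are computed and returned in SI
(Pa·s·m⁻³, m³/s, Pa, s⁻¹). Shear rates never require the viscosity; the
fluid-wide viscosity (default 1.5 mPa·s, of the order of cytoplasmic
endoplasm, configurable on `VeinNetwork`) enters only resistances and
pressure maps.

**Kirchhoff solver.** Each vein is a resistor R = 8μL/(π a⁴) evaluated at
the caller's choice of instantaneous a(t) (snapshot flow fields) or
time-averaged ⟨a⟩ (adaptation-timescale problems). A vein's volume change
rate L·d(πa²)/dt — central differences in time, one-sided at the ends — is
lumped half-and-half onto its endpoint nodes as a fluid source; contraction
expels fluid into the network. Node pressures solve the
conductance-weighted graph Laplacian per connected component
(sparse solve with one pinned row, then re-gauged to mean zero — pressure
is physical only up to an additive constant). Two boundary conventions are
supported: declared *open* nodes are pinned at the reference pressure and
exchange freely; otherwise a closed component whose sources do not sum to
zero absorbs the excess uniformly across its nodes, standing in for the
unmodelled remainder of the organism. Conservation residuals are tracked
and stay below 10⁻¹⁰ of the largest source on the tested ensembles.

**Norton reduction and the time-averaged pumping problem.** For a vein
between nodes (u, v), injecting its pumping flow +Q_in at u and −Q_in at v
with *all* resistors present realises the Norton equivalent exactly: the
current divider gives the vein flow Q_in/(1 + R/R_net), where R_net is the
two-terminal effective resistance of the network with the vein removed.
One scheme therefore covers every topology — dangling ends and bridges
simply carry the whole Q_in (their R_net is undefined, consistent with the
relative-resistance map leaving them unset). The orientation of the
injection is immaterial for shear, which depends on |Q|.

**Relative resistance.** R/R_net is undefined for bridges (removal
disconnects the endpoints) and dangling ends; both are reported as None
and exempted from the pruning rule.

## Adaptation dynamics

The two equations per vein are integrated with explicit adaptive RK45
(rtol 10⁻⁷, atol 10⁻⁹, max step t_delay/10) — the system is non-stiff in
the physiological regime t_delay ≪ t_adapt. The a = 0 boundary is made
absorbing by a vanish threshold a_min (default 0.5 μm): integrating the
a⁻⁴ resistance divergence is avoided and the (0,0) fixed point, reached
only asymptotically, is truncated. Dangling-end growth is capped at 10×
the initial radius and logged as an outcome.

**Fixed points.** With β = 32Lε/(Tτ0) and c = 8μL/(πR_net), the nonzero
fixed points are the positive roots of a⁴ − βa³ + c = 0 (computed by
`numpy.roots`), paired with τs* = τ0; stability comes from the analytic
Jacobian's eigenvalues (classification tolerance 10⁻⁹ on the
1/t_delay scale, cross-checked against finite differences in the tests).
Two positive roots exist iff c < 27β⁴/256; the bisection sweep in the
tests locates this boundary to much better than 1 %.

**Dangling ends.** The dangling closure ⟨τ⟩ = 32Lε/(aT) decreases with a,
so the printed equations admit an interior equilibrium at
a* = 32Lε/(τ0 T) with Jacobian trace −1/t_delay and determinant
2/(t_adapt t_delay): formally attracting, and also the c → 0 limit of the
mid-vein system. The observed shrink-or-grow dichotomy of dangling ends is
the regime where τ0 places a* outside the physical radius window
[a_min, cap] — τ0, hence the local pressure through
τ0 ≈ τ_active − ⟨P−P0⟩/μ, is then exactly the growth-versus-vanish
threshold. Because t_adapt > 8 t_delay makes the eigenvalues real
(overdamped), dangling trajectories are monotone after a transient of
order t_delay and never oscillate. The tests assert these
regime-conditional properties rather than a global absence of the interior
point, which the printed closure does not support.

**The "∼" in the pressure relation** is implemented as equality with an
optional dimensionless prefactor (default 1), with τ0 clipped below at 0
and flagged.

**Network-coupled simulation.** `simulate_network` advances all veins with
a fixed-step explicit midpoint rule (dt ≤ t_delay/10) and recomputes every
vein's ⟨τ⟩ each step from full Kirchhoff solves rather than from the
two-resistor closure, which is exact only for a single perturbed vein. The
shear has two contributions on separate timescales:

1. the vein's own peristaltic pumping (the Norton-consistent per-vein
   injection problem above), and
2. the slow flow driven by every vein's adaptation-rate volume change
   L·d(π⟨a⟩²)/dt, solved with the half-half source lumping.

The second term is the mass redistribution that shields the outer segments
of a shrinking loop (the expelled volume of the whole loop transits
through them, so the middle segment reaches the vanish threshold first)
and transiently boosts the survivor when a parallel partner collapses.
Cross-vein peristaltic contributions time-average out under independent
contraction phases and are not resolved; the fast oscillation enters only
through Q_in(ε, T). Veins crossing a_min are removed and freed degree-2
nodes series-merged, with both events logged.

## Time-series analysis

**Trend.** Centered moving average with trapezoidal end-weights (half
weight on the outermost samples): on a uniform grid a sinusoid whose
period divides the window cancels exactly, so averaging over one or two
contraction periods removes the peristaltic component rather than merely
attenuating it. Edge windows are truncated. The default analysis window is
one contraction period, configurable.

**Contraction period.** Periodogram of the moving-average-detrended
series; the largest non-zero-frequency peak is accepted only if its power
exceeds 10× the mean spectral power, otherwise the period is undefined
(white noise fails this test by a wide margin).

**Delay estimation.** Pearson correlation of ⟨τ⟩(t − Δ) against
d⟨a⟩/dt(t) (central differences of the radius trend), Δ scanned over both
signs at cadence resolution; the argmax is reported with its peak value
and a significance flag (threshold 0.5, configurable). Ties break toward
the smallest |Δ|. Differencing amplifies any peristaltic residue that
survives the trend average, and the lag scan can then lock onto the
contraction period; re-smoothing the rate series with the same centred
window suppresses this without adding lag (symmetric filters are
zero-phase), and the estimator exposes it as `derivative_smooth_s`. On
driven synthetic veins the estimator recovers delays of 1–3 min with a
mean absolute error below one 6 s cadence step; with a first-order sensing
filter the cross-correlation lag equals t_delay only up to
O((ω t_delay)²) for excitation at frequency ω, which is why the benchmark
generator drives the loop slowly (1 h period) — a real limitation to keep
in mind for strongly excited veins.

**Classification.** A trajectory is *shrinking* if the radius trend ends
below 0.25× its start or reaches a_min; the sub-label comes from the sign
structure of the smoothed shear trend (monotonic decrease / increase;
non-monotonic = exactly one interior maximum). It is *stable* if the net
radius drift stays below 0.2× the mean, with the loop orientation from
the shoelace signed area of the (⟨a⟩, ⟨τ⟩) polyline (negative =
clockwise). Records shorter than 15 min (configurable) are
unclassifiable. These thresholds are package defaults exposed in
`ClassifyConfig`; the census criteria of the underlying experiments are
not published, so absolute census fractions should not be compared
against this package's labels without calibrating them.

## Model fitting

The fit takes ⟨τ⟩(t) as exogenous input, integrates the sensing equation
with an exact exponential integrator on the piecewise-linear input, and
obtains ⟨a⟩(t) in closed form as a0·exp(∫(τs²/τ0² − 1)dt/t_adapt)
(trapezoidal quadrature). The objective is the paper-of-record metric for
this field's trajectory fits, the relative L1 error
ε_err = (1/T_obs)∫|⟨a⟩ − ⟨a⟩_fit|/⟨a⟩ dt, which is dimensionless and
invariant to radius rescaling. Optimisation is derivative-free
Nelder–Mead (the objective is non-smooth) over (log t_adapt, log τ0
[, t_delay]) with 8 log-spaced multistarts; bounds t_adapt ∈ [1, 1000]
min, τ0 ∈ (0.01, 100] s⁻¹, t_delay ∈ [0, 15] min are enforced by
penalty-plus-clipping, so reported parameters always lie inside them. The
initial sensed shear is set to the first observed ⟨τ⟩ value (the internal
state is unobservable). The delay is either held fixed (a per-vein
cross-correlation estimate or an ensemble mean) or fitted. On seeded
synthetic ensembles spanning t_adapt = 10–100 min the median parameter
recovery error is ≈ 1–3 % and ε_err lands in 0.004–0.01 at the default
noise levels; fits of delayed data with the delay forced to zero are
consistently worse.

## Pruning avalanches

A vein with R/R_net > 1 dissipates more than rerouting its flow through
the rest of the network would; `prune_step` removes the single vein with
the largest such ratio (one removal per step — simultaneous removal could
skip the cascade structure; ties break toward the smallest vein id).
After a removal, veins meeting in series at a freed degree-2 node merge:
lengths and resistances add, the effective radius follows from inverting
R = 8μL/(πa⁴) (the viscosity cancels), and ε and T inherit
length-weighted means. A merge that would create a self-loop removes both
veins instead. Frozen edges — the abstract rest-of-network resistor of
the region fixture — are exempt from both removal and merging.

The minimal region fixture (documented in `region_fixture`) anchors six
similar veins, including a parallel *path* pair (a direct vein against a
two-vein chain) and a shortcut loop, to a backbone resistor
R_rest = r/0.1. A note on its design: a true multigraph parallel pair of
comparable resistances r1 ≤ r2 always gives the larger vein
R/R_net ≥ r2/r1 ≥ 1, so a literal parallel edge pair cannot appear inside
an all-stable region — the fixture's parallelism is therefore a pair of
parallel paths. Doubling one vein's resistance drives its ratio above 1
while all unperturbed region veins stay strictly below; the subsequent
removal-plus-merge raises the merged neighbour's ratio above 1 (it lands
in parallel with the shortcut), producing a two-removal cascade whose
per-step ratio maps the tests replay against a dense pseudoinverse
oracle. The guarantees hold across r/R_rest ∈ [0.01, 0.5] and are
verified at construction. A separate parallel-pair fixture shows the rare
opposite effect: a removal that *lowers* a neighbour's ratio back below
threshold.

## Synthetic data

The generator emulates the statistical structure of whole-network
bright-field measurements: jittered-grid planar-ish multigraphs
(guaranteed ≥ 1 loop, ≥ 1 dangling end, ≥ 1 true parallel pair for ≥ 12
nodes), log-uniform radii in 5–70 μm, lengths from node geometry,
peristaltic series a(t) = ⟨a⟩(t)(1 + ε sin(2πt/T + φ)) with ε = 0.05,
T = 100 s, 6 s cadence, i.i.d. uniform phases, and additive Gaussian
noise of 1 % of the mean radius; the default duration is one hour,
matching the 10–60 min trend analyses the pipeline targets. All
randomness derives from one integer seed. What it does **not** emulate:
travelling contraction waves (phases are independent — time-averaged
analyses are insensitive to phase structure, which is what the package
tests), vessel-wall viscoelasticity, viscosity aging, parameter drift
within a recording, and segmentation artefacts of real imaging. Passing
tests on this generator therefore validates the analysis machinery, not
the biology of any particular specimen.

`generate_vein_benchmark` provides estimator ground truth in two modes:
*driven* (default) — an exogenous slow sinusoidal shear modulation (10 %
amplitude, 1 h period, 3 h duration) around τ0, filtered through the
sensing equation, with the first 15 min (sensing transient) discarded —
and *autonomous*, the closed-loop decaying-spiral / shrinkage dynamics
from `simulate_vein`. Problem sizes in the tests and the acceptance
script (10-node flow graphs, 6–8-vein dynamical fixtures, ensembles of
8–20 veins) were chosen so the full suite completes in about a minute
while every property is exercised at meaningful size.

## Known limitations

- Quasi-static laminar flow only; no unsteady Stokes or inertial
  corrections, no viscoelastic walls.
- Only the quadratic shear-response kernel is implemented; robustness to
  other monotone kernels with a Murray zero is not exercised.
- t_adapt and τ0 are constants per simulation; slow drift of either (as
  expected over ≳ 40 min in reorganising specimens) is out of scope, and
  fitting windows beyond ~40 min should be treated with caution.
- The cross-correlation delay estimate inherits the first-order filter's
  O((ω t_delay)²) bias under fast excitation.
- Experimentally reported census fractions and fit values depend on the
  underlying microscopy datasets and are not reproduced at desk scale;
  the package's synthetic conditions are calibrated to the reported
  parameter scales instead.
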
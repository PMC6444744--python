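# Methods

## Signal model

The micro-resonator is a damped harmonic oscillator. A trapped DNA bundle
adds stiffness `K_DNA` and viscosity `η_DNA` in parallel with the bare device
(`K_T`, `η_T`), shifting the resonance frequency and quality factor:

    K_DNA = K_T (F² − F_T²) / F_T²
    η_DNA = (K_T + K_DNA) / (2π Q F) − η_T

`F_T` and `Q_T` are the calibrated reference response of the bare device in
its operating medium; immersion and meniscus effects are folded into this
reference, so no separate meniscus term is modelled, and the effective mass
never appears (it cancels out of both relations). The `2π Q F` denominator
takes `F` in Hz exactly as written; there is no rad/s variant. The forward
model is the exact algebraic inverse (`F = F_T √(1 + K_DNA/K_T)`,
`Q = (K_T + K_DNA)/(2π F (η_T + η_DNA))`), and a property test pins the
round trip to 1e−10 relative over the physical range.

Noisy traces can extract a slightly negative `K_DNA` when `F` dips below
`F_T`. These values are returned unclamped with a warning: clamping would
bias averages of repeated extractions.

Defaults `F_T = 1000 Hz` and `η_T = 1e−5 N·s/m` (hence `Q_T ≈ 398`) are
package configuration, chosen as typical MEMS-resonator values; only
`K_T = 25 N/m` is anchored to the reference device. None of the downstream
inference depends on these two defaults — stiffness extraction uses only
`K_T` and the frequency ratio.

## Break kinetics

Irradiation creates double-strand breaks at a constant rate `b` (breaks/s)
across the bundle while broken fragments re-link pairwise (knotting,
sticking), a second-order loss A + A → B: one new link consumes two free
ends, so links appear at half the rate ends disappear. The net break count
obeys

    dN/dt = b − b β N²,   N(0) = 0
    N(t)  = tanh(b √β t) / √β,   N(∞) = 1/√β

`β` is the dimensionless healing coefficient; the kinetic constant of the
quadratic term is `w = β b`. `N` is a real-valued expectation; integer
realizations live in the network module. The closed form is verified against
adaptive Runge–Kutta integration of the ODE to 1e−6 relative over random
parameter pairs, and `β = 0` is handled as the constant-rate limit `N = bt`.

The dose anchor: a cell receives ~40 double-strand breaks per gray on a
genome of 3×10⁹ base pairs at 3.4 Å spacing (≈1.02 m of DNA). A trapped
bundle of total length `M·l = 0.03 m` therefore receives ≈1.2 breaks/Gy, and
120 Gy delivered over 1375 s implies `b ≈ 0.1 /s`. A bare bundle in solvent
is far less protected than chromatin, so the operating value is `b = 1 /s`.
Both the 1375 s "total irradiation time" convention used in that arithmetic
and the cumulative beam-on convention (4×210 = 840 s) are available;
kinetics composed with a schedule always run on cumulative beam-on time,
frozen during the recovery gaps (the default assumption; whether healing
continues in gaps is untestable from stiffness traces that are flat there).

## Degradation law

At low break density the effective stiffness of `M` coupled parallel fibers
decays exponentially in breaks per fiber:

    k_eff(N) = M (E A / l) exp(−φ(α) N / M)

with single-molecule stiffness `E A / l` (reference values: `E = 350 MPa`,
`A = 3.2e−18 m²`, `l = 15 µm`, giving 7.47e−5 N/m, and `M = 1800` from the
ratio of initial bundle stiffness 0.1344 N/m to the single-molecule value).
`A` defaults to `πR²` but is an explicit input: all reference-value checks
use the rounded 3.2e−18 m² so printed numbers reproduce exactly. A soft
warning flags `N/M > 1`, outside the law's validity domain. `φ` is stored as
a scalar at the operating coupling; its functional dependence on `α` is only
accessible empirically through the network module.

Composition with the kinetics gives
`k_eff(t) = k₀ exp(−φ tanh(b√β t)/(M√β))`, initial slope
`dk_eff/dt(0) = −(EA/l) φ b` (independent of `β` and `M`), and long-time
plateau `k₀ exp(−φ/(M√β))`.

## Spring-network oracle

Each fiber is a chain of `n_seg` equal springs (segment stiffness
`n_seg·k_chain` so the intact chain has `k_chain = EA/l`); lateral coupling
springs `c` join corresponding interior nodes of adjacent chains in a 1-D
nearest-neighbour arrangement — the minimal geometry consistent with a
confined bundle, and the abstraction that also subsumes loose-end sticking
and knotting. Breaks delete segments uniformly at random without
replacement. Only the static elastic response is computed (dash-pot
viscosity does not affect quasi-static stiffness): unit displacement on all
left ends, right ends clamped, interior equilibrium solved as a sparse SPD
system, reaction force summed at the driven side. Graph components that
touch neither boundary are pruned before the solve, so floating fragments
never produce a singular system. A hand-solved two-chain instance
(`k_eff = 4k(k+c)/(4k+3c)`, equal to 8/7 at `k = c = 1`) pins the assembly
to 1e−12, including its `c = 0` and `c → ∞` limits.

`estimate_phi` regresses the replicate-mean `log(k_eff/k₀)` on `N/M`;
`φ̂ = −slope` with its regression standard error. At moderate coupling the
relation is linear to R² > 0.99 up to `N/M = 0.5`, supporting the
exponential law, and `φ̂` is order unity (≈0.75 at `c = 0.5·k_chain`,
`n_seg = 4`), consistent with the operating value 0.7.

Units: `α = k_int l²/E` is not dimensionless if `k_int` has spring-constant
units, so the package reports the convention `α = c·n_seg·l/(E·A)` — the
total lateral coupling stiffness along one chain over the fiber's axial
stiffness. This is a package convention, flagged as such, not a measured
fact. `n_seg` is a sensitivity parameter (the break-position distribution
along a molecule is unknown; uniform over segments is assumed).

## Inference

Only `φ·b` and `b√β` enter the decay law, so `b` is not separately
identifiable from a stiffness trace; it is a fixed input (default 1/s) and
`φ` is reported at that value. The reference procedure is two-step:

1. **Slope step** — linear least squares of `k_eff` over the first
   `window` seconds of beam-on time, scaled by `−l/(EA)`, estimating `φ·b`.
   Default window 20 s (≈2% of the saturation timescale `1/(b√β) ≈ 1111 s`).
2. **β step** — nonlinear least squares (lmfit/Levenberg–Marquardt, unit
   weights) of the full decay law with `φ = φb/b` fixed; `β` free in
   (0, 1], started from the apparent saturation drop when visible and from
   1e−6 otherwise; `k₀` pinned to `M·EA/l` by default or optionally freed.

A bias–variance analysis of the slope step motivates the default third
stage: the exponential curvature biases a linear slope by ≈2e−4 per second
of window, while the slope noise scales as `window^(−3/2)`, so no window is
simultaneously unbiased and quiet at realistic noise. `fit()` therefore
refines `(φ·b, β)` jointly by least squares from the two-step solution
(`refine=True`, the default), using the slope step only as an initializer;
if the noisy slope comes out nonpositive, the joint fit starts from the
whole-trace mean log decay instead. The Monte-Carlo harness
(`recovery_experiment`) measures the consequence at the reference operating
point: with default noise the refined pipeline recovers `β` within ~2%
across 50 seeded replicates, whereas the unrefined two-step is
noise-dominated. A short trace that never bends toward saturation
(`b√β·T ≪ 1`) leaves `β` weakly identified; this is surfaced as a large
reported standard error plus a warning, never a silent fallback.

## Synthetic data

The generator emulates the fractionated irradiation runs: stiffness follows
the decay law on cumulative beam-on time (flat in the 180 s recovery gaps),
is pushed through the forward oscillator model, and receives Gaussian noise
on the frequency *shift* (so noise scales with the DNA signal, emulating
PLL jitter) and on `Q`. Defaults: 1 Hz sampling (tracking cadence is a
package choice), relative shift noise 0.0019 — about 0.005 Hz sd, i.e.
~0.02 Hz peak-to-peak, on the ≈2.7 Hz initial shift of the reference
bundle, comfortably inside the 0.1 Hz worst-case charge-accumulation drift
observed at large collimator apertures; a linear dose-proportional drift
term is available and off by default (small apertures keep drift inside the
PLL noise). `η_DNA` is held constant during degradation: only stiffness
degradation is modelled, and a hook (the `eta_dna` argument) exists for a
future viscosity model.

What the generator does *not* emulate: dielectrophoretic trapping
transients, meniscus/humidity effects, charge-accumulation artefacts beyond
the linear drift term, in-air vs in-water stiffness regimes (only the
in-water operating point is parameterised by default), and any viscosity
time course. Passing tests therefore demonstrate correctness of the
numerical chain and identifiability under the stated noise model — not
robustness to these unmodelled instrumental effects.

## Numerical choices

- Kinetics ODE oracle: RK45, rtol 1e−11/atol 1e−12, far tighter than the
  1e−6 contract it certifies.
- Network solve: chain-major node ordering, sparse COO→CSC assembly,
  `spsolve`; tiny negative reaction forces from round-off are clamped to 0.
- `β` bounded in (1e−14, 1]; saturation-based start
  `β₀ = (φ/(M·log(k₀/k_min)))²` clipped into bounds.
- Trace CSV I/O writes full `repr` precision and parses with C-locale
  `float()`, so read∘write is exact and locale-independent; malformed rows
  fail with the line number.
- Degenerate inputs: `β = 0` saturation returns +inf with a warning;
  `k₀ = 0` molecule-count estimates return 0 with a warning; all-zero break
  sweeps return `φ̂ = 0` rather than a degenerate regression.

## Problem sizes

Tests and the acceptance script use the reference protocol (840 beam-on
samples at 1 Hz), 50-replicate Monte-Carlo batches for recovery statistics,
and network bundles of M ≤ 200 chains with n_seg ≤ 4 — sizes at which the
sparse solves and fits are essentially instantaneous while leaving the
Monte-Carlo standard errors well below the tolerances being checked.

## Known limitations

- `φ(α)` is treated as a scalar at the operating point; mapping the full
  universal curve `φ(·)` would require a systematic network sweep study.
- The exponential law is used outside its strict derivation regime once
  `N/M` approaches 1 (soft warning only).
- `b` is a convention, not an estimate; all reported `φ` values scale as
  1/b.
- The network's 1-D nearest-neighbour coupling is the minimal choice; real
  bundles are 3-D with heterogeneous coupling.
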
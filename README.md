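# radbundle

Real-time mechanics of X-ray-degraded DNA bundles, measured with a
silicon-nanotweezer (SNT) micro-resonator.

A bundle of roughly parallel λ-phage DNA molecules trapped between the tips of
an SNT adds a stiffness `K_DNA` and viscosity `η_DNA` to the device's damped
oscillator (bare stiffness `K_T = 25 N/m`). Tracking the resonance frequency
`F` and quality factor `Q` in real time during therapeutic X-ray irradiation
therefore reads out the bundle's mechanical degradation as double-strand
breaks accumulate. `radbundle` implements the full quantitative chain from
the raw `(t, F, Q)` trace to kinetic parameters:

- **Oscillator model** — `K_DNA = K_T (F² − F_T²)/F_T²` and
  `η_DNA = (K_T + K_DNA)/(2π Q F) − η_T`, with exact inverses used by the
  simulator.
- **Break kinetics** — breaks are created at rate `b` and self-heal pairwise
  (A + A → B), giving `dN/dt = b − b β N²` with solution
  `N(t) = tanh(b√β t)/√β` and saturation count `1/√β`; `β` is the healing
  coefficient.
- **Degradation law** — a bundle of `M` fibers (modulus `E`, cross-section
  `A`, length `l`) with `N` random breaks has effective stiffness
  `k_eff = M (EA/l) exp(−φ N/M)`, where `φ(α)` is a universal decay value set
  by the inter-fiber coupling `α`. Composed with the kinetics:
  `k_eff(t) = M (EA/l) exp(−φ tanh(b√β t)/(M√β))`, with initial slope
  `dk_eff/dt(0) = −(EA/l) φ b`.
- **Spring-network oracle** — a brute-force coupled-chain spring model
  (random segment removal, sparse static equilibrium solve) that validates
  the exponential law and estimates `φ` at a given coupling.
- **Inference** — `BundleDegradationModel` / `BundleDegradationResults`
  (statsmodels-style): an initial-slope estimate of the product `φ·b`, a
  nonlinear least-squares fit of `β`, and a joint refinement; plus a seeded
  Monte-Carlo recovery harness.
- **Synthetic data** — a seeded generator emulating fractionated irradiation
  runs (four 210 s sessions of 30 Gy with 180 s recovery gaps; stiffness
  decays on cumulative beam-on time and is frozen in the gaps) with Gaussian
  PLL noise, so the whole pipeline is testable without instrument data.

## Worked example

Simulate a realistic noisy run at the reference operating point
(`M = 1800`, `E = 350 MPa`, `A = 3.2 nm²`, `l = 15 µm`, `b = 1 /s`,
`β = 8.1e−7`, `φ = 0.7`) and fit it back:

```python
import radbundle as rb

device   = rb.DeviceParams()                      # K_T = 25 N/m, F_T = 1 kHz
geom     = rb.BundleGeometry.reference()
kin      = rb.KineticsParams(b=1.0, beta=8.1e-7)
deg      = rb.DegradationParams(phi=0.7)
schedule = rb.make_schedule(4, 210.0, 180.0, 30.0)  # 4 x 30 Gy, 180 s gaps

trace = rb.simulate_trace(device, geom, kin, deg, schedule,
                          noise=rb.NoiseModel(), seed=42)
model = rb.BundleDegradationModel.from_resonance(trace, schedule, device, geom)
res = model.fit()
print(res.summary())
```

```
Bundle degradation fit
======================================================
observations                    840
trace span (beam-on s)        839.0
break rate b (fixed)              1  1/s
slope window                   20.0  s
joint refinement               True
k0 (pinned)              1.3440e-01  N/m
------------------------------------------------------
phi*b                        0.7011  1/s  (+/- 0.00069)
phi (at b fixed)             0.7011
beta                     8.1914e-07  (+/- 8.22e-09)
saturation breaks            1104.9
------------------------------------------------------
residual norm            6.2594e-03
converged                      True
```

The fit recovers the generating decay-rate product `φ·b` (0.701 vs 0.7) and
healing coefficient `β` (8.19e−7 vs 8.1e−7) from 840 one-hertz samples; the
implied saturation count `1/√β ≈ 1105` breaks is the level at which
self-healing balances break creation. `res.plot_fit()` overlays data and
model on the cumulative beam-on axis.

The same pipeline is scriptable from a shell (`radbundle simulate / extract /
fit / network / recover`, all driven by one YAML config plus `--seed`).

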
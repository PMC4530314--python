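# Methods

This note documents the model implemented by `dendtf`, its assumptions, the
parameter choices that matter, and the design decisions taken where more than
one reasonable implementation existed.

## Model and assumptions

The package computes peak somatic EPSPs from a fast–slow separation of
dendritic dynamics.  Three currents are considered: fast ionic currents
(treated as instantaneous and passive), the ohmic leak, and a slow
NMDAR-mediated current.  The separation rests on three empirical time-scale
facts: fast channels relax orders of magnitude quicker than NMDARs; NMDAR
opening and Mg²⁺ unblocking are orders of magnitude quicker than closing; and
the macroscopic NMDAR current is carried by bursts/super-clusters far longer
than individual openings.  The NMDAR system is therefore treated as binary
(closed, then open), with *expectations* over single-channel dwell-time
distributions replacing explicit time courses:

1. **Before opening** a site's local input decays through the leak with
   expected factor `φ = Σ θ_i τ_m/(τ_i + τ_m)` (closed-time mixture `θ_i, τ_i`;
   `τ_m = R_m C = 10 ms`).  Nonlocal input arrives spatially attenuated by
   `exp(−Δx/λ_eff)`.  These constants form the decay matrix `Φ`, and the
   opening potentials are `V₀ = Φ v` — one matrix–vector product.
2. **While open**, only leak and NMDAR currents flow.  Because the steepened
   blockade makes `B(V)` nearly a step away from its midpoint, the blockade is
   frozen at `B(V₀)`; the membrane equation becomes linear and relaxes toward
   `Veq(V₀) = gE·B(V₀)/(g·B(V₀)+R⁻¹)`.  Averaged over a mixture-exponential
   burst length `(ω_i, a_i)` this gives the closed-form expected NMDA
   component (`expected_vnmda`); the infinite-burst limit is the "Simple
   Model" sigmoid (`simple_vnmda`).  This freezing is valid only for deciding
   *which equilibrium* the site approaches — it is not a time-course model.
3. **After closing**, components propagate to the soma with weights
   `δ_i = exp(−x_i/λ)` and are summed under the soft boundary `G`, which
   mimics branch saturation (no summed response meaningfully exceeds the
   NMDAR reversal).

The frozen-blockade step requires bistability of the reduced membrane.  With
only leak + NMDAR retained, the standard blockade slope (k = 12.5 mV) yields a
single, almost always spike-like equilibrium — glutamate binding would always
spike, which is pathological.  The slope is therefore steepened five-fold
(k = 2.5 mV) to restore the threshold nonlinearity contributed in vivo by the
omitted voltage-gated Na⁺/Ca²⁺ currents.  The package's bistability analysis
(`find_equilibria`, `rest_spike_threshold_conductance`) quantifies exactly
this: with k = 2.5 mV and g = 3.9 nS the net-current curve crosses zero three
times, while with k = 12.5 mV the single equilibrium is spike-like for all
conductances above ≈ 0.12 nS (and no conductance in (0, 100] nS is bistable).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `rm_specific` | 10 | kΩ·cm² | specific membrane resistance |
| `c_specific` | 1 | μF/cm² | specific capacitance (τ_m = 10 ms) |
| compartment | 10 × 1 | μm | cylinder per input site; lateral area only |
| `g` | 3.9 | nS | max NMDAR conductance of a segment |
| `e_nmda` | 70 | mV | NMDAR reversal, rest-translated (0 mV absolute) |
| `v_mid` | 46.3 | mV | Mg²⁺ blockade midpoint, rest-translated (−23.7 mV) |
| `k` | 2.5 | mV | blockade slope; 12.5 mV is the standard value |
| `lambda_to_soma` | 77 | μm | functional length constant, basal spikes → soma |
| `lambda_back` | 138 | μm | back-propagation constant (asymmetric option) |
| `spike_lambda_fraction` | 0.5 | — | spike-generation λ is half the functional λ |
| boundary | ±12 (±16.5 paired-pulse) | mV | branch saturation bounds, α = 0.5 /mV |

Unit system: mV, ms, nS, GΩ, pF, pA, μm (mV/GΩ = nS·mV = pA).  Absolute
quantities derive from specific constants via the lateral cylinder area
π·d·L; dimensionless `g·R` products use the segment's absolute input
resistance (31.83 GΩ for the default compartment).  The half-λ rule for spike
generation makes the spike threshold's dependence on electrode spacing much
stronger than passive attenuation over the same distance, as observed
experimentally.

**Dwell-time mixtures.**  The recombinant NR1a/NR2A multi-exponential tables
this parameterisation points at are not redistributable here, so the packaged
defaults are *synthetic approximations* with the right structure: a
closed-time (inter-opening) mixture with a dominant sub-millisecond component
plus 1.5 and 6 ms components, and a burst/super-cluster mixture with 0.8, 7
and 60 ms components weighted toward slow charge carriers.  Filtering removes
opening components < 0.5 ms (giving nonlocal input time to arrive) and burst
components < 2 ms (emphasising the slow components that carry most charge),
then reweights to unit mass.  All quantitative claims in the tests use either
single-exponential or explicitly stated mixtures; the defaults only shape the
qualitative protocol replications and are fully user-overridable in YAML.

**Kinetic scheme.**  The 5-state validation model (C0↔C1↔C2↔O with a
desensitised branch C2↔D) uses the published NMDA rate set it mirrors
(binding 5 /mM/ms; unbinding 0.0129, desensitisation 0.0084, resensitisation
0.0068, opening 0.0465, closing 0.0738 /ms), 1 mM glutamate for 10 ms with
the membrane clamped at the initial depolarisation, then 40 ms free running;
single-site conductance 0.6 nS.  The transfer-function conductance used in
the comparison is the kinetic conductance *weighted by the peak open
probability* (≈ 0.31, so g_tf ≈ 0.19 nS): the transfer function's `g·B(E−V)`
must equal the kinetic `g_kin·P_open·B(E−V)` at the current's peak for the
two descriptions to refer to the same macroscopic current.  With that
equivalence the kinetic spike plateau and the Simple-Model plateau agree to
≈ 2 %.

## Numerical choices

* Equilibria: 5000-point sign scan over [−5, 75] mV, Brent refinement to
  |I| < 1e−9 pA; stability from the sign of the net-current slope (central
  difference, h = 1e−6 mV).  The conductance transition bisects to 1e−4 nS,
  classifying "spike-only" as *all* equilibria above the blockade midpoint, so
  in a bistable window it returns the lower boundary of spike-only behaviour.
* `boundary_G` is evaluated via softplus/log-sum-exp and is overflow-safe for
  arbitrarily large |V|; logistic arguments elsewhere are clamped at ±700.
* Kinetic integration: LSODA, rtol 1e−8 / atol 1e−10, output every 0.05 ms;
  occupancy conservation holds to < 1e−8 by construction of the generator
  matrix.
* Degenerate inputs: equal site positions are rejected (strictly increasing
  along the branch); zero-distance attenuation is exactly 1; sites with zero
  stimulus receive no NMDA component (no glutamate, unbound receptors).
* Weights of dwell-time mixtures are renormalised at construction, so raw
  amplitudes may be supplied.

## Design decisions

* **`nmda_component = "total"` by default.**  In the branch transfer the
  per-site nonlinear term is the full frozen-blockade expectation of the local
  potential, added to the separately attenuated linear term.  A `"relative"`
  switch substitutes the relative-spike form `(sat − V₀)·σ(·)` used by the
  boundary-free single-synapse transfer, for users who prefer the
  excess-over-opening-potential reading.
* **Spike and linear components share δ_i** by default; differential spatial
  decay of spikes vs. subthreshold EPSPs is available by constructing a
  geometry with a different `lambda_to_soma` for the caller's own composition.
* **Boundary calibration is a check, not a solver**: `check_boundary_saturation`
  warns when one full-amplitude spike from the most proximal site fails to
  reach 95 % of b_U, rather than silently re-fitting the boundary.
* **Paired-pulse facilitation** is modelled *only* through the two documented
  mechanisms — primed synapses use the unfiltered opening distribution
  (faster expected opening → less leak decay → higher V₀) and the wider
  ±16.5 mV boundary.  No glutamate-dependence or residual-depolarisation model
  is layered on top, keeping the single-/paired-pulse contrast attributable.
* **Stimulus grid.**  Protocol stimuli are induced local depolarisations, both
  electrodes equal, default 0–50 mV in 1 mV steps.  With λ = 77 μm and the
  200 μm proximal distance this local range maps onto a 0–12 mV somatic
  "expected" range — the scale on which the saturation bounds are defined.
  The supra-linearity threshold detector (first level with actual − expected
  > 2 mV) is a configurable convention; the comparisons used are ordinal.
* **Inter-branch summation** is plain addition of per-branch transfer outputs
  (`sum_branches`), with no further transformation.

## What the simulated protocols do and do not show

The experiment module reproduces the *structure* of the classical focal
dual-electrode protocols: identical stimuli at two sites, expected = sum of
individual somatic peaks, actual = simultaneous response.  Passing tests show
the mechanism produces the right phenomenology — near-linear summation at
200 μm spacing, a supra-linearity threshold that falls as electrodes approach,
a paired-pulse threshold below the single-pulse one, and the "linear hook"
(linear, then a supra-linear hump, then compression at saturation).  They do
not certify quantitative agreement with any empirical recording: real basal
dendrites add voltage-gated Na⁺/Ca²⁺ currents, intracellular Ca²⁺ dynamics,
capacitive interactions between spikes, branched-tree loading and synaptic
noise, none of which are modelled.  Likewise the kinetic comparison validates
the internal time-scale-separation assumptions against a finer-grained model
of the *same* reduced membrane, not against biology.

## Problem sizes

Everything here is desk-scale by design: equilibrium scans use 5000-point
grids; the kinetic comparison runs 15 simulations of 50 ms; the protocol
tables use 51 stimulus levels × 3 spacings; Monte-Carlo oracles in the test
suite use 10⁵ draws.  The full test suite runs in a few seconds.

## Known limitations

* The transfer function is a peak-EPSP map; it carries no time-course
  information and must not be used to approximate voltage trajectories.
* The frozen-blockade expectation is accurate only with a steep blockade and
  opening potentials away from the midpoint; near threshold the Distribution
  model over-predicts relative to the kinetic model (visible in
  `compare_models`), exactly the regime the Simple Model handles better.
* One branch path is modelled; sibling branches sharing current are out of
  scope (branches combine only by linear summation at the soma).
* The shipped dwell-time mixtures are structural stand-ins, not fits to
  single-channel records.
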
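# Default parameter set for dendtf.
#
# Membrane constants follow the standard basal-dendrite parameterisation:
# Rm = 10 kOhm cm2, C = 1 uF/cm2, 10 um x 1 um compartments, g_NMDA = 3.9 nS,
# E_NMDA = 70 mV and V_mid = 46.3 mV on the rest-translated scale, and a
# five-fold steepened Mg2+ blockade slope (k = 2.5 mV) so that the reduced
# leak+NMDAR membrane is bistable.
#
# The dwell-time mixtures below are editable SYNTHETIC approximations of
# recombinant NR1a/NR2A single-channel statistics (the exact published
# multi-exponential tables are not shipped): an inter-opening (closed-time)
# mixture with sub-millisecond and slower components, and a burst/super-
# cluster length mixture dominated by slow components.  Filtering removes
# opening components < 0.5 ms and burst components < 2 ms, then reweights.

membrane:
  rm_specific: 10.0          # kOhm cm2
  c_specific: 1.0            # uF/cm2
  compartment_length: 10.0   # um
  compartment_diameter: 1.0  # um
  g: 3.9                     # nS
  e_nmda: 70.0               # mV, rest-translated
  v_mid: 46.3                # mV, rest-translated
  k: 2.5                     # mV (standard slope is 12.5)

geometry:
  positions: [200.0, 230.0]  # um path distance from soma
  lambda_to_soma: 77.0       # um, functional length constant toward the soma
  lambda_back: null          # um; null -> symmetric (= lambda_to_soma)
  spike_lambda_fraction: 0.5 # spike-generation lambda is half the functional one

boundary:
  b_l: -12.0   # mV
  b_u: 12.0    # mV
  alpha_l: 0.5 # 1/mV
  alpha_u: 0.5 # 1/mV

distributions:
  opening_full:              # closed times prior to opening (synthetic)
    weights: [0.55, 0.30, 0.15]
    time_constants_ms: [0.15, 1.5, 6.0]
  opening_min_tau_ms: 0.5
  burst_full:                # burst / super-cluster lengths (synthetic)
    weights: [0.40, 0.35, 0.25]
    time_constants_ms: [0.8, 7.0, 60.0]
  burst_min_tau_ms: 2.0

transfer:
  model: simple              # simple | distribution
  nmda_component: total      # total | relative

pattern:
  v0: [20.0, 20.0]           # mV local depolarisation per site

kinetic:
  rb: 5.0            # /mM/ms
  ru: 0.0129         # /ms
  rd: 0.0084         # /ms
  rr: 0.0068         # /ms
  ro: 0.0465         # /ms
  rc: 0.0738         # /ms
  glut_concentration: 1.0    # mM
  pulse_duration: 10.0       # ms
  g_kin: 0.6                 # nS
  t_end: 50.0                # ms

experiment:
  proximal_distance_to_soma: 200.0   # um
  spacings: [20.0, 60.0, 200.0]      # um inter-electrode spacings
  stimulus_grid: {start: 0.0, stop: 50.0, step: 1.0}  # mV local, per electrode
  model: simple
  symmetric_decay: true
  lambda_back_asymmetric: 138.0      # um, back-propagation length constant
  threshold_criterion_mv: 2.0        # actual - expected level defining supra-linearity
  ppf:
    enabled: false
    isi_ms: 20.0
    spacing_um: 30.0
    boundary: {b_l: -16.5, b_u: 16.5, alpha_l: 0.5, alpha_u: 0.5}
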
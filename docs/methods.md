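# Methods

## The model

`kv4pace` implements a multicompartment conductance-based model of a
substantia nigra pars compacta (SNc) dopaminergic neuron and the analysis
pipeline built around it.  Each compartment obeys

    Cm dV/dt = - sum_i g_i m_i^a h_i^b (V - E_i) - I_axial + I_stim

with six active conductances — fast sodium (I_Na), delayed-rectifier
potassium (I_KDR), A-type potassium (I_A), hyperpolarization-activated cation
(I_H), L-type calcium (I_CaL) and SK calcium-gated potassium (I_SK) — plus an
ohmic leak.  Gates follow first-order Hodgkin–Huxley kinetics with Boltzmann
steady states; every Boltzmann parameter, time-constant closed form and
region-specific maximal density lives in one machine-readable file,
`src/kv4pace/data/channels.json`, so any constant can be audited or corrected
in one place.  Sign convention: membrane currents are outward-positive,
everywhere.

Distinctive couplings of the A-type current:

* activation is 50× faster than inactivation (tau_m = tau_h / 50) and its
  half-activation voltage sits 50 mV above the half-inactivation voltage;
* the I_A half-inactivation voltage co-varies with the I_H half-activation
  voltage: V50_inact(I_A) = 0.814 · V50_act(I_H) + 3.36 (mV).  Over the I_H
  grid (−100 to −80 mV) this induces the I_A window −78.0 to −61.8 mV.

Channel placement: soma, dendrites and the axon-start section carry the full
complement; the AIS and axon carry only Na, KDR (at 4000/4000 and 400/400
pS/µm²) and leak, which makes the action potential initiate in the AIS — a
property the tests assert by comparing threshold-crossing times at the AIS
and somatic recording sites.

Passive properties: axial resistivity 150 Ω·cm, specific capacitance
0.75 µF/cm², specific membrane resistance 100 kΩ·cm² (leak density
0.1 pS/µm²), leak reversal −50 mV.

### Two constants worth flagging

* The I_H activation time constant is `556 + 1100·exp(−0.5·(V/11.06)²)` ms
  with no voltage offset, i.e. its Gaussian term is centred at 0 mV and the
  value is effectively ~556 ms at physiological potentials.
* The adopted L-type and SK densities are g_CaL = 1 pS/µm² and
  g_SK = 0.125 pS/µm² (somatodendritic only).  Both sit in the defaults file
  so a single edit changes them everywhere.

## Numerics

* **Integration.**  Backward-Euler implicit step: conductances frozen at the
  current gate states, the branched-cable linear system solved by
  Hines-ordered tridiagonal elimination (parents precede children in the
  compartment arrays), then gates advanced by their exact exponential update
  m' = m∞ + (m − m∞)·e^(−dt/τ) at the new voltage (first-order staggering).
  Unconditionally stable at the working step dt = 0.02 ms; the test suite
  pins a passive-RC oracle to < 0.5 % and post-stabilization ISI changes to
  < 1 % under dt halving.
* **Tabulated kinetics.**  Steady states and exponential gate factors are
  pre-tabulated on a 0.05 mV grid over [−150, +100] mV and linearly
  interpolated inside the numba-compiled step loop; the interpolation error
  is far below solver error and the loop runs an 8-s default-cell simulation
  (~140 compartments) in a couple of seconds on one core.
* **Calcium.**  Single-shell decay model: influx −i_CaL/(2 F d) into a shell
  of depth d, first-order return to baseline.  The constants are this
  package's own calibration: d = 1 µm, decay tau = 5 ms, baseline 50 nM —
  classic decay-model values at which SK activation is phasic
  (spike-triggered) rather than tonic.  With a thin shell / slow decay the SK current develops
  a standing subthreshold activation that traps the cell at ~−63 mV; the
  adopted constants reproduce the defining behaviours of the cell type:
  spontaneous pacemaking across the parameter grid, AIS spike initiation,
  ~30 mV sag, and rebound delays that grow with g_A and I_A tau and shrink
  with g_H.  All three constants are exposed in `CalciumModel`.
* **Discretization.**  d_lambda rule with d_lambda = 0.1 at 100 Hz (the
  standard compartmental-simulator convention; both are configurable),
  compartment counts forced odd so every section has a midpoint recording
  site.
* **Divergence guard** at |V| > 200 mV, checked every 500 steps.
* **Pulse calibration.**  The rebound protocol's pulse amplitude is bisected
  per cell and condition until the somatic peak is −120 ± 2 mV; sweep
  calibration runs use dt = 0.05 ms (the peak is smooth), final runs the
  working dt.

## Morphologies

The generator emulates the reconstructed-cell population the model database
was built on: soma diameter 25–30 µm (the electrophysiological
identification criterion), 3–6 tapering dendritic trunks with binary
branching, and an axon-start (20 µm) → AIS (30 µm) → axon (300 µm) chain.
Section dimensions are template parameters, not constants.  A fixed seed
gives a bit-reproducible population; the default 22-cell population spans a
~3-fold membrane-area range.  SWC I/O uses the standard 7-column format plus
a JSON sidecar recording the axon-start/AIS/axon distinction SWC cannot
express; without the sidecar those kinds are assigned in path order.

## Feature extraction

Spike detection: upward dV/dt crossing of 10 mV/ms, 2-ms refractory period,
spike time = AP peak; candidates rising < 20 mV above the crossing voltage,
or still rising at the end of the 10-ms peak-search window, are rejected
(this suppresses the fast passive transient at release from a
hyperpolarizing step).  CV of the ISI uses the sample SD (n−1) — pinned by a
worked-example test ({100, 200} ms → 47.14 %).  Rebound delay is measured
from stimulus offset to the first AP *peak* (robust to the threshold
criterion; censored as NaN when no spike falls in the 5-s window).  Sag is
the pulse-peak hyperpolarization minus the mean of the last 10 % of the
pulse.  Excitability definitions (start frequency = 1/first ISI, end
frequency = 1/mean of last two ISIs, gains = least-squares slope per 100 pA,
SFA = start/end at the largest step) follow the conventions of the upstream
current-clamp literature and are configurable interpretation, not asserted
against recorded values.

Voltage clamp: I_A is isolated by subtracting the −40 mV-prestep trace and
removing the residual late baseline; half-inactivation from a least-squares
Boltzmann fit of peak current vs prestep voltage; inactivation tau from a
mono-exponential fit of the decay (a relative RMS residual > 2 % of the
fitted amplitude flags multi-exponential decay); charge as the trapezoidal
integral over the 500-ms step.  I_H activation V50 is fitted on normalized
chord conductance (amplitude over driving force), steady-state convention.

## Parameter database and stacking

Four parameters, five linearly equidistributed values each (endpoints
included): g_A 15–150 pS/µm², I_A tau_h 15–150 ms, g_H 0.25–2.5 pS/µm², I_H
activation V50 −100 to −80 mV (the I_A voltage dependence rides along through
the coupling).  625 combinations × 22 morphologies = 13,750 model
specifications, enumerated in a deterministic lexicographic order.  Each
record carries mean post-stabilization ISI (first four spikes excluded) and
the calibrated-pulse rebound delay; silent and censored runs are flagged,
never dropped.  Per-combination averages over morphologies feed a 25 × 25
dimensionally stacked heatmap (outer axes g_A × V50, inner axes tau × g_H,
log10 features); the embedding is a bijection and the tests invert it
exactly.

**Problem sizes.**  The repository's analyses and acceptance checks run a
reduced sweep — 2 morphologies × the 16 grid corners, ~2 minutes on one core
— which is sufficient for the qualitative claims checked here: marginal mean
ISI and rebound delay non-decreasing in g_A, rebound delay non-increasing in
g_H, and the standardized ISI sensitivity regression ranking |coef(g_A)| and
|coef(V50)| above |coef(g_H)| and |coef(tau)|.  The full 13,750-run database
is a several-hour computation invoked the same way by widening the subset.
One caveat the corner design introduces: models at maximal g_A with the most
hyperpolarized V50 can be silent; they are censored from the rebound
averages, and under that censoring the *rebound* sensitivity regression
ranks g_H above g_A — the ISI regression is the stable ranking at this
problem size, and is what the acceptance check asserts.

## Statistics

* **Correlation.**  y ~ x is fitted by least squares; a Shapiro–Wilk test on
  the residuals gates the method (p ≥ 0.05 → Pearson, else Spearman; the
  0.05 gate is convention).  Families of correlations are
  Benjamini–Hochberg-adjusted.  BH values are monotone but not idempotent as
  numbers (step-up re-adjustment can raise them); what is stable is the
  rejection decision, and the property test asserts exactly that.
* **Best-subset regression.**  Variables are log-transformed and z-scored
  (sample SD).  Exhaustive subset search per model size, best per size by
  adjusted R² (AIC/BIC reported); the final model minimizes mean RMSE over
  20 repeats of 10-fold cross-validation with shared, seeded folds; VIF of
  retained predictors is screened at < 1.5.  A known property of min-CV
  selection, reproduced in this package's recovery simulation: it behaves
  like AIC and admits a noise predictor in roughly a third of replicates, so
  exact final-model recovery plateaus near ~50–70 % while the size-2
  best-subset stage identifies the true pair essentially always and the
  chosen model contains it in ≥ 90 % of replicates with standardized
  coefficient bias < 0.05.  The acceptance script reports all three rates.
* **Fisher exact test.**  Two-sided by direct hypergeometric summation of
  all tables with the observed margins whose probability does not exceed the
  observed one; pinned against a from-scratch enumeration oracle on all
  tables with N ≤ 30 and against the scipy/R implementations.

## Synthetic data

The population generator replaces recordings with a Gaussian copula:
log-normal marginals for positive skewed quantities (median/IQR matched in
closed form), normal marginals for half-(in)activation voltages, latent
correlations r(V50_A, V50_H) = 0.658 and r(log tau_A, log I_H amp) = −0.4
(the sign of the latter is an empirical observation in this cell type; its
magnitude is this package's configurable default).  Firing features are generated *from* the
biophysics: log-feature = µ + Σ b_j·z_j + ε with weights mirroring the
reported predictor sets (ISI: +tau, −I_H amplitude; rebound: those plus a
V50 term), rescaled so each feature's own median/IQR target is met exactly;
by default 40 % of log-feature variance is noise.  Every generator returns a
truth record sufficient to score downstream recovery, and a zero-noise draw
refits its generating coefficients exactly.

What the generator does **not** emulate: patch-clamp artifacts (series
resistance, capacitive transients), non-Gaussian copula dependence, any
within-cell longitudinal structure, or the real covariance between the
five biophysical variables beyond the two modelled correlations.  Passing
recovery tests therefore demonstrate correctness of the estimators under the
stated generative model, not robustness to real recording pathologies.

## Known limitations

* The simulator's quantitative ISI (~170 ms at grid centre for the first
  stylized cell) is faster than the recorded wild-type median (~670 ms);
  morphology, the unprinted calcium constants and the stylized dendrites all
  contribute.  Only qualitative grid trends are asserted.
* Voltage-clamp traces are generated analytically; the compartmental model
  is not voltage-clamped.
* No temperature dependence, stochastic gating, or synaptic input.
* The corner-only reduced sweep censors silent high-g_A models (see above).
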
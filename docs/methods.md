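# Methods

## The equilibrium model behind the inference

A blocker with state-dependent affinity is described by two dissociation
constants: K_r for resting (closed) channels and K_i for fast-inactivated
channels, with K_i < K_r for local-anesthetic-like block.  At a holding
potential where a fraction h of channels is inactivated, single-site
equilibrium occupancy gives an apparent constant

    1/K_app(h) = h/K_i + (1 − h)/K_r,

so block of the peak current is B = D/(D + K_app(h)).  Inverting these
relations yields the two estimators: K_r = D·(1 − B_rest)/B_rest from block
measured where h ≈ 0, and K_i from block measured where 30–50% of channels
are inactivated (the h that makes the estimator best conditioned), given
K_r and h.  B_max, the maximal block, is taken as 1 (complete block).

Because drug binding stabilizes the inactivated state by the free energy
k_BT·ln(K_r/K_i), the availability (steady-state fast-inactivation) curve
of a drugged channel shifts hyperpolarized by

    ΔV½ = −k·ln[(1 + D/K_i)/(1 + D/K_r)],

with k the availability slope factor in mV.  For two co-applied drugs the
statistical weights multiply if the sites are independent and add if the
drugs compete for one site, giving the separate-site and shared-site
predictions in the README.  Since (1 + x₁ + x₂) < (1 + x₁)(1 + x₂) for
positive occupancy factors, the shared-site shift is always the smaller in
magnitude; the classifier exploits that gap.  The verdict rule: a binding
model wins when its prediction alone falls inside the observed shift ±
1.96·SE; when the two predictions are closer than 2·SE, or when both or
neither fall inside, the result is *indeterminate* (the nearer model is
still reported).

All of these relations are equilibrium statements.  They are exact for the
synthetic data generator below (which is built from the same equilibrium
constants) and approximate for real recordings to the extent that 500 ms
conditioning prepulses and multi-second inter-sweep intervals reach
binding equilibrium.

## The synthetic-data generator

### Gating scheme

Five states, C3–C2–C1–O–I.  Activation is a three-step chain with binomial
multiplicities (an m³ gate written as a Markov chain): per-gate rates
α(V) = a₀·e^{V/V_a}, β(V) = b₀·e^{−V/V_b}.  Fast inactivation is reachable
from rest (C3↔I) and from the open state (O→I).  The C3↔I pair is
parameterized directly by the availability midpoint V_h and slope k_h: the
forward rate is f(V) = f₀·e^{V/V_f} and the recovery rate is derived so
that f/g = e^{(V−V_h)/k_h} at every voltage.  The I→O return rate is a
small fixed leak (1e−4/ms), so the gating loop is slightly irreversible —
the usual convention in Markov sodium-channel models.  Exact loop balance
would force the sustained open fraction at depolarized potentials to equal
K_act(V)/K_CI(V), which is incompatible with a deeply hyperpolarized
availability midpoint and a realistic activation curve; with the leak
convention the steady-state availability remains a Boltzmann to better
than 0.1 mV because the C3↔I edge dominates state exchange at every
conditioning potential.

Current is I(t) = g_max·P_O(t)·(V − E_rev)/1000 (nA) from unbound open
channels, plus optional linear leak and additive i.i.d. Gaussian noise.

### Drug binding

Each ligand adds a mirror of the five gating states (no doubly-bound
states, so co-applied ligands compete for one site — the shared-site
scenario).  Binding rates: kon·D onto every state, koff = kon·K_class off
it, with K_class = K_r for closed states, K_o (default K_r) for open, K_i
for inactivated.  Bound channels gate with the same rates except that each
bound transition s→t is scaled by √(K(s)/K(t)) in both directions, which
makes the bound equilibrium constant K_st·K(s)/K(t) — exactly what
detailed balance around every gating-edge/binding square requires, and
precisely the modulated-receptor mechanism.  Consequences the test suite
verifies: the equilibrium block at any holding potential equals
D/(D + K_app(h)); the drugged availability midpoint shifts by the
closed-form ΔV½ above; state-independent binding (K_i = K_r = K_o) changes
nothing about normalized train responses; and use-dependent block emerges
from kinetics alone (binding during depolarized/inactivated epochs,
incomplete unbinding during short gaps) rather than from any prescribed
frequency dependence.  Bound open channels carry no current (pore block).

Wash-in is instantaneous at the configured onset sweep (perfusion kinetics
are not modeled), and the vehicle (0.1% ethanol) is treated as inert.

### Numerical integration

Voltage is piecewise-constant per epoch.  Occupancies are propagated with
the matrix exponential of the generator over the output step —
unconditionally stable for arbitrarily stiff rates (some derived rates
reach 10⁴/ms at −160 mV) and exact for constant voltage; propagators are
cached per (voltage, concentration, step).  The remainder of each
inter-sweep interval relaxes at the holding potential in a single
exponential jump.  The only step-size constraint is output resolution: the
configuration rejects dt > 1 ms, which could not resolve the ~1 ms decay
of the macroscopic current.  Default output step 0.05 ms (20 kHz); the
demo pipeline samples at 5 kHz, which leaves all peak-ratio measurements
unchanged (peaks are ratios of identically sampled quantities).

### Calibration and what the defaults mean

The electrophysiology this emulates publishes no kinetic rates, so the
rate constants are artifact choices constrained by the published
steady-state and kinetic phenotypes.  The frozen defaults reproduce, with
the package's own measurement pipeline (noise off, fine step):

| observable                     | target        | calibrated model |
|--------------------------------|---------------|------------------|
| WT availability V½ / k         | −90.4 / 5.1 mV| −90.26 / 5.21 mV |
| F1760A availability V½ / k     | −79.9 / 5.8 mV| −79.61 / 6.05 mV |
| activation midpoint (peak G–V) | −32.0 mV      | −31.7 mV         |
| decay τ at −10 mV              | 1.1 ms        | 1.099 ms         |

Other defaults: g_max 120 nS, E_rev +70 mV (Nernst for the ~140/10 mM
Na⁺ gradient), kon 10⁻³ µM⁻¹ms⁻¹ for both reference compounds (chosen so
that unbinding at rest, τ ≈ 17 ms for BPA, straddles the inter-pulse gaps
of the 30/50 Hz trains and use dependence grades with frequency), noise
0.02 nA, leak 1 nS with P/4 emulation enabled (the known linear leak is
subtracted rather than simulating four scaled subpulses).  Recovery from
inactivation at −120 mV has τ ≈ 3 ms — fast enough that 1 Hz trains show
no rundown, slow enough that 30–50 Hz gaps recover incompletely, which is
what makes use-dependent block grow with frequency.  The F1760A mutant is
the wild type with its own availability midpoint/slope and a per-compound
multiplicative scale on all dissociation constants (defaults 1.41 for BPA,
1.92 for mexiletine, from the ratios of published mutant/wild-type
tonic-block constants).

Every synthetic sweep set can be accompanied by a ground-truth manifest
(JSON) listing the full rate table, affinities, seed and calibrated
phenotype, which is what recovery tests compare against.

### What the generator does and does not emulate

It emulates: episodic voltage-clamp recordings under the four standard
protocol families, state-dependent block with the correct equilibrium
signatures, genotype differences, recording noise, and P/4-style leak
handling.  It does not emulate: capacitive transients, series-resistance
error, perfusion kinetics, slow inactivation, temperature effects,
single-channel stochasticity, cell-to-cell parameter variability beyond
noise-seed replication, or any vehicle effect.  Passing recovery tests
therefore demonstrates that the analysis chain is correct and
well-conditioned under the stated noise model — not that it is robust to
every artifact of real recordings.

One deliberate consequence of building the generator on (K_r, K_i) as
primitive truth: its emergent tonic dose–response constant at −120 mV
equals K_app(h ≈ 0.003) ≈ 57 µM for BPA, slightly below K_r, whereas the
published dose–response estimate (74 µM) sits *above* the published K_r
(58.6 µM) — single-cell estimates and pooled Hill fits need not coincide
in real data.  Estimator-recovery checks therefore generate dose–response
data directly from the Hill forward model with the published constants as
truth, and use the gating simulator for everything that is about state
dependence.

## Analysis conventions and numerical choices

* Peaks: extremum of largest absolute value inside an epoch after a 0.3 ms
  blanking window (residual edge artifacts in real data); inward current
  negative; block fractions on absolute peaks.  Block estimates outside
  [0, 1] (possible by chance at low drug effect) are clipped and flagged,
  not raised.
* Tonic block: B = 1 − mean(|peak|, pulses 16–25)/mean(|peak|, 1–10) with
  wash-in after pulse 10 (the post window starts five pulses after wash-in
  so bath and binding have settled); a single-pulse variant (pulse 25
  alone) is available.
* Reversal potential: zero-crossing interpolation between bracketing
  levels (error when the peaks never change sign, and crossings are only
  accepted depolarized of the largest inward peak — sub-threshold noise
  can fabricate crossings); an ohmic-limb extrapolation over the four most
  depolarized levels serves protocols that stop short of E_rev, as the
  standard −90..+45 mV activation protocol does.
* Fits: Levenberg–Marquardt (lmfit), tolerances 1e−12, up to three
  perturbed restarts on non-convergence.  Initialization: Boltzmann
  midpoint from the sample nearest half-range with k = 6 mV; Hill K_d from
  the dose nearest half-block with n_H = 1; exponential τ from a
  log-linear regression of the first 10 ms.  Hill endpoints fixed at 0 and
  1; n_H free by default and fixable to 1.  Boltzmann amplitude free by
  default (normalized data fit close to 1) and fixable.  Standard errors
  from the Jacobian covariance scaled by residual variance, reported
  "best fit ± SE".  The Hill confidence band propagates the parameter
  covariance to the curve and uses the Student-t quantile with
  n − n_free degrees of freedom; simulated coverage at the test's noise
  level is within a few percent of nominal.
* The activation protocol's nominal −90..+45 mV range in 10 mV steps is
  arithmetically inconsistent; the factory emits −90..+40 and appends a
  final +45 mV sweep (15 sweeps).  The availability test-pulse level
  defaults to −10 mV with an override (reported test levels vary).
* Statistics: paired one-sided t on pre/post means; one-way ANOVA with
  Fisher LSD posthoc — pairwise t using the pooled within-group variance,
  df = N − k, deliberately unadjusted (that is the LSD procedure).
  Summaries follow the mean ± SEM convention.
* Shifts are signed, negative = hyperpolarizing.  The slope k used in
  predictions defaults to the drug-free availability fit of the same
  dataset (configurable).  An option subtracts a measured vehicle shift
  before classification; it is off by default.

## Problem sizes

The test suite and the reproduction script run at desk scale as the
package's own default study conditions: 200 replicates for each
estimator-recovery median (500 for the fit-noise and band-coverage
checks), 17-voltage availability curves, 6-dose response curves, 1000
random draws for the shift-ordering property, 25-sweep tonic trains and
30-pulse use trains at 5 kHz output, and 2–3 replicate synthetic cells per
condition in the demo panel.  The full suite completes in well under a
minute of simulation time; the demo pipeline (simulate + analyze) takes a
few seconds.

## Known limitations

* The five-state scheme has one inactivated state: no slow inactivation,
  and recovery from inactivation is mono-exponential.
* Kinetic (non-equilibrium) aspects of block are emergent but not fitted
  to any published use-dependence magnitudes; only their qualitative
  structure (frequency monotonicity, absence under state-independent
  binding) is asserted.
* Single-drug observed availability shifts in real data can exceed the
  equilibrium prediction from measured (K_r, K_i) — the discrimination
  machinery is designed for the co-application comparison, where both
  candidate models share whatever bias the single-drug constants carry.
* The separate-sites scenario exists only as a closed-form prediction;
  the simulator binds competitively (one site) by construction.
* The shared-site verdict inherits the uncertainty of the fitted
  availability midpoints; with fewer than ~15 sweeps per curve or noise
  well above 0.02 nA the verdict degrades to *indeterminate* rather than
  flipping.
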
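# Methods

This note documents the models and estimators implemented in `neuroinfo`,
the parameter choices that matter, what the built-in simulators do and do
not emulate, and the numerical conventions.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Probability estimation and binning

All estimators are plug-in functionals of a joint probability table
obtained by counting joint states: `p(s) = N_s / N_obs`.  This is maximum
likelihood estimation and assumes stationarity — every observation is a
draw from one unchanging distribution.  Two layouts are supported:
single-trial (each time bin is one observation; the result is one
time-averaged value) and trial-based (each trial is one observation at a
fixed within-trial bin; the result is a per-bin time course).

Continuous variables are discretized per variable:

- **uniform width** — `n_bins` equal-width intervals over `[min, max]`,
  half-open `[lo, hi)` with the last interval closed (standard histogram
  convention).  Preserves the gross shape of the data distribution;
  sensitive to outliers.
- **uniform count** — bin edges at empirical quantiles, giving
  `floor(n/n_bins)` or `ceil(n/n_bins)` observations per state for
  distinct values.  Maximizes marginal entropy (and hence the available
  information signal) and makes null models reusable across variables.
  Identical values are never split across states: a quantile boundary that
  falls inside a tie group shifts to the group's end, so marginals may be
  non-uniform with heavily tied data — callers should verify marginal
  equality before sharing a null model (`reuse_null` enforces this).

`n_bins` has no default anywhere: bin count is an analysis parameter the
user must choose, and it bounds every downstream value (a two-state
variable can never show more than 1 bit).  Constant input is an error
rather than a silent one-state variable, because a one-state variable
nullifies every downstream measure.  Missing/non-finite values are
rejected at ingestion.  Bin edges for uniform-width binning are
per-variable (min/max of that variable), not global.

Lag assembly (`assemble_lagged`) builds the joint observations that
role-aware measures need (`Yfuture`, `Xpast`, `Ypast`, …).  Single-trial
layout slides a reference time over the series and drops boundary bins
lacking a full lag tuple; trial-based layout fixes the within-trial bin and
iterates trials.  A window of `w > 1` past bins enters as a single
vector-valued axis (mixed-radix coded), one axis per role.

## Estimator family

Base-2 logarithms throughout (bits), with `0·log2(0/q) ≡ 0` (zero-probability
terms skipped).  Every implemented measure is provably non-negative, so
floating-point residues in `[-1e-12, 0)` are clamped to zero and anything
more negative raises (it signals an inconsistent input table).  Mutual
information is computed in a canonical ascending axis order so the symmetry
`I(X;Y) = I(Y;X)` is bit-exact, not merely within rounding.

The minimum information is implemented exactly as a per-target-state
minimum of joint-weighted pointwise terms,

    Imin({X1},{X2};Y) = Σ_y min_i Σ_{x_i} p(x_i,y) log2 p(x_i,y)/(p(x_i)p(y)),

and its algebraic equality with the specific-information form
`p(y)·KL(p(x|y)‖p(x))` is asserted in tests rather than assumed.  The
partial information decomposition sets redundancy `R = Imin` and derives
`U_i = I(X_i;Y) − R`, `S = I({X1,X2};Y) − R − U1 − U2`; the bookkeeping
identities hold to 1e-12 by construction and all four components are
non-negative for two sources.  Decompositions over three or more sources
are out of scope.  Note that Imin measures a redundant *amount*, not
redundant *content*: two sources that resolve different partitions of the
target's states in equal measure register as fully redundant (the
four-triple "quantity" table in the fixtures demonstrates this, with
R = S = 1 bit).

Transfer entropy is conditional mutual information with the temporal roles
`TE(X→Y) = I(Yfuture; Xpast | Ypast)`.  The default lag structure is one
past bin per variable at delay 1; deeper pasts and delay scanning go
through `LagVar` windows, since the appropriate history length is an
analysis choice, not a constant.

Information gain and transmission are Imin-based, time-ordered measures
about a third variable X:

    IG(X; Y_t)  = I(X; Yfuture) − Imin({Yfuture},{Ypast}; X)
    IT(X; Y→Z)  = Imin({Zfuture},{Zpast,Ypast}; X) − Imin({Zfuture},{Zpast}; X)

The IT grouping — Z's future against its past augmented by Y's past, each
side a (possibly vector-valued) single source — is this package's
convention, chosen because it reproduces the defining limit cases: a
deterministic relay (`Zfuture = Ypast = X`, `Zpast` independent) transmits
exactly `H(X)`, and a `Ypast` unrelated to X and Z transmits exactly zero.
Augmenting a source with extra axes can only increase its specific
information, which makes IT non-negative.

### Estimation bias

Plug-in information estimates from finite data are biased: entropy
downward, mutual information upward, because noise in the estimated table
always looks like structure and the measures are non-negative.  No bias
correction is applied anywhere; instead, inference is delegated to
surrogate testing, which measures the observed value against the same-bias
null.  The bias behavior itself is reproduced as a test experiment (median
MI of an independent pair falls toward 0 as `n_obs` grows through
10→10,000; median entropy of a skewed four-state model rises toward its
true ≈0.33 bits — at small n the downward bias dominates, while at
convergence the median of the skewed sampling distribution may sit a few
thousandths above the true value even though the mean remains below).

## Surrogate significance testing

Surrogates permute the observation sequence of designated variables, each
independently, preserving per-variable marginal counts exactly while
destroying joint structure in expectation.  Permutation (rather than
resampling a count table) is exact at any `n`.  The p-value is the
fraction of `n_rand` surrogate values **≥** the observed value; when no
surrogate reaches it, the p-value is reported as the floor `1/(2·n_rand)`
with a below-resolution flag, never as zero.  One master seed spawns
independent per-surrogate substreams, so results are reproducible and
order-independent.

For transfer entropy only the source-past axis should be permuted,
preserving the receiver's own past–future coupling.  A precomputed null
can be shared across measurements, but only when per-variable marginal
counts match exactly (checked, else error) — uniform-count binning with a
common `n_obs` typically guarantees this.  Raw p-values are returned;
multiple-comparison control is the caller's responsibility, with a
Benjamini–Hochberg convenience wrapper provided.  Spike-time jittering
surrogates are out of scope (they are system-specific).

The tunable-dependence pair model used for calibration draws binary pairs
with matching-state probability `0.25(1+a)`: `a = 0` is exact independence
(population MI 0), `a = 1` exact copying (1 bit).  Under `a = 0` the test's
type-I error at α = 0.05 is calibrated to 0.05 ± 0.02 over 1000
repetitions; power rises monotonically in `a` and in `n_obs`.

## Spiking-circuit simulators

Small circuits use two dimensional Izhikevich units integrated by forward
Euler at dt = 0.1 ms (no adaptive stepping): a regular-spiking cell
(C = 100 pF, vr = −60, vt = −40, vpeak = 35 mV, k = 0.7, b = −2, a = 0.03,
c = −50, d = 100) and a fast-spiking interneuron (C = 20, vr = −55,
vt = −40, vpeak = 25, k = 3.5, b = 0.025, a = 0.2, c = −45, vb = −55) with
piecewise-cubic recovery drive and a voltage-only reset.  Halving dt
changes the 1-s spike count of a tonically driven RS cell by at most one
spike (checked in tests).

Synaptic currents are gamma-shaped pulses with mean 30 ms and sd 20 ms
(shape 2.25, scale 40/3 ms), normalized so the pulse **peak** equals the
synapse weight in pA — the weight tables are specified as maxima — and
truncated at mean + 5 sd = 130 ms, where the tail is < 1e-3 of the peak.
Events trigger at the presynaptic spike time with no axonal delay beyond
the kernel's rise.  Excitatory (RS) sources must have non-negative
weights, inhibitory (FSI) sources non-positive ones.

Membrane noise is 1/f ("pink"): Gaussian white noise filtered in frequency
space to a 1/f power spectrum and inverse-transformed; the log-log
spectral slope is −1.  Its standard deviation is a free parameter,
defaulting to 100 pA, calibrated once so an unstimulated RS cell fires
spontaneously at a low rate (~3 Hz, within the 1–5 Hz target band).

Circuit presets are named for their function: `feedforward_pair` (E1→E2,
200 pA), `inhibition_modulated` (E1→E2 200, E1→I1 200, I1→E2 scanned over
0…−150 pA), `two_stimulus_unique` (only E1 of two stimulated cells drives
the readout), `xor_gate` (E1,E2→I1 50 each; E1,E2→E3 200 each; I1→E3
−250; constant −100 pA background inhibition on E3), `nor_gate` (two
stimulated interneurons at −30 pA onto a cell with 0 or 200 pA tonic
drive) and `correlated_inputs` (two 100-pA inputs with a tunable stimulus
correlation).  Stimuli are square pulses; their amplitude is not dictated
by the circuit tables and defaults per preset (200 pA for the pairs,
300 pA for the inhibition scan, 600 pA for the gate circuits) — the gate
values are chosen so the shared interneuron is recruited only under
co-stimulation, which is what makes the readout implement XOR/NOR.  In the
`inhibition_modulated` circuit, inhibition lags excitation by the kernel
rise (~17 ms), so OFF-type suppression is assessed after the onset
transient.

The 1000-neuron network (800 excitatory, 200 inhibitory) lives on the unit
torus with minimal wrap-around distances.  Ordered pairs connect with
probability `p_con(r) = 0.513·e^(−0.513 r)` (0.5 at r = 0.05); raw weights
are uniform(0, 0.5) excitatory and uniform(−1, 0) inhibitory, then rescaled
class-wise so total excitatory and inhibitory weight equal the all-to-all
reference totals (expected values of the same uniform draws over all
ordered pairs: 800·1000·0.25 and −200·1000·0.5).  Dynamics follow the
canonical dimensionless heterogeneous two-population formulation at 1-ms
steps (two half-steps for the voltage update) with per-ms Gaussian
thalamic drive (sd 5 excitatory, 2 inhibitory) and instantaneous synaptic
delivery — the standard formulation for this network, distinct from the
dimensional RS/FSI units of the small circuits.  Stimulation injects a
square pulse of magnitude 50 (same units as the model's current term; the
magnitude is not tied to pA) into the 40 excitatory neurons nearest each
stimulus line (one or two lines) for 100 ms at 1000-ms intervals.

## Canonical experiment models

All four probabilistic models emit spikes as Bernoulli draws on a 1-ms
internal step (`p = rate × 1 ms`), aggregated to the stated analysis bins
(so counts per analysis bin are Binomial).  The per-analysis-bin
formulation was rejected because the stated peak rates times the stated
bins exceed probability 1 (100 Hz × 25 ms = 2.5); the 1-ms step keeps every
emission probability far from the cap, and a cap-with-warning guard
remains for misconfigured rates.

- ***Aplysia* habituation** — sensory and motor RS cells; the sensory cell
  is driven by 200-pA square pulses (500–1000 ms of each 1500-ms trial)
  and its synapse onto the motor cell depresses exponentially in the
  session-wide presynaptic spike index, pinned exactly to the stated
  endpoints: first spike 200 pA, last spike 30 pA (the decay constant
  itself is unstated, so the endpoint-pinned exponential
  `w_k = 200·(30/200)^(k/(K−1))` is used, with K the total sensory spike
  count).  Because the coupling is feedforward, the session is simulated
  in two exact stages: the sensory cell for all trials in one batch, then
  the motor cell driven by the scheduled synaptic current, with per-trial
  noise streams shared between stages.  Spike counts are binned at 50 ms.
  A constant-synapse control (`habituate=False`) is provided.
- **Retinal ganglion cells** — 300 ON-center/OFF-surround cells on the
  unit torus (ON radius 0.1, surround outer radius 0.3); 400 dot stimuli;
  rates 100 Hz (ON disc), 1 Hz (annulus), 30 Hz (background); 25-ms bins;
  stimulus locations discretized to a 4×4 grid for analysis.  Each
  presentation lasts 250 ms, a documented default (the duration scales the
  statistics but not their structure).
- **Motor cortex** — cosine direction tuning
  `rate = 50·(1 + r·cos(θ−θ_pref)·g(t))` with a unit-peak Gaussian time
  profile (mean −100 ms before movement onset, sd 100 ms), so an `r = 1`
  cell spans 0–100 Hz at the profile peak; 20 strong (r = 1) plus 100
  random-responsiveness cells, 150 trials over 8 equiprobable directions,
  25-ms bins.  The cosine form is the standard direction-tuning
  convention, chosen to satisfy the stated extremes; preferred angles are
  continuous uniform.
- **Place cells** — 200 cells with Gaussian place fields (sd 0.15 spatial
  units, peak 100 Hz over a 20-Hz floor) on the torus; a random-walk
  trajectory with Gaussian steps (sd 0.05 units per 100-ms bin, a
  documented default chosen so 200 s covers the arena), wrapped on the
  torus; 100-ms bins; location discretized to the 4×4 grid (row-major from
  the origin corner), with a warning if any square is unvisited (location
  information is undefined for unseen states).  Rate-matched,
  location-blind control cells (constant rate equal to a place cell's
  spatial mean) are generated alongside for comparison.

### What the generators do and do not emulate

The simulators produce data with realistic surface statistics — conductance
-free spiking dynamics, synaptic delays from kernel rise times, 1/f
background variability, overlapping receptive/place fields, trial
structure — sufficient to exercise every estimator end to end.  They do not
model conductance-based synapses, plasticity beyond the fixed habituation
schedule, refractory interactions between the probabilistic models' bins,
correlated noise across neurons, or measurement artifacts (sorting errors,
missing spikes).  Passing tests therefore demonstrate that the estimators
recover known structure from data of this kind at these sample sizes; they
do not certify performance on real recordings, where bin choices,
nonstationarity and lower effect sizes dominate.

## Scales used in the automated checks

The integration checks run 5 model repetitions per scenario (40–48 trials
each, 500 surrogates at α = 0.05); the calibration check runs 1000
repetitions at n_obs = 100 with 1000 surrogates; the power-ordering check
runs a 3×3 grid (a ∈ {0.1, 0.3, 0.5} × n_obs ∈ {25, 100, 400}) at 100
repetitions with 200 surrogates; bias curves use 200 repetitions per
sample size.  These sizes give comfortable statistical margins for every
asserted ordering while keeping the whole suite fast.

## Known limitations

- Estimators are plug-in only; no bias-corrected or binless/kernel
  estimators are provided by design (significance testing covers
  inference, and several of the multivariate measures have no established
  corrected forms).
- PID is limited to two sources; Imin is the only redundancy measure
  offered and measures redundant amount, not content.
- The IT/IG source groupings are one defensible reading of an
  under-specified construction; both are documented above and pinned by
  limit-case tests.
- Forward Euler at 0.1 ms is adequate for the RS/FSI parameter sets used
  here (verified by the dt-refinement check) but is not a general-purpose
  stiff integrator.
- The surrogate scheme permutes whole observation sequences; it does not
  implement spike-time jittering or trial-structure-aware shuffles.
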
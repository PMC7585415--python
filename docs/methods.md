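# Methods

## Kinetic schemes

All models share a linear activation limb — resting (R), agonist-bound
closed (AR), gated (AO) — with a single binding step and no unliganded
opening. At the supersaturating working concentration (10 mM) one binding
event is kinetically sufficient; the second site would be occupied far
faster than any desensitization process and adds no resolvable structure
to a macroscopic decay. From the gated state, each desensitizable subunit
flips independently between its active and desensitized conformation, so
the gated manifold is the hypercube over the desensitizable set. With
SU3, SU4 and SU5 desensitizing this gives 2 + 2³ = 10 states (AO, three
AD_i, three AD_ij, AD_345); admitting all five subunits would give 34.
SU1/SU2 desensitization is excluded throughout: their single mutants
barely change the decay, leaving nothing for such states to be fitted to.

Rates, stored as per-second floats (binding per-molar-per-second,
concentrations molar):

* binding/gating: k_on = 1×10⁶ M⁻¹s⁻¹, k_off = 1×10³ s⁻¹, β = 200 s⁻¹,
  α = 20 s⁻¹ (efficacy E = β/α = 10). These are fixed, not calibrated:
  at 10 mM, activation equilibrates in well under a millisecond, three
  orders of magnitude away from the second-scale desensitization the data
  constrain. The decay observables are insensitive to their exact values.
* desensitization: δ₃⁺/δ₃⁻ for SU3; one shared pair δ⁺/δ⁻ for SU4 and
  SU5 (their single mutants are phenotypically indistinguishable).
* model III couplings, applied to wild type and mutants alike:
  desensitization of SU3 accelerates desensitization of SU4 by γ and vice
  versa; desensitization of SU4 slows recovery of SU5 by ε and vice
  versa. Placing γ on both partners' entries and ε on both partners'
  recoveries keeps every 4-cycle of the desensitization layer in detailed
  balance, which `check_detailed_balance` verifies on all variants and
  mutation profiles.

A mutation multiplies the mutated subunit's own entry rate by c_i⁺ and
(models II/II-β only — model III fixes c₄⁻ = c₅⁻ = 1 and model I scales
entry only) its recovery by c_i⁻; in models II-β/III a mutated SU3
additionally rescales SU4's rates by c₃₄⁺/c₃₄⁻. Multipliers are bounded
to [1, 1000]: the mutation is a gain-of-desensitization substitution and
accelerates the rates it touches.

The conductance rule is the variants' pivot: concerted and model I
conduct only in AO; models II/II-β/III conduct whenever at most one
subunit is desensitized. The concerted variant replaces the hypercube
with two pseudo-symmetric desensitized states, D_fast and D_slow, as
parallel branches off AO — the minimal wiring that produces two decay
components with independently tunable rates; mutated subunits multiply
its four rates by per-subunit factor quadruples (γ_f, ε_f, γ_s, ε_s)
that combine multiplicatively across subunits (energy-additive).

## Simulation

Occupancies follow dp/dt = pQ with the generator piecewise constant per
protocol segment. For constant Q the propagation is exact: Q is
eigendecomposed and p(t) evaluated in closed form on any time grid (an
expm-stepping fallback covers ill-conditioned eigenbases; a stiff
adaptive integrator serves as test oracle at 1e-6). The default sampling
step is 2 ms (500 Hz, the digitization rate); a warning flags steps
coarser than the fastest relaxation, which the default activation rates
trigger by design — the stepping is exact regardless, only fast
transients go unsampled. Finite solution exchange in the simulator
resamples the concentration each step along an exponential approach.
Macroscopic current is N·i·Σp_conducting with inward current negative;
binomial channel noise draws the conducting-channel count per sample.

## Observables

The decay analysis mirrors the experimental one: the magnitude trace
from the peak to the end of the application is fitted with
C + A_f·exp(−t/τ_fast) + A_s·exp(−t/τ_slow), nonnegative amplitudes,
unweighted least squares. The fit is variable-projection: only the two
time constants are nonlinear (refined by a small damped Gauss–Newton
from multiple log-spaced starts), the amplitudes come from an inner
nonnegative linear solve. %A_fast = 100·A_f/(A_f+A_s);
τ_w = %A_fast·τ_fast + (1−%A_fast)·τ_slow; %I_res is measured on the
trace at the end of the application (trailing-1% average), not read off
the fitted plateau C, which is reported separately as a diagnostic. A
degenerate second component (amplitude share < 1% or τ ratio < 1.5)
collapses to a mono-exponential reported as %A_fast = 100. For long
traces the fitter keeps the first two seconds at full resolution and
strides the tail with √stride weights, which preserves the
uniform-sampling least-squares objective to well below the fit's
model-mismatch floor. Constructs with τ_fast < 0.3 s get zero weight on
τ_slow and %I_res in every objective — those observables are unreliable
for strongly desensitizing constructs.

## Calibration

Wild type first: with binding/gating fixed, each variant has exactly four
free rates against four observables (τ_fast, τ_slow, %A_fast, %I_res).
The objective compares observables on transformed scales — log for time
constants, logit for fractions (clipped to [1%, 99%]; beyond that the
experiment cannot distinguish amplitudes) — so equal relative errors count
equally. Optimization is deterministic: closed-form ballpark initializers
(reading the stated relaxation relations as rates, e.g. 1/τ_fast ≈
2·D·δ⁺ with D = δ⁺/δ⁻ from the quadratic amplitude relation for model
II), a coarse screen over fixed rate-scale grids (including 1/γ-scaled
SU3 guesses under model III couplings), and trust-region refinement of
the best candidates. Models I and III (γ = 100, ε = 10) fit the wild
type exactly; model II cannot reach %I_res = 10% (its conducting set
bounds the equilibrium residual from below) and settles on a flagged
compromise in which SU3 recovery is effectively absorbing.

Mutant multipliers are then fitted with the wild type frozen, per the
study design: singles constrain the multipliers, combinations are pure
predictions obtained by composing single-mutant multipliers. The SU4/SU5
multiplier is shared between C4 and C5 and fitted jointly. Model I's
single free multiplier is matched on the two decay time constants — that
model cannot move the amplitude share, and its verdict rests on kinetics.
Simulation *a* fits the multiplier to the singles and predicts the
double; simulation *b* fits it to the double and predicts the singles.
Fits start from a deterministic coarse screen over decade grids of
multiplier values (local gradients at the unperturbed start can fall
below the inner fit's jitter and stall a purely gradient-based fit).

Every mutant fit carries a weak parsimony prior (ridge on
log-multipliers, weight 0.15, i.e. a zero-mean Gaussian with sd ≈ 6.7
log-units): order-of-magnitude effects are freely reachable, but where
the likelihood is flat — model III's C4 objective improves monotonically
into c₄⁺ → ∞ because the amplitude share saturates — the fit settles on
the smallest perturbation consistent with the observables, the standard
reading of a point mutation's effect.

Synergy flags use a mutant-cycle comparison on predicted τ_fast: with
fold1 = τ(WT)/τ(C4) and fold2 = τ(C4)/τ(C45), independent (additive)
effects give fold2 ≈ fold1; fold2 ≥ 1.25·fold1 is flagged synergistic,
fold2 ≤ 0.8·fold1 anti-synergistic.

The model III couplings are not free parameters: they are searched on
the grid {1, 10, 100, 1000}², each pair calibrated in full and scored
over the whole construct table.

## Occupancy analysis

"Kinetically favored pathway" is operationalized as a greedy
maximum-cumulative-flux walk: each desensitization edge's flux is
∫ rate·p_source dt over the application, and from AO the walk repeatedly
takes the largest-flux outgoing desensitization edge. Exact ties — the
symmetric SU4/SU5 rates — are reported as co-dominant steps, not broken
silently. Flux bookkeeping closes: the net integrated flux into the
terminal state equals its final occupancy to 1e-6.

## Synthetic recordings

The generator emulates the study's acquisition: 60 s application, 500 Hz
sampling, causal 4-pole Butterworth low-pass at 100 Hz, 20,000 channels
(binomial noise), Gaussian instrument noise at 0.5% of peak (a free
knob; the recordings' actual noise amplitude is not reported). Solution
exchange is modelled at the population level: membrane patches see the
agonist step after exponentially distributed delays, so the recorded
current is the step response convolved with the exchange kernel
(τ = 14 ms). The time constant is set so the *measured* 20–80% rise —
exchange plus the filter's own rise — lands at ~22 ms, the middle of the
reported 20–25 ms range. A concentration-ramp reading of exchange would
be wrong here: at 10 mM the dose–response curve saturates within
microseconds of the ramp and the simulated rise would be filter-limited
(~8 ms). Observable-mode traces build the same convolution analytically
from a bi-exponential decomposition.

What the generator does *not* emulate: endogenous oocyte conductances,
electrode/series-resistance artefacts, slow drift, inter-cell
variability, and any SU1/SU2 contribution. Passing recovery tests
therefore shows that the pipeline inverts its own generative model under
realistic noise and filtering — not that every feature of real
recordings is handled.

Two recovery studies are first-class results: (1) model II wild-type
recordings (reference rates from the printed ballpark constraints,
D ≈ 0.9, δ⁺ ≈ 0.14 s⁻¹), re-calibrated from scratch in 20 repetitions —
median rate bias below 5%; (2) model III full-library recordings
(reference rates reproducing wild-type observables under γ = 100,
ε = 10; mutant multipliers of order 4–20), with the coupling pair
re-selected per repetition. Candidate pairs are calibrated against the
fitted observables but *ranked by trace overlay* (mean squared
normalized-trace residual across all constructs, the analysis analogue
of judging fits by eye on superimposed currents): summary observables
alone leave γ nearly degenerate with the SU3 multipliers — a refit can
compensate a tenfold γ change almost exactly — while full traces
separate the pairs by an order of magnitude in score. The grid scoring
disables the parsimony prior, which would otherwise let large couplings
masquerade as small multipliers.

## Numerical choices and limitations

* Probability vectors are clipped at zero and renormalized after eigen
  propagation (round-off is ~1e-15).
* Decay-fit time constants are bounded within a decade of the sampled
  window; the two-tier fit grid's coarse tail uses √stride weights.
* The calibration's inner decay fit warm-starts from the previous
  iterate's time constants and falls back to the multi-start grid when
  its residual exceeds 1.5× the construct's observed model-mismatch
  floor (never below 2.5% rms).
* Optimizer finite-difference steps are 2% in log-parameter space, large
  enough to dominate the inner fit's convergence jitter.
* Reduced-effort settings (coarser observable grid, fewer refinement
  starts) are used inside the 16-pair × 20-repetition grid experiment,
  where only the loss *ordering* between coupling pairs matters; pair
  margins are an order of magnitude above the optimizer tolerance.
* Model II's wild-type compromise (absorbing SU3 corner) means its C3
  prediction keeps two decay components here; a manual calibration
  accepting a worse residual-current fit can instead produce the
  mono-exponential C3 that motivates model II-β. The II-β mechanism
  itself (c₃₄ cross-effect restoring a bi-exponential C3) is reproduced.
* The concerted variant's mutant fits are underdetermined (four factors,
  three weighted constraints per single mutant); the parsimony prior
  selects the smallest consistent perturbation, and the headline
  prediction (the fold by which C45 misses experiment) should be read
  with that in mind.
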
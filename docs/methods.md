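# Methods

## Scope and model of the experiment

`oddball` implements the computational side of a freely-moving-rodent
auditory oddball go/no-go experiment. A session presents a train of pure
tones at a fixed onset-to-onset interval (ISI): a frequent *standard*
frequency and rare *deviants*. The animal earns a food pellet for a
nose-poke within the limited hold (response window, 1.49 s) after a
deviant (HIT); a poke after a standard is a false alarm (FA) punished with
a 5 s timeout; the silent outcomes are correct rejection (CR) and miss
(MISS). The package covers: constrained sequence generation, discrete-event
trial scoring, d′ sensitivity with the log-linear correction, hit-rate
versus preceding-standards (adaptation) analysis with a quadratic trend
fit, within-session engagement timecourses with single-term exponential
fits and the HIT/MISS crossing time, and a generative rat agent that
supplies sessions with the statistical structure those analyses assume.

## Sequence generation

A session is specified by exact counts (e.g. 630 standards / 70 deviants
in 700 tones for the 90/10 probability; 648/72 in 720 tones for the
many-deviant task), a lead-in of initial forced standards (default 5) and
a minimum run of standards before each deviant (default 3). Deviant
placements are sampled *uniformly over all feasible placements* by drawing
a uniform random composition of the spare standards (total standards minus
lead-in minus the per-gap minima) into n_deviant + 1 gaps via stars-and-bars,
then adding the minima back. This is exact — no rejection sampling — and
makes the minimum-run constraint bind with overwhelming probability at
session scale. Feasibility requires
`n_standard ≥ lead_in + min_run × n_deviant`; an infeasible request raises
an error naming the largest feasible minimum run
(`floor((n_standard − lead_in)/n_deviant)`), and `auto_relax=True` permits
generation at that value (the 70/30 sessions, 493/207, need min_run 2).
The trailing gap after the last deviant is also held at `min_run`, which is
marginally stricter than the behavioural constraint but keeps the counting
identity above exact.

Frequency design uses a quarter-octave geometric ladder anchored at
4.0 kHz, rounded to 0.1 kHz (4.0, 4.8, 5.7, 6.7, 8.0, 9.5, 11.3, 13.5,
16.0, 19.0 kHz). Contrasts are realised as whole ladder steps rather than
direct `2^x` multiplication because the rounded training pairs
(8.0 → 11.3 kHz, 4.8 → 6.7 kHz at 0.5 octaves) follow ladder arithmetic
(4.8 × 2^0.5 rounds to 6.8, not 6.7). Many-deviant sessions draw each
deviant's frequency from nine candidates, balanced by default (each used
`floor(n/9)` or one more; 72 deviants → exactly 8 each) with an i.i.d.
mode behind a flag, since the experimental intent is a fixed per-frequency
probability (1.11% per candidate at 10% overall).

## Trial scoring

The response window is half-open, `[onset, onset + 1.49 s)`: a poke exactly
at the window end is not a response. The earliest not-yet-consumed poke in
a window is the trial's response; later in-window pokes and pokes during a
timeout are reported unassigned and trigger nothing — every poke is
consumed by exactly one trial or listed unassigned. Latency is measured
from tone onset. In *scheduled* mode the scorer advances the clock itself
(`onset_{k+1} = onset_k + ISI + 5 s·[FA_k]`), modelling hardware that
pauses stimulation during punishment; *recorded* mode trusts logged onsets
so data from hardware with either convention is scorable. Which convention
the original control software used is not derivable from session summaries,
so neither is claimed — both are provided. The scheduled clock is verified
in tests against an independent event-by-event walk of the timeline.

## d′ and the log-linear correction

Sensitivity is `d′ = Φ⁻¹(H) − Φ⁻¹(F)` with the standard-normal quantile
function (μ = 0, σ = 1; any common (μ, σ) cancels in the difference).
Extreme counts make a proportion exactly 0 or 1 and d′ infinite; the
log-linear correction adds 0.5 to both response counts and 1 to both trial
counts. The default mode applies it conditionally — only when some count
is extreme, and then to *both* rates — with `always` and `never` modes
available, because conditional application is the common reading of
"necessary in cases with a minimum or maximum" but unconditional use is
also defensible. Many-deviant sessions pool hits over all deviant
frequencies. A ceiling session (70/70 hits, 0/630 FAs) corrects to
H = 70.5/71, F = 0.5/631 and d′ ≈ 5.62.

## Adaptation analysis

For each deviant, `k` is the number of standards in the run immediately
before it (the first deviant's run includes the lead-in). Deviant trials
are pooled across sessions (pooled counts by default; a per-session-mean
mode would weight sessions equally instead, and the pooled default is the
package's choice, not a claim about the original analysis). The trend is
fitted by unweighted least squares to `rate = c0 + c1·k + c2·k²` over the
per-k mean rates, with a deviant-count-weighted mode behind a flag; R² is
reported, defined as 1 when the rates are constant (zero total variance).
k bins are raw integers with no smoothing, and the plateau is described,
not estimated as a parameter. Note that preceding-run counts do not sum to
the standard total in general: standards after the last deviant belong to
no deviant's run.

## Timecourse analysis

Trials are cut into fixed-width onset-time bins (default 120 s, chosen to
give ~8 deviants per bin at the 90/10 ratio and 1.5 s ISI; configurable).
HIT and MISS are normalised by deviants per bin, FA and CR by standards,
so the pairs sum to 1 wherever defined; bins with no relevant tone are
omitted for that pair. Normalisation is per-bin (a cumulative variant is a
caller-side transform). Each timecourse is fitted with `y = a·exp(b·t)`,
`a > 0`, `b` sign-free: a log-linear regression on the strictly positive
values seeds a nonlinear least-squares refinement over all points. The
HIT/MISS crossing is computed on the *fitted* curves in closed form,
`t* = ln(a₁/a₂)/(b₂ − b₁)`, reported only inside `[0, t_max]`; equal rate
constants give no crossing (or a degenerate everywhere-equal flag when the
amplitudes also match).

## The synthetic rat

The agent is an expectation/prediction-error responder, built so that every
analysis stage has input with the right structure; it is *not* fitted to
any animal. State is a mass field E(g) on the octave axis, decaying with
time constant τ_E and incremented by α at each tone's frequency. A tone is
judged by novelty ν (one minus the kernel-weighted overlap of the field
with the tone, Gaussian kernel of bandwidth σ_gen octaves), confidence
c = M/(M + κ) in the accumulated regularity, and engagement
A(t) = A_min + (1 − A_min)·e^(−t/τ_eng). Poke probability is
`A·[λ + (1 − λ)·σ(β(νc − θ))]`; latency is `lat0 + lat_slope·(1 − νc)`
plus truncated-Gaussian noise (so clear detections are faster; under the
defaults FAs, which carry low νc, are slower than HITs — the converse
ordering seen in trained animals is reachable by raising λ so impulsive
responding dominates, and is deliberately not asserted in tests).
Responses whose drawn latency reaches the response window are censored at
source rather than emitted and discarded, which keeps the agent's
scheduled clock provably identical to the scorer's; the censoring rate at
default parameters is negligible.

Defaults (frozen): α = 1, τ_E = 12 s, σ_gen = 0.22 oct, κ = 1, β = 9,
θ = 0.58, λ = 0.12, A_min = 0.02, τ_eng = 2000 s, lat0 = 0.5 s,
lat_slope = 0.25 s, lat_σ = 0.10 s. They were derived once from the
mechanism's closed-form operating point and then frozen:

* τ_E = 12 s makes a deviant's own memory fade over ~3τ_E/ISI ≈ 24
  standards at the 1.5 s ISI, placing the adaptation plateau near 25
  preceding standards; it is the lever behind both the rising hit-rate-vs-k
  curve (the previous deviant's trace suppresses novelty at small k) and
  the probability-of-occurrence effect (at 30% deviants the trace never
  fades, so d′ drops — the defaults give d′ ≈ 1.5 at 90/10 vs ≈ 0.9 at
  70/30).
* κ = 1 keeps confidence near saturation once the field is populated, so
  the stochastic mass dips caused by FA-timeout gaps do not mask the
  novelty-driven k-trend; its remaining role is suppressing responses in
  the first seconds of a session, before any regularity exists.
* β = 9, θ = 0.58 put the typical deviant drive on the rising flank of the
  sigmoid (mean hit rate ~60%, correct rejections ~90%) while leaving the
  k-trend resolvable.
* A_min = 0.02, τ_eng = 2000 s give a clear within-session decline of
  active responding whose FA timecourse, fitted with the single-term
  exponential, recovers −1/τ_eng to ~10% (median): the small floor keeps
  the offset bias of an offset-free exponential fit inside the 15% band.

What the agent does **not** emulate: satiety as a mechanism distinct from
engagement, the improvement of d′ with longer ISIs seen in animals (the
expectation field decays more between tones at long ISIs, so the agent's
raw d′ *falls* with ISI unless τ_E is rescaled — tests that probe ISI
effects on the engagement timecourse rescale τ_eng with the ISI and assert
only the timecourse prediction), inter-animal variability, and any neural
quantity. Passing tests therefore show the analyses behave correctly on
data with the assumed structure, not that the agent is a model of a rat.

## Numerical and design choices

* Uniform placement sampling is exact (stars-and-bars composition), seeded;
  identical spec + seed reproduces the identical sequence, and one session
  seed feeds independent named RNG streams (placement, deviant frequencies,
  agent) so adding a consumer never perturbs another.
* The quantile function is SciPy's `norm.ppf`; tests pin it to an
  independent bisection inversion of the CDF at 1e−9.
* Quadratic fits use `numpy.polyfit`; exponential fits use
  `scipy.optimize.curve_fit` with the amplitude bounded positive;
  R² totals below float-rounding scale are reported as 1.
* Exact-count sessions, window-end exclusivity, first-poke-wins and
  ignore-pokes-during-timeout are fixed conventions chosen for
  reproducibility where the underlying experiment leaves room; each is
  stated at the API it affects.
* Problem sizes in tests (20–100 sessions of 700 tones, 100–200 fit
  replicates) are the package's verification defaults: large enough that
  the asserted trends are many standard errors from chance, small enough
  to keep the suite quick.

## Known limitations

* Recorded-onset mode trusts the log; it does not detect hardware clock
  drift or dropped events.
* The adaptation and timecourse modules assume one animal's sessions are
  exchangeable; cross-animal normalisation (normalise per animal, then
  average) is left to the caller.
* `criterion_reached` implements the d′ ≥ threshold, k-consecutive-sessions
  training rule but the package does not model the shaping stages that
  precede it.
* No group statistics: the package emits tidy per-session tables intended
  for external ANOVA tooling.
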
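# Methods

## The inference problem

A fishing trip is a series of timestamped positions at roughly hourly,
occasionally irregular, intervals.  Each *step* (the interval between two
consecutive records) belongs to one latent behavioural mode — cruising,
searching or fishing — and the task is to reconstruct the whole mode
sequence from per-step movement descriptors.  Everything here is
*supervised*: ground-truth labels (from on-board observers in the real
fishery, from the simulator here) are available for training, so model
parameters are estimated directly rather than by EM.

## Observed variables

Six per-step variables are computed from positions (`features`):
speed `v` (km/h; haversine distance over step duration, Earth radius
6371 km), heading `phi` (forward azimuth at the step's start, radians in
(−π, π]), and the changes of speed and turning angles between the
previous and current step (`dv_prev`, `dphi_prev`) and between the
current and next step (`dv_next`, `dphi_next`).  Units are km/h, radians
and hours throughout.  Irregular sampling is used as-is (no
interpolation); `dt` enters the speed and all duration accounting.
Lag/lead variables are undefined at trip boundaries and carried as NaN:
excluded from distribution fits and classifier training rows, and treated
as a unit emission factor during decoding.

## Emission and duration distributions (`dists`)

State-conditional emissions and state durations are univariate
parametric families fitted by maximum likelihood — closed form where it
exists (lognormal, Laplace, uniform, exponential), numerically otherwise,
and by EM for the two-component mixtures (k-means-style initialisation,
10 restarts, tolerance 1e-6).  Families on [0, 1] (Beta, Kumaraswamy) are
fitted after an affine min–max map to the unit interval; the map is
stored with the fit and densities include its Jacobian.  Circular
families are fitted on data wrapped to (−π, π].

Goodness of fit uses the Cramér–von Mises statistic
`W² = 1/(12n) + Σᵢ (u₍ᵢ₎ − (2i−1)/(2n))²` with a parametric-bootstrap
p-value (each replicate redraws a sample from the fit and refits the same
family; 200 replicates and α = 0.05 by default).  Selection among
candidates drops families rejected by the test and takes the minimum AIC
among the survivors; if everything is rejected, the overall minimum-AIC
fit is returned with a warning.  AIC counts only *estimated* parameters:
families fitted with the location pinned at zero (lognormal, gamma,
Weibull, loglogistic, origin-anchored GPD) count two, the exponential
one.

Two deliberate choices:

- **Duration candidates use an origin-anchored generalized Pareto**
  (`genpareto_zero`, threshold fixed at 0).  A data-dependent positive
  threshold would declare segments shorter than the observed minimum
  impossible — wrong for durations, whose support is all of (0, ∞) — and
  its estimated-at-the-minimum likelihood advantage distorts AIC
  comparisons.  For emissions such as speed, where a physical lower bound
  exists, the threshold-at-minimum GPD is retained.
- **Training-time selection is AIC-only by default** (`n_boot=0` in
  `train_hmm`/`train_hsmm`): the bootstrap screen costs 200 refits per
  candidate per (mode, variable) and is left opt-in; `cvm_gof` itself
  defaults to 200 replicates.

## Markovian models (`markov_models`)

**HMM.** Initial probabilities put mass one on the trip-starting mode
(cruising); step transitions are relative frequencies of consecutive
labelled step pairs within trips; emissions factorise over variables
given the state.  Global decoding is log-space Viterbi; ties break toward
the lower mode index.

**HSMM.** The state process lives at the segment scale: transitions only
between distinct modes (zero diagonal, relative frequencies of
consecutive distinct segments), an explicit continuous duration density
`d_j(u)` per mode, and for each trip's last visited state the survival
`S_j(u) = P(U ≥ u)` of its right-censored duration.  The joint
log-likelihood of a segmentation with visited states s₁..s_R and
durations u₁..u_R is

```
log π(s₁) + Σ_{r<R} [ log d_{s_r}(u_r) + log a(s_r, s_{r+1}) ]
          + log S_{s_R}(u_R) + Σ_t Σ_k log b_{s_t}(y_tk)
```

with u_r the sum of the member steps' actual durations, so irregular
steps enter directly.  Decoding is an exact dynamic programme over
(step, mode, segment length ≤ `d_max_steps`), O(T·d_max·M²) in log space,
with the survival term scoring the final segment (consistent with the
likelihood); ties break toward the lower mode index, then the shorter
segment.  `d_max_steps` defaults to 50 (≈ 2 days at hourly steps); the
decoder warns when a decoded segment hits the cap.  Both decoders are
verified against exhaustive enumeration on all small instances, and the
classical equivalence — discrete-geometric durations with parameter p
decode identically to the HMM with self-transition 1 − p — is asserted as
a test.

**Numerical guards.**  Per-variable emission log-densities are floored at
−40 nats, and a value outside *every* mode's fitted support contributes a
unit factor: bounded-support families fitted on one partition otherwise
make individual validation steps infeasible under all modes at once.
Segment durations observed at step quantization (whole multiples of the
step) receive a ±half-step uniform jitter before duration fitting, the
usual continuity correction for binned data; without it, continuous
families collapse onto density spikes at coarse sampling.  Censored final
segments are excluded from duration fitting (and scored by survival in
the likelihood), which makes the duration estimator target the
uncensored-segment population — slightly shorter-tailed than the free
process because long segments straddle the trip end more often.

## Discriminative baselines (`discriminative`)

Random forest (trees ∈ {100, 500}; per-node variables ∈ {1, ⌈√M⌉, M}),
Gaussian-kernel SVM (γ ∈ {0.01, 0.1, 1, 10}, C ∈ {1, 10, 100}) and a
single-hidden-layer MLP (1–10 hidden neurons).  Each grid point is fitted
on 75% of the training rows and scored by accuracy on the stratified
remaining 25%; the winner is refitted on all rows.  Features are z-scored
for SVM and MLP, raw for the forest.  Prediction is per-step and
order-independent; boundary rows with missing lag/lead values are
mean-imputed at prediction time.

## Evaluation (`evaluation`)

Step scale: accuracy (% matching steps) and mean accuracy (MA, the
unweighted average of per-mode step accuracies, modes with no true steps
excluded).  Segment scale, per mode: an inferred segment counts toward
precision when it shares ≥ 1 step with a true segment of the same mode; a
true segment counts toward recall when overlapped by ≥ 1 inferred step of
its mode; F1 is the harmonic mean (0 when P + R = 0); indicators with an
empty denominator are undefined (NaN) and excluded from averages rather
than zero-filled.  A stricter majority-overlap variant is available
behind a flag.  The duration statistic is the mean squared difference
between the ECDFs of true and inferred segment durations, evaluated on
the union of observed durations; 0 is error-free and 1 the upper bound.

Model comparison uses trip-level repeated random sub-sampling (default 20
repetitions, 50/50 trip split, the same seeded partitions for every
model), and a two-sided sign-flip randomization test on paired
per-repetition scores (exhaustive when 2ⁿ fits the permutation budget).
Variable-subset selection enumerates all non-empty subsets (≤ 10
variables) on a fixed internal split and maximises accuracy, preferring
smaller subsets on ties.

## The simulator (`synthetic_data`)

The latent process is an explicit-duration semi-Markov chain: trips start
in cruising; each visited mode draws a continuous duration in hours
(non-positive or non-finite draws are rejected with bounded retries);
transitions happen only between distinct modes; the final segment is
right-censored at the trip end.  States are sampled at multiples of the
base step, so excursions shorter than the step can vanish — exactly as in
real sampled data (a 30-minute search between two fishing sets leaves a
mixed signature at hourly steps).  Observations are drawn per step from
the current mode's distributions, mutually independently across variables
(mirroring the models' conditional-independence assumption — which also
means the simulated `dv_prev`/`dv_next` do not satisfy the deterministic
shift identity that position-derived features do).  Circular variables
are wrapped to (−π, π].  Feature-level simulation is primary because the
models consume features; a secondary position-level path dead-reckons
speed and heading into lon/lat so the feature-extraction stage is tested
end to end.  Occasional irregular intervals replace the nominal step with
lognormal draws (5% of steps by default).

**Hourly fishery scenario** (`make_fishery_scenario`): three modes;
fishing durations lognormal with mean 2 h and log-sd 0.7 (spread enough
that the family is identifiable against its gamma/GEV cousins at
realistic sample sizes); searching and cruising durations GEV with means
≈ 0.9 h and ≈ 3.2 h; emissions follow the per-variable families of the
fishery analysis with cruising fast, fishing slow, and searching
overlapping both — calibrated so that hourly-step inference lands in the
study's regime (overall accuracy near 80%, cruising easiest, searching
hardest with segment F1 near 60%).

**High-resolution scenario** (`make_highres_scenario`): same latent
structure with duration distributions concentrated around their
characteristic times, 16-hour trips at a 1-minute base step (a 1-second
process sampled at any multiple of a minute is statistically identical to
its 1-minute sampling, which is what all analysis rates use).  Real
sub-hourly movement descriptors are smooth in time, not independent
draws, so emissions decorrelate over a 12-minute movement-smoothness
horizon: one value per within-segment block.  Each mode's speed
distribution leaks into a neighbour's range (cruising has a slow
manoeuvring mixture component, fishing a heavy fast tail, searching
overlaps fishing), making single blocks ambiguous while segments remain
identifiable from aggregate evidence plus duration.  This is the regime
in which the two Markovian models separate: the HMM's cost of entering
and leaving a segment grows like 2·log(1/Δ) as the step Δ shrinks, so
marginal-evidence segments detected at 30-minute steps are absorbed at
1-minute steps, while the HSMM's duration-density entry cost is O(1) in
Δ and its duration template vetoes block-length artefacts.  Free
parameters of this scenario (duration spreads, leak weights, horizon) are
a reconstruction calibrated against the reported behaviour of the
original high-resolution simulation, whose exact generator is not
public; the persisting quantitative gap (the step-scale model does not
collapse all the way to 50% mean accuracy at 1-minute steps under this
generator) is a limitation of the feature-level, conditionally
independent design, not a tuning residual.

## Problem sizes and defaults

Analysis drivers default to 60 trips / 5 repetitions (model comparison)
and 50 trips / 3 repetitions / 5 rates (resolution experiment);
`scripts/acceptance.py` uses 50 trips × 3 repetitions per rate.  These
sizes put Monte-Carlo noise on mean accuracy near ±1–2 points, which is
the tolerance the qualitative claims are read at.  The exhaustive decoder
checks run all instances with T ≤ 7 and M ≤ 3 over 50 seeds; parameter
recovery uses 200 simulated trips.

## Known limitations

- Feature-level emissions cannot reproduce every property of
  position-derived features (shift identities, fine-scale kinematic
  constraints); the position-level path exists but is secondary.
- The duration estimator targets the uncensored-segment population
  (censored segments are excluded rather than entered through their
  survival), a small negative bias for long-duration modes on short
  trips.
- Duration densities (not interval probabilities) score candidate
  segments, so likelihoods are comparable only within a model.
- Supervised training only; no EM, no higher-order chains, no hybrid
  Markov–discriminative models.
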
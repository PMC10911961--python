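# Methods

## Observation model

Tracks are sequences of GPS fixes at a nominal 1 s cadence. Each
consecutive pair of fixes yields a step length `r_t` (haversine distance on
a sphere of radius `R = 6371` km, configurable) and each consecutive pair
of *steps* yields a turning angle `psi_t` — the change of heading, wrapped
to (−π, π], counter-clockwise positive (bearings are clockwise from north,
so the heading difference is negated). The first angle of every sequence is
undefined and contributes only its step density to the likelihood; this is
the momentum-free choice for sequence starts. Exact-zero steps (repeated
fixes) are replaced by ε = 10⁻⁶ km so the strictly positive gamma support
applies, counted, and their headings carried forward from the last moving
step; this preserves sequence alignment rather than silently dropping
fixes. Distances under ~100 km make the spherical approximation error
negligible, so no map projection is used anywhere.

Tracks with irregular gaps are split at any gap differing from the modal
cadence by more than a tolerance (default 0.5 s); each segment is then an
independent sequence. Inclusion rules for observed tracks: total duration
must exceed 60 s, and more than one distinct behaviour must have been
recorded (a constant-behaviour track carries no validation contrast).

The observer ethogram maps to the binary response as: active search →
foraging; transit search and direct flight → not-foraging.

## The HMM and its variants

States follow a first-order Markov chain with transition matrix Γ, steps
are gamma (mean μ_j, sd σ_j; internally shape (μ/σ)², scale σ²/μ) and
angles von Mises (mean ρ_j, concentration κ_j), independent given the
state. The likelihood is computed by a log-space forward recursion
(log-sum-exp at every step; numba-compiled), so arbitrarily long 1 Hz
sequences are stable. The engine is written for general N; the analysis
suite fixes N = 2 (foraging / not-foraging).

Model variants 0–6 vary (i) pooling of the transition matrix and of the
step parameters across tracks and (ii) a distance-to-colony covariate on
the state and/or observed process. Reading "unique step length parameters"
literally, angle parameters stay pooled in the per-track variants; the
initial distribution δ is shared when the state process is pooled and
per-track otherwise. Transition covariates enter through a multinomial
logit with the diagonal as reference (η_ii = 0), which reduces to a
logistic regression on each off-diagonal for N = 2; the transition from
t to t+1 is evaluated at the covariate of the origin step t. Step
covariates enter log-linearly in both the mean and the sd, with separate
(β0, β1) per state for each, and are only combined with pooled step
parameters (the variants that need anything else do not exist in the
suite).

The covariate is standardised by its pooled mean and sd before entering
any linear predictor — purely an optimiser-conditioning device; estimates
are also reported per raw km. Explicit centring constants can be supplied
when coefficients must be interpreted on a known scale (the covariate-
recovery test generates data on fixed constants and fits on the same
ones, so the estimate and truth are on one scale).

## Estimation

Maximum likelihood over unconstrained working parameters: log for μ, σ, κ;
multinomial logits for δ; free coefficients for β; ρ bounded to [−π, π]
(the density is periodic so the bound loses nothing). Optimisation is
L-BFGS-B with finite-difference gradients, relative tolerance 10⁻⁸, and
box bounds that keep every density evaluation finite (e.g. log κ ≤ 9).
Starting values are data-driven: steps are split at their pooled quantiles,
the lower group seeding the short-step state; κ starts at (0.5, 5), ρ at 0,
off-diagonal transition probabilities at 0.1, δ uniform. `fit()` runs 25
restarts by default, the first from the unperturbed start and the rest
from seeded Gaussian perturbations on the working scale; the best restart
wins and the whole procedure is deterministic given the seed. On the
well-separated synthetic regime the data-driven start almost always reaches
the optimum, so the tests and the acceptance script use 3 restarts as their
problem size.

Standard errors come from the numerical Hessian of the negative
log-likelihood at the optimum (`statsmodels.tools.numdiff.approx_hess`,
pseudo-inverse for safety).

Decoding: Viterbi in log space with ties broken toward the lower state
index; local probabilities are forward–backward smoothing posteriors by
default, with a filtered (forward-only) option since either reading of
"locally decoded" is defensible. State labels are assigned by fitted mean
step — smaller mean = foraging — evaluated at the median standardised
covariate when the step mean is covariate-driven; exact equality raises
rather than guessing.

## Validation

Point metrics pool time points across all tracks of a group (per-track
tables can be derived from the decoded output). PPV = tp/(tp+fp),
TPR = tp/(tp+fn), NPV = tn/(tn+fn), F1 the harmonic mean of PPV and TPR
(0 when both are 0). Metrics with zero denominators are reported as
missing (NaN), never as 0. Log-loss uses the smoothed posterior of the
foraging-labelled state, clipped to [10⁻¹², 1−10⁻¹²]. Model selection
ranks by log-loss ascending, ties broken by fewer parameters; AIC
(2k − 2logL) is always reported but never used for selection unless
explicitly requested.

Foraging events are maximal runs of observed foraging; per-event coverage
is the fraction of its time points decoded as foraging. Histogram bins:
missed (exactly 0), (0, 25%), [25, 50%), [50, 75%), [75, 100%] — a
boundary value belongs to the upper bin, since "less than 25%" is
exclusive. Missed events are summarised by count and median duration in
seconds (duration = run length × cadence).

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
tern ecology in full:

- **Bird movement** — a step-and-turn walk on the sphere: heading plus a
  von Mises turn, then a gamma step along the new heading; first heading
  uniform. Defaults: μ = (0.005, 0.020) km, σ = (0.003, 0.008) km,
  ρ = (0, 0), κ = (1, 20), symmetric switching at 0.05 s⁻¹ (≈ 20 s dwell),
  start 1 km from the colony (Coquet Island coordinates). These are chosen
  so 1 Hz speeds span realistic tern flight (5–20 m/s) with clearly
  separated, strongly autocorrelated states; they are package choices, not
  field estimates. κ ≥ 10¹² is treated as the deterministic limit ψ = ρ.
- **Covariate effect** — optional logistic slopes on the switching
  probabilities in the standardised distance to colony (centre 3 km,
  scale 2 km by default), recomputed each second from the current
  position.
- **Boat pursuit** — the observer platform blends its previous heading
  with the bearing to the bird (weight 0.7 on the old heading) and smooths
  its speed toward the range error (weight 0.5, cap 0.04 km/s, idle drift
  1 m/s, 0.5 m/s throttle noise), never closing inside 50 m by its own
  motion. This is a minimal mechanism reproducing the qualitative
  boat/bird contrast — the boat turns more smoothly than the bird —
  and it is not a claim about real skipper behaviour. The bird itself can
  transiently overfly the boat, so the 50–200 m band holds for the bulk of
  fixes (median in-band; ≥ 80% asserted in tests) rather than every fix;
  harder band enforcement (reversal back-offs, standoff-point steering)
  was tried and rejected because it imprints artefacts (π-reversals,
  control oscillations) that dominate the fitted state structure. Exact
  bearing and range from boat to bird are emitted at every fix, so
  reconstruction of the bird's track is exact by construction.
- **Labels** — observed behaviour equals the true state, optionally
  flipped independently at a configurable noise rate (default 0: the
  protocol treats observers as ground truth; the option exists for
  robustness studies).

What passing tests on this generator shows: the estimator, decoder,
validation metrics and pipeline are correct and well-calibrated when the
data follow the assumed two-state gamma/von Mises process. What it does
not show: performance under GPS error, behaviour misclassification by
observers, more than two behavioural modes, tidal drift, or evasive
responses to the boat — none of which are modelled.

## Problem sizes and determinism

Default study conditions are 10 tracks × 2000 s. Recovery checks run five
seeds at this size; the oracle-equivalence checks compare the recursions
with exhaustive enumeration over all 2^T sequences for 200 random T ≤ 8
instances at 10⁻¹⁰. The proxy assessment uses 4 tracks × 1000 s. All
randomness flows from explicit integer seeds (child seeds derived
deterministically per track), and identical configuration + seed gives
byte-identical output files.

## Known limitations

- Gradients are finite-difference; an analytic or AD gradient would speed
  up the per-track variants (Models 1–3), whose parameter count grows with
  the number of tracks.
- The per-track variants fit all tracks jointly because angle parameters
  are shared; with many tracks the Hessian-based standard errors become
  expensive.
- Label switching is resolved only at the 2-state labelling step; general
  N would need a canonical ordering.
- The boat model's inner-band guarantee is one-sided by design (see
  above).
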
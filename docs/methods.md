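# Methods notes

## The choice model and its state

Every site interaction (cache, check, retrieval) is an event in an
ordered per-bird log. For each event the package reconstructs the arena
state at the instant *before* the event: per-site occupancy n (cache
sites holding at least one tracked seed), the checked-empty flags c
(checked this trial and currently empty), elapsed time since the bird's
last interaction with each site this trial, recache flags (latest cache
into the site happened during the feeder-closed phase), the totals N and
C, and the previous-site pointer. Cache sites are treated as empty at the
start of every trial; seeds left over from an earlier trial are ignored —
their withdrawal is not a retrieval (the event is flagged and excluded
from retrieval statistics), but re-placement of such a seed counts as a
cache.

The choice probability multiplies the bird's baseline bias by five log10
scaling factors (proximity; occupied-site and checked-empty Gaussian
sums with optional time- and capacity-decay; recache and older-cache
site-local terms) and renormalizes over all S = 68 sites. The factors are
base-10 by convention while the likelihood uses the natural log; both
conventions are kept deliberately.

Conventions that the defining formulas leave open:

* **Previous site.** The most recent interaction within the same
  *session*, crossing trial and phase boundaries (the delay phase
  contains no interactions, so the first feeder-closed check's previous
  site is typically the last feeder-open interaction); reset across
  sessions. A session's first event has no previous site and the
  proximity factor contributes nothing.
* **σ → 0.** A Gaussian whose width is below 10⁻⁶ cm is an exact
  site-local indicator. Best fits on real data put σ_occ and σ_emp at
  0.01–0.02 cm — effectively site-local — so this is the operative regime
  for the content factors. The proximity kernel is zero at the previous
  site itself at any width.
* **t = ∞.** Sites untouched this trial carry infinite elapsed time; the
  associated decay factor is defined as zero. It only ever multiplies
  n = 0 or c = 0, so the convention is inert; the code guards the ∞·0
  product explicitly.
* **Feeders** carry their empirical baseline mass (feeder retrievals are
  interactions) but are never occupied-by-cache and never checked-empty;
  normalization runs over all 68 sites. The capacity totals N and C count
  cache sites only.
* **μ (next-seed-action flag).** Defined at the instant before event i,
  so the "next interaction involving a seed" includes event i itself —
  a cache event therefore always has μ = 1, which is what makes the
  first-check-before-caching mask include the cache when it is itself the
  first site opened.
* **Zero-bias sites.** Masks whose likelihood events are not a subset of
  the baseline-defining events (e.g. first checks scored against a
  cache-derived baseline) can place an event on a site with zero baseline
  mass. The default is a hard error naming the events; an ε-floor
  (ε = 1/(2·ΣG), renormalized) is available as an explicit option.

## Fitting

Each model of the nested family fixes some of the twelve parameters at
zero and frees the rest; unbounded ranges are realized as wide finite
boxes (|γ| ≤ 10 decades, σ ≤ 100 cm, inverse scales ≤ 1) that the Ridge
penalty makes unreachable in practice. Optimization is L-BFGS-B with
analytic gradients of the penalized cost, five random starts drawn from
γ ∈ [−2, 2], σ ∈ [1, 30] cm, inverse scales ∈ [0, 0.1], plus two
deterministic starts with every free amplitude at +1 and at −1
(σ = 10 cm), convergence tolerance 10⁻⁸ on the cost; the lowest-cost
converged start wins, and all randomness is seeded. A line search that
stalls with the iterate at the optimum to numerical precision is
accepted as a usable solution.

Two numerical facts about this objective are worth knowing:

* **(γ, σ) = (0, 0) is a stationary trap.** With a Gaussian-pair factor,
  σ = 0 zeroes the kernel and with it the gradient in γ, so data without
  the effect (or data-starved bootstrap resamples) legitimately collapse
  there — and descent from a wrong-signed amplitude start can end there
  even when the data carry signal. The two sign-seeded deterministic
  starts guarantee one start on the correct side of every amplitude.
* **Ridge shrinkage of σ is material at per-bird scale.** The penalty
  gradient on the proximity width is 2λσ ≈ 31 nats/cm at σ = 15.5 cm and
  λ = 1, while a single bird's ~500 caches supply likelihood curvature of
  the same order; per-bird width estimates are therefore strongly shrunk,
  and even the pooled fit over 20 birds recovers σ_prv about 1.5–2 cm
  below the generative value. Amplitude (γ) estimates, with penalty
  gradient 2λγ ≲ 2, are essentially unaffected. Recovery checks therefore
  fit pooled and allow the width a ±2 cm tolerance.
* **Plug-in baseline bias.** The baseline is the empirical site frequency
  of the masked events themselves. At a few hundred events over 64 sites
  this plug-in overstates the probability of repeat visits to
  already-used sites, which the occupancy factor then compensates —
  mimicking a weak negative γ_occ even for a bias-only agent. Parameter
  recovery and null-specificity checks on simulated data therefore
  condition on the generative baseline, isolating the estimator under
  test; analyses of real data necessarily use the empirical baseline and
  inherit this small-sample bias.

Model comparison uses AIC on the pooled fit with bootstrap-over-birds
significance: one common set of bird resamples is drawn, every model is
refit on each resample (warm-started at its full-data optimum; bird
multiplicities enter as likelihood weights, so only unique birds are
evaluated), and the p-value is the fraction of bootstrap AIC differences
above zero, ties counting as "not improved". A fast mode that recombines
per-bird log-likelihoods at the fixed full-data optimum is available but
is not the default. Per-parameter significance is assessed two ways: a
one-tailed Wilcoxon signed-rank test on per-bird estimates (exact
enumeration up to n = 20), and a per-bird session bootstrap whose p-value
is the fraction of resampled estimates on the opposite side of zero from
the population-level direction; the direction is fixed externally, which
is what makes the procedure a calibrated one-sided test.

## Spatial-bias analyses

Entropy of the bias is computed over the 64 cache sites (bounded by
6 bits) and compared to 10,000 simulated uniform draws of the same event
count. Split-half correlations divide each bird's sessions into two
near-equal groups and compare within-bird to identity-shuffled
across-bird correlations (shuffles optionally restricted to the same
principal-component cluster). Bias maps are smoothed with a 3 × 3
Gaussian window (σ = one site pitch) truncated and renormalized at arena
edges — the edge handling is this package's choice. Two-means clustering
on the first principal component uses 10 seeded restarts, with cluster
labels ordered by the mean map's mass-distance from the arena center so
that label 0 is always the center-preferring group. Lag stability
correlates smoothed per-session maps at session lags 1..N, where N is
the largest lag with at least two pairs in at least five birds (capped
at 8), and bootstraps birds for the regression slope's CI.

## Diagnostics

The retrieval-order analysis ranks each retrieval among the caches
available at that moment (oldest-first or newest-first) against a null
that retrieves uniformly at random from the available caches; transient
caches — those retrieved by the immediately next interaction at the same
site, the tracking-free operationalization of "without leaving the
perch" — can be excluded, and exclusion can only lower the order-1
recency fraction. Checks-to-find-cache counts feeder-closed checks up to
and including the first check of an occupied site and compares against
reassigning each trial's check sequence to another trial's cache
configuration; pairs whose sequence never visits the configuration are
reported as missing rather than censored at an arbitrary cap, with found
fractions alongside (a trial's own sequence ends soon after its caches
are found, so censoring treats observed and shuffled pairs
asymmetrically). The long-unchecked-empty-site analysis considers caches
into sites the bird has seen this session but not within the gap — sites
whose contents it once knew — and compares the empty-site fraction to the
occupancy-implied chance level by a one-sided binomial test.

## Event detection

Synthetic per-site ROI stacks stand in for real video: a fixed baseline
pattern, a persistent blob while a seed is present, a short random
perturbation at every flap opening, and Gaussian pixel noise. Traces per
site are the Pearson correlation with the empty-baseline image
(median-subtracted, SD-normalized; peak threshold 10 SD) and with the
previous frame (200-frame centered moving average subtracted; threshold
0.3), peaks at least 100 frames apart. Candidates are classified by the
pre-to-post change of the raw baseline correlation in units of its
frame-to-frame noise (median absolute successive difference), which
remains valid when long occupied stretches make the global SD
uninformative: a sustained drop is a cache, a sustained recovery a
retrieval, anything else a check. The reference workflow classified
candidates by manual review; this automated classifier is validated on
synthetic stacks with known schedules and recovers exact event counts at
pixel-noise SD up to ~0.1 against unit signal amplitudes. The seed-count
low-pass filter y_n = 0.01·x_n + 0.99·y_{n−1} (y_0 = 0, rounded) delays a
unit step by 69 frames (~1.2 s at 57 fps), so single-frame events never
register.

## Simulators

The Caching task runs 1 hr sessions under the feeder state machine
(state 0 with probability 1/4, states 1–4 with 3/16 each; after three
state-0 draws in a row states 1–4 with 1/4 each) with dwell times of
60 s plus an exponential 15 s tail truncated at 90 s — the package's
reading of "between 60 and 90 s with 15 s decay". The Retrieval task
builds trials from a feeder-open phase (eating timers 30–60 s with the
15 s tail; feeder re-draw on each newly occupied site; phase ends 15 s
after a post-cache feeder visit or at three occupied sites), a 2 min
delay with no interactions, and a feeder-closed phase ending 15 s after
the last cache is removed or after 10 min.

Only the agent's *site choice given an event type* follows the choice
model — that is the object every test exercises. When the bird eats
versus caches versus checks versus retrieves is a simple configurable
stochastic policy (exponential inter-event gaps, default mean 10 s;
cache-versus-eat probability 0.35; check probability 0.75 when idle;
own-cache retrieval probability 0.04; optional transient-cache
probability). The defaults yield roughly 20 caches per hour-long session
and peak simultaneous occupancy near 10–15 sites, matching the regime the
apparatus was designed around. Retrieval of own caches is uniform over
occupied sites, which is exactly the retrieval-order null — so the
order analysis's self-consistency is testable. The simulators share their
state bookkeeping contract with the likelihood (verified by a
generative-consistency test: at n ≥ 5000 choices the likelihood of the
simulated choices peaks at the generative parameters against ±0.3
amplitude perturbations).

What the simulator does not emulate: body trajectories between sites,
lights-off behavioral modulation, olfactory or visual leakage,
session-to-session drift in the bias, and any dependence of event *rates*
on arena state beyond the protocol rules. Passing tests therefore show
that the estimator recovers the model's parameters from data generated
under the model at realistic volumes — not that real chickadee behavior
follows the model.

## Problem sizes

Test and acceptance runs use scaled study conditions chosen as this
package's own defaults: 20 replicate birds × ~500 caches for parameter
recovery; 10 birds × 10 sessions with 300 bird-bootstrap resamples for
the AIC ladder; 1000 and 400 replicates for the two null-calibration
checks (400 inner simulations / 50 bootstrap refits each); 6000-frame ROI
stacks for detection.
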
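# Methods

## The model

Identification performance for a high-contrast Tumbling-E target flanked by
four randomly oriented Tumbling-Es is modeled as a function of the
edge-to-edge gap `x` (arcminutes) between target and flankers.  The curve has
three regimes — recovery at the nearest spacings, crowding at intermediate
spacings, asymptotic performance beyond the critical spacing — captured by
the pointwise maximum of a line and a guess-corrected cumulative Gaussian:

    Psi(x)          = max( Psi_recovery(x), Psi_crowding(x) )
    Psi_recovery(x) = m * x + b
    Psi_crowding(x) = gamma + (A - gamma) * Phi((x - mu) / sigma)

with `Phi` the standard normal CDF and `gamma = 0.25` the chance rate of the
four-alternative task.  `A` is the unflanked asymptote, `mu` and `sigma` the
location and width of the crowding sigmoid, `m <= 0` and `b` the slope and
abutting-gap intercept of the recovery line.  Unflanked trials are treated as
the `x -> +inf` limit, probability exactly `A`; the unflanked condition is a
distinguished token (`UNFLANKED`), never a sentinel number, so it cannot leak
into spacing arithmetic.  The recovery line is clipped to [0, 1] purely to
preserve probability semantics; with `m <= 0`, `b <= 1` the clip never
engages over fitted gap ranges.

Assumptions worth stating: trials are independent Bernoulli draws; there is
no lapse rate (the upper asymptote is `A` itself, estimated from the data);
the crowding branch is symmetric (Gaussian), and the recovery branch exactly
linear.  Degenerate `A = gamma` yields a flat chance-level curve and is
accepted by the curve evaluators, though parameter validation for fitting
requires `A > gamma`.

## Probit-unit normalization

To compare curves across optotype sizes, proportions are mapped to Z-scores
("probit units") via the inverse normal CDF, and each curve is expressed as
the *reduction in Z-units from its own fitted asymptote*:
`dz = Phi^-1(p') - Phi^-1(A')`.  The primes denote optional guess
correction `p' = (p - gamma)/(1 - gamma)`.

`z_reduction` takes an explicit `mode` argument.  The default is `raw`
(no guess correction), which reproduces the standard worked arithmetic for
this normalization — a drop from 95% to 90% is `1.645 - 1.282 = 0.363`
Z-units, and from 65% to 60% is `0.385 - 0.253 = 0.132` — i.e. those are raw
standard-normal quantiles.  A `guess_corrected` mode implements the
correct-then-transform procedure; the two differ and both are exact inverses
of `from_z_reduction` under the same mode.  Proportions at exactly 0 or 1
are clamped into `[1e-6, 1 - 1e-6]` (with a warning) before the transform so
empirical cells stay finite; below-chance proportions raise rather than
silently clip, because a cell below chance is a data problem the analyst
must see.

## Bayesian fitting

Each condition cell (observer x optical condition x stroke size) is fit by
MCMC under independent uniform priors: `A (0, 1)`, `sigma (0, 5)`,
`mu (-1, 1)`, `m (-1, 0)`, `b (0, 1)`.  The likelihood is Bernoulli per
trial with success probability `Psi(gap)`; unflanked trials contribute at
probability `A`, so the asymptote is estimated jointly with the curve rather
than plugged in from the unflanked proportion (joint estimation subsumes the
plug-in and propagates its uncertainty).

The sampler is an affine-invariant ensemble (emcee) with a
differential-evolution move mixture (80% DEMove, 20% DESnookerMove), which
mixes several times faster than the default stretch move on this correlated
posterior.  All walkers are evaluated in one vectorized likelihood call per
move, on per-gap aggregated counts.  Parameters are sampled on their natural
scales; the hard uniform boxes already bound the geometry, and a log-scale
sigma would only add a Jacobian without improving mixing for these widths.

Defaults: 32 walkers, 2 000 warmup + 5 000 sampling moves; the pooled
post-warmup draws are thinned to 1 000 retained parameter sets used for
summaries, pointwise log-likelihoods, and Monte-Carlo spacing intervals.
Convergence is monitored with split-R-hat computed across walkers (each
walker's post-warmup path treated as a chain); a fit with any R-hat above
1.01 is returned flagged `converged=False`, never silently.  Posteriors with
more than 5% of their mass within 1% of a prior bound are flagged
boundary-hugging (e.g. `mu` near 1 arcmin, or `A` near 1 for the largest,
ceiling-level letters); all-correct or all-wrong cells are flagged
prior-dominated.  Walkers initialize uniformly over a 2%-inset prior box,
and every stage is seeded: the same seed reproduces draws bit-for-bit.

## Hierarchical model family and WAIC

Only `A` and `b` must change with stimulus size.  The other three parameters
each receive one of four sharing codes — `F` one value overall, `O` one per
observer, `C` one per observer x optical condition, `N` free per cell — and
the family is the fixed 12-member lattice of `(sigma, mu, m)` code triples
(ids 0-11: FFF, FOF, OFF, OFO, FFO, OOF, OOO, FCF, CCF, CCC, NOF, NNN).
Sharing is implemented as hard equality constraints (shared slots in one
joint parameter vector), not partial pooling with hyperpriors, matching the
fixed/yoked design of the lattice; shared slots keep the same uniform
priors.

Fits are scored by the widely applicable information criterion,

    WAIC  = -2 (lppd - pWAIC)
    lppd  = sum_i log( mean_s exp l_is )
    pWAIC = sum_i Var_s( l_is )

with `l_is` the log-likelihood of trial `i` under retained draw `s`,
computed with log-sum-exp stabilization.  The pointwise unit is the
individual Bernoulli trial (not the per-cell binomial), which makes the
score invariant to how trials were blocked into sessions.  `pWAIC` uses the
sample variance (ddof = 1); arviz uses the population variance, a known
convention difference of factor `(S-1)/S` that the test suite accounts for
when cross-checking.  The per-point variance is computed after centering on
the first draw so that identical draws give `pWAIC = 0` exactly.  Ranking
sorts ascending by WAIC with ties broken by lower `pWAIC`, then lower model
id.  The comparison table reports `lppd` and the best total log-likelihood
over retained draws explicitly, since "log-likelihood of a model" is
otherwise ambiguous for a posterior.

## Critical spacing

The critical spacing is the largest gap at which performance sits a
criterion amount below the asymptote; the conservative default criterion is
an absolute drop of 0.025 *on the proportion-correct scale*.  On the sigmoid
branch the crossing has the closed form

    x* = mu + sigma * Phi^-1( (A - c - gamma) / (A - gamma) )

The estimate is flagged undefined when (a) `A - c <= gamma` (the target
level is at or below chance), (b) `x* < 0` (the curve never drops below the
level at a physical gap), or (c) the recovery line exceeds `A - c` at `x*`,
in which case the full compound curve has no crossing there; no sigmoid-only
value is reported in that case.

Uncertainty comes from the posterior: 1 000 parameter sets are resampled
from the retained draws, the closed form applied to each, and the 2.5/97.5
percentiles of the defined values reported.  The reported point value is the
median of the same Monte-Carlo sample, which guarantees it lies inside its
own interval.  The fraction of undefined draws is reported, and an interval
with more than half undefined draws is flagged unreliable.  A parametric
bootstrap (resimulate at fixed parameters, refit) would be an alternative
interval; posterior resampling was chosen because the fits are Bayesian and
it requires no refitting.

For cross-study synthesis, edge-to-edge spacings convert to center-to-center
as `ee + 0.6 * size` for bar flankers and `ee + size` for letter flankers,
with the Tumbling-E letter size equal to 5 stroke widths (5x5 optotype
grid).  The foveal size-limited reference line predicts a center-to-center
critical spacing of `1.4 * size`.

## Synthetic data

No trial-level data from the original experiment are distributable, so the
generator emulates the design: 3 observers; with/without adaptive-optics
correction; the stroke sizes tested per observer and condition (2-5 sizes,
0.37-0.97 arcmin); finite gaps from abutting (0) to 1.6 arcmin; an unflanked
condition in every cell; 20 trials per size x spacing cell (10 per block,
each condition run in at least two sessions).  The finite grid uses
0.2-arcmin steps (9 gaps) — the published endpoints with a step matching the
~8-10-point curves of this paradigm; it is an emulation, not a
reconstruction of the exact per-observer grids, and is configurable.

The canonical ground truth mirrors the best-supported sharing structure:
`sigma` and `mu` per observer (0.40-0.50 and 0.30-0.45 arcmin), one
recovery slope (-0.30 per arcmin), and per-cell `A` and `b`.  Asymptotes
follow a cumulative-Gaussian acuity curve anchored so each condition's
75%-correct stroke size matches that observer's estimated acuity, with
width 0.15 arcmin; `b = A - 0.2` (floored at chance) reproduces the roughly
20% abutting-flanker deficit.  Responses are independent Bernoulli draws
from `Psi`; each (cell, gap) has its own hash-derived substream of the
top-level seed, so adding or removing a cell never perturbs other cells'
draws.

What the generator does *not* emulate: sequential dependencies, learning or
fatigue, lapses, session-level drift, response bias across the four
orientations, and any optical or fixational variability.  Passing
parameter-recovery and model-selection tests on these data therefore shows
that the estimation machinery is correct and calibrated for the assumed
Bernoulli process — not that the model is adequate for real observers.

## Problem sizes used in the test suite

The calibration study uses one cell at 200 trials per spacing over the
default grid, 50 replicates — enough for binomial coverage counts with
roughly 4-point resolution.  The model-selection study uses 2 observers x 3
sizes at 100 trials per cell with asymptotes spanning 0.80-0.95, 10
replicates, comparing the observer-yoked (OOF) and saturated (NNN) members;
these sizes keep one full run of everything in minutes on a single core
while leaving the comparisons well away from degeneracy.  End-to-end
pipeline checks run the full default design with reduced sampler budgets,
since the property under test there is bitwise reproducibility, not
posterior accuracy.

## Known limitations

- The 2.5% criterion on small-`n` cells (20 trials) yields wide spacing
  intervals; the default design reproduces that honest uncertainty.
- Split-R-hat across interacting walkers is conservative but not a
  guarantee; ensemble walkers are not independent chains.
- Hard parameter sharing cannot express partial pooling; a hyperprior
  hierarchy is out of scope.
- `mu`'s (-1, 1) prior can pinch fits when the true location approaches
  1 arcmin; bounds are configurable and boundary-hugging posteriors are
  flagged.
- WAIC differences of a few units between structurally close models are
  within Monte-Carlo error of the retained-draw budget; the model-selection
  test asks only for a majority preference, not a fixed margin.
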
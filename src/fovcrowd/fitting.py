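"""Bayesian estimation of the compound psychometric curve.

One condition cell (subject x optical condition x stroke size) contributes
Bernoulli trials at each flanker gap; the posterior over the five curve
parameters (A, mu, sigma, m, b) under independent uniform priors is sampled
with an affine-invariant ensemble MCMC (emcee), with the likelihood evaluated
for all walkers at once on per-gap aggregated counts.  Unflanked trials enter
the likelihood directly with success probability ``A``, so the asymptote is
estimated jointly with the rest of the curve.

Priors are the weakly-informative uniform boxes used throughout the study:
A in (0, 1), sigma in (0, 5), mu in (-1, 1), m in (-1, 0), b in (0, 1).

Convergence is checked with split-R-hat computed across walkers (each walker
treated as a chain); a fit whose worst R-hat exceeds the threshold is
returned flagged, never silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import ndtr

from .model import GUESS_RATE_4AFC, UNFLANKED, CrowdingParams
from .synth import aggregate

__all__ = [
    "PriorSpec",
    "SamplerSettings",
    "PosteriorFit",
    "CellData",
    "condense",
    "loglik",
    "fit_condition",
    "summarize",
]

PARAM_NAMES = ("A", "mu", "sigma", "m", "b")


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform prior bounds per parameter."""

    A: Tuple[float, float] = (0.0, 1.0)
    sigma: Tuple[float, float] = (0.0, 5.0)
    mu: Tuple[float, float] = (-1.0, 1.0)
    m: Tuple[float, float] = (-1.0, 0.0)
    b: Tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"prior for {name} must have lower < upper")

    def bounds(self, order: Sequence[str] = PARAM_NAMES) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array([getattr(self, p)[0] for p in order])
        hi = np.array([getattr(self, p)[1] for p in order])
        return lo, hi


@dataclass(frozen=True)
class SamplerSettings:
    """Ensemble-sampler budget.

    ``walkers`` parallel chains take ``warmup + steps`` moves; warmup is
    discarded, the rest pooled, and at most ``max_retained`` evenly-spaced
    draws kept for summaries and pointwise log-likelihoods (the retained
    budget plays the role of the study's "1000 estimates generated for each
    model").
    """

    walkers: int = 32
    steps: int = 5000
    warmup: int = 2000
    max_retained: int = 1000
    rhat_threshold: float = 1.01

    def __post_init__(self):
        if self.steps < 2 or self.warmup < 0:
            raise ValueError("need steps >= 2 and warmup >= 0")
        if self.walkers < 4 or self.walkers % 2:
            raise ValueError("need an even number of walkers >= 4")


@dataclass
class CellData:
    """Trials condensed to per-gap counts plus the trial-level index back.

    ``gap``/``unflanked``/``k``/``n`` describe each aggregated (gap) row;
    ``trial_row`` maps every original trial to its row, and ``correct`` keeps
    the per-trial outcomes so pointwise log-likelihoods stay per-trial.
    """

    gap: np.ndarray  # (R,) float; 0 where unflanked
    unflanked: np.ndarray  # (R,) bool
    k: np.ndarray  # (R,) int, correct count
    n: np.ndarray  # (R,) int, trial count
    trial_row: np.ndarray  # (N,) int
    correct: np.ndarray  # (N,) int

    @property
    def n_trials(self) -> int:
        return len(self.correct)


def condense(trials: pd.DataFrame) -> CellData:
    """Aggregate one cell's trials by gap, retaining the per-trial mapping."""
    agg = aggregate(trials)
    keys = list(zip(agg["subject"], agg["optical"], agg["stroke_arcmin"], agg["gap_arcmin"]))
    row_of = {key: i for i, key in enumerate(keys)}
    trial_row = np.array(
        [
            row_of[(s, o, st, g)]
            for s, o, st, g in zip(
                trials["subject"], trials["optical"],
                trials["stroke_arcmin"], trials["gap_arcmin"],
            )
        ],
        dtype=int,
    )
    unflanked = np.array([g is UNFLANKED for g in agg["gap_arcmin"]])
    gap = np.array([0.0 if g is UNFLANKED else float(g) for g in agg["gap_arcmin"]])
    return CellData(
        gap=gap,
        unflanked=unflanked,
        k=agg["n_correct"].to_numpy(),
        n=agg["n_total"].to_numpy(),
        trial_row=trial_row,
        correct=trials["correct"].to_numpy().astype(int),
    )


def _psi_matrix(theta: np.ndarray, data: CellData, gamma: float) -> np.ndarray:
    """Curve probabilities for W parameter rows over R aggregated gap rows.

    ``theta`` columns follow PARAM_NAMES order: A, mu, sigma, m, b.
    """
    A = theta[:, 0:1]
    mu = theta[:, 1:2]
    sigma = theta[:, 2:3]
    m = theta[:, 3:4]
    b = theta[:, 4:5]
    x = data.gap[None, :]
    crowd = gamma + (A - gamma) * ndtr((x - mu) / sigma)
    recov = np.clip(m * x + b, 0.0, 1.0)
    p = np.maximum(crowd, recov)
    if data.unflanked.any():
        p = np.where(data.unflanked[None, :], A, p)
    return p


def _binom_loglik_matrix(theta: np.ndarray, data: CellData, gamma: float) -> np.ndarray:
    """Bernoulli log-likelihood (without the binomial constant) per theta row."""
    p = _psi_matrix(theta, data, gamma)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = data.k[None, :] * np.log(p) + (data.n - data.k)[None, :] * np.log1p(-p)
    # 0 * log 0 is a well-defined 0 contribution here
    term = np.where((data.k[None, :] == 0) & (p == 0.0), 0.0, term)
    term = np.where(((data.n - data.k)[None, :] == 0) & (p == 1.0), 0.0, term)
    out = term.sum(axis=1)
    return np.where(np.isnan(out), -np.inf, out)


def _pointwise_loglik(theta: np.ndarray, data: CellData, gamma: float) -> np.ndarray:
    """Per-trial Bernoulli log-likelihood matrix, shape (draws, trials)."""
    p = _psi_matrix(theta, data, gamma)[:, data.trial_row]
    c = data.correct[None, :]
    with np.errstate(divide="ignore"):
        return np.where(c == 1, np.log(p), np.log1p(-p))


def loglik(trials: pd.DataFrame, params: CrowdingParams) -> Tuple[float, np.ndarray]:
    """Log-likelihood of one parameter set: (total, per-trial vector).

    A trial whose predicted probability is exactly 0 or 1 with the
    contradicting outcome contributes -inf (returned, not raised).
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    params.validate()
    data = condense(trials)
    theta = np.array([[params.A, params.mu, params.sigma, params.m, params.b]])
    pointwise = _pointwise_loglik(theta, data, params.gamma)[0]
    return float(pointwise.sum()), pointwise


@dataclass
class PosteriorFit:
    """Posterior draws and the bookkeeping needed downstream.

    ``draws`` has one named column per sampled quantity; ``pointwise_loglik``
    is draws x trials (for WAIC); ``diagnostics`` records split-R-hat per
    column, convergence and data-degeneracy flags.
    """

    draws: pd.DataFrame
    pointwise_loglik: np.ndarray
    diagnostics: Dict[str, object]
    bounds: Dict[str, Tuple[float, float]]
    gamma: float = GUESS_RATE_4AFC

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def params_at(self, i: int) -> CrowdingParams:
        row = self.draws.iloc[i]
        return CrowdingParams(
            A=row["A"], mu=row["mu"], sigma=row["sigma"],
            m=row["m"], b=row["b"], gamma=self.gamma,
        )

    def summary(self) -> pd.DataFrame:
        return summarize(self)


def _run_ensemble(
    log_prob,
    lo: np.ndarray,
    hi: np.ndarray,
    settings: SamplerSettings,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Run the seeded ensemble; return (pooled thinned draws, rhat per dim).

    Walkers start uniform in the (slightly inset) prior box; warmup is
    discarded; R-hat treats each walker's post-warmup path as a chain.
    """
    ndim = len(lo)
    nwalkers = max(settings.walkers, 2 * ndim + 2)
    nwalkers += nwalkers % 2
    rng = np.random.default_rng(seed)
    span = hi - lo
    p0 = lo + span * (0.02 + 0.96 * rng.random((nwalkers, ndim)))

    def bounded_log_prob(theta):
        theta = np.atleast_2d(theta)
        ok = np.all((theta > lo) & (theta < hi), axis=1)
        out = np.full(len(theta), -np.inf)
        if ok.any():
            out[ok] = log_prob(theta[ok])
        return out

    # differential-evolution moves mix much faster than the default stretch
    # move on the correlated (A, mu, sigma) posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, bounded_log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(seed % (2**31)).get_state()
    sampler.run_mcmc(p0, settings.warmup + settings.steps, progress=False)
    chain = sampler.get_chain(discard=settings.warmup)  # (steps, walkers, ndim)

    per_walker = np.moveaxis(chain, 1, 0)  # (walkers, steps, ndim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(az.convert_to_dataset(per_walker))
    rhat = np.asarray(rhat_ds["x"])

    pooled = chain.reshape(-1, ndim)
    if len(pooled) > settings.max_retained:
        idx = np.linspace(0, len(pooled) - 1, settings.max_retained).round().astype(int)
        pooled = pooled[idx]
    return pooled, rhat


def _boundary_flags(
    draws: np.ndarray, lo: np.ndarray, hi: np.ndarray, names: Sequence[str]
) -> List[str]:
    """Parameters whose posterior hugs a prior bound (>5% of mass within 1%)."""
    span = hi - lo
    flagged = []
    for j, name in enumerate(names):
        near = (draws[:, j] < lo[j] + 0.01 * span[j]) | (draws[:, j] > hi[j] - 0.01 * span[j])
        if near.mean() > 0.05:
            flagged.append(name)
    return flagged


def fit_condition(
    trials: pd.DataFrame,
    priors: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    gamma: float = GUESS_RATE_4AFC,
) -> PosteriorFit:
    """Sample the five-parameter posterior for one condition cell's trials."""
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    priors = priors or PriorSpec()
    settings = settings or SamplerSettings()

    finite_gaps = {g for g in trials["gap_arcmin"] if g is not UNFLANKED}
    has_unflanked = any(g is UNFLANKED for g in trials["gap_arcmin"])
    if len(finite_gaps) < 2 or not has_unflanked:
        warnings.warn(
            "fit is weakly constrained: fewer than 2 distinct finite gaps "
            "or no unflanked trials present",
            stacklevel=2,
        )

    data = condense(trials)
    lo, hi = priors.bounds()
    pooled, rhat = _run_ensemble(
        lambda th: _binom_loglik_matrix(th, data, gamma), lo, hi, settings, seed
    )

    draws = pd.DataFrame(pooled, columns=list(PARAM_NAMES))
    pointwise = _pointwise_loglik(pooled, data, gamma)

    total_correct = int(data.correct.sum())
    degenerate = total_correct in (0, len(data.correct))
    diagnostics = {
        "rhat": dict(zip(PARAM_NAMES, np.asarray(rhat, dtype=float).ravel())),
        "converged": bool(np.all(rhat <= settings.rhat_threshold)),
        "prior_dominated": degenerate,
        "boundary_hugging": _boundary_flags(pooled, lo, hi, PARAM_NAMES),
        "n_trials": data.n_trials,
        "seed": seed,
    }
    return PosteriorFit(
        draws=draws,
        pointwise_loglik=pointwise,
        diagnostics=diagnostics,
        bounds={p: getattr(priors, p) for p in PARAM_NAMES},
        gamma=gamma,
    )


def summarize(fit: PosteriorFit) -> pd.DataFrame:
    """Mean, median, and central 95% interval per sampled quantity.

    Percentiles are order statistics of the pooled post-warmup draws.
    """
    if len(fit.draws) == 0:
        raise ValueError("no draws to summarize")
    d = fit.draws
    return pd.DataFrame(
        {
            "mean": d.mean(),
            "median": d.median(),
            "q2.5": d.quantile(0.025),
            "q97.5": d.quantile(0.975),
        }
    )
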
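"""Compound psychometric model of identification performance vs. flanker spacing.

Foveal crowding data show three regimes as the edge-to-edge gap ``x`` between a
target optotype and its flankers grows: a *recovery* region at the nearest
spacings where performance falls with increasing gap (modeled as a straight
line ``m·x + b`` with non-positive slope), a *crowding* region where
performance climbs back toward the unflanked level (a guess-corrected
cumulative Gaussian), and an asymptotic region at the unflanked level ``A``.
The full curve is the pointwise maximum of the linear and sigmoidal branches:

    Ψ(x) = max( m·x + b ,  γ + (A − γ)·Φ((x − μ)/σ) )

with Φ the standard normal CDF and γ the guess rate (0.25 for a
four-alternative Tumbling-E task).  Unflanked trials are the x → ∞ limit of
the sigmoid, i.e. probability ``A`` exactly.

The module also provides the probit-unit ("Z-score") transforms used to
normalize curves measured at different optotype sizes onto a common
sensitivity-like scale: proportions are (optionally guess-corrected and)
mapped through the inverse normal CDF, and each curve is expressed as the
reduction in Z-units from its own fitted asymptote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "UNFLANKED",
    "GUESS_RATE_4AFC",
    "PROB_EPS",
    "CrowdingParams",
    "InvalidParameterError",
    "ProportionDomainError",
    "psi",
    "psi_recovery",
    "psi_crowding",
    "correct_for_guessing",
    "clamp_proportion",
    "to_z",
    "z_reduction",
    "from_z_reduction",
]

#: Chance performance for the four-alternative forced-choice Tumbling-E task.
GUESS_RATE_4AFC = 0.25

#: Clamping half-width applied to empirical proportions before the probit
#: transform, so cells at exactly 0 or 1 map to finite Z-values.
PROB_EPS = 1e-6


class _Unflanked:
    """Distinguished token for trials presented without flankers.

    Compares greater than every finite gap (it is the x → +∞ limit of the
    crowding sigmoid) and refuses arithmetic, so it can never be silently
    folded into a spacing computation.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNFLANKED"

    def __gt__(self, other):
        if isinstance(other, _Unflanked):
            return False
        return True

    def __ge__(self, other):
        return True

    def __lt__(self, other):
        return False

    def __le__(self, other):
        return isinstance(other, _Unflanked)

    def __hash__(self):
        return hash("UNFLANKED")


UNFLANKED = _Unflanked()


class InvalidParameterError(ValueError):
    """Raised when psychometric parameters violate their constraints."""


class ProportionDomainError(ValueError):
    """Raised when a proportion falls outside the domain of a transform."""


@dataclass(frozen=True)
class CrowdingParams:
    """The five free parameters of the compound curve plus the fixed guess rate.

    Parameters
    ----------
    A : float
        Asymptotic (unflanked) proportion correct, in (gamma, 1].
    mu : float
        Location of the crowding sigmoid, arcmin of edge-to-edge gap.
    sigma : float
        Width (SD) of the crowding sigmoid, arcmin; must be positive.
    m : float
        Slope of the recovery line, proportion correct per arcmin; <= 0.
    b : float
        Intercept of the recovery line at gap 0 (abutting flankers), in [0, 1].
    gamma : float
        Guess rate; fixed at 0.25 for the four-orientation Tumbling E.
    """

    A: float
    mu: float
    sigma: float
    m: float
    b: float
    gamma: float = GUESS_RATE_4AFC

    def validate(self) -> "CrowdingParams":
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if not (self.gamma < self.A <= 1):
            raise InvalidParameterError(
                f"A must lie in (gamma, 1] = ({self.gamma}, 1], got {self.A}"
            )
        if self.m > 0:
            raise InvalidParameterError(f"recovery slope m must be <= 0, got {self.m}")
        if not (0 <= self.b <= 1):
            raise InvalidParameterError(f"b must lie in [0, 1], got {self.b}")
        return self

    def with_(self, **kwargs) -> "CrowdingParams":
        return replace(self, **kwargs)


def psi_recovery(x, params: CrowdingParams):
    """Recovery branch: the straight line ``m·x + b`` clipped to [0, 1].

    The clip preserves probability semantics; within the fitted region
    (b <= 1, m <= 0, small gaps) it never engages.
    """
    x = np.asarray(x, dtype=float)
    return np.clip(params.m * x + params.b, 0.0, 1.0)


def psi_crowding(x, params: CrowdingParams):
    """Crowding branch: guess-corrected cumulative Gaussian.

    ``gamma + (A - gamma) * Phi((x - mu) / sigma)``; the UNFLANKED token
    evaluates to ``A`` exactly (the x → ∞ limit).
    """
    if not params.sigma > 0:
        raise InvalidParameterError(f"sigma must be > 0, got {params.sigma}")
    if x is UNFLANKED:
        return params.A
    x = np.asarray(x, dtype=float)
    return params.gamma + (params.A - params.gamma) * norm.cdf(
        (x - params.mu) / params.sigma
    )


def psi(x, params: CrowdingParams):
    """Full compound curve: pointwise max of recovery and crowding branches.

    Accepts a finite gap (scalar or array, arcmin, >= 0) or the UNFLANKED
    token, which returns ``A`` exactly.
    """
    if x is UNFLANKED:
        if not params.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {params.sigma}")
        return params.A
    return np.maximum(psi_recovery(x, params), psi_crowding(x, params))


def correct_for_guessing(p, gamma: float = GUESS_RATE_4AFC):
    """Map a raw proportion onto the guess-corrected scale (p − γ)/(1 − γ).

    Raises :class:`ProportionDomainError` for p below the guess rate rather
    than clipping: a cell below chance is a data problem the caller must see.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < gamma):
        bad = np.atleast_1d(p)[np.atleast_1d(p) < gamma]
        raise ProportionDomainError(
            f"proportion(s) below guess rate {gamma}: {bad.tolist()}"
        )
    if np.any(p > 1):
        raise ProportionDomainError("proportion above 1")
    out = (p - gamma) / (1.0 - gamma)
    return float(out) if out.ndim == 0 else out


def clamp_proportion(p, eps: float = PROB_EPS):
    """Clamp proportions into [eps, 1 − eps], warning when a value moves.

    Empirical cells at exactly 0 or 1 would otherwise map to ±∞ under the
    probit transform.
    """
    p = np.asarray(p, dtype=float)
    clamped = np.clip(p, eps, 1.0 - eps)
    if np.any(clamped != p):
        warnings.warn(
            f"proportion(s) clamped into [{eps}, {1 - eps}] before probit transform",
            stacklevel=2,
        )
    return float(clamped) if clamped.ndim == 0 else clamped


def to_z(p):
    """Probit transform: Φ⁻¹(p), the Z-score of a proportion.

    Defined on (0, 1); callers with empirical 0/1 cells should pre-clamp via
    :func:`clamp_proportion`.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ProportionDomainError(
            "probit transform requires 0 < p < 1; clamp empirical cells first"
        )
    out = norm.ppf(p)
    return float(out) if out.ndim == 0 else out


def _maybe_correct(p, gamma, mode):
    if mode == "raw":
        return np.asarray(p, dtype=float)
    if mode == "guess_corrected":
        return np.asarray(correct_for_guessing(p, gamma), dtype=float)
    raise ValueError(f"mode must be 'raw' or 'guess_corrected', got {mode!r}")


def z_reduction(p, A, mode: str = "raw", gamma: float = GUESS_RATE_4AFC):
    """Reduction in Z-units from the fitted asymptote: Φ⁻¹(p′) − Φ⁻¹(A′).

    ``mode`` selects whether proportions are first guess-corrected (primes
    above).  The default is ``raw``: a drop from 95% to 90% is
    Φ⁻¹(0.90) − Φ⁻¹(0.95) = −0.363 Z-units.  The result is <= 0 for p <= A.
    """
    pz = to_z(_maybe_correct(p, gamma, mode))
    az = to_z(_maybe_correct(A, gamma, mode))
    out = pz - az
    return float(out) if np.ndim(out) == 0 else out


def from_z_reduction(dz, A, mode: str = "raw", gamma: float = GUESS_RATE_4AFC):
    """Exact inverse of :func:`z_reduction`: recover the proportion from ΔZ.

    Round-trips with :func:`z_reduction` to machine precision.  Raises
    :class:`ProportionDomainError` if the inverted proportion falls below 0
    (raw mode) or below the guess rate (corrected mode).
    """
    dz = np.asarray(dz, dtype=float)
    az = to_z(_maybe_correct(A, gamma, mode))
    p_prime = norm.cdf(az + dz)
    if mode == "raw":
        p = p_prime
    else:
        p = gamma + (1.0 - gamma) * p_prime
    if np.any(p < 0):
        raise ProportionDomainError("inverted proportion below 0")
    return float(p) if p.ndim == 0 else p
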
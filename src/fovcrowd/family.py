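"""Hierarchical model family over the crowding-curve parameters, ranked by WAIC.

Only the asymptote ``A`` and the recovery intercept ``b`` must move with
stimulus size; the crowding-sigmoid width ``sigma`` and location ``mu`` and
the recovery slope ``m`` can each be constrained across conditions.  Each of
the three gets one of four sharing codes:

    F  one value shared by all observers, optical conditions, and sizes
    O  one value per observer (shared across optics and sizes)
    C  one value per observer x optical condition (shared across sizes)
    N  unconstrained: one value per observer x optics x size cell

The family evaluated here is the fixed 12-member lattice of code triples
(sigma, mu, m), fit jointly across all condition cells by hard parameter
sharing (equality constraints, not partial pooling), and compared by the
widely applicable information criterion

    WAIC = -2 (lppd - pWAIC),
    lppd  = sum_i log mean_s exp l_is,
    pWAIC = sum_i Var_s(l_is),

where l_is is the log-likelihood of trial i under posterior draw s.  The
pointwise unit is the individual Bernoulli trial, making the score invariant
to how trials were blocked into sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .fitting import (
    GUESS_RATE_4AFC,
    PosteriorFit,
    PriorSpec,
    SamplerSettings,
    _run_ensemble,
    _boundary_flags,
)
from .model import UNFLANKED
from .synth import ConfigurationError, DesignSpec, aggregate

__all__ = [
    "ModelSpec",
    "ParameterIndex",
    "WaicResult",
    "FamilyPosteriorFit",
    "MODEL_CODES",
    "enumerate_models",
    "parameter_index",
    "fit_family",
    "waic",
    "compare",
]

#: The 12 code triples (sigma, mu, m), keyed by their model ids.
MODEL_CODES: Dict[int, str] = {
    0: "FFF",
    1: "FOF",
    2: "OFF",
    3: "OFO",
    4: "FFO",
    5: "OOF",
    6: "OOO",
    7: "FCF",
    8: "CCF",
    9: "CCC",
    10: "NOF",
    11: "NNN",
}

CODED_PARAMS = ("sigma", "mu", "m")
FREE_PARAMS = ("A", "b")  # always one per condition cell


@dataclass(frozen=True)
class ModelSpec:
    """One member of the lattice: an id and its (sigma, mu, m) codes."""

    id: int
    codes: Tuple[str, str, str]

    def __post_init__(self):
        if any(c not in "FOCN" for c in self.codes):
            raise ValueError(f"codes must be in {{F,O,C,N}}, got {self.codes}")

    @property
    def label(self) -> str:
        return "".join(self.codes)

    @classmethod
    def from_id(cls, model_id: int) -> "ModelSpec":
        return cls(id=model_id, codes=tuple(MODEL_CODES[model_id]))


def enumerate_models() -> List[ModelSpec]:
    """All 12 lattice members, in id order."""
    return [ModelSpec.from_id(i) for i in sorted(MODEL_CODES)]


Cell = Tuple[str, str, float]


def _slot_key(code: str, cell: Cell):
    subject, optical, stroke = cell
    if code == "F":
        return ("*",)
    if code == "O":
        return (subject,)
    if code == "C":
        return (subject, optical)
    return (subject, optical, stroke)


@dataclass
class ParameterIndex:
    """Layout of the joint parameter vector for one ModelSpec over given cells.

    ``names`` orders the vector's columns; ``cell_cols[param]`` maps each
    cell (by position in ``cells``) to the column holding that cell's value
    of ``param``.
    """

    cells: List[Cell]
    names: List[str]
    lo: np.ndarray
    hi: np.ndarray
    cell_cols: Dict[str, np.ndarray]

    @property
    def ndim(self) -> int:
        return len(self.names)

    def slot_counts(self) -> Dict[str, int]:
        return {
            p: len(np.unique(self.cell_cols[p])) for p in CODED_PARAMS + FREE_PARAMS
        }


def parameter_index(
    spec: ModelSpec, cells: Sequence[Cell], priors: PriorSpec | None = None
) -> ParameterIndex:
    """Assign shared-parameter slots for every cell under a ModelSpec.

    Slot counts follow the codes (F: 1, O: one per observer, C: one per
    observer x optics, N: one per cell); A and b always get one per cell.
    """
    if len(cells) == 0:
        raise ConfigurationError("no condition cells")
    priors = priors or PriorSpec()
    cells = list(cells)
    names: List[str] = []
    lo: List[float] = []
    hi: List[float] = []
    cell_cols: Dict[str, np.ndarray] = {}

    code_by_param = dict(zip(CODED_PARAMS, spec.codes))
    for param in CODED_PARAMS + FREE_PARAMS:
        code = code_by_param.get(param, "N")
        slot_of: Dict[tuple, int] = {}
        cols = np.empty(len(cells), dtype=int)
        for i, cell in enumerate(cells):
            key = _slot_key(code, cell)
            if key not in slot_of:
                slot_of[key] = len(names)
                tag = "*" if key == ("*",) else "|".join(str(k) for k in key)
                names.append(f"{param}[{tag}]")
                b = getattr(priors, param)
                lo.append(b[0])
                hi.append(b[1])
            cols[i] = slot_of[key]
        cell_cols[param] = cols

    return ParameterIndex(
        cells=cells,
        names=names,
        lo=np.array(lo),
        hi=np.array(hi),
        cell_cols=cell_cols,
    )


@dataclass
class _FamilyData:
    gap: np.ndarray  # (R,)
    unflanked: np.ndarray  # (R,) bool
    k: np.ndarray
    n: np.ndarray
    cell_idx: np.ndarray  # (R,) -> position in index.cells
    trial_row: np.ndarray  # (N,) -> aggregated row
    correct: np.ndarray  # (N,)


def _condense_family(trials: pd.DataFrame, cells: Sequence[Cell]) -> _FamilyData:
    agg = aggregate(trials)
    cell_pos = {c: i for i, c in enumerate(cells)}
    keys = list(zip(agg["subject"], agg["optical"], agg["stroke_arcmin"], agg["gap_arcmin"]))
    cell_idx = np.array([cell_pos[(s, o, st)] for s, o, st, _ in keys], dtype=int)
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
    return _FamilyData(
        gap=np.array([0.0 if g is UNFLANKED else float(g) for g in agg["gap_arcmin"]]),
        unflanked=np.array([g is UNFLANKED for g in agg["gap_arcmin"]]),
        k=agg["n_correct"].to_numpy(),
        n=agg["n_total"].to_numpy(),
        cell_idx=cell_idx,
        trial_row=trial_row,
        correct=trials["correct"].to_numpy().astype(int),
    )


def _family_psi(theta: np.ndarray, data: _FamilyData, index: ParameterIndex, gamma: float) -> np.ndarray:
    """Curve probability for W joint-parameter rows over R aggregated rows."""
    cols = {p: index.cell_cols[p][data.cell_idx] for p in CODED_PARAMS + FREE_PARAMS}
    from scipy.special import ndtr

    A = theta[:, cols["A"]]
    mu = theta[:, cols["mu"]]
    sigma = theta[:, cols["sigma"]]
    m = theta[:, cols["m"]]
    b = theta[:, cols["b"]]
    x = data.gap[None, :]
    crowd = gamma + (A - gamma) * ndtr((x - mu) / sigma)
    recov = np.clip(m * x + b, 0.0, 1.0)
    p = np.maximum(crowd, recov)
    if data.unflanked.any():
        p = np.where(data.unflanked[None, :], A, p)
    return p


def _family_loglik(theta: np.ndarray, data: _FamilyData, index: ParameterIndex, gamma: float) -> np.ndarray:
    p = _family_psi(theta, data, index, gamma)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = data.k[None, :] * np.log(p) + (data.n - data.k)[None, :] * np.log1p(-p)
    term = np.where((data.k[None, :] == 0) & (p == 0.0), 0.0, term)
    term = np.where(((data.n - data.k)[None, :] == 0) & (p == 1.0), 0.0, term)
    out = term.sum(axis=1)
    return np.where(np.isnan(out), -np.inf, out)


@dataclass
class FamilyPosteriorFit(PosteriorFit):
    """Joint posterior over all shared slots of one lattice member."""

    spec: ModelSpec | None = None
    index: ParameterIndex | None = None

    def cell_draws(self, cell: Cell) -> pd.DataFrame:
        """Per-cell parameter draws (columns A, mu, sigma, m, b)."""
        i = self.index.cells.index(cell)
        cols = {
            p: self.index.names[self.index.cell_cols[p][i]]
            for p in CODED_PARAMS + FREE_PARAMS
        }
        out = pd.DataFrame(
            {p: self.draws[name].to_numpy() for p, name in cols.items()}
        )
        return out[["A", "mu", "sigma", "m", "b"]]


def default_family_settings(ndim: int) -> SamplerSettings:
    """Ensemble budget scaled to the joint dimension."""
    walkers = max(64, 2 * ndim + 2)
    walkers += walkers % 2
    return SamplerSettings(walkers=walkers, steps=1500, warmup=1500, max_retained=1000)


def fit_family(
    trials: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    design: DesignSpec | None = None,
    gamma: float = GUESS_RATE_4AFC,
) -> FamilyPosteriorFit:
    """Jointly fit all condition cells under one lattice member's sharing.

    Cells are taken from the trials; if a design is supplied, trials must not
    reference cells outside it.  Pointwise per-trial log-likelihoods for the
    retained draws are kept for WAIC.
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    priors = priors or PriorSpec()
    observed = sorted(
        set(zip(trials["subject"], trials["optical"], trials["stroke_arcmin"]))
    )
    if design is not None:
        extra = set(observed) - set(design.cells())
        if extra:
            raise ConfigurationError(f"trials reference cells absent from design: {sorted(extra)}")
    index = parameter_index(spec, observed, priors)
    data = _condense_family(trials, index.cells)
    settings = settings or default_family_settings(index.ndim)

    pooled, rhat = _run_ensemble(
        lambda th: _family_loglik(th, data, index, gamma),
        index.lo, index.hi, settings, seed,
    )
    draws = pd.DataFrame(pooled, columns=index.names)
    p = _family_psi(pooled, data, index, gamma)[:, data.trial_row]
    c = data.correct[None, :]
    with np.errstate(divide="ignore"):
        pointwise = np.where(c == 1, np.log(p), np.log1p(-p))

    diagnostics = {
        "rhat": dict(zip(index.names, np.asarray(rhat, dtype=float).ravel())),
        "converged": bool(np.all(rhat <= settings.rhat_threshold)),
        "prior_dominated": int(data.correct.sum()) in (0, len(data.correct)),
        "boundary_hugging": _boundary_flags(pooled, index.lo, index.hi, index.names),
        "n_trials": len(data.correct),
        "seed": seed,
    }
    return FamilyPosteriorFit(
        draws=draws,
        pointwise_loglik=pointwise,
        diagnostics=diagnostics,
        bounds={n: (float(l), float(h)) for n, l, h in zip(index.names, index.lo, index.hi)},
        gamma=gamma,
        spec=spec,
        index=index,
    )


@dataclass(frozen=True)
class WaicResult:
    waic: float
    p_waic: float
    lppd: float


def waic(fit: PosteriorFit) -> WaicResult:
    """WAIC from the retained draws' pointwise log-likelihood matrix.

    lppd is computed with log-sum-exp stabilization; pWAIC is the pointwise
    posterior variance (sample variance over draws).
    """
    ll = np.asarray(fit.pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("WAIC needs a draws x points matrix with >= 2 draws")
    s = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(s)))
    # center per point before the variance so identical draws give exactly 0
    p_waic = float(np.sum(np.var(ll - ll[0:1, :], axis=0, ddof=1)))
    return WaicResult(waic=-2.0 * (lppd - p_waic), p_waic=p_waic, lppd=lppd)


def compare(fits: Dict[int, PosteriorFit] | Sequence[Tuple[ModelSpec, PosteriorFit]]) -> pd.DataFrame:
    """Rank fitted lattice members by WAIC (ascending; lower is better).

    Ties break toward the lower pWAIC, then the lower model id.  The
    ``loglik`` column is the best (maximum) total log-likelihood over the
    retained draws; ``lppd`` is the pointwise predictive density.
    """
    items: List[Tuple[int, str, PosteriorFit]] = []
    if isinstance(fits, dict):
        for mid, fit in fits.items():
            label = fit.spec.label if getattr(fit, "spec", None) else MODEL_CODES.get(mid, "?")
            items.append((mid, label, fit))
    else:
        for spec, fit in fits:
            items.append((spec.id, spec.label, fit))
    if len(items) < 2:
        raise ValueError("need at least 2 fitted models to compare")

    rows = []
    for mid, label, fit in items:
        w = waic(fit)
        rows.append(
            {
                "model_id": mid,
                "codes": label,
                "WAIC": w.waic,
                "pWAIC": w.p_waic,
                "lppd": w.lppd,
                "loglik": float(np.max(fit.pointwise_loglik.sum(axis=1))),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        by=["WAIC", "pWAIC", "model_id"], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
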
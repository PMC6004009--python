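"""Synthetic trial-level data with the statistical structure of the experiment.

The study measured Tumbling-E identification for 3 observers under two
optical conditions (with and without adaptive-optics correction of ocular
aberrations), at 2-5 stroke sizes per condition, with flanker gaps from
abutting (0 arcmin edge-to-edge) to 1.6 arcmin plus an unflanked condition,
and at least 20 trials per size x spacing cell (10 per block, each condition
run in at least two sessions).  No raw data were deposited, so this module
generates datasets with that design: binomial responses drawn from the
compound psychometric curve of :mod:`fovcrowd.model`.

The default ground truth follows the study's headline structure: the crowding
sigmoid's width and location are shared across sizes within an observer, the
recovery slope is shared across everything, and only the asymptote ``A`` and
recovery intercept ``b`` move with stimulus size (``A`` via a cumulative-
Gaussian acuity curve anchored at each condition's 75%-correct stroke size,
``b`` about 0.2 below ``A`` to mirror the ~20% abutting-flanker deficit).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import GUESS_RATE_4AFC, UNFLANKED, CrowdingParams, psi

__all__ = [
    "TrialRecord",
    "DesignSpec",
    "GroundTruth",
    "ConfigurationError",
    "default_design",
    "canonical_truth",
    "shared_structure_truth",
    "simulate",
    "aggregate",
    "gap_sort_key",
    "TRIAL_COLUMNS",
]

#: Canonical column order of a trial table.
TRIAL_COLUMNS = ["subject", "optical", "stroke_arcmin", "gap_arcmin", "correct"]

#: Stroke sizes tested per subject and optical condition (arcmin of one
#: stroke; letter height is 5 strokes).
STROKES_AO = {
    "S1": (0.61, 0.73),
    "S2": (0.37, 0.42, 0.47, 0.53, 0.58),
    "S3": (0.53, 0.58, 0.63, 0.69),
}
STROKES_NOAO = {
    "S1": (0.85, 0.97),
    "S2": (0.63, 0.69, 0.79),
    "S3": (0.63, 0.69, 0.74, 0.79),
}

#: Estimated stroke size (arcmin) at 75% unflanked accuracy, per condition.
MAR75 = {
    ("S1", "AO"): 0.55,
    ("S1", "noAO"): 0.75,
    ("S2", "AO"): 0.40,
    ("S2", "noAO"): 0.625,
    ("S3", "AO"): 0.60,
    ("S3", "noAO"): 0.625,
}


class ConfigurationError(ValueError):
    """A design/ground-truth mismatch or otherwise unusable configuration."""


@dataclass(frozen=True)
class TrialRecord:
    """One psychophysical trial."""

    subject: str
    optical: str  # "AO" | "noAO"
    stroke_arcmin: float
    gap: object  # float arcmin or UNFLANKED
    correct: int


@dataclass(frozen=True)
class DesignSpec:
    """The factorial layout of an experiment.

    ``strokes`` maps (subject, optical) to the stroke sizes tested; every
    cell shares the finite ``gaps`` grid plus, optionally, an unflanked
    condition, with ``trials_per_cell`` trials in each size x spacing cell.
    """

    subjects: Tuple[str, ...]
    strokes: Dict[Tuple[str, str], Tuple[float, ...]]
    gaps: Tuple[float, ...]
    include_unflanked: bool = True
    trials_per_cell: int = 20
    seed: int | None = None

    def __post_init__(self):
        if self.trials_per_cell < 1:
            raise ConfigurationError("trials_per_cell must be >= 1")
        if len(self.gaps) == 0:
            raise ConfigurationError("gap grid must be non-empty")
        if any(g < 0 for g in self.gaps):
            raise ConfigurationError("gaps must be non-negative")
        if list(self.gaps) != sorted(self.gaps):
            raise ConfigurationError("gap grid must be sorted")

    def cells(self) -> List[Tuple[str, str, float]]:
        """All (subject, optical, stroke) condition cells, in canonical order."""
        out = []
        for subject in self.subjects:
            for optical in ("AO", "noAO"):
                for stroke in self.strokes.get((subject, optical), ()):
                    out.append((subject, optical, stroke))
        return out

    def gap_values(self) -> list:
        gaps = [float(g) for g in self.gaps]
        if self.include_unflanked:
            gaps.append(UNFLANKED)
        return gaps


@dataclass(frozen=True)
class GroundTruth:
    """Mapping from each condition cell to its generating parameters."""

    params: Dict[Tuple[str, str, float], CrowdingParams]

    def for_cell(self, cell: Tuple[str, str, float]) -> CrowdingParams:
        try:
            return self.params[cell]
        except KeyError:
            raise ConfigurationError(f"no ground-truth parameters for cell {cell}")


def default_design(trials_per_cell: int = 20, gap_step: float = 0.2) -> DesignSpec:
    """The study's factorial design: 3 subjects x 2 optical conditions.

    Stroke sizes are the ones tested per subject; finite gaps run from
    abutting (0) to 1.6 arcmin in ``gap_step`` increments, plus an unflanked
    condition.  20 trials/cell reflects 10 trials per block over at least two
    sessions.
    """
    n = int(round(1.6 / gap_step))
    gaps = tuple(round(i * gap_step, 10) for i in range(n + 1))
    strokes: Dict[Tuple[str, str], Tuple[float, ...]] = {}
    for subject in ("S1", "S2", "S3"):
        strokes[(subject, "AO")] = STROKES_AO[subject]
        strokes[(subject, "noAO")] = STROKES_NOAO[subject]
    return DesignSpec(
        subjects=("S1", "S2", "S3"),
        strokes=strokes,
        gaps=gaps,
        include_unflanked=True,
        trials_per_cell=trials_per_cell,
    )


#: Per-subject crowding-sigmoid parameters for the canonical ground truth:
#: width sigma and location mu are shared across sizes and optical conditions
#: within an observer; the recovery slope is shared across everything.
_SUBJECT_SIGMOID = {
    "S1": {"sigma": 0.50, "mu": 0.45},
    "S2": {"sigma": 0.40, "mu": 0.30},
    "S3": {"sigma": 0.45, "mu": 0.40},
}
_RECOVERY_SLOPE = -0.30
_ACUITY_WIDTH = 0.15  # arcmin; spread of the A-vs-stroke acuity curve
_ABUTTING_DEFICIT = 0.20  # b sits this far below A (floored at gamma)


def _asymptote(stroke: float, mar75: float, gamma: float = GUESS_RATE_4AFC) -> float:
    """Unflanked accuracy vs. stroke size: cumulative Gaussian through 75% at MAR."""
    loc = mar75 - _ACUITY_WIDTH * norm.ppf((0.75 - gamma) / (1 - gamma))
    a = gamma + (1 - gamma) * norm.cdf((stroke - loc) / _ACUITY_WIDTH)
    return float(np.clip(a, gamma + 1e-3, 1 - 1e-4))


def canonical_truth(design: DesignSpec) -> GroundTruth:
    """Ground truth with the study's best-supported sharing structure.

    sigma and mu per observer, one recovery slope overall, A and b per cell.
    """
    params = {}
    for subject, optical, stroke in design.cells():
        sig = _SUBJECT_SIGMOID[subject] if subject in _SUBJECT_SIGMOID else {
            "sigma": 0.45, "mu": 0.35
        }
        mar = MAR75.get((subject, optical), 0.6)
        a = _asymptote(stroke, mar)
        b = max(a - _ABUTTING_DEFICIT, GUESS_RATE_4AFC)
        params[(subject, optical, stroke)] = CrowdingParams(
            A=a, mu=sig["mu"], sigma=sig["sigma"], m=_RECOVERY_SLOPE, b=b
        ).validate()
    return GroundTruth(params)


def shared_structure_truth(
    design: DesignSpec,
    sigma_by_subject: Dict[str, float],
    mu_by_subject: Dict[str, float],
    m: float = _RECOVERY_SLOPE,
    A_by_cell: Dict[Tuple[str, str, float], float] | None = None,
    b_offset: float = _ABUTTING_DEFICIT,
) -> GroundTruth:
    """Ground truth with explicit observer-shared sigma/mu and global slope.

    Used for model-selection recovery studies: data generated this way have
    exactly the sharing structure of the observer-yoked ('OOF') model.
    """
    params = {}
    for cell in design.cells():
        subject, optical, stroke = cell
        if A_by_cell is not None and cell in A_by_cell:
            a = A_by_cell[cell]
        else:
            a = _asymptote(stroke, MAR75.get((subject, optical), 0.6))
        b = max(a - b_offset, GUESS_RATE_4AFC)
        params[cell] = CrowdingParams(
            A=a, mu=mu_by_subject[subject], sigma=sigma_by_subject[subject], m=m, b=b
        ).validate()
    return GroundTruth(params)


def gap_sort_key(gap) -> tuple:
    """Sort key placing finite gaps ascending, then UNFLANKED last."""
    if gap is UNFLANKED:
        return (1, 0.0)
    return (0, float(gap))


def _cell_rng(seed: int, subject: str, optical: str, stroke: float, gap) -> np.random.Generator:
    """Independent, reproducible substream per (cell, gap).

    The stream key hashes the cell coordinates, so adding or removing a cell
    never perturbs the draws of any other cell.
    """
    tag = f"{subject}|{optical}|{stroke:.6f}|{'U' if gap is UNFLANKED else format(float(gap), '.6f')}"
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(tag.encode())])


def simulate(
    design: DesignSpec,
    truth: GroundTruth,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a full synthetic dataset: one Bernoulli trial per row.

    Each trial in cell (subject, optical, stroke, gap) is an independent
    Bernoulli draw with success probability ``psi(gap, truth params)``
    (unflanked trials succeed with probability ``A``).  The same seed yields
    a byte-identical table.
    """
    if seed is None:
        seed = design.seed
    if seed is None:
        raise ConfigurationError("a seed is required (in the design or as an argument)")
    rows = []
    n = design.trials_per_cell
    for cell in design.cells():
        subject, optical, stroke = cell
        params = truth.for_cell(cell)
        for gap in design.gap_values():
            p = float(psi(gap, params))
            rng = _cell_rng(seed, subject, optical, stroke, gap)
            correct = (rng.random(n) < p).astype(int)
            gap_out = gap if gap is UNFLANKED else float(gap)
            for c in correct:
                rows.append((subject, optical, stroke, gap_out, int(c)))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def aggregate(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse trials to per-cell counts (n_correct, n_total).

    Keyed by (subject, optical, stroke_arcmin, gap_arcmin); the total count
    equals the number of input trials and each observed key appears once.
    """
    if len(trials) == 0:
        return pd.DataFrame(
            columns=["subject", "optical", "stroke_arcmin", "gap_arcmin", "n_correct", "n_total"]
        )
    grouped = trials.groupby(
        ["subject", "optical", "stroke_arcmin", "gap_arcmin"], sort=False
    )["correct"].agg(n_correct="sum", n_total="count").reset_index()
    grouped = grouped.sort_values(
        by=["subject", "optical", "stroke_arcmin", "gap_arcmin"],
        key=lambda col: col.map(gap_sort_key) if col.name == "gap_arcmin" else col,
        kind="stable",
    ).reset_index(drop=True)
    return grouped
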
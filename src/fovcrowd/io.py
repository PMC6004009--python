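"""Trial-table CSV dialect, run configuration, and artifact provenance.

A trial table is a flat CSV with header ``subject,optical,stroke_arcmin,
gap_arcmin,correct``: one row per trial, ``gap_arcmin`` a non-negative
decimal or the literal token ``UNFLANKED`` (a token, never a sentinel
number, so it can't leak into arithmetic), ``correct`` in {0,1}, ``optical``
in {AO,noAO}.  Lines starting with ``#`` are provenance comments and are
ignored by the reader; the writer emits the canonical float formatting, so
parse-then-write round-trips canonical files byte-identically.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field  # field used by RunConfig
from pathlib import Path
from typing import Dict, List

import pandas as pd

from . import __version__
from .model import UNFLANKED
from .synth import TRIAL_COLUMNS

__all__ = [
    "TrialTableError",
    "read_trials",
    "write_trials",
    "provenance_header",
    "RunConfig",
]

_HEADER = ",".join(TRIAL_COLUMNS)
_OPTICAL = {"AO", "noAO"}


class TrialTableError(ValueError):
    """Malformed trial table; the message lists offending line numbers."""


def _format_gap(g) -> str:
    if g is UNFLANKED:
        return "UNFLANKED"
    return repr(float(g))


def _format_float(x: float) -> str:
    return repr(float(x))


def read_trials(path) -> pd.DataFrame:
    """Parse a trial-table CSV, validating every row.

    Returns a DataFrame in canonical column order with ``gap_arcmin`` holding
    floats or the UNFLANKED token.  All malformed rows are collected and
    reported together, each with its 1-based line number.
    """
    path = Path(path)
    errors: List[str] = []
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if not header_seen:
            if line.strip() != _HEADER:
                raise TrialTableError(
                    f"line {lineno}: expected header '{_HEADER}', got '{line.strip()}'"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 5:
            errors.append(f"line {lineno}: expected 5 fields, got {len(parts)}")
            continue
        subject, optical, stroke_s, gap_s, correct_s = (p.strip() for p in parts)
        if optical not in _OPTICAL:
            errors.append(f"line {lineno}: unknown optical token '{optical}'")
            continue
        try:
            stroke = float(stroke_s)
            if stroke <= 0:
                raise ValueError
        except ValueError:
            errors.append(f"line {lineno}: invalid stroke '{stroke_s}'")
            continue
        if gap_s == "UNFLANKED":
            gap = UNFLANKED
        else:
            try:
                gap = float(gap_s)
                if gap < 0:
                    errors.append(f"line {lineno}: negative gap {gap_s}")
                    continue
            except ValueError:
                errors.append(f"line {lineno}: invalid gap '{gap_s}'")
                continue
        if correct_s not in ("0", "1"):
            errors.append(f"line {lineno}: non-binary correct '{correct_s}'")
            continue
        rows.append((subject, optical, stroke, gap, int(correct_s)))
    if not header_seen:
        raise TrialTableError("no header line found")
    if errors:
        raise TrialTableError("malformed trial table:\n  " + "\n  ".join(errors))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(trials: pd.DataFrame, path, comments: List[str] | None = None) -> None:
    """Write a trial table in the canonical dialect (plus ``#`` comments)."""
    path = Path(path)
    buf = _io.StringIO()
    for c in comments or []:
        buf.write(f"# {c}\n")
    buf.write(_HEADER + "\n")
    for row in trials.itertuples(index=False):
        buf.write(
            f"{row.subject},{row.optical},{_format_float(row.stroke_arcmin)},"
            f"{_format_gap(row.gap_arcmin)},{int(row.correct)}\n"
        )
    path.write_text(buf.getvalue(), encoding="utf-8")


def provenance_header(seed: int | None, config: Dict | None = None) -> List[str]:
    """Comment lines recording package version, seed, and a config digest."""
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    digest = hashlib.sha256(blob).hexdigest()[:12]
    return [f"fovcrowd {__version__} seed={seed} config_sha={digest}"]


@dataclass
class RunConfig:
    """End-to-end run settings; every field validates in its home module.

    Design overrides feed :func:`fovcrowd.synth.default_design`; prior and
    sampler settings are constructed (and therefore validated) by
    :class:`fovcrowd.fitting.PriorSpec` / ``SamplerSettings``.
    """

    seed: int = 0
    trials_per_cell: int = 20
    gap_step: float = 0.2
    walkers: int = 32
    steps: int = 500
    warmup: int = 500
    criterion: float = 0.025
    n_mc: int = 1000
    outdir: str = "results"
    models: List[int] = field(default_factory=lambda: list(range(12)))

    def __post_init__(self):
        if not 0 < self.criterion < 0.75:
            raise ValueError("criterion must be in (0, 0.75)")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        bad = [m for m in self.models if m not in range(12)]
        if bad:
            raise ValueError(f"unknown model ids: {bad}")

    def as_dict(self) -> Dict:
        return {
            "seed": self.seed,
            "trials_per_cell": self.trials_per_cell,
            "gap_step": self.gap_step,
            "walkers": self.walkers,
            "steps": self.steps,
            "warmup": self.warmup,
            "criterion": self.criterion,
            "n_mc": self.n_mc,
            "models": list(self.models),
        }
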
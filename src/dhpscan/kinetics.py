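"""First-order phospho-decay fits: semilog OLS half-lives for phospho-His.

The phosphoramidate (P-N) bond of phospho-His hydrolyzes faster at acidic pH.
Band intensities from a dephosphorylation time course are normalized to 100%
at t = 0, log-transformed, and fit by ordinary least squares against time;
the decay constant is the negative slope and the half-life ln2/k.  A slope
indistinguishable from zero (or positive) reports an infinite half-life —
"no measurable decay within the observation window".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TimeCourse",
    "DecayFit",
    "normalize_t0",
    "fit_decay",
    "compare_conditions",
    "DEFAULT_TIME_GRID",
]

# Dephosphorylation sampling grid (minutes): t0 plus the stopped time points.
DEFAULT_TIME_GRID = (0.0, 1.0, 3.0, 5.0, 15.0, 30.0)

# |slope| below this (per minute) is treated as no measurable decay.
ZERO_SLOPE_TOL = 1e-10


@dataclass(frozen=True)
class TimeCourse:
    """A phosphosignal decay time course (minutes, arbitrary positive units)."""

    times: tuple[float, ...]
    signal: tuple[float, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and signal must be matching 1-D sequences")
        if t.size == 0:
            raise ValueError("empty time course")
        if t[0] != 0.0:
            raise ValueError("first time point must be t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(s)):
            raise ValueError("non-finite signal")

    @classmethod
    def from_arrays(cls, times, signal, condition: str = "") -> "TimeCourse":
        return cls(tuple(float(x) for x in times), tuple(float(y) for y in signal), condition)


@dataclass(frozen=True)
class DecayFit:
    """Semilog fit result: rate constant (1/min), half-life (min), diagnostics."""

    k: float
    half_life: float
    intercept: float
    r_squared: float
    n_points: int
    condition: str = ""

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("rate constant must be >= 0")
        if math.isfinite(self.half_life) and not math.isclose(
            self.half_life * self.k, math.log(2.0), rel_tol=1e-9
        ):
            raise ValueError("half_life inconsistent with k")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r^2 out of [0,1]: {self.r_squared}")


def normalize_t0(tc: TimeCourse) -> TimeCourse:
    """Scale the course so the t = 0 signal reads 100 (percent of initial)."""
    s0 = tc.signal[0]
    if s0 <= 0:
        raise ValueError("t=0 signal must be positive to normalize")
    scale = 100.0 / s0
    return TimeCourse(tc.times, tuple(v * scale for v in tc.signal), tc.condition)


def fit_decay(tc: TimeCourse, drop_nonpositive: bool = True) -> DecayFit:
    """Fit ln(signal) vs time by OLS; return rate constant and half-life.

    Non-positive signal points (a gel band can read zero) are dropped with
    ``drop_nonpositive``; at least three positive points must remain.  A
    non-negative fitted slope yields k = 0 and an infinite half-life.
    """
    t = np.asarray(tc.times, dtype=float)
    s = np.asarray(tc.signal, dtype=float)
    if drop_nonpositive:
        keep = s > 0
        t, s = t[keep], s[keep]
    elif np.any(s <= 0):
        raise ValueError("non-positive signal; cannot log-transform")
    if t.size < 3:
        raise ValueError(f"need >= 3 positive points, have {t.size}")
    res = stats.linregress(t, np.log(s))
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2
    if not math.isfinite(r2):  # constant signal: correlation undefined
        r2 = 0.0
    k = -slope
    if k <= ZERO_SLOPE_TOL:
        return DecayFit(
            k=0.0, half_life=math.inf, intercept=intercept,
            r_squared=min(r2, 1.0), n_points=int(t.size), condition=tc.condition,
        )
    return DecayFit(
        k=k, half_life=math.log(2.0) / k, intercept=intercept,
        r_squared=min(r2, 1.0), n_points=int(t.size), condition=tc.condition,
    )


def compare_conditions(
    fits: Sequence[DecayFit], reference: Optional[str] = None
) -> list[dict]:
    """Tabulate half-lives with the ratio to a reference condition.

    The reference defaults to the first fit.  Ratios against an infinite
    reference half-life are reported as None with a "reference stable" note;
    an infinite half-life itself is reported as "no measurable decay".
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    ref = fits[0]
    if reference is not None:
        matches = [f for f in fits if f.condition == reference]
        if not matches:
            raise ValueError(f"reference condition {reference!r} not among fits")
        ref = matches[0]
    rows = []
    for f in fits:
        if math.isinf(f.half_life):
            ratio, note = None, "no measurable decay"
        elif math.isinf(ref.half_life):
            ratio, note = None, "reference stable"
        else:
            ratio, note = f.half_life / ref.half_life, ""
        rows.append(
            {
                "condition": f.condition,
                "k_per_min": f.k,
                "half_life_min": f.half_life,
                "r_squared": f.r_squared,
                "n_points": f.n_points,
                "ratio_vs_reference": ratio,
                "note": note,
            }
        )
    return rows
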
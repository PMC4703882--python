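"""Quantifiers for densitometry-style biochemical readouts.

Covers the EMSA fraction-bound titration (percent DNA bound vs protein
concentration and its half-saturation point), ATP-hydrolysis time courses
(linear rate and ssDNA stimulation ratio) and simple fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TitrationCurve:
    concentrations: np.ndarray  # uM, strictly ascending
    fraction_bound: np.ndarray  # percent in [0, 100]

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        f = np.asarray(self.fraction_bound, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "fraction_bound", f)
        if len(c) != len(f):
            raise ValueError("concentration and fraction arrays differ in length")
        if not (np.diff(c) > 0).all():
            raise ValueError("concentrations must be strictly ascending")
        if ((f < 0) | (f > 100)).any():
            raise ValueError("fractions must lie in [0, 100]")


@dataclass(frozen=True)
class TimeCourse:
    times: np.ndarray       # minutes
    hydrolysed: np.ndarray  # amount of ATP hydrolysed

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.hydrolysed, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "hydrolysed", y)
        if len(t) != len(y):
            raise ValueError("times and amounts differ in length")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be ascending")
        if (y < 0).any():
            raise ValueError("hydrolysed amounts must be non-negative")


def fraction_bound(concentrations, bound, unbound) -> TitrationCurve:
    """Percent DNA bound per lane: 100 * bound / (bound + unbound)."""
    bound = np.asarray(bound, dtype=float)
    unbound = np.asarray(unbound, dtype=float)
    if (bound < 0).any() or (unbound < 0).any():
        raise ValueError("band intensities must be non-negative")
    total = bound + unbound
    zero = np.flatnonzero(total == 0)
    if len(zero):
        raise ValueError(f"all-zero lane at index {int(zero[0])}")
    return TitrationCurve(
        concentrations=np.asarray(concentrations, dtype=float),
        fraction_bound=100.0 * bound / total,
    )


def half_saturation(curve: TitrationCurve) -> float:
    """Concentration at which 50% of the DNA is bound.

    Linear interpolation at the first upward crossing of 50%; the curve must
    span 50% (reported as the crossing concentration, not a fitted binding
    constant).
    """
    f = curve.fraction_bound
    c = curve.concentrations
    if f.min() >= 50 or f.max() < 50:
        raise ValueError("titration curve does not span 50% bound")
    for i in range(1, len(f)):
        if f[i - 1] < 50 <= f[i]:
            return float(c[i - 1] + (50 - f[i - 1]) * (c[i] - c[i - 1]) / (f[i] - f[i - 1]))
    raise ValueError("no upward crossing of 50% found")


def hydrolysis_rate(tc: TimeCourse, window: tuple[float, float] | None = None) -> float:
    """Least-squares slope of the (linear-phase) time course.

    ``window`` optionally restricts the fit to times within [t0, t1]; by
    default all points are used.
    """
    t, y = tc.times, tc.hydrolysed
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, y = t[sel], y[sel]
    if len(t) < 3:
        raise ValueError("need at least three time points")
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def stimulation_ratio(plus_dna: float, minus_dna: float) -> float:
    """Ratio of hydrolysis rates with vs without ssDNA."""
    if minus_dna == 0:
        raise ValueError("baseline rate is zero")
    return float(plus_dna) / float(minus_dna)


def fold_change(signal_a: float, signal_b: float) -> float:
    if signal_a <= 0 or signal_b <= 0:
        raise ValueError("fold change needs positive signals")
    return float(signal_a) / float(signal_b)
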
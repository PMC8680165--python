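"""Sigmoid dose-response curves and tumor-level IC50 aggregation.

Each clone's response is a two-parameter logistic in log2 dose with fixed
asymptotes (0% and 100% cell death): death(x) = 1 / (1 + 2^{b (m - x)}),
where m = log2(IC50 uM) and b > 0 is the slope (default 1).  A tumor is a
weighted mixture of clones; its combined curve is the weighted average of
clone curves, which is no longer a logistic, so the combined IC50 (the
dose killing half the cells) is found with a safeguarded Newton iteration
instead of averaging the clone IC50s — the naive weighted average ignores
the sigmoid shape and is biased whenever the clone IC50s differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ValidationError

_LN2 = np.log(2.0)
_CLAMP = 1e-12


@dataclass
class DoseResponseCurve:
    """A clone's curve: m = log2(IC50 uM) and unitless slope b."""

    m: float
    b: float = 1.0

    def __post_init__(self):
        self.m = float(self.m)
        self.b = float(self.b)
        if not np.isfinite(self.m):
            raise ValidationError("log2 IC50 must be finite")
        if self.b <= 0:
            raise ValidationError("dose-response slope must be positive")


@dataclass
class MixtureCurve:
    """Weighted mixture of clone dose-response curves (weights sum to 1)."""

    components: list  # list of (weight, DoseResponseCurve)

    def __post_init__(self):
        clean = []
        for w, curve in self.components:
            if not (0.0 < w <= 1.0):
                raise ValidationError(f"mixture weight {w} outside (0, 1]")
            if not isinstance(curve, DoseResponseCurve):
                curve = DoseResponseCurve(*curve)
            clean.append((float(w), curve))
        self.components = clean
        total = sum(w for w, _ in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"mixture weights sum to {total}, expected 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.components])

    @property
    def ms(self) -> np.ndarray:
        return np.array([c.m for _, c in self.components])

    @property
    def bs(self) -> np.ndarray:
        return np.array([c.b for _, c in self.components])


def cell_death_fraction(curve: DoseResponseCurve, dose_log2) -> float | np.ndarray:
    """Fraction of cells killed at a dose (log2 uM); 0.5 exactly at the IC50."""
    dose_log2 = np.asarray(dose_log2, dtype=float)
    out = 1.0 / (1.0 + np.exp2(curve.b * (curve.m - dose_log2)))
    return float(out) if out.ndim == 0 else out


def mixture_death_fraction(mix: MixtureCurve, dose_log2) -> float | np.ndarray:
    dose_log2 = np.asarray(dose_log2, dtype=float)
    out = sum(w * cell_death_fraction(c, dose_log2) for w, c in mix.components)
    return float(out) if np.ndim(out) == 0 else out


def naive_aggregate(mix: MixtureCurve) -> float:
    """Weighted average of clone log2-IC50s — the biased shortcut, kept as
    the Newton initializer and for contrast with the proper aggregate."""
    return float(np.dot(mix.weights, mix.ms))


def _death_and_derivative(mix: MixtureCurve, x: float):
    w, m, b = mix.weights, mix.ms, mix.bs
    h = 1.0 / (1.0 + np.exp2(b * (m - x)))
    h = np.clip(h, _CLAMP, 1.0 - _CLAMP)
    g = float(np.dot(w, h)) - 0.5
    dg = float(np.dot(w, _LN2 * b * h * (1.0 - h)))
    return g, dg


def aggregate_ic50_newton(mix: MixtureCurve, tol: float = 1e-8,
                          max_iter: int = 100) -> float:
    """Combined log2 IC50 of a clone mixture via safeguarded Newton iteration.

    The root of g(x) = mixture_death(x) - 0.5 is unique (g is strictly
    increasing) and lies in [min m, max m].  Iterations start from the
    naive weighted average; any Newton step that leaves the bracket or
    fails to shrink |g| falls back to a bisection step, so convergence is
    guaranteed.
    """
    ms = mix.ms
    if len(mix.components) == 1:
        return float(ms[0])
    lo, hi = float(ms.min()), float(ms.max())
    if hi - lo < 1e-15:
        return lo
    x = min(max(naive_aggregate(mix), lo), hi)
    g, dg = _death_and_derivative(mix, x)
    for _ in range(max_iter):
        if abs(g) <= tol:
            return float(x)
        if g > 0:
            hi = x
        else:
            lo = x
        x_new = x - g / dg if dg > 0 else None
        if x_new is None or not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        g_new, dg_new = _death_and_derivative(mix, x_new)
        if abs(g_new) >= abs(g):
            x_new = 0.5 * (lo + hi)
            g_new, dg_new = _death_and_derivative(mix, x_new)
        x, g, dg = x_new, g_new, dg_new
        if hi - lo < 1e-14:
            return float(x)
    if abs(g) <= tol * 10:
        return float(x)
    raise ValidationError("Newton aggregation failed to converge")  # unreachable in practice
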
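"""Median-effect analysis and combination-index synergy scoring.

The median-effect model relates dose D to the fraction of cells affected,
fa, through  fa/fu = (D/Dm)^m  with fu = 1 - fa.  In log-log form,

    log10(fa/fu) = m * log10(D) - m * log10(Dm),

the model is a straight line whose slope is m and whose x-intercept is
log10(Dm).  Constant-ratio two-drug mixtures are scored by the combination
index (CI): the sum of the dose fractions each component contributes at a
given effect level, relative to the monotherapy doses that would produce
the same effect.  CI < 1 is synergism, CI = 1 additivity, CI > 1
antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MedianEffectFit",
    "CombinationIndexResult",
    "median_effect_fit",
    "fa_at_dose",
    "dose_at_fa",
    "combination_index",
    "ci_profile",
    "classify_interaction",
]

DEFAULT_FA_GRID = (0.50, 0.75, 0.90)


@dataclass(frozen=True)
class MedianEffectFit:
    """Straight-line fit of the median-effect plot.

    Attributes
    ----------
    m
        Slope of the plot (sigmoidicity of the dose-effect curve).
    dm
        Median-effect dose in µM (dose producing fa = 0.5), from the
        x-intercept.
    r
        Linear correlation coefficient of the plotted points.
    n_used
        Number of points entering the regression.
    excluded
        Indices of points dropped because fa was outside (0, 1).
    """

    m: float
    dm: float
    r: float
    n_used: int
    excluded: tuple[int, ...] = ()


@dataclass(frozen=True)
class CombinationIndexResult:
    """CI of a constant-ratio pair tabulated over effect levels."""

    fa: np.ndarray
    ci_exclusive: np.ndarray
    ci_nonexclusive: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    dx1: np.ndarray
    dx2: np.ndarray
    ratio: tuple[float, float]
    classification: tuple[str, ...]


def median_effect_fit(concentrations, fa) -> MedianEffectFit:
    """Fit the median-effect line by ordinary least squares.

    Points with fa outside the open interval (0, 1) carry no information
    on the log-odds scale; they are excluded and recorded.  At least two
    usable points are required.
    """
    conc = np.asarray(concentrations, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if conc.shape != fa.shape or conc.ndim != 1:
        raise ValueError("concentrations and fa must be 1-D and equally long")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    usable = (fa > 0.0) & (fa < 1.0)
    excluded = tuple(int(i) for i in np.flatnonzero(~usable))
    if usable.sum() < 2:
        raise ValueError(
            f"median-effect fit needs >= 2 points with fa in (0,1); "
            f"got {int(usable.sum())}"
        )
    x = np.log10(conc[usable])
    y = np.log10(fa[usable] / (1.0 - fa[usable]))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m == 0:
        raise ValueError("degenerate median-effect fit: zero slope")
    dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(
        m=m, dm=dm, r=float(res.rvalue),
        n_used=int(usable.sum()), excluded=excluded,
    )


def fa_at_dose(fit: MedianEffectFit, dose: float) -> float:
    """Fraction affected predicted at a dose; fa(0) = 0."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if dose == 0:
        return 0.0
    return float(1.0 / (1.0 + (fit.dm / dose) ** fit.m))


def dose_at_fa(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing a given effect level; inverse of :func:`fa_at_dose`."""
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must lie strictly inside (0, 1)")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_mix: MedianEffectFit,
    ratio: tuple[float, float],
    fa: float,
    mode: str = "exclusive",
) -> float:
    """Combination index at one effect level for a constant-ratio mixture.

    The total mixture dose reaching ``fa`` is read off the mixture fit and
    split into component doses by ``ratio``; each is divided by the
    monotherapy dose isoeffective at ``fa``.  ``mode="nonexclusive"`` adds
    the product of the two dose fractions.
    """
    r1, r2 = ratio
    if not np.isclose(r1 + r2, 1.0):
        raise ValueError("ratio fractions must sum to 1")
    if mode not in ("exclusive", "nonexclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    d_total = dose_at_fa(fit_mix, fa)
    d1, d2 = r1 * d_total, r2 * d_total
    dx1 = dose_at_fa(fit_a, fa)
    dx2 = dose_at_fa(fit_b, fa)
    ci = d1 / dx1 + d2 / dx2
    if mode == "nonexclusive":
        ci += (d1 * d2) / (dx1 * dx2)
    return float(ci)


def classify_interaction(ci: float, band_epsilon: float = 0.0) -> str:
    """Map a CI value to synergism / additive / antagonism.

    ``band_epsilon`` widens the additive band for noisy data; the default
    0 applies the strict rule (only CI exactly 1 is additive).
    """
    if ci <= 0:
        raise ValueError("CI must be positive")
    if ci < 1.0 - band_epsilon:
        return "synergism"
    if abs(ci - 1.0) <= band_epsilon:
        return "additive"
    return "antagonism"


def ci_profile(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_mix: MedianEffectFit,
    ratio: tuple[float, float],
    fa_grid=DEFAULT_FA_GRID,
    band_epsilon: float = 0.0,
) -> CombinationIndexResult:
    """Tabulate exclusive and nonexclusive CI over a grid of effect levels.

    Classification per level uses the exclusive CI.
    """
    fa_arr = np.asarray(fa_grid, dtype=float)
    if fa_arr.ndim != 1 or fa_arr.size < 1:
        raise ValueError("fa_grid must be a non-empty 1-D sequence")
    r1, r2 = ratio
    n = fa_arr.size
    ci_ex = np.empty(n)
    ci_nx = np.empty(n)
    d1 = np.empty(n)
    d2 = np.empty(n)
    dx1 = np.empty(n)
    dx2 = np.empty(n)
    labels = []
    for i, fa in enumerate(fa_arr):
        d_total = dose_at_fa(fit_mix, float(fa))
        d1[i], d2[i] = r1 * d_total, r2 * d_total
        dx1[i] = dose_at_fa(fit_a, float(fa))
        dx2[i] = dose_at_fa(fit_b, float(fa))
        ci_ex[i] = d1[i] / dx1[i] + d2[i] / dx2[i]
        ci_nx[i] = ci_ex[i] + (d1[i] * d2[i]) / (dx1[i] * dx2[i])
        labels.append(classify_interaction(float(ci_ex[i]), band_epsilon))
    return CombinationIndexResult(
        fa=fa_arr, ci_exclusive=ci_ex, ci_nonexclusive=ci_nx,
        d1=d1, d2=d2, dx1=dx1, dx2=dx2,
        ratio=(float(r1), float(r2)), classification=tuple(labels),
    )
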
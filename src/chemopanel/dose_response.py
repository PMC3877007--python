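"""Plate normalization and four-parameter logistic (4PL) IC50 estimation.

Signals from a dose-response plate are normalized against the mean of the
untreated control wells (treated-over-control, T/C).  Per compound and cell
line a 4PL curve

    TC(D) = bottom + (top - bottom) / (1 + (D / ec50)^hill)

is fitted by least squares on a log10-dose axis.  The reported potency is
the *absolute* IC50: the concentration at which the fitted curve crosses
T/C = 0.5.  If the curve never reaches 0.5 inside the tested concentration
range the result is censored (``above_max`` / ``below_min``).  Independent
experiments are aggregated by the arithmetic mean of their uncensored IC50s.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Censor",
    "PlateExperiment",
    "NormalizedPlate",
    "DoseResponseFit",
    "PotencySummary",
    "normalize_plate",
    "fit_4pl",
    "aggregate_ic50",
]

# 4PL parameter bounds: (bottom, top, log10 ec50 pad, hill)
_BOTTOM_BOUNDS = (-0.2, 1.0)
_TOP_BOUNDS = (0.5, 1.5)
_HILL_BOUNDS = (1e-3, 10.0)
_LOGE_PAD = 3.0  # decades beyond tested range allowed for ec50
_HILL_STARTS = (0.5, 1.0, 3.0)


class Censor(str, enum.Enum):
    """Where the absolute IC50 falls relative to the tested range."""

    IN_RANGE = "in_range"
    ABOVE_MAX = "above_max"
    BELOW_MIN = "below_min"


@dataclass(frozen=True)
class PlateExperiment:
    """One compound x cell-line dose-response plate.

    Parameters
    ----------
    concentrations
        Tested concentrations in µM, strictly increasing, length >= 4.
    signals
        Fluorescence units, shape ``(n_concentrations, n_replicates)``
        with at least two replicates.
    control_signals
        Untreated control wells (fluorescence units), length >= 1.
    assay
        ``"adherent-PI"`` or ``"suspension-viability"``.
    """

    compound: str
    cell_line: str
    concentrations: np.ndarray
    signals: np.ndarray
    control_signals: np.ndarray
    assay: str = "adherent-PI"

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        ctrl = np.asarray(self.control_signals, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "signals", sig)
        object.__setattr__(self, "control_signals", ctrl)
        if conc.ndim != 1 or conc.size < 4:
            raise ValueError("need at least 4 concentrations")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if sig.ndim != 2 or sig.shape[0] != conc.size or sig.shape[1] < 2:
            raise ValueError(
                "signals must be (n_concentrations, n_replicates>=2)"
            )
        if np.any(sig < 0) or np.any(ctrl < 0):
            raise ValueError("signals must be non-negative")
        if ctrl.size < 1 or ctrl.mean() <= 0:
            raise ValueError("control mean must be positive")


@dataclass(frozen=True)
class NormalizedPlate:
    """Control-normalized plate: T/C and fraction affected per concentration."""

    compound: str
    cell_line: str
    concentrations: np.ndarray
    tc: np.ndarray
    fa: np.ndarray
    stimulated: np.ndarray  # fa < 0: apparent growth stimulation
    control_mean: float


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of one 4PL fit.

    ``ic50`` is the absolute IC50 (curve crossing T/C = 0.5); ``ec50`` is
    the relative midpoint, kept for diagnostics.  ``ic50`` is ``None``
    whenever ``censor`` is not ``in_range`` or the fit failed.
    """

    bottom: float
    top: float
    hill: float
    ec50: float
    ic50: float | None
    censor: Censor | None
    rss: float
    converged: bool
    conc_min: float
    conc_max: float
    n_experiments: int = 1


@dataclass(frozen=True)
class PotencySummary:
    """Aggregate over independent experiments for one compound x line."""

    ic50: float | None
    censor: Censor
    censor_bound: float | None
    n_experiments: int
    partial: bool = False  # some but not all experiments were censored


def normalize_plate(p: PlateExperiment) -> NormalizedPlate:
    """Normalize replicate signals against the untreated-control mean.

    T/C is the mean replicate signal at each concentration divided by the
    control-well mean; fa = 1 - T/C is returned unclipped, with negative
    values flagged as growth stimulation.
    """
    control_mean = float(np.mean(p.control_signals))
    if control_mean <= 0:
        raise ValueError("plate cannot be normalized: control mean <= 0")
    tc = p.signals.mean(axis=1) / control_mean
    fa = 1.0 - tc
    return NormalizedPlate(
        compound=p.compound,
        cell_line=p.cell_line,
        concentrations=p.concentrations.copy(),
        tc=tc,
        fa=fa,
        stimulated=fa < 0,
        control_mean=control_mean,
    )


def _model(logd: np.ndarray, bottom: float, top: float, loge: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logd - loge) * hill))


def _absolute_ic50(
    bottom: float, top: float, loge: float, hill: float, conc_min: float, conc_max: float
) -> tuple[float | None, Censor]:
    """Solve TC(D) = 0.5 and classify against the tested range."""
    if bottom >= 0.5:  # floor above half-control: never reaches 50%
        return None, Censor.ABOVE_MAX
    if top <= 0.5:  # already below 50% at zero dose
        return None, Censor.BELOW_MIN
    ic50 = 10.0 ** loge * ((top - 0.5) / (0.5 - bottom)) ** (1.0 / hill)
    if ic50 > conc_max:
        return None, Censor.ABOVE_MAX
    if ic50 < conc_min:
        return None, Censor.BELOW_MIN
    return float(ic50), Censor.IN_RANGE


def fit_4pl(concentrations: np.ndarray, tc: np.ndarray) -> DoseResponseFit:
    """Least-squares 4PL fit of T/C fractions against log10 dose.

    Multi-start over hill seeds to avoid local minima.  On optimizer
    failure a non-converged fit without an IC50 is returned.
    """
    conc = np.asarray(concentrations, dtype=float)
    tc = np.asarray(tc, dtype=float)
    if conc.ndim != 1 or tc.shape != conc.shape:
        raise ValueError("concentrations and tc must be 1-D and equally long")
    if np.unique(conc).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    logd = np.log10(conc)
    lo = (_BOTTOM_BOUNDS[0], _TOP_BOUNDS[0], logd.min() - _LOGE_PAD, _HILL_BOUNDS[0])
    hi = (_BOTTOM_BOUNDS[1], _TOP_BOUNDS[1], logd.max() + _LOGE_PAD, _HILL_BOUNDS[1])

    bottom0 = float(np.clip(tc.min(), lo[0], hi[0] - 1e-6))
    top0 = float(np.clip(tc.max(), lo[1] + 1e-6, hi[1]))
    if top0 <= bottom0:
        top0 = min(bottom0 + 0.1, hi[1])
    mid = 0.5 * (top0 + bottom0)
    loge0 = float(logd[np.argmin(np.abs(tc - mid))])

    best: tuple[float, np.ndarray] | None = None
    for hill0 in _HILL_STARTS:
        p0 = np.clip([bottom0, top0, loge0, hill0], lo, hi)
        try:
            popt, _ = curve_fit(
                _model, logd, tc, p0=p0, bounds=(lo, hi), maxfev=10000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((_model(logd, *popt) - tc) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)

    conc_min, conc_max = float(conc.min()), float(conc.max())
    if best is None:
        return DoseResponseFit(
            bottom=np.nan, top=np.nan, hill=np.nan, ec50=np.nan,
            ic50=None, censor=None, rss=np.nan, converged=False,
            conc_min=conc_min, conc_max=conc_max,
        )
    rss, (bottom, top, loge, hill) = best
    ic50, censor = _absolute_ic50(bottom, top, loge, hill, conc_min, conc_max)
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), hill=float(hill),
        ec50=float(10.0 ** loge), ic50=ic50, censor=censor,
        rss=rss, converged=True, conc_min=conc_min, conc_max=conc_max,
    )


def aggregate_ic50(fits: list[DoseResponseFit]) -> PotencySummary:
    """Mean of uncensored IC50s across independent experiments.

    If every converged fit is censored ``above_max``, the summary carries
    the largest tested concentration as the censoring bound.
    """
    if not fits:
        raise ValueError("cannot aggregate an empty list of fits")
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fit to aggregate")
    in_range = [f.ic50 for f in converged if f.censor is Censor.IN_RANGE]
    if in_range:
        return PotencySummary(
            ic50=float(np.mean(in_range)),
            censor=Censor.IN_RANGE,
            censor_bound=None,
            n_experiments=len(fits),
            partial=len(in_range) < len(converged),
        )
    if all(f.censor is Censor.ABOVE_MAX for f in converged):
        return PotencySummary(
            ic50=None,
            censor=Censor.ABOVE_MAX,
            censor_bound=float(max(f.conc_max for f in converged)),
            n_experiments=len(fits),
        )
    return PotencySummary(
        ic50=None,
        censor=Censor.BELOW_MIN,
        censor_bound=float(min(f.conc_min for f in converged)),
        n_experiments=len(fits),
    )
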
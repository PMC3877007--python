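"""Gene-expression / compound-potency correlation screen.

Every expressed gene (mean natural-scale signal above a floor, default 500)
is correlated across the cell-line panel with a compound's IC50 vector.
Significance uses the two-sided t transform of the Pearson correlation,

    t = |r| * sqrt(n - 2) / sqrt(1 - r^2)   on n - 2 degrees of freedom,

and hits are reported below a raw p cutoff (default 0.0005), with Bonferroni
and Benjamini-Hochberg thresholds available for context.  A gene is a
"sensitivity" gene when r < 0 (higher expression, lower IC50) and a
"resistance" gene otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneAssociation",
    "filter_expression",
    "correlate_potency",
    "correlation_pvalue",
    "screen_associations",
    "bonferroni_threshold",
    "bh_threshold",
]

_FILTER_STATS = {"mean": np.mean, "median": np.median, "max": np.max}


@dataclass(frozen=True)
class GeneAssociation:
    gene: str
    compound: str
    r: float
    p: float
    n: int
    direction: str


def filter_expression(
    em: pd.DataFrame, min_signal: float = 500.0, statistic: str = "mean"
) -> pd.DataFrame:
    """Keep genes whose summary signal across lines exceeds ``min_signal``.

    The summary statistic defaults to the per-gene mean; ``median`` and
    ``max`` are selectable.  The comparison is strict (> min_signal).
    """
    if statistic not in _FILTER_STATS:
        raise ValueError(f"unknown filter statistic {statistic!r}")
    if (em.to_numpy() < 0).any():
        raise ValueError("expression matrix must be non-negative")
    summary = em.apply(_FILTER_STATS[statistic], axis=1)
    return em.loc[summary > min_signal]


def correlate_potency(ic50_row: pd.Series, expr_row: pd.Series) -> float:
    """Pearson correlation over pairwise-complete cell lines.

    Lines missing either value are dropped; at least 4 complete pairs are
    required and both vectors must vary.
    """
    joined = pd.concat([ic50_row, expr_row], axis=1, join="inner").dropna()
    if len(joined) < 4:
        raise ValueError("need >= 4 pairwise-complete cell lines")
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("correlation undefined: zero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation from its t transform."""
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return 0.0  # limiting value of the t tail
    t = abs(r) * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, df=n - 2))


def _rowwise_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X against y; NaN where undefined."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = Xc @ yc
    den = np.sqrt((Xc * Xc).sum(axis=1) * (yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def screen_associations(
    em: pd.DataFrame,
    potency_row: pd.Series,
    compound: str = "",
    p_cutoff: float = 5e-4,
    potency_log10: bool = False,
    min_lines: int = 4,
) -> list[GeneAssociation]:
    """Screen a (filtered) expression matrix against one potency vector.

    Returns associations with p < ``p_cutoff``, sorted by ascending p with
    ties broken by gene id.  Genes with undefined correlations (zero
    variance, too few complete lines) are skipped.  ``potency_log10``
    switches the potency axis to log10 µM; everything downstream of the
    transform is shared.
    """
    if em.empty:
        return []
    potency = potency_row.dropna().astype(float)
    if potency_log10:
        potency = np.log10(potency)
    lines = [c for c in em.columns if c in potency.index]
    em = em[lines]
    y = potency[lines].to_numpy(dtype=float)

    out: list[GeneAssociation] = []
    X = em.to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    genes = np.asarray(em.index)

    if len(lines) >= min_lines and y.std() > 0:
        r_all = _rowwise_pearson(X[complete], y)
        n = len(lines)
        for gene, r in zip(genes[complete], r_all):
            if np.isnan(r):
                continue
            p = correlation_pvalue(float(r), n)
            if p < p_cutoff:
                out.append(
                    GeneAssociation(
                        gene=str(gene), compound=compound, r=float(r), p=p,
                        n=n, direction="sensitivity" if r < 0 else "resistance",
                    )
                )

    # genes with missing expression values: pairwise-complete fallback
    for gene in genes[~complete]:
        try:
            r = correlate_potency(pd.Series(y, index=lines), em.loc[gene])
        except ValueError:
            continue
        n = int(pd.concat([pd.Series(y, index=lines), em.loc[gene]], axis=1).dropna().shape[0])
        if n < min_lines:
            continue
        p = correlation_pvalue(r, n)
        if p < p_cutoff:
            out.append(
                GeneAssociation(
                    gene=str(gene), compound=compound, r=r, p=p, n=n,
                    direction="sensitivity" if r < 0 else "resistance",
                )
            )

    out.sort(key=lambda a: (a.p, a.gene))
    return out


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise corrected per-test threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def bh_threshold(pvalues, alpha: float = 0.05) -> float:
    """Benjamini-Hochberg step-up cutoff: largest p(i) <= i/m * alpha.

    Returns 0.0 when nothing passes.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = p.size
    if m == 0:
        return 0.0
    crit = (np.arange(1, m + 1) / m) * alpha
    passing = p <= crit
    if not passing.any():
        return 0.0
    return float(p[np.nonzero(passing)[0].max()])
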
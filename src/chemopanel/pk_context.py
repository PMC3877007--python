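"""Pharmacokinetic contextualization of panel potencies.

Plasma exposures reported in mass units (ng/ml) are converted to molar
units (µM = ng/ml divided by molecular weight in g/mol) and compared
against per-line IC50s: the coverage of a compound is the fraction of cell
lines whose IC50 is at or below the peak plasma concentration.

A reference exposure table for several antimalarial drugs ships as a
packaged TSV fixture for demonstration runs (`load_reference_pk`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PKRecord",
    "CompoundMW",
    "ExposureCoverage",
    "mass_to_molar",
    "molar_to_mass",
    "exposure_coverage",
    "load_reference_pk",
]


@dataclass(frozen=True)
class PKRecord:
    """One clinical exposure record (per compound and dose regimen)."""

    compound: str
    dose: str
    cmax_ng_ml: float | None = None
    auc_ng_h_ml: float | None = None
    half_life_h: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        for v in (self.cmax_ng_ml, self.auc_ng_h_ml, self.half_life_h):
            if v is not None and v < 0:
                raise ValueError("PK quantities must be non-negative")


@dataclass(frozen=True)
class CompoundMW:
    compound: str
    mw_g_mol: float

    def __post_init__(self) -> None:
        if self.mw_g_mol <= 0:
            raise ValueError("molecular weight must be positive")


@dataclass(frozen=True)
class ExposureCoverage:
    compound: str
    cmax_uM: float
    ratios: pd.Series  # Cmax(µM) / IC50(µM) per line; NaN where censored/missing
    fraction_covered: float


def mass_to_molar(conc_ng_ml: float, mw_g_mol: float) -> float:
    """ng/ml -> µM.  1 µg/ml is 2 µM at MW 500 and 3 µM at MW 333."""
    if mw_g_mol <= 0:
        raise ValueError("molecular weight must be positive")
    if conc_ng_ml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ng_ml / mw_g_mol


def molar_to_mass(conc_uM: float, mw_g_mol: float) -> float:
    """µM -> ng/ml; exact inverse of :func:`mass_to_molar`."""
    if mw_g_mol <= 0:
        raise ValueError("molecular weight must be positive")
    if conc_uM < 0:
        raise ValueError("concentration must be non-negative")
    return conc_uM * mw_g_mol


def exposure_coverage(
    pk: PKRecord,
    mw: CompoundMW | None,
    ic50s_uM: pd.Series,
    censored: pd.Series | None = None,
) -> ExposureCoverage:
    """Compare a compound's Cmax against its per-line IC50s.

    Censored IC50s (only known to exceed a bound) count as not covered.
    The summary fraction uses all lines in ``ic50s_uM`` as denominator.
    """
    if pk.cmax_ng_ml is None:
        raise ValueError(f"no Cmax available for {pk.compound!r}")
    if mw is None:
        raise ValueError(f"no molecular weight supplied for {pk.compound!r}")
    cmax_uM = mass_to_molar(pk.cmax_ng_ml, mw.mw_g_mol)
    values = ic50s_uM.astype(float)
    if censored is not None:
        values = values.where(~censored.astype(bool), np.nan)
    ratios = cmax_uM / values
    n_lines = len(ic50s_uM)
    covered = int((ratios >= 1.0).sum())
    return ExposureCoverage(
        compound=pk.compound,
        cmax_uM=float(cmax_uM),
        ratios=ratios,
        fraction_covered=covered / n_lines if n_lines else 0.0,
    )


def load_reference_pk() -> list[PKRecord]:
    """Packaged clinical-exposure fixture (ranges stored as midpoints)."""
    with resources.files("chemopanel.data").joinpath("pk_reference.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    records = []
    for _, row in df.iterrows():
        records.append(
            PKRecord(
                compound=str(row["compound"]),
                dose=str(row["dose"]),
                cmax_ng_ml=None if pd.isna(row["cmax_ng_ml"]) else float(row["cmax_ng_ml"]),
                auc_ng_h_ml=None if pd.isna(row["auc_ng_h_ml"]) else float(row["auc_ng_h_ml"]),
                half_life_h=None if pd.isna(row["half_life_h"]) else float(row["half_life_h"]),
                source=str(row["source"]) if not pd.isna(row["source"]) else "",
            )
        )
    return records
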
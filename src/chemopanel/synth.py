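"""Synthetic data generators with known ground truth.

Everything downstream — plate fitting, combination-index scoring, potency
clustering, the expression screen and GO summarization — is testable against
data produced here, where the generating parameters are known exactly.

All generators are pure functions of their parameters and a seed.  Noise on
fluorescence signals is multiplicative lognormal with a given coefficient of
variation (plate readers show roughly constant CV); with ``noise_cv=0``
every signal lies exactly on the model curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import PlateExperiment

__all__ = [
    "PlateDesign",
    "TruePanelModel",
    "PlantedAssociation",
    "ExpressionBackground",
    "CombinationDataset",
    "gen_plate_experiment",
    "gen_combination_dataset",
    "equipotent_ratio",
    "gen_true_panel",
    "gen_expression_panel",
    "gen_annotation_table",
]

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested CV; exact 1s at cv=0."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


@dataclass(frozen=True)
class PlateDesign:
    """Layout and noise model of a simulated dose-response plate."""

    n_conc: int = 10
    dilution_factor: float = 10.0 ** 0.5  # half-log series
    n_replicates: int = 2
    n_controls: int = 6
    control_mean_signal: float = 10000.0
    noise_cv: float = 0.1
    top_conc: float | None = None  # None: center the series on the true IC50
    assay: str = "adherent-PI"

    def __post_init__(self) -> None:
        if min(self.n_conc, self.n_replicates, self.n_controls) < 1:
            raise ValueError("design counts must be >= 1")
        if self.n_conc < 4:
            raise ValueError("need >= 4 concentrations for downstream fitting")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.control_mean_signal <= 0:
            raise ValueError("control_mean_signal must be positive")
        if self.top_conc is not None and self.top_conc <= 0:
            raise ValueError("top_conc must be positive")


def _design_concentrations(design: PlateDesign, center: float) -> np.ndarray:
    n, f = design.n_conc, design.dilution_factor
    if design.top_conc is not None:
        exps = np.arange(n) - (n - 1)
        return design.top_conc * f ** exps.astype(float)
    exps = np.arange(n) - (n - 1) / 2.0
    return center * f ** exps


def gen_plate_experiment(
    true_ic50: float,
    hill: float,
    design: PlateDesign,
    seed,
    compound: str = "CPD",
    cell_line: str = "LINE",
) -> PlateExperiment:
    """Simulate one plate from the model TC(D) = 1 / (1 + (D/IC50)^hill).

    Treated signals are ``control_mean_signal * TC(D)`` times lognormal
    noise; control wells sit at TC = 1 with the same noise model.
    """
    if true_ic50 <= 0:
        raise ValueError("true_ic50 must be positive")
    if hill <= 0:
        raise ValueError("hill must be positive")
    rng = _rng(seed)
    conc = _design_concentrations(design, true_ic50)
    tc = 1.0 / (1.0 + (conc / true_ic50) ** hill)
    noise = _lognormal_factors(rng, design.noise_cv, (design.n_conc, design.n_replicates))
    signals = design.control_mean_signal * tc[:, None] * noise
    controls = design.control_mean_signal * _lognormal_factors(
        rng, design.noise_cv, design.n_controls
    )
    return PlateExperiment(
        compound=compound,
        cell_line=cell_line,
        concentrations=conc,
        signals=signals,
        control_signals=controls,
        assay=design.assay,
    )


@dataclass(frozen=True)
class CombinationDataset:
    """Mono plates for two drugs plus their constant-ratio mixture plate."""

    plate_a: PlateExperiment
    plate_b: PlateExperiment
    plate_mix: PlateExperiment
    ratio: tuple[float, float]
    psi: float
    dm_mix: float


def equipotent_ratio(dm_a: float, dm_b: float) -> tuple[float, float]:
    """Dose fractions proportional to the two median-effect doses.

    At total mixture dose ``dm_a + dm_b`` each component then sits exactly
    at its own Dm, i.e. the components are isoeffective at the 50% level.
    """
    total = dm_a + dm_b
    return (dm_a / total, dm_b / total)


def gen_combination_dataset(
    m: float,
    dm_a: float,
    dm_b: float,
    ratio: tuple[float, float],
    psi: float,
    design: PlateDesign,
    seed,
    compound_a: str = "A",
    compound_b: str = "B",
    cell_line: str = "LINE",
) -> CombinationDataset:
    """Simulate a constant-ratio combination experiment with known interaction.

    Both drugs share the slope ``m`` (a generation restriction: only then is
    a Loewe-additive mixture itself exactly median-effect).  The mixture
    follows a median-effect curve with

        Dm_mix = psi / (r1/Dm_A + r2/Dm_B)

    so ``psi = 1`` encodes exact Loewe additivity, ``psi < 1`` synergy and
    ``psi > 1`` antagonism; the exclusive CI of the noise-free dataset
    equals ``psi`` at every effect level.
    """
    if not np.isclose(sum(ratio), 1.0):
        raise ValueError("ratio fractions must sum to 1")
    if psi <= 0:
        raise ValueError("psi must be positive")
    if dm_a <= 0 or dm_b <= 0:
        raise ValueError("median-effect doses must be positive")
    r1, r2 = ratio
    dm_mix = psi / (r1 / dm_a + r2 / dm_b)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    seed_a, seed_b, seed_mix = ss.spawn(3)
    plate_a = gen_plate_experiment(dm_a, m, design, seed_a, compound_a, cell_line)
    plate_b = gen_plate_experiment(dm_b, m, design, seed_b, compound_b, cell_line)
    plate_mix = gen_plate_experiment(
        dm_mix, m, design, seed_mix, f"{compound_a}+{compound_b}", cell_line
    )
    return CombinationDataset(
        plate_a=plate_a, plate_b=plate_b, plate_mix=plate_mix,
        ratio=(float(r1), float(r2)), psi=float(psi), dm_mix=float(dm_mix),
    )


@dataclass(frozen=True)
class TruePanelModel:
    """Ground truth of a simulated compound x cell-line potency panel."""

    compounds: tuple[str, ...]
    cell_lines: tuple[str, ...]
    true_ic50: pd.DataFrame  # compounds x lines, µM
    true_hill: dict[str, float]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if (self.true_ic50.values <= 0).any():
            raise ValueError("all true IC50s must be positive")
        if any(h <= 0 for h in self.true_hill.values()):
            raise ValueError("all true hill slopes must be positive")


def gen_true_panel(
    groups: dict[str, list[str]],
    cell_lines: list[str] | int,
    seed,
    within_group_r: float = 0.95,
    between_group_r: float = 0.2,
    log10_ic50_sd: float = 1.0,
    center_uM: float = 1.0,
    compound_offset_sd: float = 0.3,
    hill_range: tuple[float, float] = (0.8, 1.5),
) -> TruePanelModel:
    """Simulate a potency panel whose compounds form correlated groups.

    log10 IC50 profiles across lines are built from a shared line factor
    (between-group correlation), a group factor and compound noise, so the
    pairwise Pearson correlation of profiles is ``within_group_r`` within a
    group and ``between_group_r`` across groups, in expectation.
    """
    if not 0 <= between_group_r < within_group_r < 1:
        raise ValueError("need 0 <= between_group_r < within_group_r < 1")
    rng = _rng(seed)
    if isinstance(cell_lines, int):
        cell_lines = [f"L{i + 1:02d}" for i in range(cell_lines)]
    compounds = [c for members in groups.values() for c in members]
    if len(set(compounds)) != len(compounds):
        raise ValueError("compound ids must be unique across groups")
    n_lines = len(cell_lines)
    if n_lines < 2:
        raise ValueError("need >= 2 cell lines")

    w, b = within_group_r, between_group_r
    shared = rng.standard_normal(n_lines)
    group_factor = {g: rng.standard_normal(n_lines) for g in groups}
    rows = {}
    group_of: dict[str, str] = {}
    hills: dict[str, float] = {}
    for g, members in groups.items():
        for c in members:
            eps = rng.standard_normal(n_lines)
            profile = (
                np.sqrt(b) * shared
                + np.sqrt(w - b) * group_factor[g]
                + np.sqrt(1.0 - w) * eps
            )
            offset = np.log10(center_uM) + compound_offset_sd * rng.standard_normal()
            rows[c] = 10.0 ** (offset + log10_ic50_sd * profile)
            group_of[c] = g
            hills[c] = float(rng.uniform(*hill_range))
    true_ic50 = pd.DataFrame.from_dict(rows, orient="index", columns=list(cell_lines))
    true_ic50 = true_ic50.loc[compounds]
    return TruePanelModel(
        compounds=tuple(compounds),
        cell_lines=tuple(cell_lines),
        true_ic50=true_ic50,
        true_hill=hills,
        group_of=group_of,
    )


@dataclass(frozen=True)
class PlantedAssociation:
    """A gene constructed to correlate with a compound's potency profile."""

    gene: str
    compound: str
    direction: str  # "sensitivity" (r < 0) or "resistance" (r > 0)
    target_abs_r: float

    def __post_init__(self) -> None:
        if not 0.0 < self.target_abs_r < 1.0:
            raise ValueError("target_abs_r must lie strictly inside (0, 1)")
        if self.direction not in ("sensitivity", "resistance"):
            raise ValueError("direction must be 'sensitivity' or 'resistance'")


@dataclass(frozen=True)
class ExpressionBackground:
    """Lognormal background-intensity model for unrelated genes.

    ``fraction_below_floor`` positions the gene-level median distribution so
    that this fraction of background genes falls under the expression floor
    (default 500 signal units) and is removed by the screen's filter.  An
    explicit ``log10_mean`` overrides that placement.
    """

    log10_sd_between: float = 0.5
    log10_sd_within: float = 0.15
    fraction_below_floor: float = 0.2
    floor_signal: float = 500.0
    log10_mean: float | None = None

    def resolved_log10_mean(self) -> float:
        if self.log10_mean is not None:
            return self.log10_mean
        z = stats.norm.ppf(self.fraction_below_floor)
        return float(np.log10(self.floor_signal) - z * self.log10_sd_between)


def gen_expression_panel(
    n_genes: int,
    potency_row: pd.Series,
    planted: list[PlantedAssociation],
    background: ExpressionBackground,
    seed,
    planted_mean_signal: float = 5000.0,
    planted_sd_signal: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Natural-scale expression matrix with planted potency correlations.

    A planted gene is a direction-signed mixture of the standardized potency
    vector and independent noise, weighted so its expected Pearson
    correlation with potency is ``target_abs_r``; the mixture is mapped
    affinely to intensity units (Pearson r is affine-invariant) and
    truncated at 0.  Background genes are independent of potency.

    Returns the genes x lines matrix and a truth table of the planted
    associations.
    """
    if len(potency_row) < 4:
        raise ValueError("need >= 4 cell lines")
    if n_genes < len(planted):
        raise ValueError("n_genes smaller than number of planted genes")
    rng = _rng(seed)
    lines = list(potency_row.index)
    n_lines = len(lines)
    planted_ids = [p.gene for p in planted]
    if len(set(planted_ids)) != len(planted_ids):
        raise ValueError("planted gene ids must be unique")

    width = max(4, len(str(n_genes)))
    background_ids = []
    i = 1
    while len(background_ids) < n_genes - len(planted):
        gid = f"G{i:0{width}d}"
        if gid not in planted_ids:
            background_ids.append(gid)
        i += 1

    y = potency_row.to_numpy(dtype=float)
    z = (y - y.mean()) / y.std(ddof=0)

    rows = {}
    for p in planted:
        sign = -1.0 if p.direction == "sensitivity" else 1.0
        rho = p.target_abs_r
        latent = sign * rho * z + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n_lines)
        rows[p.gene] = np.maximum(
            planted_mean_signal + planted_sd_signal * latent, 0.0
        )

    mu = background.resolved_log10_mean()
    medians = 10.0 ** (
        mu + background.log10_sd_between * rng.standard_normal(len(background_ids))
    )
    within = 10.0 ** (
        background.log10_sd_within * rng.standard_normal((len(background_ids), n_lines))
    )
    for gid, med, w in zip(background_ids, medians, within):
        rows[gid] = med * w

    em = pd.DataFrame.from_dict(rows, orient="index", columns=lines)
    em = em.sort_index()
    truth = pd.DataFrame(
        [
            {
                "gene": p.gene,
                "compound": p.compound,
                "direction": p.direction,
                "target_abs_r": p.target_abs_r,
            }
            for p in planted
        ],
        columns=["gene", "compound", "direction", "target_abs_r"],
    )
    return em, truth


def gen_annotation_table(
    genes: list[str],
    terms: list[str],
    mean_terms_per_gene: float,
    seed,
) -> dict[str, set[str]]:
    """Random gene -> GO-BP term sets; Poisson-many distinct terms per gene."""
    if not terms:
        raise ValueError("terms must be non-empty")
    if mean_terms_per_gene < 0:
        raise ValueError("mean_terms_per_gene must be >= 0")
    rng = _rng(seed)
    table: dict[str, set[str]] = {}
    for g in genes:
        k = int(min(rng.poisson(mean_terms_per_gene), len(terms)))
        table[g] = set(rng.choice(terms, size=k, replace=False)) if k else set()
    return table
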
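"""End-to-end orchestration of the synthetic panel analysis.

Chains panel simulation, plate fitting, combination-index scoring, potency
clustering, the expression screen, GO summarization and PK coverage, and
writes one plain-text artifact per stage plus a JSON run-metadata record.
Deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..dose_response import Censor, aggregate_ic50, fit_4pl, normalize_plate
from ..expression_association import (
    bonferroni_threshold,
    filter_expression,
    screen_associations,
)
from ..go_frequency import term_frequencies, top_k
from ..median_effect import ci_profile, median_effect_fit
from ..pk_context import CompoundMW, PKRecord, exposure_coverage
from ..profile_clustering import (
    PotencyMatrix,
    to_newick,
    transform_potency,
    ward_cluster,
)
from ..synth import (
    ExpressionBackground,
    PlantedAssociation,
    PlateDesign,
    equipotent_ratio,
    gen_annotation_table,
    gen_combination_dataset,
    gen_expression_panel,
    gen_plate_experiment,
    gen_true_panel,
)
from . import io
from .config import PipelineConfig

__all__ = ["run_pipeline", "fit_panel_potency"]

logger = logging.getLogger("chemopanel.pipeline")

_STAGES = ("panel", "plates", "synergy", "expression", "annotation")


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the offending input."""


def _plate_design(cfg: PipelineConfig) -> PlateDesign:
    return PlateDesign(
        n_conc=cfg.n_conc,
        dilution_factor=cfg.dilution_factor,
        n_replicates=cfg.n_replicates,
        n_controls=cfg.n_controls,
        control_mean_signal=cfg.control_mean_signal,
        noise_cv=cfg.noise_cv,
    )


def fit_panel_potency(panel, design: PlateDesign, n_experiments: int, seed) -> PotencyMatrix:
    """Simulate and fit plates for every compound x line; aggregate to a matrix."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    values = pd.DataFrame(
        np.nan, index=list(panel.compounds), columns=list(panel.cell_lines)
    )
    censored = pd.DataFrame(
        False, index=list(panel.compounds), columns=list(panel.cell_lines)
    )
    n_pairs = len(panel.compounds) * len(panel.cell_lines)
    pair_seeds = ss.spawn(n_pairs)
    k = 0
    for compound in panel.compounds:
        for line in panel.cell_lines:
            child = pair_seeds[k]
            k += 1
            fits = []
            for exp_seed in child.spawn(n_experiments):
                plate = gen_plate_experiment(
                    true_ic50=float(panel.true_ic50.at[compound, line]),
                    hill=panel.true_hill[compound],
                    design=design,
                    seed=exp_seed,
                    compound=compound,
                    cell_line=line,
                )
                norm = normalize_plate(plate)
                fits.append(fit_4pl(norm.concentrations, norm.tc))
            try:
                summary = aggregate_ic50(fits)
            except ValueError as exc:
                raise StageError(f"plates: {compound}/{line}: {exc}") from exc
            if summary.censor is Censor.IN_RANGE:
                values.at[compound, line] = summary.ic50
            elif summary.censor is Censor.ABOVE_MAX:
                values.at[compound, line] = summary.censor_bound
                censored.at[compound, line] = True
            # below_min stays missing: no usable bound representation
    return PotencyMatrix(values=values, censored=censored)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all enabled stages; return run metadata (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"chemopanel {__version__}; config={cfg.config_hash()}"
    root_ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = dict(zip(_STAGES, root_ss.spawn(len(_STAGES))))
    meta: dict = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
        "outputs": [],
    }

    def _record(name: str, path: Path) -> None:
        meta["outputs"].append(str(path.name))
        logger.info("%s -> %s", name, path)

    # ---- potency panel ----------------------------------------------------
    panel = gen_true_panel(
        groups=cfg.groups,
        cell_lines=cfg.n_cell_lines,
        seed=stage_seeds["panel"],
        within_group_r=cfg.within_group_r,
        between_group_r=cfg.between_group_r,
    )
    design = _plate_design(cfg)
    pm = fit_panel_potency(panel, design, cfg.n_experiments, stage_seeds["plates"])
    potency_path = outdir / "potency.tsv"
    io.write_potency_table(pm, potency_path, header_comment=header)
    _record("potency", potency_path)
    n_censored = int(pm.censored.to_numpy().sum())
    meta["stages"]["potency"] = {
        "n_compounds": len(pm.compounds),
        "n_cell_lines": len(pm.cell_lines),
        "n_censored": n_censored,
        "group_of": panel.group_of,
    }

    # ---- combination index ------------------------------------------------
    if cfg.run_synergy:
        cpd_a, cpd_b = cfg.compounds[:2]
        line = panel.cell_lines[0]
        dm_a = float(panel.true_ic50.at[cpd_a, line])
        dm_b = float(panel.true_ic50.at[cpd_b, line])
        ratio = equipotent_ratio(dm_a, dm_b)
        combo = gen_combination_dataset(
            m=cfg.combo_m, dm_a=dm_a, dm_b=dm_b, ratio=ratio, psi=cfg.combo_psi,
            design=design, seed=stage_seeds["synergy"],
            compound_a=cpd_a, compound_b=cpd_b, cell_line=line,
        )
        try:
            fits = {}
            for key, plate in (
                ("A", combo.plate_a), ("B", combo.plate_b), ("mix", combo.plate_mix)
            ):
                norm = normalize_plate(plate)
                fits[key] = median_effect_fit(norm.concentrations, norm.fa)
            res = ci_profile(
                fits["A"], fits["B"], fits["mix"], ratio,
                fa_grid=cfg.fa_grid, band_epsilon=cfg.band_epsilon,
            )
        except ValueError as exc:
            raise StageError(f"synergy: {cpd_a}+{cpd_b}: {exc}") from exc
        ci_path = outdir / "ci_table.tsv"
        io.write_ci_table(res, ci_path, header_comment=header)
        _record("synergy", ci_path)
        meta["stages"]["synergy"] = {
            "pair": [cpd_a, cpd_b],
            "cell_line": line,
            "psi": cfg.combo_psi,
            "ratio": list(ratio),
            "median_effect_r": {k: f.r for k, f in fits.items()},
            "excluded_points": {k: len(f.excluded) for k, f in fits.items()},
        }

    # ---- clustering -------------------------------------------------------
    if cfg.run_cluster:
        try:
            matrix = transform_potency(
                pm, log10=cfg.cluster_log10, censor_policy=cfg.censor_policy
            )
            tree = ward_cluster(matrix)
        except ValueError as exc:
            raise StageError(f"cluster: potency matrix: {exc}") from exc
        newick_path = outdir / "potency_tree.nwk"
        io.write_newick(to_newick(tree), newick_path)
        merges_path = outdir / "potency_merges.tsv"
        io.write_merge_table(tree, merges_path, header_comment=header)
        _record("cluster", newick_path)
        _record("cluster", merges_path)
        meta["stages"]["cluster"] = {
            "n_lines_used": int(matrix.shape[1]),
            "log10": cfg.cluster_log10,
            "censor_policy": cfg.censor_policy,
        }

    # ---- expression screen ------------------------------------------------
    genes_universe: list[str] = []
    hits_by_compound: dict[str, list[str]] = {}
    if cfg.run_expression:
        expr_ss = stage_seeds["expression"].spawn(len(cfg.compounds) + 1)
        potency_for_screen = pm.values.where(~pm.censored)
        n_background = cfg.n_genes - cfg.planted_per_compound * len(cfg.compounds)
        if n_background < 0:
            raise StageError("expression: n_genes too small for planted genes")
        background = ExpressionBackground()
        ref_row = potency_for_screen.iloc[0].dropna()
        if len(ref_row) < 4:
            raise StageError("expression: fewer than 4 uncensored lines")
        em_bg, _ = gen_expression_panel(
            n_genes=n_background, potency_row=ref_row, planted=[],
            background=background, seed=expr_ss[0],
        )
        parts = [em_bg]
        truths = []
        for i, compound in enumerate(cfg.compounds):
            row = potency_for_screen.loc[compound].dropna()
            if len(row) < 4:
                raise StageError(f"expression: {compound}: fewer than 4 usable lines")
            planted = [
                PlantedAssociation(
                    gene=f"PL_{compound}_{j + 1}",
                    compound=compound,
                    direction="sensitivity" if j % 2 == 0 else "resistance",
                    target_abs_r=cfg.planted_abs_r,
                )
                for j in range(cfg.planted_per_compound)
            ]
            if planted:
                em_p, truth = gen_expression_panel(
                    n_genes=len(planted), potency_row=row, planted=planted,
                    background=background, seed=expr_ss[i + 1],
                )
                # planted-only matrices cover the reference row's lines
                parts.append(em_p.reindex(columns=em_bg.columns))
                truths.append(truth)
        em = pd.concat(parts).sort_index()
        truth_table = (
            pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
        )
        expr_path = outdir / "expression.tsv"
        io.write_expression_table(em, expr_path, header_comment=header)
        _record("expression-matrix", expr_path)
        if not truth_table.empty:
            truth_path = outdir / "expression_truth.tsv"
            truth_table.to_csv(truth_path, sep="\t", index=False)
            _record("expression-truth", truth_path)

        kept = filter_expression(em, min_signal=cfg.min_signal)
        genes_universe = list(kept.index)
        assoc_meta = {}
        for compound in cfg.compounds:
            row = potency_for_screen.loc[compound]
            assocs = screen_associations(
                kept, row, compound=compound, p_cutoff=cfg.p_cutoff,
                potency_log10=cfg.potency_log10,
            )
            assoc_path = outdir / f"assoc_{compound}.tsv"
            io.write_associations(assocs, assoc_path, header_comment=header)
            _record("associations", assoc_path)
            hits_by_compound[compound] = [a.gene for a in assocs]
            assoc_meta[compound] = len(assocs)
        meta["stages"]["expression"] = {
            "n_genes": int(em.shape[0]),
            "n_kept_after_filter": len(genes_universe),
            "min_signal": cfg.min_signal,
            "p_cutoff": cfg.p_cutoff,
            "bonferroni_threshold": bonferroni_threshold(0.05, max(len(genes_universe), 1)),
            "hits_per_compound": assoc_meta,
        }

    # ---- GO term frequencies ----------------------------------------------
    if cfg.run_go and cfg.run_expression:
        terms = [f"BP{i + 1:03d}" for i in range(cfg.n_terms)]
        ann = gen_annotation_table(
            genes=sorted(genes_universe), terms=terms,
            mean_terms_per_gene=cfg.mean_terms_per_gene,
            seed=stage_seeds["annotation"],
        )
        ann_path = outdir / "annotation.tsv"
        io.write_annotation_table(ann, ann_path, header_comment=header)
        _record("annotation", ann_path)
        go_meta = {}
        for compound, hits in hits_by_compound.items():
            freq = term_frequencies(hits, ann)
            ranked = top_k(freq.counts, k=cfg.go_top_k)
            go_path = outdir / f"go_{compound}.tsv"
            io.write_go_table(ranked, freq, go_path, header_comment=header)
            _record("go", go_path)
            go_meta[compound] = {"n_terms": len(ranked), "mass": freq.total_mass}
        meta["stages"]["go"] = go_meta

    # ---- PK coverage ------------------------------------------------------
    if cfg.run_pk:
        coverages = []
        for compound in cfg.compounds:
            pk = PKRecord(compound=compound, dose="demo", cmax_ng_ml=cfg.pk_cmax_ng_ml)
            mw = CompoundMW(compound=compound, mw_g_mol=cfg.pk_mw_g_mol)
            coverages.append(
                exposure_coverage(
                    pk, mw, pm.values.loc[compound], censored=pm.censored.loc[compound]
                )
            )
        cov_path = outdir / "pk_coverage.tsv"
        io.write_coverage_table(coverages, cov_path, header_comment=header)
        _record("pk", cov_path)
        meta["stages"]["pk"] = {
            c.compound: round(c.fraction_covered, 6) for c in coverages
        }

    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    _record("metadata", meta_path)
    return meta
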
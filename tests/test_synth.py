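import numpy as np
import pandas as pd
import pytest

from chemopanel.dose_response import normalize_plate
from chemopanel.median_effect import fa_at_dose, MedianEffectFit
from chemopanel.synth import (
    CombinationDataset,
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


class TestPlateDesign:
    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            PlateDesign(n_conc=0)
        with pytest.raises(ValueError):
            PlateDesign(n_replicates=1)
        with pytest.raises(ValueError):
            PlateDesign(n_controls=0)

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            PlateDesign(noise_cv=-0.1)

    def test_rejects_nonpositive_top_conc(self):
        with pytest.raises(ValueError):
            PlateDesign(top_conc=0.0)


class TestGenPlateExperiment:
    def test_model_midpoint_noise_free(self):
        # odd count centers a tested concentration exactly at the IC50
        design = PlateDesign(n_conc=9, noise_cv=0.0)
        p = gen_plate_experiment(1.0, 1.3, design, seed=0)
        idx = int(np.argmin(np.abs(p.concentrations - 1.0)))
        assert p.concentrations[idx] == pytest.approx(1.0)
        treated_mean = p.signals[idx].mean()
        assert treated_mean == pytest.approx(0.5 * p.control_signals.mean())

    def test_noise_free_signals_on_curve(self):
        design = PlateDesign(noise_cv=0.0)
        p = gen_plate_experiment(2.0, 1.7, design, seed=5)
        tc = 1.0 / (1.0 + (p.concentrations / 2.0) ** 1.7)
        expected = design.control_mean_signal * tc[:, None]
        np.testing.assert_allclose(p.signals, np.broadcast_to(expected, p.signals.shape))
        np.testing.assert_allclose(p.control_signals, design.control_mean_signal)

    def test_same_seed_bit_identical(self, noisy_design):
        p1 = gen_plate_experiment(1.0, 1.0, noisy_design, seed=77)
        p2 = gen_plate_experiment(1.0, 1.0, noisy_design, seed=77)
        np.testing.assert_array_equal(p1.signals, p2.signals)
        np.testing.assert_array_equal(p1.control_signals, p2.control_signals)
        np.testing.assert_array_equal(p1.concentrations, p2.concentrations)

    def test_different_seed_differs(self, noisy_design):
        p1 = gen_plate_experiment(1.0, 1.0, noisy_design, seed=1)
        p2 = gen_plate_experiment(1.0, 1.0, noisy_design, seed=2)
        assert not np.array_equal(p1.signals, p2.signals)

    def test_noise_cv_realized(self):
        design = PlateDesign(n_conc=10, n_replicates=200, noise_cv=0.1)
        p = gen_plate_experiment(1.0, 1.0, design, seed=3)
        tc = 1.0 / (1.0 + p.concentrations / 1.0)
        ratios = p.signals / (design.control_mean_signal * tc[:, None])
        cv = ratios.std() / ratios.mean()
        assert cv == pytest.approx(0.1, rel=0.15)

    def test_rejects_bad_params(self, noise_free_design):
        with pytest.raises(ValueError):
            gen_plate_experiment(-1.0, 1.0, noise_free_design, seed=0)
        with pytest.raises(ValueError):
            gen_plate_experiment(1.0, 0.0, noise_free_design, seed=0)

    def test_top_conc_design(self):
        design = PlateDesign(top_conc=30.0, noise_cv=0.0)
        p = gen_plate_experiment(1.0, 1.0, design, seed=0)
        assert p.concentrations[-1] == pytest.approx(30.0)


class TestGenCombinationDataset:
    def test_ratio_must_sum_to_one(self, noise_free_design):
        with pytest.raises(ValueError):
            gen_combination_dataset(1.0, 1.0, 1.0, (0.4, 0.4), 1.0, noise_free_design, 0)

    def test_psi_positive(self, noise_free_design):
        with pytest.raises(ValueError):
            gen_combination_dataset(1.0, 1.0, 1.0, (0.5, 0.5), 0.0, noise_free_design, 0)

    def test_additive_mixture_dm(self, noise_free_design):
        combo = gen_combination_dataset(1.5, 1.0, 3.0, (0.5, 0.5), 1.0, noise_free_design, 0)
        assert combo.dm_mix == pytest.approx(1.0 / (0.5 / 1.0 + 0.5 / 3.0))

    def test_deterministic(self, noisy_design):
        c1 = gen_combination_dataset(1.0, 1.0, 2.0, (0.5, 0.5), 0.5, noisy_design, 9)
        c2 = gen_combination_dataset(1.0, 1.0, 2.0, (0.5, 0.5), 0.5, noisy_design, 9)
        np.testing.assert_array_equal(c1.plate_mix.signals, c2.plate_mix.signals)

    def test_equipotent_ratio_isoeffective_at_50(self):
        # at total dose Dm_A + Dm_B the components each sit at their own Dm
        dm_a, dm_b, m = 0.5, 2.0, 1.3
        r = equipotent_ratio(dm_a, dm_b)
        assert sum(r) == pytest.approx(1.0)
        total = dm_a + dm_b
        fit_a = MedianEffectFit(m=m, dm=dm_a, r=1.0, n_used=10)
        fit_b = MedianEffectFit(m=m, dm=dm_b, r=1.0, n_used=10)
        assert fa_at_dose(fit_a, r[0] * total) == pytest.approx(0.5)
        assert fa_at_dose(fit_b, r[1] * total) == pytest.approx(0.5)


class TestGenTruePanel:
    def test_groups_and_positivity(self):
        panel = gen_true_panel(
            {"a": ["c1", "c2"], "b": ["c3"]}, cell_lines=6, seed=0
        )
        assert panel.compounds == ("c1", "c2", "c3")
        assert (panel.true_ic50.to_numpy() > 0).all()
        assert panel.group_of == {"c1": "a", "c2": "a", "c3": "b"}
        assert all(h > 0 for h in panel.true_hill.values())

    def test_correlation_structure_post_hoc(self):
        # with many lines the profile correlations approach the generation params
        panel = gen_true_panel(
            {"a": ["c1", "c2"], "b": ["c3", "c4"]},
            cell_lines=3000, seed=1, within_group_r=0.95, between_group_r=0.2,
        )
        logp = np.log10(panel.true_ic50.to_numpy())
        corr = np.corrcoef(logp)
        assert corr[0, 1] == pytest.approx(0.95, abs=0.05)
        assert corr[2, 3] == pytest.approx(0.95, abs=0.05)
        assert abs(corr[0, 2]) < 0.5
        assert corr[0, 2] == pytest.approx(0.2, abs=0.15)

    def test_rejects_bad_correlations(self):
        with pytest.raises(ValueError):
            gen_true_panel({"a": ["c1"]}, 5, 0, within_group_r=0.2, between_group_r=0.5)

    def test_deterministic(self):
        p1 = gen_true_panel({"a": ["c1", "c2"]}, 5, seed=3)
        p2 = gen_true_panel({"a": ["c1", "c2"]}, 5, seed=3)
        pd.testing.assert_frame_equal(p1.true_ic50, p2.true_ic50)


class TestPlantedAssociation:
    @pytest.mark.parametrize("bad_r", [0.0, 1.0, -0.5, 1.5])
    def test_target_r_open_interval(self, bad_r):
        with pytest.raises(ValueError):
            PlantedAssociation("g", "c", "sensitivity", bad_r)

    def test_direction_validated(self):
        with pytest.raises(ValueError):
            PlantedAssociation("g", "c", "both", 0.5)


class TestGenExpressionPanel:
    def test_same_seed_identical(self, potency_row):
        planted = [PlantedAssociation("PL1", "c", "sensitivity", 0.8)]
        em1, t1 = gen_expression_panel(50, potency_row, planted, ExpressionBackground(), 5)
        em2, t2 = gen_expression_panel(50, potency_row, planted, ExpressionBackground(), 5)
        pd.testing.assert_frame_equal(em1, em2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_all_values_nonnegative(self, potency_row):
        planted = [PlantedAssociation("PL1", "c", "resistance", 0.9)]
        em, _ = gen_expression_panel(200, potency_row, planted, ExpressionBackground(), 2)
        assert (em.to_numpy() >= 0).all()
        assert em.shape == (200, len(potency_row))

    def test_planted_truth_contract_large_n(self):
        # empirical |r| converges to target_abs_r as lines -> inf; a
        # light-tailed potency spread keeps the sample correlation's own
        # variance near the bivariate-normal rate
        rng = np.random.default_rng(0)
        lines = [f"L{i}" for i in range(2000)]
        pot = pd.Series(rng.uniform(0.5, 5.0, 2000), index=lines)
        target = 0.6
        planted = [
            PlantedAssociation("PLS", "c", "sensitivity", target),
            PlantedAssociation("PLR", "c", "resistance", target),
        ]
        em, _ = gen_expression_panel(2, pot, planted, ExpressionBackground(), 8)
        r_s = np.corrcoef(em.loc["PLS"], pot)[0, 1]
        r_r = np.corrcoef(em.loc["PLR"], pot)[0, 1]
        assert r_s == pytest.approx(-target, abs=0.02)
        assert r_r == pytest.approx(target, abs=0.02)

    def test_background_fraction_below_floor(self):
        rng = np.random.default_rng(1)
        lines = [f"L{i}" for i in range(6)]
        pot = pd.Series(10.0 ** rng.normal(0, 1, 6), index=lines)
        bg = ExpressionBackground(fraction_below_floor=0.3)
        em, _ = gen_expression_panel(4000, pot, [], bg, 3)
        frac = (em.mean(axis=1) < 500).mean()
        assert frac == pytest.approx(0.3, abs=0.05)

    def test_requires_four_lines(self):
        pot = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            gen_expression_panel(10, pot, [], ExpressionBackground(), 0)


class TestGenAnnotationTable:
    def test_mean_zero_unannotated(self):
        ann = gen_annotation_table(["g1", "g2"], ["t1", "t2"], 0.0, seed=0)
        assert ann == {"g1": set(), "g2": set()}

    def test_deterministic(self):
        genes = [f"g{i}" for i in range(20)]
        terms = [f"t{i}" for i in range(5)]
        a1 = gen_annotation_table(genes, terms, 2.0, seed=4)
        a2 = gen_annotation_table(genes, terms, 2.0, seed=4)
        assert a1 == a2

    def test_terms_distinct_and_subset(self):
        genes = [f"g{i}" for i in range(50)]
        terms = [f"t{i}" for i in range(8)]
        ann = gen_annotation_table(genes, terms, 3.0, seed=1)
        for ts in ann.values():
            assert ts <= set(terms)

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            gen_annotation_table(["g"], [], 1.0, seed=0)
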
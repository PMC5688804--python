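"""The synthetic-data generator: determinism, planted structure, truth tables."""

import numpy as np
import pandas as pd
import pytest

from tnbc_targets.io import read_matrix, read_sample_sheet
from tnbc_targets.normalize import beta_to_m
from tnbc_targets.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_correlated_pairs,
    simulate_gene_annotation,
    simulate_marker_panel,
    simulate_methylome,
    simulate_proteome,
    simulate_scenario,
    simulate_target_annotations,
    simulate_two_group_counts,
    write_scenario,
)


class TestConfigValidation:
    def test_planted_budget_must_fit(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(n_genes=100, n_up=40, n_down=40, n_common_up=5, n_common_down=5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ihc_error_rate": 1.5},
            {"marker_mu_pos": 4.0, "marker_mu_neg": 5.0},
            {"planted_lfc": -1.0},
            {"n_tnbc": 0},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_identical_outputs(self, small_sim_cfg):
        a = simulate_scenario(small_sim_cfg)
        b = simulate_scenario(small_sim_cfg)
        pd.testing.assert_frame_equal(a.expression.data, b.expression.data)
        pd.testing.assert_frame_equal(a.sample_sheet, b.sample_sheet)
        pd.testing.assert_frame_equal(a.probe_beta, b.probe_beta)
        pd.testing.assert_frame_equal(a.target_annotations, b.target_annotations)
        assert a.truth.target_gene == b.truth.target_gene

    def test_different_seed_different_counts(self, small_sim_cfg):
        import dataclasses

        a = simulate_scenario(small_sim_cfg)
        b = simulate_scenario(dataclasses.replace(small_sim_cfg, seed=small_sim_cfg.seed + 1))
        assert not a.expression.data.equals(b.expression.data)


class TestMarkerPanel:
    def test_clean_ihc_equals_latent_truth(self):
        cfg = SimulationConfig(ihc_error_rate=0.0, ihc_missing_rate=0.0, seed=2)
        values, truth, ihc = simulate_marker_panel(cfg, n_tnbc=50, n_other=100)
        for marker, col in (("ESR1", "ihc_er"), ("PGR", "ihc_pr"), ("ERBB2", "ihc_her2")):
            np.testing.assert_array_equal(ihc[col] == "pos", truth[marker])

    def test_tnbc_samples_are_triple_negative(self):
        cfg = SimulationConfig(seed=3)
        _, truth, _ = simulate_marker_panel(cfg, n_tnbc=40, n_other=60)
        first40 = truth.iloc[:40]
        assert (~first40[["ESR1", "PGR", "ERBB2"]]).all().all()
        assert first40["tnbc"].all()
        assert truth.iloc[40:][["ESR1", "PGR", "ERBB2"]].any(axis=1).all()

    def test_marker_values_are_bimodal(self):
        cfg = SimulationConfig(seed=4)
        values, truth, _ = simulate_marker_panel(cfg, n_tnbc=200, n_other=400)
        v = values["ESR1"].to_numpy()
        # two quantile clusters: nothing should sit near the midpoint of the
        # component means when separation is several pooled SD
        mid = (cfg.marker_mu_neg + cfg.marker_mu_pos) / 2
        near_mid = np.mean(np.abs(v - mid) < 1.0)
        assert near_mid < 0.05
        assert v[truth["ESR1"].to_numpy()].mean() > v[~truth["ESR1"].to_numpy()].mean() + 4


class TestCohort:
    def test_planted_fold_change_recovered_from_group_means(self):
        cfg = SimulationConfig(n_tnbc=150, n_nontnbc=150, libsize_log2_sd=0.0, seed=5)
        matrix, sheet, truth = simulate_cohort(cfg)
        tnbc = [s for s in matrix.samples if s.startswith("TNBC")]
        nont = [s for s in matrix.samples if s.startswith("NONT")]
        up = truth.de_truth.index[truth.de_truth["tissue"] == "up"]
        ratios = np.log2(
            matrix.data.loc[up, tnbc].mean(axis=1) / matrix.data.loc[up, nont].mean(axis=1)
        )
        assert ratios.mean() == pytest.approx(cfg.planted_lfc, abs=0.2)

    def test_sheet_and_matrix_share_samples(self, small_scenario):
        assert list(small_scenario.sample_sheet["sample_id"]) == list(
            small_scenario.expression.samples
        )

    def test_cell_line_ihc_is_complete_and_exact(self, small_scenario):
        sheet = small_scenario.sample_sheet.set_index("sample_id")
        cells = sheet[sheet["cohort"] == "cell_line"]
        truth = small_scenario.truth.marker_truth.loc[cells.index]
        assert (cells[["ihc_er", "ihc_pr", "ihc_her2"]] != "missing").all().all()
        np.testing.assert_array_equal(cells["ihc_er"] == "pos", truth["ESR1"])


class TestMethylome:
    def test_planted_delta_m_sign_opposes_expression(self, small_sim_cfg, small_scenario):
        truth = small_scenario.truth
        meta, beta = small_scenario.probe_meta, small_scenario.probe_beta
        m = beta_to_m(beta)
        tnbc = [s for s in beta.columns if s.startswith("TNBC")]
        nont = [s for s in beta.columns if s.startswith("NONT")]
        # recompute gene-level delta from the generated tables
        ann = small_scenario.gene_annotation.set_index("gene_id")
        for gene, row in truth.meth_genes.iterrows():
            tss = ann.loc[gene, "tss"]
            near = meta[(meta["chrom"] == ann.loc[gene, "chrom"]) & ((meta["pos"] - tss).abs() < 300)]
            delta = (m.loc[near.index, tnbc].mean(axis=1) - m.loc[near.index, nont].mean(axis=1)).mean()
            expr_status = truth.de_truth.loc[gene, "tissue"]
            assert np.sign(delta) == -np.sign(1 if expr_status == "up" else -1)

    def test_zero_effect_leaves_no_group_shift(self):
        import dataclasses

        cfg = SimulationConfig(seed=9, meth_effect=0.0, n_probes=600, n_islands=60)
        matrix, sheet, truth = simulate_cohort(cfg)
        ann = simulate_gene_annotation(cfg, list(matrix.genes))
        meta, beta, islands = simulate_methylome(cfg, truth, ann)
        m = beta_to_m(beta)
        tnbc = [s for s in beta.columns if s.startswith("TNBC")]
        nont = [s for s in beta.columns if s.startswith("NONT")]
        delta = m[tnbc].mean(axis=1) - m[nont].mean(axis=1)
        assert abs(delta.mean()) < 0.05

    def test_beta_values_clipped(self, small_scenario):
        values = small_scenario.probe_beta.to_numpy()
        assert values.min() >= 0.001 and values.max() <= 0.999

    def test_gene_without_tss_annotation_is_error(self):
        cfg = SimulationConfig(seed=9, n_probes=600, n_islands=60)
        matrix, sheet, truth = simulate_cohort(cfg)
        ann = simulate_gene_annotation(cfg, list(matrix.genes)).iloc[:3]
        with pytest.raises(ValueError, match="TSS"):
            simulate_methylome(cfg, truth, ann)


class TestProteome:
    def test_perfect_correlation_means_zero_noise(self):
        import dataclasses

        cfg = SimulationConfig(seed=10, protein_corr=1.0, protein_scale=0.5,
                               n_genes=400, n_up=40, n_down=40, n_common_up=10,
                               n_common_down=8, n_protein_genes=200)
        matrix, sheet, truth = simulate_cohort(cfg)
        protein = simulate_proteome(cfg, matrix, truth)
        from tnbc_targets.normalize import log2p1, upper_quartile_normalize
        from tnbc_targets.io import ExpressionMatrix

        tumors = list(protein.samples)
        logex = log2p1(upper_quartile_normalize(
            ExpressionMatrix(matrix.data[tumors], unit="counts")))
        np.testing.assert_allclose(
            protein.data.to_numpy(),
            0.5 * logex.data.loc[protein.genes].to_numpy(),
            atol=1e-12,
        )

    def test_calibrated_fc_correlation(self):
        cfg = SimulationConfig(seed=11, protein_corr=0.5, n_genes=2100, n_up=150,
                               n_down=150, n_common_up=40, n_common_down=30,
                               n_protein_genes=2000, n_tnbc=60, n_nontnbc=120)
        matrix, sheet, truth = simulate_cohort(cfg)
        protein = simulate_proteome(cfg, matrix, truth)
        from tnbc_targets.io import ExpressionMatrix
        from tnbc_targets.normalize import log2p1, upper_quartile_normalize

        tumors = list(protein.samples)
        tnbc = np.array([s.startswith("TNBC") for s in tumors])
        logex = log2p1(upper_quartile_normalize(
            ExpressionMatrix(matrix.data[tumors], unit="counts")))
        x = logex.data.loc[protein.genes].to_numpy()
        mrna_fc = x[:, tnbc].mean(axis=1) - x[:, ~tnbc].mean(axis=1)
        prot = protein.data.to_numpy()
        prot_fc = prot[:, tnbc].mean(axis=1) - prot[:, ~tnbc].mean(axis=1)
        r = np.corrcoef(mrna_fc, prot_fc)[0, 1]
        assert r == pytest.approx(0.5, abs=0.1)


class TestTargetAnnotations:
    def test_exactly_one_common_up_gene_passes_all_gates(self, small_scenario):
        truth = small_scenario.truth
        table = small_scenario.target_annotations.set_index("gene_id")
        common = table.loc[truth.common_up]
        passing = (
            (common["pub_count"] < 2)
            & common["has_structure"]
            & common["structure_druggable"]
            & (common["ligand_percentile"] >= 75)
        )
        assert passing.sum() == 1
        assert passing.idxmax() == truth.target_gene
        assert table.loc[truth.target_gene, "ligand_percentile"] >= 95


class TestHelpers:
    def test_correlated_pairs_hit_target_rho(self):
        x, y = simulate_correlated_pairs(20000, -0.2, seed=0)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(-0.2, abs=0.03)

    def test_two_group_counts_plants_effects(self):
        matrix, groups, status = simulate_two_group_counts(
            2000, 30, 30, 100, 100, lfc=2.0, dispersion=0.1, seed=3, libsize_log2_sd=0.0
        )
        counts = matrix.data
        a = counts.loc[:, groups == "A"].mean(axis=1)
        b = counts.loc[:, groups == "B"].mean(axis=1)
        up = status == "up"
        assert np.log2(a[up] / b[up]).mean() == pytest.approx(2.0, abs=0.2)
        assert (status == "up").sum() == 100

    def test_two_group_overplanting_rejected(self):
        with pytest.raises(ValueError, match="plant"):
            simulate_two_group_counts(50, 5, 5, 40, 40, 1.0, 0.1)


class TestScenarioRoundTrip:
    def test_written_tables_read_back_identically(self, small_scenario, tmp_path):
        write_scenario(small_scenario, tmp_path)
        matrix = read_matrix(tmp_path / "expression_counts.tsv", unit="counts")
        pd.testing.assert_frame_equal(
            matrix.data.astype(float), small_scenario.expression.data.astype(float)
        )
        sheet = read_sample_sheet(tmp_path / "samples.tsv")
        pd.testing.assert_frame_equal(sheet, small_scenario.sample_sheet)
        assert (tmp_path / "truth_meta.yaml").exists()
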
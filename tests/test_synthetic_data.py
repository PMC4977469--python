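import numpy as np
import pandas as pd
import pytest

from mesopotency.containers import ConfigurationError
from mesopotency.enrichment import assign_tf_targets, ease_test
from mesopotency.induction import ddct_log2fc, delta_ct, max_induction
from mesopotency.synthetic_data import (
    QpcrTruth,
    SimulationTruth,
    plant_labels,
    simulate_annotations,
    simulate_expression,
    simulate_methylation,
    simulate_qpcr,
    write_simulation,
)


class TestTruthValidation:
    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationTruth(deg_fraction_increasing=0.7, deg_fraction_decreasing=0.5)

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationTruth(n_replicates=1)

    def test_enrichment_fold_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationTruth(planted_set_enrichment_fold=0.5)


class TestSimulateExpression:
    def test_zero_noise_limit_recovers_planted_means(self):
        truth = SimulationTruth(seed=1, n_genes=50, noise_sd=1e-12, effect_size=2.0,
                                mid_fraction=0.5)
        matrix, labels = simulate_expression(truth)
        means = matrix.condition_means()
        gene = labels[labels == "increasing"].index[0]
        base = means.loc[gene, "baseline"]
        assert means.loc[gene, "mid"] == pytest.approx(base + 1.0, abs=1e-9)
        assert means.loc[gene, "high"] == pytest.approx(base + 2.0, abs=1e-9)
        null_gene = labels[labels == "null"].index[0]
        assert means.loc[null_gene].std() == pytest.approx(0.0, abs=1e-9)

    def test_all_null_design_has_no_planted_genes(self):
        truth = SimulationTruth(seed=2, n_genes=100, deg_fraction_increasing=0,
                                deg_fraction_decreasing=0)
        _, labels = simulate_expression(truth)
        assert (labels == "null").all()

    def test_same_seed_is_byte_identical(self, small_truth):
        m1, l1 = simulate_expression(small_truth)
        m2, l2 = simulate_expression(small_truth)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_series_equal(l1, l2)

    def test_label_bookkeeping_matches_fractions(self):
        truth = SimulationTruth(seed=5, n_genes=1000, deg_fraction_increasing=0.07,
                                deg_fraction_decreasing=0.03)
        labels = plant_labels(truth)
        assert (labels == "increasing").sum() == 70
        assert (labels == "decreasing").sum() == 30


class TestSimulateMethylation:
    def test_coupled_gene_moves_against_expression(self):
        truth = SimulationTruth(seed=3, n_genes=60, beta_noise_sd=1e-12,
                                meth_coupled_fraction=1.0)
        _, labels = simulate_expression(truth)
        table, meth_labels = simulate_methylation(truth, labels)
        gene = labels[labels == "increasing"].index[0]
        probes = table.probe_to_gene[table.probe_to_gene == gene].index
        delta = (
            table.condition_values("high").loc[probes].mean(axis=1)
            - table.condition_values("baseline").loc[probes].mean(axis=1)
        )
        assert (delta <= -0.25).all()

    def test_betas_clipped_to_unit_interval(self):
        truth = SimulationTruth(seed=4, n_genes=80, beta_noise_sd=0.3,
                                meth_coupled_fraction=1.0)
        _, labels = simulate_expression(truth)
        table, _ = simulate_methylation(truth, labels)
        vals = table.betas.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_uncoupled_genes_flat_up_to_noise(self):
        truth = SimulationTruth(seed=5, n_genes=60, beta_noise_sd=1e-12,
                                meth_coupled_fraction=0.0)
        _, labels = simulate_expression(truth)
        table, meth_labels = simulate_methylation(truth, labels)
        assert (meth_labels == "uncoupled").all()
        delta = (
            table.condition_values("high").mean(axis=1)
            - table.condition_values("baseline").mean(axis=1)
        )
        assert delta.abs().max() < 1e-9

    def test_every_gene_has_one_to_three_probes(self, small_truth):
        _, labels = simulate_expression(small_truth)
        table, _ = simulate_methylation(small_truth, labels)
        counts = table.probe_to_gene.value_counts()
        assert set(counts.index) == set(labels.index)
        assert counts.between(1, 3).all()


class TestSimulateAnnotations:
    def test_planted_tf_targets_recovered_by_window_rule(self, small_truth):
        _, labels = simulate_expression(small_truth)
        ann = simulate_annotations(small_truth, labels)
        targets = assign_tf_targets(ann.peaks, ann.gene_models, 10_000, 3_000)
        assert targets["FOXC1"] == ann.tf_targets["FOXC1"]
        assert targets["DECOY_TF"] == ann.tf_targets["DECOY_TF"]

    def test_planted_set_flagged_across_seeds(self):
        flagged = 0
        n_seeds = 10
        for seed in range(n_seeds):
            truth = SimulationTruth(seed=seed, n_genes=500)
            _, labels = simulate_expression(truth)
            ann = simulate_annotations(truth, labels)
            increasing = set(labels[labels == "increasing"].index)
            res = ease_test(increasing, ann.gene_sets["planted_set_1"], set(labels.index))
            flagged += res.ease_p < 0.05
        assert flagged == n_seeds

    def test_peak_beyond_window_is_not_target(self, small_truth):
        # moving every planted peak 10001 bp past the upstream limit breaks targeting
        _, labels = simulate_expression(small_truth)
        ann = simulate_annotations(small_truth, labels)
        far = ann.peaks.copy()
        plus = ann.gene_models.set_index("gene")["strand"]
        far["start"] = far["start"] - 20_000
        far["end"] = far["end"] - 20_000
        targets = assign_tf_targets(far[far["tf"] == "FOXC1"], ann.gene_models, 10_000, 3_000)
        # plus-strand genes lose their peaks (moved out 5' beyond 10 kb);
        # minus-strand peaks move toward/through the gene body and may remain
        plus_targets = {g for g in targets["FOXC1"] if plus[g] == "+"}
        assert plus_targets == set()


class TestSimulateQpcr:
    def test_zero_noise_round_trip_recovers_planted_folds(self):
        truth = SimulationTruth(seed=6, qpcr_truth=QpcrTruth(ct_noise_sd=0.0))
        data = simulate_qpcr(truth)
        ct = data.ct_table
        gene = truth.qpcr_truth.genes[0]
        for unit in data.max_inductions.columns:
            groups = sorted(
                (c for c in ct.design.conditions if c.startswith(f"{unit}:")),
                key=lambda g: float(g.split(":t")[1]),
            )
            dct0 = delta_ct(ct, groups[0])
            folds = [1.0]
            for g in groups[1:]:
                log2fc, fold = ddct_log2fc(delta_ct(ct, g)[gene], dct0[gene])
                folds.append(fold)
            assert max(folds) == pytest.approx(data.max_inductions.loc[gene, unit], rel=1e-9)

    def test_max_induction_within_72h_matches_truth(self):
        truth = SimulationTruth(seed=7, qpcr_truth=QpcrTruth(ct_noise_sd=0.0))
        data = simulate_qpcr(truth)
        gene = truth.qpcr_truth.genes[0]
        series = [s for s in data.series if s.gene.startswith(f"{gene}@")]
        for s in series:
            unit = s.gene.split("@")[1]
            fold, _ = max_induction(s, 72)
            assert fold == pytest.approx(data.max_inductions.loc[gene, unit])

    def test_perfect_correlation_limit(self):
        truth = SimulationTruth(seed=8, qpcr_truth=QpcrTruth(r_true=1.0, ct_noise_sd=0.0))
        data = simulate_qpcr(truth)
        x = data.max_inductions.iloc[0].to_numpy()
        r = np.corrcoef(x, data.outcomes.to_numpy())[0, 1]
        assert r == pytest.approx(1.0)

    def test_r_true_recovered_on_average(self):
        rs = []
        for seed in range(200):
            truth = SimulationTruth(
                seed=seed, qpcr_truth=QpcrTruth(r_true=0.95, n_units=50, ct_noise_sd=0.0)
            )
            data = simulate_qpcr(truth)
            x = data.max_inductions.iloc[0].to_numpy()
            rs.append(np.corrcoef(x, data.outcomes.to_numpy())[0, 1])
        assert abs(np.mean(rs) - 0.95) <= 0.03

    def test_outcomes_are_proportions(self):
        truth = SimulationTruth(seed=9)
        data = simulate_qpcr(truth)
        assert data.outcomes.between(0, 1).all()

    def test_invalid_r_true_rejected(self):
        truth = SimulationTruth(seed=1, qpcr_truth=QpcrTruth(r_true=1.5))
        with pytest.raises(ConfigurationError):
            simulate_qpcr(truth)


class TestWriteSimulation:
    def test_same_truth_writes_byte_identical_files(self, tmp_path, small_truth):
        p1 = write_simulation(small_truth, tmp_path / "run1")
        p2 = write_simulation(small_truth, tmp_path / "run2")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name

    def test_label_file_counts_match_planted_classes(self, tmp_path, small_truth):
        paths = write_simulation(small_truth, tmp_path / "run")
        # keep_default_na: the literal class string "null" must not parse as NaN
        labels = pd.read_csv(paths["labels"], sep="\t", index_col=0, keep_default_na=False)
        expected = plant_labels(small_truth)
        assert (labels["class"] == expected).all()
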
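import numpy as np
import pandas as pd
import pytest

from hrdcc import (
    EventMatrix,
    StudyConfig,
    asinh_transform,
    assign_labels,
    auto_threshold,
    build_tree,
    compare_gating,
    exclude_nuisance,
    gate_node,
    run_hrdcc,
    simulate_study,
    synthesize_events,
)
from hrdcc.gating import GateNode, GatingError, density_valleys


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestAsinhTransform:
    def test_zero_maps_to_zero_and_cofactor_to_asinh_one(self):
        em = EventMatrix("s", pd.DataFrame({"CD4": [0.0, 150.0], "FSC-A": [1.0, 2.0]}))
        out = asinh_transform(em, 150.0)
        assert out.data["CD4"].iloc[0] == 0.0
        assert out.data["CD4"].iloc[1] == pytest.approx(np.arcsinh(1.0))
        assert out.data["CD4"].iloc[1] == pytest.approx(0.8814, abs=1e-4)

    def test_scatter_untouched_and_order_preserved(self):
        rng = _rng()
        vals = rng.normal(0, 500, 1000)
        em = EventMatrix("s", pd.DataFrame({"CD4": vals, "FSC-A": vals.copy()}))
        out = asinh_transform(em, 200.0)
        assert (out.data["FSC-A"] == vals).all()
        order_in = np.argsort(vals)
        order_out = np.argsort(out.data["CD4"].to_numpy())
        assert (order_in == order_out).all()

    def test_nonpositive_cofactor_rejected(self):
        em = EventMatrix("s", pd.DataFrame({"CD4": [1.0]}))
        with pytest.raises(GatingError):
            asinh_transform(em, 0.0)


class TestAutoThreshold:
    def test_valley_between_two_modes(self):
        rng = _rng(3)
        values = np.concatenate([rng.normal(0, 1, 5000), rng.normal(6, 1, 5000)])
        assert auto_threshold(values) == pytest.approx(3.0, abs=0.3)

    def test_unimodal_falls_back_to_quantile(self):
        values = _rng(4).normal(0, 1, 20_000)
        assert auto_threshold(values, fallback_quantile=0.99) == pytest.approx(
            2.326, abs=0.12)

    def test_constant_input_rejected(self):
        with pytest.raises(GatingError):
            auto_threshold(np.full(1000, 3.14))

    def test_deterministic(self):
        rng = _rng(5)
        values = np.concatenate([rng.normal(0, 1, 3000), rng.normal(5, 1, 1000)])
        assert auto_threshold(values) == auto_threshold(values)

    def test_minor_mode_detected(self):
        rng = _rng(6)
        values = np.concatenate([rng.normal(0.4, 0.3, 19_400),
                                 rng.normal(3.0, 0.3, 600)])
        cut = auto_threshold(values)
        assert 1.0 < cut < 2.6

    def test_three_mode_valleys(self):
        rng = _rng(7)
        values = np.concatenate([rng.normal(18, 3.5, 8000),
                                 rng.normal(50, 5, 3000),
                                 rng.normal(95, 7, 9000)])
        lo, hi = density_valleys(values, 2)
        assert 25 < lo < 45
        assert 60 < hi < 88


class TestGateNode:
    def test_all_double_negative_quadrant(self):
        em = EventMatrix("s", pd.DataFrame({
            "CD14": np.full(100, 0.1), "CD16": np.full(100, 0.1)}))
        node = GateNode("q", ("CD14", "CD16"), "quadrant", (1.7, 1.7))
        parts = gate_node(em, node)
        assert parts["nn"].n_events == 100
        assert parts["pp"].n_events == 0

    def test_balanced_quadrant_mixture(self):
        rng = _rng(8)
        n = 40_000
        a = rng.choice([0.4, 3.0], n)
        b = rng.choice([0.4, 3.0], n)
        em = EventMatrix("s", pd.DataFrame({
            "CD14": rng.normal(a, 0.3), "CD16": rng.normal(b, 0.3)}))
        node = GateNode("q", ("CD14", "CD16"), "quadrant", (1.7, 1.7))
        parts = gate_node(em, node)
        for key in ("pp", "pn", "np", "nn"):
            assert parts[key].n_events / n == pytest.approx(0.25, abs=0.01)

    def test_unknown_rule_rejected(self):
        em = EventMatrix("s", pd.DataFrame({"CD4": [1.0]}))
        with pytest.raises(GatingError):
            gate_node(em, GateNode("x", ("CD4",), "banana", (1.0,)))

    def test_mec_node_tolerates_missing_panck(self):
        em = EventMatrix("s", pd.DataFrame({"CD45": [1.0, 2.0]}))
        node = GateNode("mec", ("panCK",), "threshold-above", (1.7,))
        assert gate_node(em, node) == {}


class TestNuisanceExclusion:
    def test_clean_sample_has_full_viability(self):
        from tests.test_simulate import _pure_state
        config = StudyConfig(debris_fraction=0.0, doublet_fraction=0.0)
        em = synthesize_events(_pure_state(viability=1.0), config, _rng(),
                               n_events=5_000)
        tree = build_tree("blood", config)
        live, viability = exclude_nuisance(asinh_transform(em, config.cofactor),
                                           tree)
        assert viability == 100.0
        assert live.n_events == pytest.approx(5_000, abs=25)

    def test_dead_fraction_measured(self):
        from tests.test_simulate import _pure_state
        config = StudyConfig(debris_fraction=0.0, doublet_fraction=0.0)
        em = synthesize_events(_pure_state(viability=0.7), config, _rng(2),
                               n_events=20_000)
        tree = build_tree("blood", config)
        _, viability = exclude_nuisance(asinh_transform(em, config.cofactor), tree)
        assert viability == pytest.approx(70.0, abs=4 * 100 * np.sqrt(0.21 / 20_000))

    def test_pure_debris_flagged(self):
        rng = _rng(3)
        n = 2_000
        em = EventMatrix("s", pd.DataFrame({
            "FSC-A": rng.normal(4000, 1000, n), "FSC-H": rng.normal(4000, 1000, n),
            "SSC-A": rng.normal(2500, 800, n), "Viability": rng.normal(60, 20, n)}))
        tree = build_tree("blood", StudyConfig())
        with pytest.raises(GatingError, match="debris"):
            exclude_nuisance(asinh_transform(em, 150.0), tree)


class TestRunHRDCC:
    def test_main_populations_sum_to_100(self, blood_sample, trees):
        em, _ = blood_sample
        res = run_hrdcc(em, trees["blood"], "reference")
        total = (res.percent_of_parent["granulocytes"]
                 + res.percent_of_parent["monocytes_macrophages"]
                 + res.percent_of_parent["lymphocytes"])
        assert total == pytest.approx(100.0, abs=0.01)

    @pytest.mark.parametrize("mode", ["reference", "auto"])
    def test_blood_percentages_match_truth_labels(self, blood_sample, trees, mode):
        """Gated percentages agree with the event-label composition."""
        em, _ = blood_sample
        res = run_hrdcc(em, trees["blood"], mode)
        labels = em.truth_labels
        leuk_pops = ["neutrophils", "eosinophils", "immature_granulocytes",
                     "cM", "intM", "ncM", "nk_cells", "gd_t_cells",
                     "cd4_t_cells", "cd8_t_cells", "b_cells", "dn_lymphocytes"]
        counts = {p: int(np.sum(labels == p)) for p in leuk_pops}
        n_leuk = sum(counts.values())
        gran = sum(counts[p] for p in ("neutrophils", "eosinophils",
                                       "immature_granulocytes"))
        lymph = sum(counts[p] for p in ("nk_cells", "gd_t_cells", "cd4_t_cells",
                                        "cd8_t_cells", "b_cells", "dn_lymphocytes"))
        mono = counts["cM"] + counts["intM"] + counts["ncM"]
        expected = {
            "granulocytes": 100 * gran / n_leuk,
            "monocytes_macrophages": 100 * mono / n_leuk,
            "lymphocytes": 100 * lymph / n_leuk,
            "eosinophils": 100 * counts["eosinophils"] / gran,
            "cM": 100 * counts["cM"] / mono,
            "cd4_t_cells": 100 * counts["cd4_t_cells"] / lymph,
            "b_cells": 100 * counts["b_cells"] / lymph,
        }
        for node, exp in expected.items():
            assert res.percent_of_parent[node] == pytest.approx(exp, abs=1.5)

    def test_pure_lymphocyte_sample(self):
        from tests.test_simulate import _pure_state
        config = StudyConfig(debris_fraction=0.0, doublet_fraction=0.0)
        em = synthesize_events(_pure_state(), config, _rng(5), n_events=5_000)
        res = run_hrdcc(em, build_tree("blood", config), "reference")
        assert res.percent_of_parent["lymphocytes"] == pytest.approx(100, abs=0.5)
        assert res.percent_of_parent["granulocytes"] == pytest.approx(0, abs=0.5)
        assert res.percent_of_parent["cd4_t_cells"] == pytest.approx(100, abs=0.5)

    def test_early_milk_sample_reports_null_mec(self, small_study, trees):
        row = small_study.samples[(small_study.samples.matrix == "milk")
                                  & (small_study.samples.dim < 50)].iloc[0]
        em = small_study.events_for(row.sample_id)
        res = run_hrdcc(em, trees["milk"], "reference")
        assert res.mec_percent is None
        assert "gd_t_cells" in res.percent_of_parent

    def test_late_milk_sample_reports_mec(self, milk_sample, trees):
        em, state = milk_sample
        res = run_hrdcc(em, trees["milk"], "reference")
        assert res.mec_percent == pytest.approx(
            state.truth_percentages()["mec"], abs=5.0)

    def test_missing_required_channel_rejected(self, blood_sample, trees):
        em, _ = blood_sample
        crippled = em.with_data(em.data.drop(columns=["CD45"]))
        with pytest.raises(GatingError, match="CD45"):
            run_hrdcc(crippled, trees["blood"], "reference")

    def test_reference_and_auto_agree_on_well_separated_sample(
            self, blood_sample, trees):
        em, _ = blood_sample
        ref = run_hrdcc(em, trees["blood"], "reference")
        auto = run_hrdcc(em, trees["blood"], "auto")
        for node, v in ref.percent_of_parent.items():
            assert abs(v - auto.percent_of_parent[node]) < 1.0

    def test_denominator_conventions_preserve_sibling_order(self, blood_sample,
                                                            trees):
        em, _ = blood_sample
        res = run_hrdcc(em, trees["blood"], "reference")
        lymph = ["nk_cells", "gd_t_cells", "cd4_t_cells", "cd8_t_cells", "b_cells"]
        order_parent = sorted(lymph, key=lambda k: res.percent_of_parent[k])
        order_cd45 = sorted(lymph, key=lambda k: res.percent_of_cd45[k])
        assert order_parent == order_cd45

    def test_events_partition_into_disjoint_terminal_populations(
            self, blood_sample, trees):
        em, _ = blood_sample
        labels = assign_labels(em, trees["blood"], "reference")
        assert len(labels) == em.n_events
        res = run_hrdcc(em, trees["blood"], "reference")
        # sibling counts reassemble exactly to the parent count
        assert (res.counts["granulocytes"] + res.counts["monocytes_macrophages"]
                + res.counts["lymphocytes"]) == res.counts["cd45"]


class TestLabelRecovery:
    def _f1(self, truth, pred, pop):
        tp = np.sum((truth == pop) & (pred == pop))
        fp = np.sum((truth != pop) & (pred == pop))
        fn = np.sum((truth == pop) & (pred != pop))
        return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0

    @pytest.mark.parametrize("matrix", ["blood", "milk"])
    def test_terminal_population_f1_exceeds_095(self, small_study, trees, matrix):
        sel = small_study.samples[(small_study.samples.matrix == matrix)
                                  & (small_study.samples.dim > 60)].iloc[0]
        em = small_study.events_for(sel.sample_id)
        pred = assign_labels(em, trees[matrix], "auto")
        truth = em.truth_labels
        for pop in sorted(set(truth) - {"debris", "doublet", "dead"}):
            assert self._f1(truth, pred, pop) >= 0.95, pop

    def test_zero_separation_destroys_recovery(self):
        """Ablation: collapsing all marker signatures onto the negative
        level reduces subset recovery to chance."""
        config = StudyConfig(n_animals=1, events_per_sample=20_000,
                             signature_separation=0.0)
        study = simulate_study(config, seed=2)
        row = study.samples[study.samples.matrix == "blood"].iloc[5]
        em = study.events_for(row.sample_id)
        tree = build_tree("blood", config)
        pred = assign_labels(em, tree, "reference")
        truth = em.truth_labels
        f1s = [self._f1(truth, pred, p)
               for p in ("cd4_t_cells", "b_cells", "cM", "eosinophils")]
        assert np.mean(f1s) < 0.5

    def test_modes_converge_with_increasing_separation(self, small_study):
        """Reference and auto thresholds agree ever more closely as the
        population separation grows."""
        discrepancies = []
        for sep in (1.0, 2.0):
            config = StudyConfig(n_animals=1, events_per_sample=20_000,
                                 signature_separation=sep)
            study = simulate_study(config, seed=4)
            row = study.samples[study.samples.matrix == "blood"].iloc[10]
            em = study.events_for(row.sample_id)
            tree = build_tree("blood", config)
            ref = run_hrdcc(em, tree, "reference")
            auto = run_hrdcc(em, tree, "auto")
            discrepancies.append(max(
                abs(ref.percent_of_parent[k] - auto.percent_of_parent[k])
                for k in ref.percent_of_parent))
        assert discrepancies[1] <= discrepancies[0] + 0.05
        assert discrepancies[1] < 0.5


class TestCompareGating:
    def test_identity_comparison(self, blood_sample, trees):
        em, _ = blood_sample
        res = run_hrdcc(em, trees["blood"], "reference")
        # build a minimal three-gate pool by duplicating the result
        cmp = compare_gating([res], [res])
        assert cmp.r == pytest.approx(1.0)
        assert cmp.slope == pytest.approx(1.0)
        assert cmp.intercept == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_sets_rejected(self, blood_sample, milk_sample, trees):
        em_b, _ = blood_sample
        em_m, _ = milk_sample
        res_b = run_hrdcc(em_b, trees["blood"], "reference")
        res_m = run_hrdcc(em_m, trees["milk"], "reference")
        with pytest.raises(GatingError):
            compare_gating([res_b], [res_m])
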
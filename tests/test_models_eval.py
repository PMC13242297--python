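import numpy as np
import pytest

from drpscreen import synth
from drpscreen.models_eval import (compute_metrics, crossval_protocol,
                                   evaluate_global_and_perdrug,
                                   run_panel_benchmark, screening_efficiency,
                                   selective_drugs, split_cell_lines,
                                   train_drug_model)
from drpscreen.panel_select import select_panel, threshold_for_size
from drpscreen.models_eval import _predict_all_drugs
from conftest import make_matrix


class TestSplitCellLines:
    def test_exact_division_100(self):
        tr, va, te = split_cell_lines([f"c{i}" for i in range(100)], seed=0)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_floor_rule_remainder_to_train_805(self):
        tr, va, te = split_cell_lines([f"c{i}" for i in range(805)], seed=0)
        assert (len(va), len(te), len(tr)) == (80, 80, 645)

    def test_disjoint_exhaustive_and_deterministic(self):
        ids = [f"c{i}" for i in range(47)]
        a = split_cell_lines(ids, seed=5)
        b = split_cell_lines(ids, seed=5)
        assert a == b
        parts = [set(p) for p in a]
        assert parts[0] | parts[1] | parts[2] == set(ids)
        assert not (parts[0] & parts[1] or parts[0] & parts[2]
                    or parts[1] & parts[2])

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            split_cell_lines(["a", "b"], seed=0)


class TestTrainDrugModel:
    def test_learnable_identity_training_error_shrinks(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 3))
        y = X[:, 0].copy()
        model = train_drug_model(X, y, hyperparams={"n_estimators": 300},
                                 seed=0)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 0.05

    def test_permuted_labels_give_null_heldout_correlation(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((400, 5))
        y = rng.permutation(X[:, 0] + 0.1 * rng.standard_normal(400))
        model = train_drug_model(X[:200], y[:200], seed=1)
        r = np.corrcoef(y[200:], model.predict(X[200:]))[0, 1]
        assert abs(r) < 0.2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0])
        a = train_drug_model(X, y, seed=7).predict(X)
        b = train_drug_model(X, y, seed=7).predict(X)
        assert np.array_equal(a, b)

    def test_constant_labels_flagged(self):
        X = np.random.default_rng(3).standard_normal((10, 2))
        model = train_drug_model(X, np.full(10, 5.0), seed=0)
        assert model.zero_variance_target

    def test_default_hyperparams_are_small_trees(self):
        X = np.random.default_rng(4).standard_normal((10, 2))
        model = train_drug_model(X, X[:, 0], seed=0)
        assert model.hyperparams["n_estimators"] == 50
        assert model.hyperparams["max_depth"] == 2


class TestComputeMetrics:
    def test_identity_prediction(self):
        m = compute_metrics([0, 1, 2.0], [0, 1, 2.0])
        assert m["pearson"] == pytest.approx(1.0)
        assert m["spearman"] == pytest.approx(1.0)
        assert m["mse"] == 0 and m["rmse"] == 0 and m["mae"] == 0

    def test_closed_form_worked_example(self):
        m = compute_metrics([0.0, 1.0, 2.0], [0.0, 2.0, 2.0])
        assert m["mse"] == pytest.approx(1 / 3)
        assert m["rmse"] == pytest.approx(0.5774, abs=1e-4)
        assert m["mae"] == pytest.approx(1 / 3)
        assert m["pearson"] == pytest.approx(0.8660, abs=1e-4)
        assert m["spearman"] == pytest.approx(0.8660, abs=1e-4)

    def test_constant_vector_flags_correlations_keeps_errors(self):
        m = compute_metrics([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        assert not m["correlation_defined"]
        assert np.isnan(m["pearson"])
        assert m["mse"] == pytest.approx(2 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_metrics([1.0, 2.0], [1.0])

    def test_rmse_is_sqrt_mse_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            m = compute_metrics(rng.standard_normal(n), rng.standard_normal(n))
            assert m["rmse"] == pytest.approx(np.sqrt(m["mse"]))
            if m["correlation_defined"]:
                assert -1 <= m["pearson"] <= 1
                assert -1 <= m["spearman"] <= 1


class TestEvaluateGlobalAndPerDrug:
    def test_single_drug_global_equals_per_drug(self):
        preds = {"D1": (np.array([1.0, 2, 3]), np.array([1.1, 2, 2.8]))}
        g, p = evaluate_global_and_perdrug(preds)
        assert g.metrics["rmse"] == pytest.approx(p.metrics["rmse"])
        assert p.sd["rmse"] == pytest.approx(0.0)

    def test_mean_of_two_drug_correlations(self):
        preds = {
            "a": (np.array([0.0, 1, 2]), np.array([0.0, 1, 2])),  # r = 1
            "b": (np.array([0.0, 1, 2, 1]), np.array([1.0, 1, 1, -1])),
        }
        g, p = evaluate_global_and_perdrug(preds)
        rb = compute_metrics([0.0, 1, 2, 1], [1.0, 1, 1, -1])["pearson"]
        assert p.metrics["pearson"] == pytest.approx((1.0 + rb) / 2)

    def test_global_pooled_exceeds_per_drug_mean_with_offsets(self):
        # drug-specific potency offsets inflate pooled correlation
        rng = np.random.default_rng(6)
        preds = {}
        for j, offset in enumerate([0.0, 3.0, 6.0, 9.0]):
            y = offset + rng.standard_normal(50) * 0.5
            yhat = offset + 0.5 * (y - offset) + 0.4 * rng.standard_normal(50)
            preds[f"d{j}"] = (y, yhat)
        g, p = evaluate_global_and_perdrug(preds)
        assert g.metrics["pearson"] > p.metrics["pearson"]

    def test_undefined_correlation_drugs_counted_not_imputed(self):
        preds = {
            "ok": (np.array([0.0, 1, 2]), np.array([0.0, 1, 2])),
            "flat": (np.array([5.0, 5.0]), np.array([4.0, 6.0])),
        }
        _, p = evaluate_global_and_perdrug(preds)
        assert p.n_undefined_correlation == 1
        assert p.metrics["pearson"] == pytest.approx(1.0)


class TestSelectiveDrugs:
    def test_never_active_is_selective(self):
        m = make_matrix(np.full((8, 1), 3.0))
        assert selective_drugs(m) == ["D0"]

    def test_exact_quarter_not_selective(self):
        col = np.array([7.0] + [3.0] * 3)  # active fraction exactly 0.25
        m = make_matrix(col[:, None])
        assert selective_drugs(m) == []

    def test_matches_bruteforce_planted_fractions(self):
        rng = np.random.default_rng(7)
        n = 40
        fracs = rng.uniform(0, 0.6, size=10)
        cols = []
        for f in fracs:
            k = int(round(f * n))
            col = np.concatenate([np.full(k, 7.0), np.full(n - k, 3.0)])
            cols.append(rng.permutation(col))
        m = make_matrix(np.column_stack(cols))
        expected = [f"D{j}" for j, f in enumerate(fracs)
                    if (round(f * n) / n) < 0.25]
        assert selective_drugs(m) == expected

    def test_unobserved_drug_warned_and_excluded(self):
        vals = np.column_stack([np.full(4, 3.0), np.full(4, np.nan)])
        m = make_matrix(vals)
        with pytest.warns(UserWarning, match="no observed"):
            out = selective_drugs(m)
        assert out == ["D0"]


class TestScreeningEfficiency:
    def test_perfect_ranking(self):
        cells = [f"c{i}" for i in range(10)]
        labels = {c: int(i < 3) for i, c in enumerate(cells)}
        frac, rec = screening_efficiency(cells, labels)
        assert frac == pytest.approx(0.3)
        assert rec == 3

    def test_hand_enumerated_positives_at_1_2_3_7(self):
        cells = [f"c{i}" for i in range(10)]
        labels = {c: 0 for c in cells}
        for i in (0, 1, 2, 6):  # ranks 1, 2, 3, 7
            labels[cells[i]] = 1
        frac, rec = screening_efficiency(cells, labels, recall_target=0.75)
        # need ceil(0.75*4)=3 positives -> found at rank 3 -> fraction 0.3
        assert frac == pytest.approx(0.3)
        assert rec == 3

    def test_random_ranking_mean_near_recall_target(self):
        # exchangeable ranks: expected tested fraction ~ recall target
        # (exact finite-size mean is m(n+1)/((k+1)n) for the m-th of k
        # positives among n lines; negligible bias at n = 200)
        rng = np.random.default_rng(8)
        cells = [f"c{i}" for i in range(200)]
        labels = {c: int(i < 50) for i, c in enumerate(cells)}
        fracs = []
        for _ in range(500):
            order = [cells[i] for i in rng.permutation(200)]
            fracs.append(screening_efficiency(order, labels,
                                              recall_target=0.75)[0])
        assert np.mean(fracs) == pytest.approx(0.75, abs=0.05)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            screening_efficiency(["a", "b"], {"a": 0, "b": 0})

    def test_score_ties_broken_by_id(self):
        labels = {"a": 1, "b": 0, "c": 1}
        scores = {"a": 1.0, "b": 1.0, "c": 1.0}
        frac, _ = screening_efficiency(["c", "b", "a"], labels, scores=scores,
                                       recall_target=1.0)
        # tie -> id order a, b, c; both positives found after all 3
        assert frac == pytest.approx(1.0)


class TestProtocols:
    @pytest.fixture(scope="class")
    def study(self):
        m, truth = synth.simulate_response_matrix(
            n_lines=120, n_drugs=30, seed=42)
        return m, truth

    def test_crossval_noiseless_near_perfect(self):
        m, _ = synth.simulate_response_matrix(
            n_lines=120, n_drugs=30, noise_sd=0.0, seed=43)
        g, _ = crossval_protocol(m, k_folds=2, panel_mode="all", seed=0)
        assert g.metrics["pearson"] > 0.95

    def test_crossval_random_panel_deterministic(self, study):
        m, _ = study
        a = crossval_protocol(m, k_folds=3, panel_mode="random",
                              train_frac_within_fold=0.2, seed=5)
        b = crossval_protocol(m, k_folds=3, panel_mode="random",
                              train_frac_within_fold=0.2, seed=5)
        assert a[0].metrics == b[0].metrics

    def test_crossval_k_exceeding_cells_rejected(self, study):
        m, _ = study
        with pytest.raises(ValueError, match="k_folds"):
            crossval_protocol(m, k_folds=500)

    def test_benchmark_self_comparison_null(self, study):
        m, _ = study
        rep = run_panel_benchmark(m, drug_panel_size=10, cell_panel_size=30,
                                  n_replicates=2, seeds=[0, 1])
        # single-arm run: no t-test, DRP summary present and finite
        assert "paired_ttest_rmse" not in rep
        assert np.isfinite(rep["summary"]["DRP"]["rmse"][0])

    def test_benchmark_rerun_identical(self, study):
        m, _ = study
        a = run_panel_benchmark(m, drug_panel_size=10, cell_panel_size=30,
                                n_replicates=2, seeds=[3, 4])
        b = run_panel_benchmark(m, drug_panel_size=10, cell_panel_size=30,
                                n_replicates=2, seeds=[3, 4])
        assert a["replicates"].equals(b["replicates"])

    def test_no_training_cell_in_evaluation(self, study):
        m, _ = study
        train, _, test = split_cell_lines(m.cell_ids, seed=9)
        assert not set(train) & set(test)
        t, _ = threshold_for_size(m.subset(cells=train), "drugs", 8, seed=9)
        panel = select_panel(m.subset(cells=train), "drugs", t, seed=9)
        preds = _predict_all_drugs(m, "DRP", panel, None, train, test, None, 9)
        for drug, (y, yhat) in preds.items():
            assert len(y) <= len(test)
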
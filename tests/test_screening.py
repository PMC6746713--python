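import numpy as np
import pandas as pd
import pytest

from typescreen.screening import (
    PipelineConfig,
    ScreeningModel,
    balance_training_sessions,
    nested_select_and_tune,
    run_loso,
    selection_frequency_report,
)

from conftest import FAST_GRID


def synthetic_feature_table(rng, n_subjects=12, sessions=6, n_features=6,
                            signal_feature=None, shift=3.0):
    """Session table with iid noise features; optionally one separating feature."""
    rows = []
    labels = {}
    for i in range(n_subjects):
        sid = f"s{i:02d}"
        label = i % 2
        labels[sid] = label
        for j in range(sessions):
            feats = {f"f{k}": float(rng.normal()) for k in range(n_features)}
            if signal_feature is not None:
                feats[signal_feature] += shift * label
            rows.append({"subject_id": sid, "session_id": f"{sid}-{j}",
                         "day_index": j // 4, **feats})
    return pd.DataFrame(rows), labels


class TestBalancing:
    def test_undersamples_to_minority_count(self, rng):
        table, _ = synthetic_feature_table(rng, n_subjects=10, sessions=10)
        labels = pd.Series({f"s{i:02d}": int(i < 4) for i in range(10)})
        out = balance_training_sessions(table, labels, np.random.default_rng(0))
        y = out["subject_id"].map(labels)
        assert (y == 1).sum() == (y == 0).sum() == 40

    def test_already_balanced_keeps_all_rows(self, rng):
        table, labels = synthetic_feature_table(rng, n_subjects=12, sessions=4)
        out = balance_training_sessions(
            table, pd.Series(labels), np.random.default_rng(0)
        )
        assert sorted(out.index) == sorted(table.index)

    def test_seeded_determinism(self, rng):
        table, _ = synthetic_feature_table(rng, n_subjects=9, sessions=7)
        labels = pd.Series({f"s{i:02d}": int(i < 3) for i in range(9)})
        a = balance_training_sessions(table, labels, np.random.default_rng(5))
        b = balance_training_sessions(table, labels, np.random.default_rng(5))
        assert a.index.tolist() == b.index.tolist()

    def test_single_class_rejected(self, rng):
        table, _ = synthetic_feature_table(rng, n_subjects=4, sessions=3)
        labels = pd.Series({f"s{i:02d}": 1 for i in range(4)})
        with pytest.raises(ValueError):
            balance_training_sessions(table, labels, np.random.default_rng(0))


class TestNestedSelection:
    def test_perfectly_separating_feature_always_selected(self, rng):
        table, labels = synthetic_feature_table(
            rng, n_subjects=12, sessions=6, signal_feature="f2", shift=5.0
        )
        cfg = PipelineConfig(k_best=1, grid=FAST_GRID, seed=0)
        for trial in range(3):
            selected, params, auc = nested_select_and_tune(
                table, pd.Series(labels), cfg, np.random.default_rng(trial)
            )
            assert selected == ["f2"]
        assert set(params) == {"max_depth", "n_estimators"}

    def test_k_equals_all_features_reduces_to_tuning(self, rng):
        table, labels = synthetic_feature_table(rng, n_subjects=12, sessions=5,
                                                n_features=4)
        cfg = PipelineConfig(k_best=4, grid=FAST_GRID, seed=0)
        selected, _, _ = nested_select_and_tune(
            table, pd.Series(labels), cfg, np.random.default_rng(0)
        )
        assert sorted(selected) == [f"f{k}" for k in range(4)]

    def test_pure_noise_selection_roughly_uniform(self):
        # regenerating noise per seed, no feature should dominate selection
        cfg = PipelineConfig(k_best=1, grid=FAST_GRID, seed=0)
        picks = []
        for seed in range(30):
            table, labels = synthetic_feature_table(
                np.random.default_rng(seed), n_subjects=12, sessions=5, n_features=5
            )
            sel, _, _ = nested_select_and_tune(
                table, pd.Series(labels), cfg, np.random.default_rng(seed)
            )
            picks.append(sel[0])
        counts = pd.Series(picks).value_counts()
        assert len(counts) >= 3  # every-ish feature gets its turn
        assert counts.iloc[0] <= 0.5 * len(picks)


class TestLoso:
    def test_one_iteration_per_subject(self, rng):
        table, labels = synthetic_feature_table(
            rng, n_subjects=12, sessions=5, signal_feature="f0", shift=4.0
        )
        res = run_loso(table, labels, PipelineConfig(grid=FAST_GRID, seed=1))
        assert len(res.iterations) == 12
        assert sorted(it.test_subject for it in res.iterations) == sorted(labels)
        assert set(res.session_table.subject_id) == set(labels)
        assert ((res.session_table.prob >= 0) & (res.session_table.prob <= 1)).all()

    def test_subject_mean_is_arithmetic_mean(self, rng):
        table, labels = synthetic_feature_table(
            rng, n_subjects=12, sessions=4, signal_feature="f0"
        )
        res = run_loso(table, labels, PipelineConfig(grid=FAST_GRID, seed=1))
        for s in res.subject_ids:
            assert res.subject_means[s] == pytest.approx(
                float(np.mean(res.session_probs(s)))
            )

    def test_determinism_same_seed(self, rng):
        table, labels = synthetic_feature_table(
            rng, n_subjects=12, sessions=4, signal_feature="f1"
        )
        cfg = PipelineConfig(grid=FAST_GRID, seed=42)
        r1 = run_loso(table, labels, cfg)
        r2 = run_loso(table, labels, cfg)
        assert r1.session_table.equals(r2.session_table)
        assert [it.selected for it in r1.iterations] == [
            it.selected for it in r2.iterations
        ]

    def test_separable_cohort_reaches_auc_one(self, rng):
        table, labels = synthetic_feature_table(
            rng, n_subjects=12, sessions=6, signal_feature="f3", shift=6.0
        )
        res = run_loso(table, labels, PipelineConfig(grid=FAST_GRID, seed=2))
        assert res.auc == pytest.approx(1.0)

    def test_single_class_cohort_rejected(self, rng):
        table, _ = synthetic_feature_table(rng, n_subjects=5, sessions=4)
        with pytest.raises(ValueError, match="single class"):
            run_loso(table, {f"s{i:02d}": 1 for i in range(5)},
                     PipelineConfig(grid=FAST_GRID))

    def test_leakage_guard_test_rows_never_trained_on(self, rng):
        table, labels = synthetic_feature_table(
            rng, n_subjects=12, sessions=5, signal_feature="f0"
        )
        res = run_loso(table, labels, PipelineConfig(grid=FAST_GRID, seed=3))
        for it in res.iterations:
            test_rows = table.reset_index(drop=True)
            test_idx = test_rows.index[test_rows.subject_id == it.test_subject]
            assert len(np.intersect1d(it.train_row_ids, test_idx)) == 0


class TestSelectionFrequency:
    def test_always_selected_feature_flagged(self, rng):
        table, labels = synthetic_feature_table(
            rng, n_subjects=12, sessions=5, signal_feature="f0", shift=6.0
        )
        res = run_loso(table, labels,
                       PipelineConfig(grid=FAST_GRID, seed=1, k_best=2))
        rep = selection_frequency_report(
            res.iterations, [f"f{k}" for k in range(6)]
        )
        f0 = rep[rep.feature == "f0"].iloc[0]
        assert f0["times_selected_pct"] == 100.0 and f0["consistent"]

    def test_never_selected_feature_zero_and_nan(self, rng):
        table, labels = synthetic_feature_table(
            rng, n_subjects=12, sessions=5, signal_feature="f0", shift=6.0
        )
        res = run_loso(table, labels,
                       PipelineConfig(grid=FAST_GRID, seed=1, k_best=1))
        rep = selection_frequency_report(res.iterations, ["f0", "f5"])
        f5 = rep[rep.feature == "f5"].iloc[0]
        assert f5["times_selected_pct"] == 0.0 and np.isnan(f5["importance_mean"])

    def test_counting_identity_when_k_always_filled(self, rng):
        table, labels = synthetic_feature_table(rng, n_subjects=12, sessions=5)
        k = 3
        res = run_loso(table, labels, PipelineConfig(grid=FAST_GRID, seed=1, k_best=k))
        rep = selection_frequency_report(res.iterations, [f"f{j}" for j in range(6)])
        total = rep["times_selected_pct"].sum() / 100 * len(res.iterations)
        assert total == pytest.approx(k * len(res.iterations))


class TestModelResultsApi:
    def test_fit_summary_and_json_round_trip(self, rng, tmp_path):
        table, labels = synthetic_feature_table(
            rng, n_subjects=12, sessions=4, signal_feature="f0", shift=5.0
        )
        model = ScreeningModel(table, labels, PipelineConfig(grid=FAST_GRID, seed=9))
        res = model.fit()
        text = res.summary(n_boot=50)
        assert "bootstrap AUC" in text and "subjects: 12" in text
        path = tmp_path / "result.json"
        res.to_json(path)
        from typescreen.screening import ScreeningResults

        back = ScreeningResults.from_json(path)
        assert back.subject_means.round(9).equals(res.subject_means.round(9))
        assert back.auc == pytest.approx(res.auc)
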
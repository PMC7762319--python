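import numpy as np
import pytest

import nirtaste as nt
from nirtaste.errors import ConfigError, CoverageError, DegenerateInputError, ProtocolError
from nirtaste.evaluate import (
    AnnModelSpec,
    PlsrModelSpec,
    aggregate_mean_predictions,
    compute_metrics,
    random_split,
    reports_to_frame,
    run_replications,
    selection_split,
    summarize,
)
from nirtaste.mlp import MLPArchitecture, TrainingConfig


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert (m.r, m.r2, m.mse, m.rmse, m.mae) == (1.0, 1.0, 0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        m = compute_metrics(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 5.0]))
        assert m.mse == pytest.approx(3.0)
        assert m.rmse == pytest.approx(np.sqrt(3.0))
        assert m.mae == pytest.approx(1.0)

    def test_anticorrelation(self):
        y = np.array([-1.0, 0.0, 1.0])
        m = compute_metrics(y, -y)
        assert m.r == pytest.approx(-1.0)
        assert m.r2 == pytest.approx(1.0)

    def test_r2_is_squared_pearson(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        y_hat = 0.5 * y + rng.normal(size=50)  # biased predictor
        m = compute_metrics(y, y_hat)
        assert m.r2 == pytest.approx(m.r**2, rel=1e-12)
        assert m.rmse == pytest.approx(np.sqrt(m.mse), rel=1e-15)

    def test_constant_truth_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_metrics(np.ones(5), np.arange(5.0))


class TestRandomSplit:
    def test_study_sizes(self):
        tr, va, te = random_split(150, seed=0)
        assert (len(tr), len(va), len(te)) == (90, 15, 45)

    def test_minimum_n(self):
        tr, va, te = random_split(10, seed=1)
        assert (len(tr), len(va), len(te)) == (6, 1, 3)
        with pytest.raises(ConfigError):
            random_split(9, seed=1)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n", [10, 37, 150])
    def test_partition_property(self, n, seed):
        tr, va, te = random_split(n, seed)
        combined = np.concatenate([tr, va, te])
        assert len(combined) == n
        np.testing.assert_array_equal(np.sort(combined), np.arange(n))

    def test_selection_split_is_60_40(self):
        tr, va = selection_split(150, seed=0)
        assert (len(tr), len(va)) == (90, 60)
        np.testing.assert_array_equal(np.sort(np.concatenate([tr, va])), np.arange(150))


def _linear_dataset(seed=0, n=60, p=3, noise=0.05):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ np.array([1.0, -0.5, 0.25])[:p] + noise * rng.normal(size=n)
    return X, y


class TestRunReplications:
    def test_single_replication(self):
        X, y = _linear_dataset()
        reports = run_replications(PlsrModelSpec(3), X, y, 1, base_seed=0)
        assert len(reports) == 1
        assert len(reports[0].test_predictions) == len(reports[0].test_idx)

    def test_deterministic_given_base_seed(self):
        X, y = _linear_dataset()
        spec = AnnModelSpec(MLPArchitecture((2,), ("tansig",), "trainrp"),
                            TrainingConfig(max_epochs=40, val_patience=40))
        a = run_replications(spec, X, y, 3, base_seed=7)
        b = run_replications(spec, X, y, 3, base_seed=7)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.test_predictions, rb.test_predictions)
            assert ra.metrics == rb.metrics

    def test_stability_of_seeded_ann_runs(self, default_bundle):
        """Low-noise planted-channel ANN: R varies little across splits."""
        _, pre, chem, truth = default_bundle
        X, y, _ = nt.join_chemistry(pre, chem, "ta")
        Xp = X[:, truth.informative_channels["ta"]]
        spec = AnnModelSpec(MLPArchitecture((1,), ("purelin",), "trainbfg"),
                            TrainingConfig(max_epochs=200, val_patience=30))
        reports = run_replications(spec, Xp, y, 20, base_seed=0)
        rs = [r.metrics.r for r in reports]
        assert np.std(rs, ddof=1) < 0.1

    def test_too_many_failures_abort(self):
        X, y = _linear_dataset(n=20)
        y = np.zeros_like(y)  # constant target: metrics undefined every time
        with pytest.raises((ProtocolError, DegenerateInputError)):
            run_replications(PlsrModelSpec(2), X, y, 5, base_seed=0)


class TestSummarize:
    def test_single_report_sd_zero(self):
        X, y = _linear_dataset()
        reports = run_replications(PlsrModelSpec(3), X, y, 1, base_seed=0)
        stats = summarize(reports)
        assert stats.sd["rmse"] == 0.0
        assert stats.best == reports[0].metrics

    def test_mean_and_best_bookkeeping(self):
        X, y = _linear_dataset(noise=0.3)
        reports = run_replications(PlsrModelSpec(3), X, y, 10, base_seed=0)
        stats = summarize(reports)
        rmses = np.array([r.metrics.rmse for r in reports])
        assert stats.mean["rmse"] == pytest.approx(rmses.mean(), rel=1e-12)
        assert stats.sd["rmse"] == pytest.approx(rmses.std(ddof=1), rel=1e-12)
        assert stats.best.rmse == pytest.approx(rmses.min(), rel=1e-12)
        assert stats.best.rmse <= stats.mean["rmse"]

    def test_frame_recomputes_summary(self):
        """Persisted per-replication table reproduces the summary (audit)."""
        X, y = _linear_dataset(noise=0.2)
        reports = run_replications(PlsrModelSpec(3), X, y, 8, base_seed=3)
        stats = summarize(reports)
        frame = reports_to_frame(reports)
        for name in ("r", "r2", "mse", "rmse", "mae"):
            assert frame[name].mean() == pytest.approx(stats.mean[name], rel=1e-12)
            assert frame[name].std(ddof=1) == pytest.approx(stats.sd[name], rel=1e-12)


class TestAggregate:
    def test_single_replication_equals_test_predictions(self):
        X, y = _linear_dataset()
        reports = run_replications(PlsrModelSpec(3), X, y, 40, base_seed=0)
        single = reports[:1]
        try:
            aggregate_mean_predictions(single, y)
        except CoverageError as exc:
            assert "never" in str(exc)
        mean_pred, r = aggregate_mean_predictions(reports, y)
        assert mean_pred.shape == y.shape
        assert -1.0 <= r <= 1.0

    def test_perfect_predictions_aggregate_to_r_one(self):
        X, y = _linear_dataset(noise=0.0)
        reports = run_replications(PlsrModelSpec(3), X, y, 30, base_seed=1)
        mean_pred, r = aggregate_mean_predictions(reports, y)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_aggregation_typically_improves_r(self, default_bundle):
        """Averaging test predictions over replications usually raises R."""
        _, pre, chem, truth = default_bundle
        X, y, _ = nt.join_chemistry(pre, chem, "ta")
        Xp = X[:, truth.informative_channels["ta"]]
        reports = run_replications(PlsrModelSpec(3), Xp, y, 30, base_seed=2)
        _, agg_r = aggregate_mean_predictions(reports, y)
        mean_r = np.mean([r.metrics.r for r in reports])
        assert agg_r >= mean_r - 0.01
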
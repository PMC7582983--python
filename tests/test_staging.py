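import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bcgsleep.features import FeatureVector
from bcgsleep.staging import (
    STAGES,
    ConfusionMatrix,
    Hypnogram,
    SleepStageModel,
    StageParams,
    accuracy,
    classify_epoch,
    fit_params,
    load_reference_confusion_matrix,
    load_reference_params,
    merge_light_sleep,
    stage_probability,
)


def _zero_params():
    return StageParams({s: np.zeros(5) for s in STAGES})


class TestStageProbability:
    def test_reference_wake_row_at_zero_features(self, reference_params):
        # intercept -2.84 alone: 1 / (1 + e^2.84)
        p = stage_probability(np.zeros(4), reference_params, "WAKE")
        assert p == pytest.approx(1.0 / (1.0 + np.exp(2.84)))
        assert p == pytest.approx(0.0552, abs=2e-4)

    def test_zero_coefficients_give_half(self, rng):
        params = _zero_params()
        for _ in range(5):
            x = rng.normal(size=4)
            for s in STAGES:
                assert stage_probability(x, params, s) == 0.5

    def test_monotone_in_positive_coefficient(self, reference_params):
        # WAKE has C > 0 on rr_std
        base = np.zeros(4)
        probs = []
        for v in np.linspace(0, 3, 7):
            x = base.copy()
            x[1] = v
            probs.append(stage_probability(x, reference_params, "WAKE"))
        assert np.all(np.diff(probs) > 0)

    def test_probabilities_do_not_normalize(self, reference_params, rng):
        x = rng.normal(size=4)
        total = sum(stage_probability(x, reference_params, s) for s in STAGES)
        assert not np.isclose(total, 1.0, atol=1e-3)
        for s in STAGES:
            assert 0.0 < stage_probability(x, reference_params, s) < 1.0

    def test_nonfinite_features_rejected(self, reference_params):
        with pytest.raises(ValueError):
            stage_probability(np.array([1.0, np.inf, 0.0, 0.0]), reference_params, "WAKE")

    def test_accepts_feature_vector(self, reference_params):
        fv = FeatureVector(1, 1.0, 0.1, 0.01, 0.5, 0.25, 2.0)
        assert 0 < stage_probability(fv, reference_params, "REM") < 1


class TestClassifyEpoch:
    def test_argmax_matches_explicit_comparison(self, reference_params, rng):
        for _ in range(20):
            x = rng.normal(size=4)
            probs = [stage_probability(x, reference_params, s) for s in STAGES]
            assert classify_epoch(x, reference_params) == STAGES[int(np.argmax(probs))]

    def test_tie_breaks_to_stage_order(self):
        assert classify_epoch(np.zeros(4), _zero_params()) == "WAKE"

    def test_high_rr_mean_is_n2_under_reference(self, reference_params):
        # N2 is the only stage with a large positive weight on mean RR
        assert classify_epoch(np.array([4.0, 0.0, 0.0, 0.0]), reference_params) == "N2"


class TestFitParams:
    def test_loss_decreases_on_separable_toy_set(self):
        X = np.array([[1.0, 0, 0, 0], [-1.0, 0, 0, 0]] * 10)
        y = ["N2", "WAKE"] * 10

        def loss(params):
            eps = 1e-12
            total = 0.0
            for xi, yi in zip(X, y):
                p = stage_probability(xi, params, "N2")
                t = 1.0 if yi == "N2" else 0.0
                total -= t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)
            return total

        losses = [loss(fit_params(X, y, n_iterations=n)) for n in (10, 100, 1000)]
        assert losses[0] > losses[1] > losses[2]

    def test_intercept_only_recovers_class_log_odds(self):
        X = np.zeros((100, 4))
        y = ["WAKE"] * 25 + ["N2"] * 75
        params = fit_params(X, y, n_iterations=20000)
        # all-zero features: slopes stay 0, intercept -> log(p/(1-p))
        np.testing.assert_allclose(params.coefficients["WAKE"][1:], 0.0, atol=1e-9)
        assert params.coefficients["WAKE"][0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-3)
        assert params.coefficients["N2"][0] == pytest.approx(np.log(0.75 / 0.25), abs=1e-3)

    def test_absent_stage_flagged_degenerate(self):
        X = np.random.default_rng(0).normal(size=(40, 4))
        y = ["WAKE"] * 20 + ["N2"] * 20
        params = fit_params(X, y, n_iterations=50)
        assert {"REM", "N1", "N3"} <= set(params.degenerate_stages)

    def test_recovers_known_coefficients(self, reference_params, rng):
        """Binary membership drawn from a stage's own logistic must be
        recovered by the one-vs-rest fit to within sampling error."""
        s = "REM"
        c = reference_params.coefficients[s]
        X = rng.standard_normal((5000, 4))
        p = 1.0 / (1.0 + np.exp(-(c[0] + X @ c[1:])))
        member = rng.random(5000) < p
        others = [o for o in STAGES if o != s]
        labels = [s if m else others[i % 4] for i, m in enumerate(member)]
        fitted = fit_params(X, labels)
        assert np.max(np.abs(fitted.coefficients[s] - c)) <= 0.15

    def test_sign_recovery_across_replicates(self, reference_params):
        """Coefficient signs of magnitude >= 0.3 recovered in >= 95% of
        seeded replicates (reduced iteration budget; signs converge long
        before magnitudes)."""
        results = []
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            s = STAGES[rep % 5]
            c = reference_params.coefficients[s]
            X = rng.standard_normal((5000, 4))
            p = 1.0 / (1.0 + np.exp(-(c[0] + X @ c[1:])))
            member = rng.random(5000) < p
            others = [o for o in STAGES if o != s]
            labels = [s if m else others[i % 4] for i, m in enumerate(member)]
            fitted = fit_params(X, labels, n_iterations=800)
            big = np.abs(c) >= 0.3
            results.append(
                bool(np.all(np.sign(fitted.coefficients[s][big]) == np.sign(c[big])))
            )
        assert np.mean(results) >= 0.95


class TestModelResults:
    def _dataset(self, reference_params, rng, n=300, noise=0.5):
        from bcgsleep.simulate import simulate_sleep_night

        return simulate_sleep_night(
            reference_params, n_epochs=n, noise_sd=noise, seed=int(rng.integers(2**31))
        )

    def test_fit_predict_round_trip(self, reference_params, rng):
        feats, hyp = self._dataset(reference_params, rng)
        model = SleepStageModel(feats, hyp)
        res = model.fit(n_iterations=1500)
        assert res.training_accuracy > 0.9
        assert set(res.predict(feats)) <= set(STAGES)

    def test_summary_lists_all_stages(self, reference_params, rng):
        feats, hyp = self._dataset(reference_params, rng, n=100)
        res = SleepStageModel(feats, hyp).fit(n_iterations=200)
        text = res.summary()
        for s in STAGES:
            assert s in text

    def test_from_dataframe_constructor(self, reference_params, rng):
        feats, hyp = self._dataset(reference_params, rng, n=80)
        feats = feats.copy()
        feats["stage"] = list(hyp.stages)
        model = SleepStageModel.from_dataframe(feats)
        assert model.nobs == 80


class TestLoso:
    def test_identical_separable_subjects_are_perfect(self, reference_params):
        from bcgsleep.simulate import simulate_sleep_night
        from bcgsleep.staging import loso_evaluate

        feats, hyp = simulate_sleep_night(reference_params, n_epochs=150, noise_sd=0.2, seed=9)
        dataset = {"a": (feats, hyp), "b": (feats, hyp)}
        cm, acc5, acc4 = loso_evaluate(dataset, n_iterations=1500)
        assert acc5 == 1.0 and acc4 == 1.0

    def test_row_totals_equal_per_stage_counts(self, reference_params):
        from bcgsleep.simulate import simulate_sleep_night
        from bcgsleep.staging import loso_evaluate

        dataset = {
            f"s{i}": simulate_sleep_night(reference_params, n_epochs=120, seed=20 + i)
            for i in range(3)
        }
        cm, acc5, _ = loso_evaluate(dataset, n_iterations=800)
        expected = {s: 0 for s in STAGES}
        for feats, hyp in dataset.values():
            for s in hyp.stages:
                expected[s] += 1
        np.testing.assert_array_equal(cm.row_totals, [expected[s] for s in STAGES])
        # synthetic cohort is far above the majority-class baseline
        baseline = max(expected.values()) / cm.total
        assert acc5 > baseline

    def test_requires_two_subjects(self, reference_params):
        from bcgsleep.simulate import simulate_sleep_night
        from bcgsleep.staging import loso_evaluate

        feats, hyp = simulate_sleep_night(reference_params, n_epochs=50, seed=1)
        with pytest.raises(ValueError):
            loso_evaluate({"only": (feats, hyp)})


class TestConfusionMatrix:
    def test_reference_matrix_row_totals(self):
        cm = load_reference_confusion_matrix()
        assert cm.labels == STAGES
        np.testing.assert_array_equal(cm.row_totals, [221, 342, 153, 899, 242])
        assert cm.total == 1857

    def test_reader_rejects_inconsistent_epoch_counts(self, tmp_path):
        p = tmp_path / "cm.csv"
        p.write_text(",WAKE,REM,N1,N2,N3,Epoch Count\nWAKE,1,0,0,0,0,5\n"
                     "REM,0,1,0,0,0,1\nN1,0,0,1,0,0,1\nN2,0,0,0,1,0,1\nN3,0,0,0,0,1,1\n")
        with pytest.raises(ValueError, match="Epoch Count"):
            ConfusionMatrix.read_csv(p)

    def test_round_trip(self, tmp_path, rng):
        cm = ConfusionMatrix(rng.integers(0, 50, size=(5, 5)))
        path = tmp_path / "cm.csv"
        cm.write_csv(path)
        back = ConfusionMatrix.read_csv(path)
        np.testing.assert_array_equal(back.counts, cm.counts)

    def test_accuracy_trace_over_total(self):
        cm = load_reference_confusion_matrix()
        assert accuracy(cm) == pytest.approx((153 + 292 + 102 + 857 + 213) / 1857)

    def test_identity_matrix_accuracy_one(self):
        cm = ConfusionMatrix(np.diag([5, 4, 3, 2, 1]))
        assert accuracy(cm) == 1.0

    def test_accuracy_ignores_offdiagonal_placement(self, rng):
        base = np.diag([10, 10, 10, 10, 10])
        a, b = base.copy(), base.copy()
        a[0, 1] = 7
        b[3, 4] = 7
        assert accuracy(ConfusionMatrix(a)) == accuracy(ConfusionMatrix(b))


class TestMergeLightSleep:
    def test_reference_matrix_merge(self):
        merged = merge_light_sleep(load_reference_confusion_matrix())
        assert merged.labels == ("WAKE", "REM", "LIGHT", "N3")
        light_row = merged.counts[merged.labels.index("LIGHT")]
        assert light_row.sum() == 153 + 899
        assert merged.total == 1857

    def test_merged_trace_gains_cross_terms(self):
        cm = load_reference_confusion_matrix()
        merged = merge_light_sleep(cm)
        i1, i2 = cm.labels.index("N1"), cm.labels.index("N2")
        assert np.trace(merged.counts) == (
            np.trace(cm.counts) + cm.counts[i1, i2] + cm.counts[i2, i1]
        )

    def test_zero_matrix(self):
        merged = merge_light_sleep(ConfusionMatrix(np.zeros((5, 5), dtype=int)))
        assert merged.total == 0

    def test_double_merge_rejected(self):
        merged = merge_light_sleep(load_reference_confusion_matrix())
        with pytest.raises(ValueError):
            merge_light_sleep(merged)

    @given(
        arrays(np.int64, (5, 5), elements=st.integers(0, 1000))
    )
    @settings(max_examples=50)
    def test_total_conserved_on_random_matrices(self, counts):
        cm = ConfusionMatrix(counts)
        assert merge_light_sleep(cm).total == cm.total


def test_hypnogram_round_trip(tmp_path):
    hyp = Hypnogram(stages=["WAKE", "N1", "N2", "N2", "REM", "N3"])
    p = tmp_path / "hyp.tsv"
    hyp.write_tsv(p)
    back = Hypnogram.read_tsv(p)
    assert back.stages == hyp.stages
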
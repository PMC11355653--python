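import numpy as np
import pytest

from pessaryfit import (
    CVConfig,
    FITTING,
    NON_FITTING,
    UNKNOWN,
    accuracy_sweep,
    best_k,
    build_design_matrix,
    classify_response,
    default_effect_profile,
    fit_pls,
    generate_cohort,
    leave_one_out_cv,
    leave_two_out_cv,
    predict,
    select_top_k,
    vip_scores,
)
from pessaryfit.crossval import LEAVE_ONE_OUT, LEAVE_TWO_OUT


class TestClassify:
    @pytest.mark.parametrize(
        "yhat,expected",
        [
            (0.5, FITTING),
            (-0.3, NON_FITTING),
            (0.1, UNKNOWN),
            (-0.1, UNKNOWN),
            (0.0, UNKNOWN),
            (0.10000001, FITTING),
        ],
    )
    def test_trichotomous_thresholds(self, yhat, expected):
        assert classify_response(yhat) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_response(float("nan"))


class TestSelectTopK:
    def test_first_k_of_ranking(self, complete_cohort):
        design = build_design_matrix(complete_cohort)
        vip = vip_scores(fit_pls(design, 2))
        assert select_top_k(vip, 2) == vip.ranking[:2]
        assert select_top_k(vip, len(vip.ranking)) == vip.ranking
        with pytest.raises(ValueError):
            select_top_k(vip, 0)
        with pytest.raises(ValueError):
            select_top_k(vip, len(vip.ranking) + 1)


@pytest.fixture(scope="module")
def signal_cohort():
    profile = default_effect_profile(standardized_effect=3.0, missing_rate=0.0)
    return generate_cohort(9, 6, profile, seed=3), sorted(profile.informative_keys)


class TestLeaveOneOut:
    def test_one_prediction_per_participant(self, signal_cohort):
        cohort, selected = signal_cohort
        report = leave_one_out_cv(cohort, selected)
        assert report.tallies["n_total"] == cohort.n
        assert len(report.predictions) == cohort.n
        predicted = [r.predicted_participant for r in report.predictions]
        assert sorted(predicted) == sorted(cohort.participant_ids)
        assert report.heatmap.shape == (cohort.n,)

    def test_partition_identity(self, signal_cohort):
        cohort, selected = signal_cohort
        t = leave_one_out_cv(cohort, selected).tallies
        assert t["n_correct"] + t["n_incorrect"] + t["n_unknown"] == t["n_total"]

    def test_matches_naive_fold_loop(self, signal_cohort):
        """Global-mode LOO must equal an independently coded fold loop bit-for-bit."""
        cohort, selected = signal_cohort
        report = leave_one_out_cv(cohort, selected, n_components=2)
        design = build_design_matrix(cohort, selected)
        by_id = {r.predicted_participant: r for r in report.predictions}
        for i, pid in enumerate(cohort.participant_ids):
            train = [j for j in range(cohort.n) if j != i]
            from conftest import make_design

            model = fit_pls(make_design(design.X[train], design.y[train]), 2)
            yhat = predict(model, design.X[[i]])[0]
            assert by_id[pid].continuous_response == yhat  # bit-for-bit

    def test_single_class_training_fold_rejected(self, signal_cohort):
        cohort, selected = signal_cohort
        tiny = cohort.subset_rows([0, 1, 2, 9])  # 3 fitting + 1 non-fitting
        with pytest.raises(ValueError, match="single outcome class"):
            leave_one_out_cv(tiny, selected)

    def test_strong_signal_accuracy(self):
        profile = default_effect_profile(standardized_effect=3.0)
        selected = sorted(profile.informative_keys)
        accs = []
        for seed in range(10):
            cohort = generate_cohort(50, 50, profile, seed=seed)
            accs.append(leave_one_out_cv(cohort, selected).accuracy_fraction)
        assert min(accs) >= 0.9

    def test_chance_level_at_null_effect(self):
        profile = default_effect_profile(standardized_effect=0.0)
        selected = sorted(profile.informative_keys)
        accs = [
            leave_one_out_cv(generate_cohort(9, 6, profile, seed=s), selected).accuracy_fraction
            for s in range(20)
        ]
        assert 0.3 <= np.mean(accs) <= 0.7


class TestLeaveTwoOut:
    @pytest.mark.parametrize("n_fit,n_non", [(3, 2), (6, 4), (9, 6)])
    def test_count_identities(self, n_fit, n_non):
        profile = default_effect_profile(missing_rate=0.0)
        cohort = generate_cohort(n_fit, n_non, profile, seed=1)
        selected = sorted(profile.informative_keys)
        # at n=5 holding out both members of the smaller class leaves a
        # single-class training fold; the unknown policy keeps counts intact
        config = CVConfig(degenerate_folds="unknown")
        report = leave_two_out_cv(cohort, selected, config=config)
        n = cohort.n
        assert report.tallies["n_total"] == n * (n - 1)
        counts = {}
        for r in report.predictions:
            counts[r.predicted_participant] = counts.get(r.predicted_participant, 0) + 1
        assert set(counts.values()) == {n - 1}
        assert int((~np.isnan(report.heatmap)).sum()) == n * (n - 1)
        assert all(np.isnan(report.heatmap[i, i]) for i in range(n))
        t = report.tallies
        assert t["n_correct"] + t["n_incorrect"] + t["n_unknown"] == t["n_total"]

    def test_reported_percentages_round_to_one_decimal(self, signal_cohort):
        # the rounding convention on a known tally split: 158+44+8 = 210
        from pessaryfit.crossval import CVReport

        report = CVReport(
            scheme=LEAVE_TWO_OUT,
            k_variables=6,
            selected_keys=[],
            predictions=[],
            tallies={"n_correct": 158, "n_incorrect": 44, "n_unknown": 8, "n_total": 210},
            accuracy_fraction=158 / 210,
            heatmap=np.full((15, 15), np.nan),
            participant_ids=[],
        )
        assert report.percentages() == {
            "correct_pct": 75.2,
            "incorrect_pct": 21.0,
            "unknown_pct": 3.8,
        }

    def test_relabelling_participants_permutes_heatmap(self, signal_cohort):
        cohort, selected = signal_cohort
        perm = np.random.default_rng(0).permutation(cohort.n)
        shuffled = cohort.subset_rows(perm)
        r1 = leave_two_out_cv(cohort, selected, n_components=2)
        r2 = leave_two_out_cv(shuffled, selected, n_components=2)
        assert r1.tallies == r2.tallies
        np.testing.assert_array_equal(
            r1.heatmap[np.ix_(perm, perm)], r2.heatmap
        )

    def test_minimum_cohort_size(self, signal_cohort):
        cohort, selected = signal_cohort
        with pytest.raises(ValueError, match="at least 5"):
            leave_two_out_cv(cohort.subset_rows([0, 1, 8, 9]), selected)


class TestAccuracySweep:
    def test_grid_size_and_best_k(self, signal_cohort):
        cohort, _ = signal_cohort
        reports = accuracy_sweep(cohort)
        assert len(reports) == 20
        assert {s for _, s in reports} == {LEAVE_ONE_OUT, LEAVE_TWO_OUT}
        for scheme in (LEAVE_ONE_OUT, LEAVE_TWO_OUT):
            k = best_k(reports, scheme)
            assert 1 <= k <= 10
            acc = reports[(k, scheme)].accuracy_fraction
            assert all(
                acc >= reports[(kk, scheme)].accuracy_fraction for kk in range(1, 11)
            )

    def test_strong_signal_peak_reached_near_informative_count(self):
        """With six informative variables, peak accuracy is attained within k in {5,6,7}."""
        profile = default_effect_profile(standardized_effect=3.0)
        hits = 0
        for seed in range(10):
            cohort = generate_cohort(9, 6, profile, seed=seed)
            reports = accuracy_sweep(cohort, schemes=(LEAVE_ONE_OUT,))
            accs = {k: reports[(k, LEAVE_ONE_OUT)].accuracy_fraction for k in range(1, 11)}
            peak = max(accs.values())
            hits += any(abs(accs[k] - peak) < 1e-12 for k in (5, 6, 7))
        assert hits >= 8

    def test_nested_selection_mode_runs(self, signal_cohort):
        cohort, _ = signal_cohort
        config = CVConfig(selection="nested")
        report = leave_one_out_cv(cohort, config=config, k=4)
        assert report.tallies["n_total"] == cohort.n
        assert report.k_variables == 4

    def test_constant_predictors_error_or_unknown_per_config(self, complete_cohort):
        constant = complete_cohort.subset_rows(np.arange(complete_cohort.n))
        constant.measurements.loc[:, :] = 5.0
        selected = constant.variable_keys[:4]
        with pytest.raises(ValueError):
            leave_one_out_cv(constant, selected, n_components=1)
        report = leave_one_out_cv(
            constant,
            selected,
            n_components=1,
            config=CVConfig(degenerate_folds="unknown"),
        )
        assert report.tallies["n_unknown"] == report.tallies["n_total"]

    def test_fold_normalization_mode_runs(self, signal_cohort):
        cohort, selected = signal_cohort
        config = CVConfig(normalization="fold")
        report = leave_one_out_cv(cohort, selected, config=config)
        t = report.tallies
        assert t["n_correct"] + t["n_incorrect"] + t["n_unknown"] == t["n_total"]
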
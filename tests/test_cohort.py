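import math

import numpy as np
import pandas as pd
import pytest

from prlfit import (
    ExclusionConfig,
    ExclusionReason,
    Group,
    LogisticModel,
    Model,
    PAPER_FIXED_MODEL,
    QParams,
    REFERENCE_CUTOFF,
    SubjectRecord,
    WSLSParams,
    apply_exclusions,
    classify_behavior,
    fit_palpha_beta,
    logistic_model_comparison,
    palpha_beta,
    roc_analysis,
    sample_parameter_cohort,
    summarize_groups,
)
from prlfit.fitting import FitResult, StrategyLabel

from conftest import oracle_concordance_auc


def make_subject(
    subject_id,
    group,
    acq=45,
    rev=35,
    alpha=0.4,
    beta=4.0,
    best_model=Model.QLEARNING,
):
    """A SubjectRecord with a stubbed strategy label (no raw sequence needed)."""
    q = FitResult(
        model=Model.QLEARNING,
        params=QParams(alpha=alpha, beta=beta),
        loglik=-50.0,
        k=2,
        aic=104.0,
        n_valid_trials=120,
    )
    w = FitResult(
        model=Model.WSLS,
        params=WSLSParams(0.8, 0.8),
        loglik=-60.0,
        k=2,
        aic=124.0,
        n_valid_trials=120,
    )
    r = FitResult(
        model=Model.RANDOM, params=None, loglik=-83.2, k=0, aic=166.4, n_valid_trials=120
    )
    label = StrategyLabel(
        best_model=best_model,
        aic_q=q.aic,
        aic_wsls=w.aic,
        aic_random=r.aic,
        fits={Model.QLEARNING: q, Model.WSLS: w, Model.RANDOM: r},
    )
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        acquisition_score=acq,
        reversal_score=rev,
        total_score=acq + rev,
        strategy=label,
    )


class TestApplyExclusions:
    def test_acquisition_threshold_arithmetic(self):
        # controls with mean 40 put the cut at mean − 1.5·SD; a subject just
        # below is excluded, one at the threshold retained (strict inequality)
        controls = [
            make_subject(f"C{i}", Group.CONTROL, acq=v, rev=40) for i, v in enumerate([32, 48, 40, 40])
        ]
        arr = np.array([32, 48, 40, 40], float)
        thr = arr.mean() - 1.5 * arr.std(ddof=1)
        borderline_in = make_subject("A_in", Group.ALS, acq=math.ceil(thr), rev=40)
        just_out = make_subject("A_out", Group.ALS, acq=math.floor(thr) - 1, rev=40)
        out = apply_exclusions(controls + [borderline_in, just_out])
        by_id = {s.subject_id: s for s in out}
        assert by_id["A_in"].included
        assert by_id["A_out"].exclusion_reason is ExclusionReason.LOW_ACQUISITION

    def test_reversal_filter_touches_controls_only_by_default(self):
        controls = [make_subject(f"C{i}", Group.CONTROL, rev=40) for i in range(4)]
        low_rev_control = make_subject("C_low", Group.CONTROL, rev=5)
        low_rev_als = make_subject("A_low", Group.ALS, rev=5)
        out = apply_exclusions(controls + [low_rev_control, low_rev_als])
        by_id = {s.subject_id: s for s in out}
        assert by_id["C_low"].exclusion_reason is ExclusionReason.LOW_REVERSAL
        assert by_id["A_low"].included  # ALS reversal scores are not filtered

    def test_non_q_strategy_excluded(self):
        subjects = [make_subject(f"C{i}", Group.CONTROL) for i in range(4)]
        subjects.append(make_subject("W1", Group.ALS, best_model=Model.WSLS))
        subjects.append(make_subject("R1", Group.ALS, best_model=Model.RANDOM))
        out = apply_exclusions(subjects)
        by_id = {s.subject_id: s for s in out}
        assert by_id["W1"].exclusion_reason is ExclusionReason.NON_Q_STRATEGY
        assert by_id["R1"].exclusion_reason is ExclusionReason.NON_Q_STRATEGY

    def test_beta_outlier_filter_on_controls(self):
        controls = [make_subject(f"C{i}", Group.CONTROL, beta=3.5 + 0.03 * i) for i in range(30)]
        outlier = make_subject("C_hot", Group.CONTROL, beta=40.0)
        als_hot = make_subject("A_hot", Group.ALS, beta=40.0)
        out = apply_exclusions(controls + [outlier, als_hot])
        by_id = {s.subject_id: s for s in out}
        assert by_id["C_hot"].exclusion_reason is ExclusionReason.BETA_OUTLIER
        assert by_id["A_hot"].included  # high β is the ALS phenotype, not filtered

    def test_clean_cohort_passes_untouched(self):
        subjects = [make_subject(f"C{i}", Group.CONTROL) for i in range(4)] + [
            make_subject(f"A{i}", Group.ALS) for i in range(4)
        ]
        out = apply_exclusions(subjects)
        assert all(s.included for s in out)
        assert all(s.exclusion_reason is ExclusionReason.NONE for s in out)

    def test_idempotent(self):
        subjects = [make_subject(f"C{i}", Group.CONTROL, acq=40 + i) for i in range(5)] + [
            make_subject("A0", Group.ALS, best_model=Model.WSLS)
        ]
        once = apply_exclusions(subjects)
        twice = apply_exclusions(once)
        assert [(s.included, s.exclusion_reason) for s in once] == [
            (s.included, s.exclusion_reason) for s in twice
        ]

    def test_requires_two_controls(self):
        with pytest.raises(ValueError, match="control"):
            apply_exclusions([make_subject("A0", Group.ALS)])


class TestPalphaBeta:
    def test_published_coefficients_at_group_means(self):
        # independent arithmetic: 1/(1+e^{0.742+1.263·0.4−0.245·4.0}) etc.
        assert palpha_beta(PAPER_FIXED_MODEL, 0.4, 4.0) == pytest.approx(0.4336, abs=1e-4)
        assert palpha_beta(PAPER_FIXED_MODEL, 0.3, 7.0) == pytest.approx(0.6443, abs=1e-4)

    def test_logistic_midpoint(self):
        beta_mid = 0.742 / 0.245
        assert palpha_beta(PAPER_FIXED_MODEL, 0.0, beta_mid) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_alpha_and_beta(self):
        alphas = np.linspace(0, 1, 11)
        betas = np.linspace(0, 20, 11)
        p_alpha = [palpha_beta(PAPER_FIXED_MODEL, a, 5.0) for a in alphas]
        p_beta = [palpha_beta(PAPER_FIXED_MODEL, 0.4, b) for b in betas]
        assert all(np.diff(p_alpha) < 0)  # higher α → less case-like
        assert all(np.diff(p_beta) > 0)  # higher β → more case-like

    def test_cutoff_sits_between_group_means(self):
        lo = palpha_beta(PAPER_FIXED_MODEL, 0.4, 4.0)
        hi = palpha_beta(PAPER_FIXED_MODEL, 0.3, 7.0)
        assert lo < REFERENCE_CUTOFF < hi

    def test_printed_form_serialization(self):
        s = PAPER_FIXED_MODEL.printed_form()
        assert "+0.742" in s and "+1.263" in s and "-0.245" in s


class TestFitPalphaBeta:
    def test_coefficient_recovery_from_generating_model(self):
        rng = np.random.default_rng(0)
        df = sample_parameter_cohort(PAPER_FIXED_MODEL, 1000, rng)
        subjects = [
            make_subject(
                f"S{i}",
                Group.ALS if c else Group.CONTROL,
                alpha=a,
                beta=b,
            )
            for i, (a, b, c) in enumerate(df.itertuples(index=False))
        ]
        model = fit_palpha_beta(subjects)
        gen = (PAPER_FIXED_MODEL.intercept, PAPER_FIXED_MODEL.coef_alpha, PAPER_FIXED_MODEL.coef_beta)
        est = (model.intercept, model.coef_alpha, model.coef_beta)
        for g, e, se in zip(gen, est, model.se):
            assert abs(g - e) <= 2 * se

    def test_no_signal_gives_null_coefficients(self):
        rng = np.random.default_rng(1)
        subjects = [
            make_subject(
                f"S{i}",
                Group.ALS if i % 2 else Group.CONTROL,
                alpha=float(rng.uniform(0, 1)),
                beta=float(rng.uniform(0, 10)),
            )
            for i in range(400)
        ]
        model = fit_palpha_beta(subjects)
        assert abs(model.coef_alpha) <= 2.5 * model.se[1]
        assert abs(model.coef_beta) <= 2.5 * model.se[2]
        table = logistic_model_comparison(subjects)
        null_ll = len(subjects) * math.log(0.5)
        assert table.loc["alpha_and_beta", "aic"] == pytest.approx(
            -2 * null_ll + 6, rel=0.05
        )

    def test_perfect_separation_flagged(self):
        subjects = [
            make_subject(f"C{i}", Group.CONTROL, alpha=0.8, beta=2.0 + 0.01 * i)
            for i in range(20)
        ] + [
            make_subject(f"A{i}", Group.ALS, alpha=0.1, beta=15.0 + 0.01 * i)
            for i in range(20)
        ]
        model = fit_palpha_beta(subjects)
        assert model.separation

    def test_single_group_rejected(self):
        subjects = [make_subject(f"C{i}", Group.CONTROL) for i in range(10)]
        with pytest.raises(ValueError, match="both groups"):
            fit_palpha_beta(subjects)


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.sensitivity_at_cutoff == 1.0
        assert res.specificity_at_cutoff == 1.0
        assert 0.2 <= res.optimal_cutoff < 0.8

    def test_all_tied_scores_give_half(self):
        res = roc_analysis([0.5] * 10, [1, 0] * 5)
        assert res.auc == pytest.approx(0.5)

    def test_auc_equals_pairwise_concordance(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            res = roc_analysis(scores, labels)
            assert res.auc == pytest.approx(
                oracle_concordance_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([0.1, 0.9], [1, 1])

    def test_tie_in_youden_takes_lowest_cutoff(self):
        # two cutoffs achieve J=1 here; the lower must be returned
        res = roc_analysis([0.1, 0.4, 0.7, 0.9], [0, 0, 1, 1])
        assert res.optimal_cutoff == pytest.approx(0.4)


class TestClassifyBehavior:
    def test_group_mean_parameters_split_at_published_cutoff(self):
        p_als = palpha_beta(PAPER_FIXED_MODEL, 0.3, 7.0)
        p_ctrl = palpha_beta(PAPER_FIXED_MODEL, 0.4, 4.0)
        assert classify_behavior([p_als, p_ctrl], REFERENCE_CUTOFF) == [
            "anomalous",
            "typical",
        ]

    def test_boundary_is_typical(self):
        assert classify_behavior([REFERENCE_CUTOFF], REFERENCE_CUTOFF) == ["typical"]

    def test_cutoff_range_validated(self):
        with pytest.raises(ValueError):
            classify_behavior([0.5], 1.5)


class TestModelComparison:
    def test_beta_only_wins_when_only_beta_differs(self):
        rng = np.random.default_rng(3)
        subjects = []
        for i in range(150):
            subjects.append(
                make_subject(
                    f"C{i}", Group.CONTROL, alpha=float(rng.uniform(0.2, 0.6)), beta=float(rng.uniform(2, 6))
                )
            )
            subjects.append(
                make_subject(
                    f"A{i}", Group.ALS, alpha=float(rng.uniform(0.2, 0.6)), beta=float(rng.uniform(5, 9))
                )
            )
        table = logistic_model_comparison(subjects)
        assert table.loc["beta_only", "aic"] < table.loc["alpha_only", "aic"]

    def test_full_model_loglik_dominates_nested(self):
        rng = np.random.default_rng(4)
        df = sample_parameter_cohort(PAPER_FIXED_MODEL, 300, rng)
        subjects = [
            make_subject(
                f"S{i}", Group.ALS if c else Group.CONTROL, alpha=a, beta=b
            )
            for i, (a, b, c) in enumerate(df.itertuples(index=False))
        ]
        table = logistic_model_comparison(subjects)
        full_ll = table.loc["alpha_and_beta", "loglik"]
        assert full_ll >= table.loc["alpha_only", "loglik"] - 1e-9
        assert full_ll >= table.loc["beta_only", "loglik"] - 1e-9
        assert (table["aic"] == (-2 * table["loglik"] + 2 * table["k"])).all()


class TestSummarizeGroups:
    def test_identical_groups_not_significant(self):
        df = pd.DataFrame(
            {
                "group": ["control"] * 20 + ["ALS"] * 20,
                "score": list(range(20)) * 2,
            }
        )
        out = summarize_groups(df, ["score"])
        assert out.loc["score", "p_value"] > 0.9

    def test_separated_normals_highly_significant(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "group": ["control"] * 50 + ["ALS"] * 50,
                "x": np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)]),
            }
        )
        out = summarize_groups(df, ["x"])
        assert out.loc["x", "p_value"] < 0.001
        assert bool(out.loc["x", "significant"])

    def test_balanced_contingency_table_has_zero_statistic(self):
        df = pd.DataFrame(
            {
                "group": ["control"] * 60 + ["ALS"] * 60,
                "sex": (["m"] * 30 + ["f"] * 30) * 2,
            }
        )
        out = summarize_groups(df, ["sex"], categorical=["sex"])
        assert out.loc["sex", "statistic"] == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"group": ["control"] * 5, "x": range(5)})
        with pytest.raises(ValueError):
            summarize_groups(df, ["x"])
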
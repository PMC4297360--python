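"""Experiment-level stages: screening, reports, complaint thresholds."""

import json

import numpy as np
import pytest

from ranksat import (
    AnalysisConfig,
    ComplaintRecord,
    ExclusionError,
    ParticipantRatings,
    complaint_threshold,
    exp3_context,
    frequency_value,
    qc_exp1,
    run_exp1,
    run_exp2,
    run_exp3,
)
from ranksat.pipelines import write_report, report_markdown
from ranksat.synthetic_data import SimulationConfig, gen_exp1, gen_exp2, gen_exp3


def _ratings(stimuli, responses, domain="feedback_time"):
    return ParticipantRatings("p1", "unimodal", domain,
                              tuple(map(float, stimuli)), tuple(responses))


class TestQCExp1:
    def test_monotone_full_range_rater_kept(self):
        stim = [9, 23, 27, 30, 33, 36, 39, 42, 45, 49, 63]
        resp = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 5]
        assert qc_exp1(_ratings(stim, resp)).keep

    def test_constant_responses_excluded_for_range(self):
        decision = qc_exp1(_ratings([9, 23, 27, 30, 33], [3] * 5))
        assert not decision.keep
        assert decision.reason == "range"

    def test_narrow_range_excluded_even_if_monotone(self):
        decision = qc_exp1(_ratings([9, 23, 27, 30, 33], [1, 1, 2, 3, 3]))
        assert not decision.keep
        assert decision.reason == "range"

    def test_weak_association_excluded_for_tau(self):
        # responses span the scale but track the stimuli only loosely
        stim = [9, 23, 27, 30, 33, 36, 39, 42, 45, 49, 63]
        resp = [1, 5, 2, 4, 1, 3, 5, 2, 4, 5, 3]
        from ranksat import kendall_tau
        assert abs(kendall_tau(stim, resp)) < 0.5  # sanity: oracle agrees
        decision = qc_exp1(_ratings(stim, resp))
        assert not decision.keep
        assert decision.reason == "tau"

    def test_wrong_sign_excluded_for_higher_is_better_domain(self):
        # dissatisfaction must FALL with interestingness; a rising pattern
        # is inappropriately signed
        stim = [9, 23, 27, 30, 33, 36, 39, 42, 45, 49, 63]
        resp = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 5]
        decision = qc_exp1(_ratings(stim, resp, domain="interestingness"))
        assert not decision.keep
        assert decision.reason == "tau"


@pytest.fixture(scope="module")
def crossover_report():
    cfg = SimulationConfig(seed=12, n_exp1=6, w=0.3, s=0.4)
    df = gen_exp1(cfg, conditions=("unimodal", "bimodal"))
    return run_exp1(df, AnalysisConfig(seed=12, n_restarts=4))


class TestRunExp1:
    def test_critical_point_crossover(self, crossover_report):
        """23 draws less dissatisfaction where it ranks 2nd (unimodal) than
        5th (bimodal); 49 reverses (rank 10 vs 7)."""
        uni = crossover_report["conditions"]["unimodal/feedback_time"]
        bi = crossover_report["conditions"]["bimodal/feedback_time"]
        assert uni["critical_point_means"]["23.0"] < bi["critical_point_means"]["23.0"]
        assert uni["critical_point_means"]["49.0"] > bi["critical_point_means"]["49.0"]

    def test_report_accounts_for_every_participant(self, crossover_report):
        for key, cond in crossover_report["conditions"].items():
            excl = crossover_report["exclusions"][key]
            assert cond["n_retained"] + excl["n_excluded"] == 6

    def test_lr_tests_present_and_valid(self, crossover_report):
        for cond in crossover_report["conditions"].values():
            for test in (cond["effect_of_rank"], cond["effect_of_range"]):
                assert test["chi2"] >= 0
                assert test["df"] == cond["n_fitted"]
                assert 0 <= test["p"] <= 1

    def test_single_participant_condition_rejected(self):
        cfg = SimulationConfig(seed=1, n_exp1=1)
        df = gen_exp1(cfg, conditions=("unimodal",))
        with pytest.raises(ValueError):
            run_exp1(df, AnalysisConfig(n_restarts=2))

    def test_report_is_json_serializable(self, crossover_report):
        json.dumps(crossover_report)


class TestRunExp2:
    def test_rank_only_generative_model_recovered(self):
        df = gen_exp2(SimulationConfig(seed=20_000))
        rep = run_exp2(df)["feedback_time"]
        c = rep["regression_1"]["coefficients"]
        assert c["subjective_rank"]["p"] < 0.05
        assert c["subjective_rank"]["coef"] > 0
        assert c["own_value"]["p"] >= 0.05
        assert 0 <= rep["regression_2"]["nagelkerke_r2"] <= 1

    def test_own_value_only_generative_model_contrast(self):
        """With satisfaction driven by the own value instead of its rank, the
        own-value coefficient is the significant one."""
        cfg = SimulationConfig(seed=77, rank_coef=0.0, own_coef=0.15)
        df = gen_exp2(cfg)
        c = run_exp2(df)["feedback_time"]["regression_1"]["coefficients"]
        assert c["own_value"]["p"] < 0.05
        assert c["subjective_rank"]["p"] >= 0.05

    def test_exclusion_counts_reported(self):
        df = gen_exp2(SimulationConfig(seed=8, probe_noise=0.08))
        rep = run_exp2(df)["feedback_time"]
        assert rep["n_retained"] + rep["n_excluded"] == 170
        assert sum(rep["exclusion_reasons"].values()) == rep["n_excluded"]

    def test_all_excluded_rejected(self):
        df = gen_exp2(SimulationConfig(seed=1, n_exp2=25))
        for k in (90, 80, 70, 60, 50):
            df[f"p{k}"] = np.nan
        with pytest.raises((ValueError, ExclusionError)):
            run_exp2(df)


@pytest.fixture(scope="module")
def pos_ctx():
    return exp3_context("pos_skew")


class TestComplaintThreshold:
    def _record(self, values, complain):
        return ComplaintRecord("p1", "pos_skew", "feedback_time",
                               tuple(map(float, values)), tuple(complain))

    def test_never_complains_excluded(self, pos_ctx):
        values = pos_ctx.values
        with pytest.raises(ExclusionError) as err:
            complaint_threshold(self._record(values, [False] * 11), pos_ctx)
        assert err.value.reason == "never_complain"

    def test_always_complains_excluded(self, pos_ctx):
        with pytest.raises(ExclusionError) as err:
            complaint_threshold(self._record(pos_ctx.values, [True] * 11), pos_ctx)
        assert err.value.reason == "all_complain"

    def test_midpoint_between_36_and_46_days(self, pos_ctx):
        # tolerates up to 36 days, complains from 46 on
        complain = [v >= 46 for v in pos_ctx.values]
        res = complaint_threshold(self._record(pos_ctx.values, complain), pos_ctx)
        assert res.threshold == pytest.approx(41.0)
        assert res.threshold_rank == pytest.approx(frequency_value(46, pos_ctx))

    def test_first_value_convention(self, pos_ctx):
        complain = [v >= 46 for v in pos_ctx.values]
        res = complaint_threshold(self._record(pos_ctx.values, complain),
                                  pos_ctx, convention="first")
        assert res.threshold == pytest.approx(46.0)

    def test_complaint_at_better_provision_excluded(self, pos_ctx):
        complain = [v == 10 or v >= 46 for v in pos_ctx.values]
        with pytest.raises(ExclusionError) as err:
            complaint_threshold(self._record(pos_ctx.values, complain), pos_ctx)
        assert err.value.reason == "non_monotone"

    def test_higher_is_better_domain_sorts_from_best(self):
        ctx = exp3_context("pos_skew", "interestingness")
        # complains when interestingness drops below 20%
        complain = [v < 20 for v in ctx.values]
        res = complaint_threshold(
            ComplaintRecord("p", "pos_skew", "interestingness",
                            ctx.values, tuple(complain)),
            ctx,
        )
        assert res.threshold == pytest.approx((20 + 17) / 2)


class TestRunExp3:
    def test_pure_rank_rule_shifts_thresholds_with_skew(self):
        df = gen_exp3(SimulationConfig(seed=5, mixing=1.0))
        rep = run_exp3(df)
        neg = rep["conditions"]["neg_skew/feedback_time"]["mean_threshold"]
        pos = rep["conditions"]["pos_skew/feedback_time"]["mean_threshold"]
        assert neg > pos

    def test_pure_absolute_rule_gives_matched_thresholds(self):
        df = gen_exp3(SimulationConfig(seed=5, mixing=0.0))
        rep = run_exp3(df)
        assert abs(rep["skew_comparison"]["feedback_time"]["cohens_d"]) < 0.5

    def test_mixed_rule_raises_rank_in_positive_skew(self):
        """An absolute component makes the rank of the complained-at level
        higher under positive skew."""
        df = gen_exp3(SimulationConfig(seed=5))  # default mixing 0.7
        rep = run_exp3(df)
        pos = rep["conditions"]["pos_skew/feedback_time"]["mean_threshold_rank"]
        neg = rep["conditions"]["neg_skew/feedback_time"]["mean_threshold_rank"]
        assert pos > neg

    def test_exclusions_counted_per_reason(self):
        df = gen_exp3(SimulationConfig(seed=5, complaint_sd=0.4))
        rep = run_exp3(df)
        for cond in rep["conditions"].values():
            assert sum(cond["exclusion_reasons"].values()) == cond["n_excluded"]


class TestDeterminismAndIO:
    def test_end_to_end_reports_are_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=99)
        texts = []
        for run in range(2):
            df = gen_exp3(cfg)
            rep = run_exp3(df, AnalysisConfig(seed=99))
            out = tmp_path / f"rep{run}.json"
            write_report(rep, out)
            texts.append(out.read_bytes())
        assert texts[0] == texts[1]

    def test_markdown_summary_contains_tables(self):
        cfg = SimulationConfig(seed=12, n_exp1=4, s=0.4)
        df = gen_exp1(cfg, conditions=("unimodal",))
        rep = run_exp1(df, AnalysisConfig(seed=12, n_restarts=2))
        md = report_markdown(rep, "Experiment 1 report")
        assert "mean dissatisfaction per stimulus" in md
        assert "| 23.0 |" in md
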
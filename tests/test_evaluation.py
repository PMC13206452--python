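import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pbpkddi.evaluation import (
    DDI_BENCHMARK,
    EvaluationError,
    afe,
    benchmark_ddi_ratios,
    ddi_ratio,
    evaluate_pairs,
    fold_classification,
    gmfe,
    mrd,
    rmse,
)


class TestMrd:
    def test_perfect_prediction(self):
        assert mrd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_one_log_unit(self):
        assert mrd([10.0], [1.0]) == pytest.approx(10.0)

    def test_symmetric_two_fold_pair(self):
        assert mrd([2.0, 0.5], [1.0, 1.0]) == pytest.approx(2.0)

    def test_non_positive_pairs_excluded(self):
        assert mrd([2.0, 0.0], [1.0, 1.0]) == pytest.approx(2.0)


class TestGmfe:
    def test_perfect_prediction(self):
        assert gmfe([5.0], [5.0]) == pytest.approx(1.0)

    def test_symmetry_of_over_and_under_prediction(self):
        assert gmfe([2.0, 0.5], [1.0, 1.0]) == pytest.approx(2.0)

    def test_mixed_fold_errors(self):
        value = gmfe([1.2, 1.25, 1.25], [1.0, 1.0, 1.0])
        assert value == pytest.approx(1.2331, abs=2e-4)

    @given(
        pairs=st.lists(
            st.tuples(st.floats(0.01, 100.0), st.floats(0.01, 100.0)),
            min_size=2,
            max_size=12,
        )
    )
    def test_order_invariance_and_log_mean_inequality(self, pairs):
        pred = [p for p, _ in pairs]
        obs = [o for _, o in pairs]
        g = gmfe(pred, obs)
        assert g == pytest.approx(gmfe(pred[::-1], obs[::-1]), rel=1e-12)
        # swapping pred and obs leaves |log| errors unchanged
        assert g == pytest.approx(gmfe(obs, pred), rel=1e-12)
        # arithmetic-quadratic mean inequality in the log domain: GMFE <= MRD
        assert g <= mrd(pred, obs) * (1 + 1e-12)


class TestRatios:
    def test_identical_metrics_give_unit_ratio(self):
        assert ddi_ratio(10.0, 10.0) == 1.0

    def test_benchmark_auc_ratio(self):
        assert round(ddi_ratio(102.3, 128.7), 2) == 0.79

    def test_benchmark_cmax_ratio(self):
        assert round(ddi_ratio(15.7, 18.4), 2) == 0.85

    def test_positive_exposures_required(self):
        with pytest.raises(EvaluationError):
            ddi_ratio(0.0, 10.0)


class TestAfeRmse:
    def test_perfect_agreement(self):
        assert afe([0.8], [0.8]) == pytest.approx(1.0)
        assert rmse([0.8], [0.8]) == 0.0

    def test_single_pair_bias_and_precision(self):
        pred, obs = 0.79487, 0.66722
        assert round(afe([pred], [obs]), 2) == 1.19
        assert round(rmse([pred], [obs]), 2) == 0.13

    def test_afe_symmetric_around_unity(self):
        assert afe([2.0], [1.0]) == pytest.approx(afe([0.5], [1.0]))


class TestFoldClassification:
    @pytest.mark.parametrize(
        "ratio, within_15, within_2",
        [(1.49, 1.0, 1.0), (1.51, 0.0, 1.0), (2.01, 0.0, 0.0)],
    )
    def test_thresholds(self, ratio, within_15, within_2):
        out = fold_classification([ratio], [1.0])
        assert out["within_1_5"] == within_15
        assert out["within_2"] == within_2

    def test_direction_symmetric(self):
        assert fold_classification([1.0], [1.6]) == fold_classification(
            [1.6], [1.0]
        )


class TestBenchmarkReproduction:
    """The printed clinical benchmark exposures reproduce the published
    qualification statistics when ratios are recomputed at full precision."""

    def test_afe_suite(self):
        obs = benchmark_ddi_ratios("observed")
        abcb1 = benchmark_ddi_ratios("predicted_abcb1")
        both = benchmark_ddi_ratios("predicted_combined")
        assert round(afe([abcb1["ddi_auc_ratio"]], [obs["ddi_auc_ratio"]]), 2) == 1.19
        assert round(afe([abcb1["ddi_cmax_ratio"]], [obs["ddi_cmax_ratio"]]), 2) == 1.12
        assert round(afe([both["ddi_cmax_ratio"]], [obs["ddi_cmax_ratio"]]), 2) == 1.10

    def test_rmse_suite(self):
        obs = benchmark_ddi_ratios("observed")
        abcb1 = benchmark_ddi_ratios("predicted_abcb1")
        both = benchmark_ddi_ratios("predicted_combined")
        assert round(rmse([abcb1["ddi_auc_ratio"]], [obs["ddi_auc_ratio"]]), 2) == 0.13
        assert round(rmse([abcb1["ddi_cmax_ratio"]], [obs["ddi_cmax_ratio"]]), 2) == 0.10
        assert round(rmse([both["ddi_cmax_ratio"]], [obs["ddi_cmax_ratio"]]), 2) == 0.08


def test_evaluate_pairs_full_report():
    obs = benchmark_ddi_ratios("observed")
    pred = benchmark_ddi_ratios("predicted_abcb1")
    pairs = pd.DataFrame(
        [
            {"arm_id": "a", "quantity": "conc", "predicted": 2.0, "observed": 1.0},
            {"arm_id": "a", "quantity": "conc", "predicted": 0.5, "observed": 1.0},
            {"arm_id": "a", "quantity": "auc",
             "predicted": DDI_BENCHMARK["predicted_abcb1"]["auc_alone"],
             "observed": DDI_BENCHMARK["observed"]["auc_alone"]},
            {"arm_id": "a", "quantity": "ddi_auc_ratio",
             "predicted": pred["ddi_auc_ratio"],
             "observed": obs["ddi_auc_ratio"]},
        ]
    )
    report = evaluate_pairs(pairs)
    assert report.mrd == pytest.approx(2.0)
    assert report.gmfe["auc"] == pytest.approx(181.2 / 128.7)
    assert round(report.afe["ddi_auc_ratio"], 2) == 1.19
    assert report.within_2 == 1.0
    assert report.to_frame().shape[0] == 6
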
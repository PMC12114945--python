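"""Detection scoring, metric aggregation, benchmark runner plumbing."""

import numpy as np
import pytest

from emgonset import Config, make_benchmark_set, run_benchmark, score_detection, summarize
from emgonset.evaluate import reports_to_frame


class TestScoreDetection:
    @pytest.mark.parametrize(
        "t_hat, t_true, expected",
        [
            (2.05, 2.00, "TP"),
            (2.50, 2.00, "FN"),
            (None, 2.00, "FN"),
            (1.00, None, "FP"),
            (None, None, "TN"),
        ],
    )
    def test_labels(self, t_hat, t_true, expected):
        assert score_detection(t_hat, t_true, tolerance_s=0.2) == expected

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            score_detection(1.0, 1.0, tolerance_s=0.0)


class TestSummarize:
    def test_rate_arithmetic(self):
        t_trues = [1.0] * 10 + [None] * 10
        t_hats = [1.05] * 8 + [9.0] * 2 + [None] * 9 + [3.0]
        rep = summarize("m", t_hats, t_trues, tolerance_s=0.2)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (8, 2, 9, 1)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.9)
        assert rep.fnr == pytest.approx(0.2)
        assert rep.fpr == pytest.approx(0.1)

    def test_rmse_over_true_positives_only(self):
        rep = summarize("m", [2.1, 1.9, 9.0], [2.0, 2.0, 2.0], tolerance_s=0.2)
        assert rep.rmse_s == pytest.approx(0.1)

    def test_reference_method_has_zero_advance(self):
        hats = [1.0, 2.0, None]
        rep = summarize("m", hats, [1.0, 2.0, None], reference_t_hats=hats)
        assert rep.advance_s == 0.0

    def test_advance_antisymmetric(self):
        a = [1.0, 2.0, 3.0]
        b = [1.5, 1.8, 3.4]
        trues = [1.0, 2.0, 3.0]
        rep_ab = summarize("a", a, trues, reference_t_hats=b)
        rep_ba = summarize("b", b, trues, reference_t_hats=a)
        assert rep_ab.advance_s == pytest.approx(-rep_ba.advance_s)

    def test_undefined_rates_are_none_not_zero(self):
        rep = summarize("m", [1.0], [1.05], tolerance_s=0.2)
        assert rep.specificity is None and rep.fpr is None

    def test_conservation_of_cases(self):
        t_trues = [1.0, None, 2.0, None, 3.0]
        t_hats = [1.1, 0.5, None, None, 8.0]
        rep = summarize("m", t_hats, t_trues)
        assert rep.tp + rep.fn == 3
        assert rep.tn + rep.fp == 2


@pytest.fixture(scope="module")
def small_benchmark():
    ds = make_benchmark_set(6, seed0=400, duration=4.0)
    methods = ["mse", "mse-only", "threshold", "rms"]
    return ds, methods, run_benchmark(ds, methods)


class TestRunBenchmark:

    def test_schema_and_bounds(self, small_benchmark):
        ds, methods, (reports, onsets) = small_benchmark
        assert set(reports) == set(methods)
        frame = reports_to_frame(reports)
        assert len(frame) == len(methods)
        for rep in reports.values():
            for rate in (rep.sensitivity, rep.specificity, rep.fnr, rep.fpr):
                assert rate is None or 0.0 <= rate <= 1.0
            assert rep.tp + rep.fn == 3 and rep.tn + rep.fp == 3
        assert list(onsets.columns) == ["signal", "t_true"] + methods

    def test_deterministic_rerun(self, small_benchmark):
        ds, methods, (reports, onsets) = small_benchmark
        reports2, onsets2 = run_benchmark(ds, methods)
        assert onsets.equals(onsets2)
        assert reports_to_frame(reports).equals(reports_to_frame(reports2))

    def test_cached_trend_matches_independent_detection(self, small_benchmark):
        from emgonset import detect

        ds, methods, (reports, onsets) = small_benchmark
        cfg = Config(detector_reject_delta=0.02)
        sig = ds[0][0]
        for m in ("mse", "mse-only"):
            stored = onsets.iloc[0][m]
            independent = detect(sig, m, cfg).t_star
            if independent is None:
                assert np.isnan(stored) or stored is None
            else:
                assert stored == independent

    def test_writes_delimited_tables(self, tmp_path):
        ds = make_benchmark_set(2, seed0=900, duration=4.0)
        run_benchmark(ds, ["threshold", "rms"], out_dir=tmp_path)
        assert (tmp_path / "metrics.tsv").exists()
        assert (tmp_path / "onsets.tsv").exists()
        header = (tmp_path / "metrics.tsv").read_text().splitlines()[0]
        assert header.split("\t")[:5] == ["method", "sensitivity", "specificity", "fnr", "fpr"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            run_benchmark([], ["mse"])

    def test_unknown_method_rejected(self):
        ds = make_benchmark_set(2, seed0=1, duration=4.0)
        with pytest.raises(ValueError):
            run_benchmark(ds, ["mse", "bogus"])

    def test_ordering_invariance_of_rates(self):
        ds = make_benchmark_set(4, seed0=500, duration=4.0)
        r1, _ = run_benchmark(ds, ["threshold"])
        r2, _ = run_benchmark(ds[::-1], ["threshold"])
        assert r1["threshold"].sensitivity == r2["threshold"].sensitivity
        assert r1["threshold"].specificity == r2["threshold"].specificity
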
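import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octcca.evaluation import (
    EvalConfig,
    confusion,
    itr,
    leave_one_block_out,
    paired_ttest,
    star_code,
    summarize,
)
from octcca.signal_model import bandpass
from octcca.synthetic import SimConfig, generate_dataset
from oracles import confusion_tally, paired_t_closed_form


class TestITR:
    @pytest.mark.parametrize(
        "acc_pct, tw, expected",
        [
            (91.67, 2.5, 47.47),  # best per-subject rate at the 2.5 s window
            (100.0, 5.0, 31.02),  # perfect accuracy: 60/T * log2(6)
            (52.78, 1.0, 29.45),
            (88.89, 2.5, 43.77),
        ],
    )
    def test_known_operating_points(self, acc_pct, tw, expected):
        assert itr(acc_pct / 100.0, 6, tw) == pytest.approx(expected, abs=0.05)

    def test_chance_level_gives_zero(self):
        for t in (1.0, 2.5, 5.0):
            assert itr(1 / 6, 6, t) == 0.0
            assert itr(0.05, 6, t) == 0.0

    def test_perfect_limit_handled(self):
        assert itr(1.0, 6, 1.0) == pytest.approx(60 * np.log2(6))

    @pytest.mark.parametrize(
        "kwargs, err",
        [
            (dict(p=0.5, n_classes=1, t_select=1.0), "n_classes"),
            (dict(p=1.5, n_classes=6, t_select=1.0), "accuracy"),
            (dict(p=0.5, n_classes=6, t_select=0.0), "selection time"),
        ],
    )
    def test_parameter_errors(self, kwargs, err):
        with pytest.raises(ValueError, match=err):
            itr(kwargs["p"], kwargs["n_classes"], kwargs["t_select"])

    def test_monotone_in_accuracy_and_time(self):
        ps = np.linspace(0.2, 1.0, 30)
        vals = [itr(p, 6, 2.0) for p in ps]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        ts = np.linspace(0.5, 6.0, 25)
        vals_t = [itr(0.9, 6, t) for t in ts]
        assert all(b < a for a, b in zip(vals_t, vals_t[1:]))


class TestSummarize:
    def test_reproduces_reported_row_statistics(self):
        mean, std = summarize([91.67, 91.67, 88.89, 88.89, 91.67])
        assert round(mean, 2) == 90.56
        assert round(std, 2) == 1.52

    def test_reproduces_command_count_statistics(self):
        mean, std = summarize([16, 18, 18, 20, 18])
        assert (round(mean, 2), round(std, 2)) == (18.0, 1.41)

    def test_single_value_convention(self):
        assert summarize([5.0]) == (5.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize([])


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        mat = confusion([0, 1, 2, 1], [0, 1, 2, 1], 3)
        np.testing.assert_array_equal(mat, np.diag([1, 2, 1]))

    def test_single_predicted_column(self):
        mat = confusion([0, 1, 2], [0, 0, 0], 3)
        assert mat[:, 0].sum() == 3 and mat[:, 1:].sum() == 0

    def test_matches_tally_oracle(self, rng):
        t = rng.integers(0, 5, size=200)
        p = rng.integers(0, 5, size=200)
        np.testing.assert_array_equal(confusion(t, p, 5), confusion_tally(t, p, 5))

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion([0, 3], [0, 1], 3)


class TestPairedTTest:
    def test_identical_vectors(self):
        t, p, stars = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p, stars) == (0.0, 1.0, "ns")

    def test_constant_positive_shift_degenerate(self):
        t, p, stars = paired_ttest([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
        assert t == np.inf and p == 0.0 and stars == "***"

    def test_matches_closed_form_distribution(self, rng):
        for _ in range(10):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            t, p, _ = paired_ttest(a, b)
            t0, p0 = paired_t_closed_form(a, b)
            assert t == pytest.approx(t0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-10)

    @pytest.mark.parametrize(
        "p, stars", [(5e-4, "***"), (5e-3, "**"), (0.03, "*"), (0.2, "ns")]
    )
    def test_star_coding(self, p, stars):
        assert star_code(p) == stars


class TestEvalConfig:
    def test_window_validation(self):
        with pytest.raises(ValueError, match="ascending"):
            EvalConfig(window_lengths=(2.0, 1.0))
        with pytest.raises(ValueError, match="positive"):
            EvalConfig(window_lengths=(0.0, 1.0))
        with pytest.raises(ValueError, match="unknown method"):
            EvalConfig(methods=("MSI",))


class TestLeaveOneBlockOut:
    def test_fold_count_and_trial_bookkeeping(self, small_dataset):
        cfg = EvalConfig(window_lengths=(1.0,), methods=("CCA",))
        report = leave_one_block_out(small_dataset, cfg)
        assert report.n_folds == 3
        # every subject classified on 6 targets x 3 held-out blocks
        assert set(report.results["n_trials"]) == {18}
        for mat in report.confusions.values():
            assert mat.sum() == 18
            np.testing.assert_array_equal(mat.sum(axis=1), np.full(6, 3))

    def test_high_snr_dataset_fully_separable(self):
        cfg = SimConfig(n_subjects=3, n_blocks=3, duration=2.5, snr_db=20, seed=21)
        ds = generate_dataset(cfg).map(lambda e: bandpass(e, 7.0, 80.0))
        report = leave_one_block_out(
            ds, EvalConfig(window_lengths=(2.0,), methods=("CCA", "OCTCCA"))
        )
        assert np.all(report.results["accuracy_pct"] == 100.0)

    def test_accuracy_and_itr_columns_consistent(self, small_dataset):
        cfg = EvalConfig(window_lengths=(1.0,), methods=("ITCCA",))
        report = leave_one_block_out(small_dataset, cfg)
        for _, row in report.results.iterrows():
            assert row["itr_bits_min"] == pytest.approx(
                itr(row["accuracy_pct"] / 100, 6, row["window_s"])
            )

    def test_summary_and_ttest_shapes(self, small_dataset):
        cfg = EvalConfig(window_lengths=(1.0,), methods=("CCA", "OCTCCA"))
        report = leave_one_block_out(small_dataset, cfg)
        summ = report.summary()
        assert set(summ["method"]) == {"CCA", "OCTCCA"}
        tt = report.ttests()
        assert len(tt) == 1
        assert tt.iloc[0]["stars"] in {"***", "**", "*", "ns"}

    def test_single_block_rejected(self, small_dataset):
        keep = {(e.subject_id, 0, e.target_index) for e in small_dataset}
        sub = small_dataset.map(lambda e: e)  # copy
        # build a one-block dataset
        from octcca.signal_model import Dataset

        one = Dataset(stimulus_config=small_dataset.stimulus_config)
        for e in small_dataset:
            if e.block_id == 0:
                one.add(e)
        with pytest.raises(ValueError, match=">= 2 blocks"):
            leave_one_block_out(one, EvalConfig(window_lengths=(1.0,)))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    p=st.floats(0.2, 0.999),
    n=st.integers(2, 40),
    t=st.floats(0.25, 10.0),
)
def test_itr_nonnegative_and_bounded(p, n, t):
    """ITR never exceeds the noiseless channel capacity 60/T * log2 N."""
    v = itr(p, n, t)
    assert 0.0 <= v <= 60.0 / t * np.log2(n) + 1e-9


def test_excluding_target_subject_from_the_common_templates(small_dataset):
    """With include_target_subject=False the optimized templates for each
    test subject are built from the other subjects only; the harness still
    produces a complete report."""
    cfg = EvalConfig(
        window_lengths=(1.0,), methods=("OCTCCA",), include_target_subject=False
    )
    report = leave_one_block_out(small_dataset, cfg)
    assert set(report.results["subject"]) == set(small_dataset.subjects)
    assert np.all(report.results["n_trials"] == 18)
    assert np.all(report.results["accuracy_pct"].between(0, 100))
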
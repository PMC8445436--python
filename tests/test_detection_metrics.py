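import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vistrain.detection_metrics import (
    ConfusionMatrix,
    MetricsReport,
    accuracy,
    cohort_summary,
    hit_rate,
    load_validation_cohort,
    npv,
    pool,
    ppv,
    random_hit_rate,
    ratz,
    reconstruct_matrix,
    reproduce_report,
    round_half_up,
    sen,
    spe,
    spearman_brown,
    split_half_reliability,
)

PERFECT = ConfusionMatrix(tn=15, fp=0, fn=0, tp=85)
SUBJ01 = ConfusionMatrix(tn=14, fp=1, fn=1, tp=84)
SUBJ36 = ConfusionMatrix(tn=13, fp=2, fn=8, tp=77)
SUBJ40 = ConfusionMatrix(tn=14, fp=1, fn=3, tp=82)


def rhr_permutation_oracle(m: ConfusionMatrix, n_shuffles=10_000, seed=0) -> float:
    """Mean agreement over random pairings of click and category labels."""
    rng = np.random.default_rng(seed)
    cat = np.repeat([0, 1], [m.n_blindspot, m.n_detectable])  # 1 = detectable
    clicks = np.repeat([1, 0], [m.tp + m.fp, m.tn + m.fn])
    agree = np.empty(n_shuffles)
    for k in range(n_shuffles):
        agree[k] = (cat == rng.permutation(clicks)).mean()
    return float(agree.mean())


class TestSenSpe:
    def test_perfect(self):
        assert sen(PERFECT) == 1.0 and spe(PERFECT) == 1.0

    def test_subject_01(self):
        assert round_half_up(sen(SUBJ01)) == 0.933
        assert round_half_up(spe(SUBJ01)) == 0.988

    def test_subject_36(self):
        assert round_half_up(sen(SUBJ36)) == 0.867
        assert round_half_up(spe(SUBJ36)) == 0.906

    def test_zero_denominator_is_nan(self):
        m = ConfusionMatrix(tn=0, fp=0, fn=1, tp=9)
        assert math.isnan(sen(m))
        m2 = ConfusionMatrix(tn=5, fp=1, fn=0, tp=0)
        assert math.isnan(spe(m2))


class TestPpvNpv:
    def test_subject_36(self):
        assert round_half_up(ppv(SUBJ36)) == 0.619  # 13 / (13 + 8)
        assert round_half_up(npv(SUBJ36)) == 0.975  # 77 / (77 + 2)

    def test_subject_40(self):
        assert round_half_up(ppv(SUBJ40)) == 0.824
        assert round_half_up(npv(SUBJ40)) == 0.988

    def test_perfect(self):
        assert ppv(PERFECT) == 1.0 and npv(PERFECT) == 1.0

    def test_zero_denominator_is_nan(self):
        all_click = ConfusionMatrix(tn=0, fp=15, fn=0, tp=85)
        assert math.isnan(ppv(all_click))
        no_click = ConfusionMatrix(tn=15, fp=0, fn=85, tp=0)
        assert math.isnan(npv(no_click))


class TestHitRates:
    def test_perfect(self):
        assert hit_rate(PERFECT) == 1.0
        assert round_half_up(random_hit_rate(PERFECT)) == 0.745

    def test_subject_36(self):
        assert round_half_up(hit_rate(SUBJ36)) == 0.900
        assert round_half_up(random_hit_rate(SUBJ36)) == 0.703

    @pytest.mark.parametrize(
        "m,expected",
        [
            (SUBJ01, 0.745),
            (ConfusionMatrix(14, 1, 0, 85), 0.752),
            (ConfusionMatrix(15, 0, 1, 84), 0.738),
            (ConfusionMatrix(15, 0, 2, 83), 0.731),
        ],
    )
    def test_every_distinct_printed_rhr_value(self, m, expected):
        assert round_half_up(random_hit_rate(m)) == expected

    @pytest.mark.parametrize("m", [PERFECT, SUBJ01, SUBJ36, SUBJ40])
    def test_permutation_oracle_on_study_matrices(self, m):
        assert random_hit_rate(m) == pytest.approx(
            rhr_permutation_oracle(m, n_shuffles=10_000), abs=0.005
        )

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_permutation_oracle_property_small_n(self, tn, fp, fn):
        tp = 30 - tn - fp - fn  # keep N = 30 fixed
        if tp < 0 or tn + fp == 0 or tp + fn == 0:
            return
        m = ConfusionMatrix(tn=tn, fp=fp, fn=fn, tp=tp)
        assert random_hit_rate(m) == pytest.approx(
            rhr_permutation_oracle(m, n_shuffles=4_000), abs=0.01
        )


class TestRatz:
    def test_subject_01(self):
        assert round_half_up(ratz(SUBJ01)) == 0.922

    def test_perfect_is_one(self):
        assert ratz(PERFECT) == 1.0

    def test_chance_performance_is_zero(self):
        # hr == rhr: e.g. all clicks regardless of category
        m = ConfusionMatrix(tn=0, fp=15, fn=0, tp=85)
        assert ratz(m) == pytest.approx(0.0, abs=1e-12)

    @given(
        st.integers(0, 15), st.integers(0, 85)
    )
    def test_sign_and_bounds(self, tn, tp):
        m = ConfusionMatrix(tn=tn, fp=15 - tn, fn=85 - tp, tp=tp)
        r, h = random_hit_rate(m), hit_rate(m)
        z = ratz(m)
        if math.isnan(z):
            assert r >= 1.0
            return
        assert z <= 1.0 + 1e-12
        assert (h >= r) == (z >= 0)
        for metric in (sen(m), spe(m), h, r):
            assert 0.0 <= metric <= 1.0


class TestAccuracy:
    def test_published_pooled_counts(self):
        assert round_half_up(accuracy(ConfusionMatrix(588, 12, 28, 3372))) == 0.990

    def test_perfect_and_total_failure(self):
        assert accuracy(PERFECT) == 1.0
        assert accuracy(ConfusionMatrix(0, 15, 85, 0)) == 0.0

    def test_invariant_under_pooling_order(self):
        ms = [PERFECT, SUBJ01, SUBJ36, SUBJ40]
        a = accuracy(pool(ms))
        b = accuracy(pool(ms[::-1]))
        c = accuracy(pool([pool(ms[:2]), pool(ms[2:])]))
        assert a == b == c


class TestCohortSummary:
    def test_published_cohort_means(self):
        df = load_validation_cohort()
        ms = [reconstruct_matrix(r.sen, r.spe) for r in df.itertuples()]
        summary = cohort_summary(ms)
        assert round_half_up(summary.loc["sen", "mean"]) == 0.980
        assert round_half_up(summary.loc["rhr", "mean"]) == 0.742

    def test_single_perfect_matrix(self):
        summary = cohort_summary([PERFECT])
        assert (summary["mean"] == 1.0).drop(["rhr"]).all()
        assert (summary["sd"] == 0.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])


class TestSpearmanBrown:
    def test_published_value(self):
        assert round_half_up(spearman_brown(0.547)) == 0.707

    def test_fixed_points(self):
        assert spearman_brown(1.0) == 1.0
        assert spearman_brown(0.0) == 0.0

    def test_minus_one_undefined(self):
        assert math.isnan(spearman_brown(-1.0))


class _Rec:
    def __init__(self, block, category, clicked):
        self.block = block
        self.category = category
        self.clicked = clicked


def _subject_records(miss_pattern):
    """Scored blind-spot records; miss_pattern[i] True = no click on trial i."""
    return [_Rec("scored", "blindspot", not miss) for miss in miss_pattern]


class TestSplitHalfReliability:
    def test_identical_halves_give_r_one(self):
        rng = np.random.default_rng(0)
        subjects = []
        for _ in range(10):
            k = int(rng.integers(0, 8))
            # same correct-rejection count in odd and even halves by construction
            pattern = ([True] * k + [False] * (8 - k))
            interleaved = [v for pair in zip(pattern, pattern) for v in pair]
            subjects.append(_subject_records(interleaved))
        r, corrected = split_half_reliability(subjects)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert corrected == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        subjects = [_subject_records([True] * 15) for _ in range(5)]
        r, corrected = split_half_reliability(subjects)
        assert math.isnan(r) and math.isnan(corrected)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            split_half_reliability([_subject_records([True] * 15)] * 2)

    def test_monte_carlo_self_consistency(self):
        # cohorts with per-subject sen ~ Beta(20, 1): the mean corrected
        # reliability over 400 replicates must agree with the estimate from
        # a 10x larger replicate set produced by the same generator
        def replicate_means(n_reps, seed):
            rng = np.random.default_rng(seed)
            vals = []
            for _ in range(n_reps):
                sens = rng.beta(20, 1, size=40)
                subjects = [
                    _subject_records(list(rng.random(15) < s)) for s in sens
                ]
                r, corrected = split_half_reliability(subjects)
                if not math.isnan(corrected):
                    vals.append(corrected)
            return np.asarray(vals)

        small = replicate_means(400, seed=1)
        big = replicate_means(4000, seed=2)
        se = small.std(ddof=1) / math.sqrt(len(small))
        assert abs(small.mean() - big.mean()) < 4 * se


class TestReproduceReport:
    def test_per_row_reproduction_of_all_printed_metrics(self):
        # every one of the 40 rows must reproduce printed SEN/SPE/PPV/NPV/HR/RHR
        # exactly after 3-decimal rounding (RATZ is the documented exception)
        df = load_validation_cohort()
        report = reproduce_report(df)
        per = report["per_subject"]
        for i, row in df.iterrows():
            assert per.loc[i, "sen"] == pytest.approx(row["sen"], abs=5e-4)
            assert per.loc[i, "spe"] == pytest.approx(row["spe"], abs=5e-4)
            assert per.loc[i, "ppv"] == row["printed_ppv"]
            assert per.loc[i, "npv"] == row["printed_npv"]
            assert per.loc[i, "hr"] == row["printed_hr"]
            assert per.loc[i, "rhr"] == row["printed_rhr"]

    def test_pooled_counts_and_accuracy(self):
        report = reproduce_report()
        assert report["pooled"] == {
            "tn": 588, "fp": 12, "fn": 28, "tp": 3372, "accuracy": 0.99,
        }

    def test_discrepancies_are_ratz_only(self):
        report = reproduce_report()
        disc = report["discrepancies"]
        assert not disc.empty
        assert set(disc["metric"]) == {"ratz"}

    def test_reconstruction_rule(self):
        m = reconstruct_matrix(0.933, 0.988)
        assert (m.tn, m.fp, m.fn, m.tp) == (14, 1, 1, 84)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("subject,sen\n01,1\n")
        with pytest.raises(ValueError, match="spe"):
            load_validation_cohort(p)


class TestConfusionMatrixValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tn=-1, fp=0, fn=0, tp=1)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tn=0, fp=0, fn=0, tp=0)

    def test_round_half_up_behaviour(self):
        assert round_half_up(0.9625, 3) == 0.963
        assert round_half_up(0.0005, 3) == 0.001
        assert math.isnan(round_half_up(math.nan))
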
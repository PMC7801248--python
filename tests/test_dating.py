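"""Ks peaks, rate/date inverses, duplication timing, LTR ages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skullcap.dating import (KsSample, calibrate_rate, calibrate_rate_multi,
                             classify_duplication_timing, date_event,
                             find_ks_peaks, ltr_insertion_age,
                             summarize_ltr_ages)
from skullcap.simulate import simulate_ltr_set

MU = 1.3e-8


# ------------------------------------------------------------ peaks


def test_unimodal_peak_location():
    rng = np.random.default_rng(1)
    values = np.clip(rng.normal(0.87, 0.1, 5000), 1e-6, None)
    peaks = find_ks_peaks(KsSample(values))
    assert abs(peaks[0].location - 0.87) <= 0.02


def test_bimodal_mixture_gives_two_peaks():
    rng = np.random.default_rng(2)
    values = np.concatenate([np.clip(rng.normal(0.16, 0.03, 2500), 1e-6, None),
                             np.clip(rng.normal(0.87, 0.10, 2500), 1e-6, None)])
    peaks = find_ks_peaks(KsSample(values))
    top2 = sorted(p.location for p in peaks[:2])
    assert abs(top2[0] - 0.16) <= 0.02 and abs(top2[1] - 0.87) <= 0.05


def test_constant_sample_peaks_at_value():
    peaks = find_ks_peaks(KsSample(np.full(100, 0.5)))
    assert peaks[0].location == pytest.approx(0.50, abs=0.001)


def test_insufficient_sample_error_names_count():
    with pytest.raises(ValueError, match="3"):
        find_ks_peaks(KsSample(np.array([0.1, 0.2, 0.3])))


def test_zero_values_excluded():
    values = np.concatenate([np.zeros(500), np.full(100, 0.4)])
    peaks = find_ks_peaks(KsSample(values))
    assert peaks[0].n == 100


# ------------------------------------------------------------ calibration


def test_rate_calibration_closed_form():
    cal = calibrate_rate(0.26, 10e6)
    assert cal.mu == pytest.approx(1.3e-8)


def test_calibration_rejects_nonpositive():
    with pytest.raises(ValueError):
        calibrate_rate(0.0, 10e6)
    with pytest.raises(ValueError):
        calibrate_rate(0.26, -1.0)
    with pytest.raises(ValueError):
        date_event(0.26, 0.0)


def test_date_event_arithmetic():
    assert date_event(0.0, MU).time_years == 0.0
    assert date_event(0.26, MU).time_mya == pytest.approx(10.0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(1e-3, 5.0), st.floats(1e4, 1e9))
def test_calibrate_and_date_are_inverses(ks, t):
    cal = calibrate_rate(ks, t)
    assert date_event(ks, cal.mu).time_years == pytest.approx(t, rel=1e-9)


def test_multi_anchor_calibration_is_mean_of_rates():
    cal = calibrate_rate_multi([(0.26, 10e6), (0.52, 10e6)])
    assert cal.mu == pytest.approx((1.3e-8 + 2.6e-8) / 2)


# ------------------------------------------------------------ timing


@pytest.mark.parametrize("ks,call", [
    (0.05, "after_speciation"),
    (0.60, "before_speciation"),
    (0.16, "ambiguous"),
])
def test_duplication_timing_calls(ks, call):
    assert classify_duplication_timing(ks, 0.16).call == call


def test_timing_recovery_on_simulated_cohorts():
    """Tandem cohorts at 2 vs 20 MY around a 6.15 MY split: >=95% correct."""
    from skullcap.kaks import kaks_pair
    from skullcap.simulate import jc_p, simulate_cds_pairs

    peak = 2 * MU * 6.15e6  # 0.16
    correct = total = 0
    for age, expected in ((2e6, "after_speciation"), (20e6, "before_speciation")):
        pairs = simulate_cds_pairs(100, 300, jc_p(MU, age), 0.0, seed=int(age))
        for a, b in pairs:
            ks = kaks_pair(a, b).Ks
            total += 1
            if classify_duplication_timing(ks, peak).call == expected:
                correct += 1
    assert correct / total >= 0.95


# ------------------------------------------------------------ LTR ages


def _repeats_with_mismatches(length, k):
    a = ("ACGT" * (length // 4 + 1))[:length]
    b = list(a)
    for i in range(k):
        b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
    return a, "".join(b)


def test_identical_repeats_age_zero():
    a, b = _repeats_with_mismatches(2000, 0)
    assert ltr_insertion_age(a, b, MU).age_years == 0.0


@pytest.mark.parametrize("mismatches,age_my", [(72, 1.41), (45, 0.88)])
def test_ltr_age_examples(mismatches, age_my):
    a, b = _repeats_with_mismatches(2000, mismatches)
    age = ltr_insertion_age(a, b, MU)
    assert age.age_years / 1e6 == pytest.approx(age_my, abs=0.01)


def test_ltr_length_mismatch_and_saturation():
    with pytest.raises(ValueError, match="length"):
        ltr_insertion_age("A" * 200, "A" * 199, MU)
    a, b = _repeats_with_mismatches(2000, 1600)  # p = 0.8
    assert ltr_insertion_age(a, b, MU).saturated


def test_ambiguous_positions_excluded_pairwise():
    a, b = _repeats_with_mismatches(200, 10)
    a = "N" * 10 + a[10:]  # mask exactly the mismatching prefix
    age = ltr_insertion_age(a, b, MU)
    assert age.p == 0.0 and age.age_years == 0.0


def test_summary_statistics():
    ages = [ltr_insertion_age(*_repeats_with_mismatches(2000, 72), MU)
            for _ in range(3)]
    mean, median, hist, n_sat = summarize_ltr_ages(ages)
    assert mean == pytest.approx(median)
    assert n_sat == 0
    assert hist["count"].sum() == 3


def test_mixed_ages_mean():
    from skullcap.dating import LTRAge

    cohort = [LTRAge("x", 0.01, 0.013, 0.5e6), LTRAge("y", 0.03, 0.039, 1.5e6)]
    mean, median, _, _ = summarize_ltr_ages(cohort)
    assert mean == pytest.approx(1.0e6)


def test_all_saturated_raises():
    a, b = _repeats_with_mismatches(2000, 1600)
    with pytest.raises(ValueError, match="saturated"):
        summarize_ltr_ages([ltr_insertion_age(a, b, MU)])


def test_ltr_estimator_unbiased_over_age_grid():
    """Cohort mean within 3 SE of truth for ages 0.5-3.5 MY."""
    for age in (0.5e6, 0.88e6, 1.41e6, 3.5e6):
        elements = simulate_ltr_set(1000, 2000, age, MU, seed=int(age // 1000))
        est = np.array([ltr_insertion_age(e.ltr5_seq, e.ltr3_seq, MU).age_years
                        for e in elements])
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - age) <= 3 * se, age
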
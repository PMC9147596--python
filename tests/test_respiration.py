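"""Apnoea scoring against an independent brute-force oracle, plus the
APD90-vs-apnoea-length correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rettephys.core_io import InsufficientDataError
from rettephys.respiration import (BreathRecord, apd_apnoea_correlation,
                                   detect_apnoeas)
from rettephys.synthetic_data import gen_breaths


def brute_force_apnoeas(onsets, te, factor, adaptation_s, analysis_s):
    """Literal re-implementation of the scoring rule: each minute's reference
    is the mean expiration time of the previous minute's non-apnoeic breaths;
    a breath is apnoeic when its expiration time exceeds factor x reference;
    consecutive apnoeic breaths merge into one episode."""
    flags = [False] * len(onsets)
    for i, (on, t) in enumerate(zip(onsets, te)):
        m = int(on // 60)
        prev = [te[j] for j in range(len(onsets))
                if int(onsets[j] // 60) == m - 1 and not flags[j]]
        if prev and t > factor * (sum(prev) / len(prev)):
            flags[i] = True
    episodes = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            if adaptation_s <= onsets[i] < adaptation_s + analysis_s:
                episodes.append(sum(te[i:j + 1]))
            i = j + 1
        else:
            i += 1
    return len(episodes), episodes


def short_record(te_values, dt=0.4, adaptation_s=60.0, analysis_s=120.0):
    onsets = dt * np.arange(len(te_values))
    return BreathRecord(onsets, np.asarray(te_values, float),
                        adaptation_s=adaptation_s, analysis_s=analysis_s)


class TestDetectApnoeas:
    def test_regular_breathing_scores_zero(self):
        rec = short_record([0.2] * 500)
        assert detect_apnoeas(rec).count == 0

    def test_single_long_expiration_detected_with_its_length(self):
        te = [0.2] * 500
        te[300] = 1.0  # > 4 x 0.2
        summary = detect_apnoeas(short_record(te))
        assert summary.count == 1
        assert summary.lengths == [1.0]
        assert summary.mean_length == 1.0

    def test_higher_factor_suppresses_detection(self):
        te = [0.2] * 500
        te[300] = 1.0
        assert detect_apnoeas(short_record(te), factor=6.0).count == 0

    def test_consecutive_apnoeic_breaths_merge(self):
        te = [0.2] * 500
        te[300] = te[301] = 1.0
        summary = detect_apnoeas(short_record(te))
        assert summary.count == 1
        assert summary.lengths[0] == pytest.approx(2.0)

    def test_apnoea_during_adaptation_not_scored(self):
        te = [0.2] * 500
        te[100] = 1.0  # onset 40 s < adaptation 60 s
        assert detect_apnoeas(short_record(te)).count == 0

    def test_empty_analysis_window_rejected(self):
        rec = BreathRecord(np.arange(0, 30, 0.4), np.full(75, 0.2),
                           adaptation_s=60.0, analysis_s=60.0)
        with pytest.raises(InsufficientDataError):
            detect_apnoeas(rec)

    def test_scaling_all_te_leaves_count_unchanged(self):
        rng = np.random.default_rng(5)
        te = list(rng.lognormal(np.log(0.2), 0.2, 600))
        te[350] = 1.5
        base = detect_apnoeas(short_record(te)).count
        scaled = detect_apnoeas(short_record([3.0 * t for t in te])).count
        assert scaled == base

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_brute_force_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        onsets = np.cumsum(rng.uniform(0.3, 0.6, n))
        te = rng.lognormal(np.log(0.2), 0.3, n)
        spikes = rng.choice(n, size=rng.integers(0, 6), replace=False)
        te[spikes] *= rng.uniform(3, 10, spikes.size)
        rec = BreathRecord(onsets, te, adaptation_s=60.0, analysis_s=120.0)
        got = detect_apnoeas(rec)
        count, lengths = brute_force_apnoeas(list(onsets), list(te), 4.0,
                                             60.0, 120.0)
        assert got.count == count
        np.testing.assert_allclose(got.lengths, lengths)

    def test_factor_monotonicity_on_random_series(self):
        rng = np.random.default_rng(17)
        te = rng.lognormal(np.log(0.2), 0.4, 600)
        rec = short_record(list(te))
        counts = [detect_apnoeas(rec, factor=f).count for f in (2, 3, 4, 6, 10)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestGeneratedRecords:
    def test_injected_apnoeas_recovered_by_the_rule(self):
        rec = gen_breaths(base_te=0.2, apnoeas=[(1300.0, 1.0), (1600.0, 1.1),
                                                (2000.0, 0.9)],
                          jitter_cv=0.05, seed=2)
        assert detect_apnoeas(rec).count == 3

    def test_no_injection_no_jitter_scores_zero(self):
        rec = gen_breaths(jitter_cv=0.0, seed=2)
        assert detect_apnoeas(rec).count == 0

    def test_same_seed_reproduces_record(self):
        a = gen_breaths(seed=9)
        b = gen_breaths(seed=9)
        np.testing.assert_array_equal(a.te, b.te)

    def test_overlapping_apnoeas_rejected(self):
        with pytest.raises(ValueError, match="verlapping"):
            gen_breaths(apnoeas=[(1300.0, 1.0), (1300.1, 1.0)])


class TestCorrelation:
    def test_printed_r_and_n_reproduce_printed_p(self):
        # r = -0.07 with n = 11 animals -> two-sided p = 0.84
        rng = np.random.default_rng(0)
        # construct an 11-point dataset with exactly r = -0.07
        x = rng.normal(size=11)
        y = rng.normal(size=11)
        x = (x - x.mean()) / x.std()
        y = y - y.mean()
        y -= x * (x @ y) / (x @ x)          # orthogonalise
        y /= y.std()
        target = -0.07
        y = target * x + np.sqrt(1 - target ** 2) * y
        r, p = apd_apnoea_correlation(list(zip(x, y)))
        assert r == pytest.approx(-0.07, abs=1e-9)
        assert round(p, 2) == 0.84

    def test_perfectly_linear_pairs(self):
        r, p = apd_apnoea_correlation([(1, 2), (2, 4), (3, 6), (4, 8)])
        assert r == pytest.approx(1.0)

    def test_constant_variable_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            apd_apnoea_correlation([(1, 2), (1, 3), (1, 4)])

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            apd_apnoea_correlation([(1, 2), (2, 3)])
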
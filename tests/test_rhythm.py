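"""DFT cyclic scoring, permutation calibration and parameter fits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielcycle.expression import ExpressionMatrix
from dielcycle.layout import SamplingLayout
from dielcycle.rhythm import (
    NullDistribution,
    assign_phase_cluster,
    call_cycling,
    cyclic_score,
    cyclic_scores,
    detect_cycling,
    dft_spectrum,
    fit_cyclic_parameters,
    null_score_distribution,
    threshold_at_top_percentile,
    upper_quartile_normalize,
)
from dielcycle.simulate import ExpressionConfig, generate_expression


def _matrix(arr, layout):
    df = pd.DataFrame(np.atleast_2d(arr),
                      index=[f"g{i}" for i in range(np.atleast_2d(arr).shape[0])],
                      columns=layout.column_labels())
    return ExpressionMatrix(df, layout)


# ---------------------------------------------------------------------------
# upper-quartile normalization
# ---------------------------------------------------------------------------


class TestUpperQuartile:
    def test_doubled_sample_equalized(self, layout):
        rng = np.random.default_rng(0)
        base = rng.lognormal(1, 1, size=(50, layout.n_points))
        arr = base.copy()
        arr[:, 1] = 2 * arr[:, 0]
        out = upper_quartile_normalize(_matrix(arr, layout)).to_array()
        np.testing.assert_allclose(out[:, 0], out[:, 1])

    def test_identical_samples_unchanged(self, layout):
        arr = np.tile(np.arange(1.0, 6.0)[:, None], (1, layout.n_points))
        out = upper_quartile_normalize(_matrix(arr, layout)).to_array()
        np.testing.assert_allclose(out, arr)

    def test_matches_hand_computed_scaling(self):
        layout = SamplingLayout(interval_hours=8, day_length_hours=24, n_days=1)
        arr = np.array([[1.0, 2.0, 4.0],
                        [2.0, 4.0, 8.0],
                        [3.0, 6.0, 12.0],
                        [4.0, 8.0, 16.0],
                        [0.0, 10.0, 20.0]])
        # nonzero upper quartiles (linear interpolation): 3.25, 8, 16;
        # reference = their mean = 109/12
        out = upper_quartile_normalize(_matrix(arr, layout)).to_array()
        expected = arr * ((109 / 12) / np.array([3.25, 8.0, 16.0]))
        np.testing.assert_allclose(out, expected)

    def test_all_zero_sample_rejected(self, layout):
        arr = np.ones((3, layout.n_points))
        arr[:, 2] = 0
        with pytest.raises(ValueError):
            upper_quartile_normalize(_matrix(arr, layout))


# ---------------------------------------------------------------------------
# the transform itself
# ---------------------------------------------------------------------------


class TestDftSpectrum:
    def test_constant_segment_all_zero_power(self):
        _, power = dft_spectrum([5.0] * 8)
        np.testing.assert_allclose(power, 0, atol=1e-20)

    def test_pure_cosine_closed_form(self):
        # |y_k| = M*A/2 at the cosine's bin, zero elsewhere
        x = np.cos(2 * np.pi * np.arange(8) / 8)
        y, power = dft_spectrum(x)
        assert abs(np.abs(y[1]) - 4.0) < 1e-12
        assert power[2:].max() < 1e-20

    def test_matches_naive_quadratic_sum(self):
        """Brute-force evaluation of y_k = sum_n x_n exp(-2 pi i k n / M)."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        xc = x - x.mean()
        y, power = dft_spectrum(x)
        for k in range(5):
            brute = sum(
                xc[n] * np.exp(-2j * np.pi * k * n / 8) for n in range(8)
            )
            assert abs(y[k] - brute) < 1e-10
            assert abs(power[k] - abs(brute) ** 2) < 1e-8

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=16))
    @settings(deadline=None, max_examples=50)
    def test_parseval_identity(self, values):
        x = np.asarray(values)
        xc = x - x.mean()
        y, _ = dft_spectrum(x)
        lhs = (xc**2).sum()
        rhs = (np.abs(y) ** 2).sum() / len(x)
        assert abs(lhs - rhs) < 1e-8 * max(1.0, lhs)


# ---------------------------------------------------------------------------
# cyclic score
# ---------------------------------------------------------------------------


def _score_oracle(x, layout):
    """Independent step-by-step reimplementation of the cyclic score."""
    m = layout.points_per_day
    scores = []
    for start in range(0, layout.n_points - m + 1):
        seg = np.asarray(x[start : start + m], dtype=float)
        seg = seg - seg.mean()
        comps = []
        for k in range(1, m // 2 + 1):
            yk = sum(seg[n] * np.exp(-2j * np.pi * k * n / m) for n in range(m))
            comps.append(abs(yk) ** 2)
        comps = np.array(comps)
        if comps.max() == comps.min():
            scores.append(0.0)
        else:
            norm = (comps - comps.min()) / (comps.max() - comps.min())
            scores.append(norm[0])
    return float(np.mean(scores))


class TestCyclicScore:
    def test_pure_diel_cosine_scores_one(self, layout, pure_cosine):
        assert cyclic_score(pure_cosine, layout) == 1.0

    def test_half_day_cosine_scores_zero(self, layout):
        t = layout.sample_times()
        x = 10 * (1 + 0.5 * np.cos(2 * np.pi * t / 12))
        assert cyclic_score(x, layout) < 1e-12

    def test_constant_vector_scores_zero(self, layout):
        assert cyclic_score(np.full(layout.n_points, 3.3), layout) == 0.0

    def test_matches_independent_oracle(self, layout):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.lognormal(1, 1, size=layout.n_points)
            assert abs(cyclic_score(x, layout) - _score_oracle(x, layout)) < 1e-10

    @given(st.floats(0.1, 50), st.floats(-5, 500), st.integers(0, 2**31))
    @settings(deadline=None, max_examples=30)
    def test_affine_invariance(self, a, b, seed):
        layout = SamplingLayout()
        x = np.random.default_rng(seed).lognormal(1, 1, size=layout.n_points)
        s1 = cyclic_score(x, layout)
        s2 = cyclic_score(a * x + b, layout)
        assert abs(s1 - s2) < 1e-9

    def test_normalized_spectrum_attains_zero_and_one(self, layout):
        # any non-constant segment's normalized spectrum spans [0, 1]
        rng = np.random.default_rng(3)
        seg = rng.normal(size=8)
        seg = seg - seg.mean()
        power = np.abs(np.fft.rfft(seg)[1:5]) ** 2
        norm = (power - power.min()) / (power.max() - power.min())
        assert norm.min() == 0.0 and norm.max() == 1.0


# ---------------------------------------------------------------------------
# permutation null and calling
# ---------------------------------------------------------------------------


class TestNullAndThreshold:
    def test_scores_in_unit_interval_and_deterministic(self, small_cohort):
        matrix, _ = small_cohort
        n1 = null_score_distribution(matrix, 500, seed=11)
        n2 = null_score_distribution(matrix, 500, seed=11)
        assert (n1.scores >= 0).all() and (n1.scores <= 1).all()
        np.testing.assert_array_equal(n1.scores, n2.scores)

    def test_sampled_null_matches_exhaustive_enumeration(self):
        """1 gene, 8 points: all 8! permutations vs a large sampled null."""
        layout = SamplingLayout(n_days=1)
        rng = np.random.default_rng(4)
        row = rng.lognormal(1, 1, size=8)
        perms = np.array(list(itertools.permutations(row)))
        exact = cyclic_scores(perms, layout)
        matrix = _matrix(row, layout)
        sampled = null_score_distribution(matrix, 20_000, seed=5).scores
        for q in (50, 90, 95, 98):
            lo, hi = np.percentile(exact, [q - 1.5, q + 1.5])
            assert lo <= np.percentile(sampled, q) <= hi

    def test_threshold_order_statistic_rule(self):
        null = NullDistribution(np.linspace(0.05, 0.95, 10), 10, 0)
        # top 20% of 10 scores -> 2nd-largest order statistic
        assert threshold_at_top_percentile(null, 20) == null.scores[-2]

    def test_vanishing_percentile_returns_max(self):
        null = NullDistribution(np.linspace(0, 0.9, 100), 100, 0)
        thr = threshold_at_top_percentile(null, 1e-6)
        assert thr == null.scores.max()
        called, _ = call_cycling(np.array([0.5, 0.85]), thr, null)
        assert not called.any()

    def test_extreme_thresholds(self, small_cohort):
        matrix, _ = small_cohort
        scores = cyclic_scores(matrix.to_array(), matrix.layout)
        all_called, _ = call_cycling(scores, 0.0)
        none_called, _ = call_cycling(scores, 1.01)
        assert all_called.all() and not none_called.any()

    def test_empirical_p_add_one_smoothed(self):
        null = NullDistribution(np.linspace(0, 1, 99), 99, 0)
        _, p = call_cycling(np.array([2.0]), 0.5, null)
        assert p[0] == pytest.approx(1 / 100)

    def test_fpr_calibrated_on_pure_noise(self, layout):
        """Top-2% threshold yields ~2% false calls on fresh null data."""
        cfg = ExpressionConfig(n_cycling=0, n_flat=4000)
        m1, _ = generate_expression(cfg, layout, seed=21)
        null = null_score_distribution(m1, 4000, seed=22)
        thr = threshold_at_top_percentile(null, 2.0)
        m2, _ = generate_expression(cfg, layout, seed=23)
        called, _ = call_cycling(cyclic_scores(m2.to_array(), layout), thr, null)
        half_width = 2.58 * np.sqrt(0.02 * 0.98 / 4000)
        assert abs(called.mean() - 0.02) < half_width + 0.003  # + threshold noise

    def test_sensitivity_and_fpr_against_truth(self, small_cohort):
        matrix, truth = small_cohort
        fits = detect_cycling(matrix, n_permutations=4000, seed=31)
        sens = fits.is_cycling[truth.is_cycling].mean()
        fpr = fits.is_cycling[~truth.is_cycling].mean()
        assert sens > 0.95  # recovery-chain property at noise CV 0.1
        assert fpr < 0.06


# ---------------------------------------------------------------------------
# parameter fits and phase clusters
# ---------------------------------------------------------------------------


class TestParameterFit:
    def test_noiseless_closed_form(self, layout, pure_cosine):
        period, amplitude, phase = fit_cyclic_parameters(pure_cosine, layout)
        assert period == pytest.approx(24.0, abs=1e-9)
        assert amplitude == pytest.approx(5.0, abs=1e-9)
        assert phase == pytest.approx(6.0, abs=1e-9)

    def test_shift_theorem(self, layout):
        t = layout.sample_times()
        x0 = 10 * (1 + 0.5 * np.cos(2 * np.pi * t / 24))
        _, _, ph0 = fit_cyclic_parameters(x0, layout)
        _, _, ph1 = fit_cyclic_parameters(np.roll(x0, 1), layout)
        assert ph0 == pytest.approx(0.0, abs=1e-9)
        assert ph1 == pytest.approx(3.0, abs=1e-9)

    def test_noisy_cohort_phase_recovery(self, small_cohort):
        matrix, truth = small_cohort
        arr = matrix.to_array()
        errors = []
        for i in np.flatnonzero(truth.is_cycling.to_numpy()):
            _, _, phase = fit_cyclic_parameters(arr[i], matrix.layout)
            d = abs(phase - truth.true_phase.iloc[i]) % 24
            errors.append(min(d, 24 - d))
        assert np.median(errors) <= 1.5

    def test_phase_cluster_peak_and_tie_break(self, layout):
        row = np.zeros(16)
        row[7] = row[15] = 5.0  # ZT 21 on both days
        assert assign_phase_cluster(row, layout) == 21.0
        tie = np.zeros(16)
        tie[[0, 8, 4, 12]] = 1.0  # exact ZT0/ZT12 tie
        assert assign_phase_cluster(tie, layout) == 0.0

    def test_planted_cohort_assigned_to_planted_bin(self, layout):
        t = layout.sample_times()
        rows = np.array([
            m * (1 + 0.5 * np.cos(2 * np.pi * (t - 21.0) / 24))
            for m in (5.0, 17.0, 40.0)
        ])
        for row in rows:
            assert assign_phase_cluster(row, layout) == 21.0
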
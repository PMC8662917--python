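"""Concordance statistics against hand computations and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beadprep.evaluation import (
    centered_correlation,
    classify_icc,
    density_mode,
    icc_oneway,
    mean_abs_diff,
    mode_deviation,
    paired_wilcoxon,
)


class TestCenteredCorrelation:
    def test_identical_duplicates_give_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 100)
        means = rng.uniform(0, 1, 100)
        assert centered_correlation(a, a.copy(), means) == pytest.approx(1.0)

    def test_three_probe_collinear_residuals(self):
        means = np.array([0.5, 0.5, 0.5])
        a = np.array([0.6, 0.4, 0.5])
        b = np.array([0.7, 0.3, 0.5])
        assert centered_correlation(a, b, means) == pytest.approx(1.0)

    def test_unrelated_residuals_near_zero(self):
        rng = np.random.default_rng(1)
        n = 10_000
        means = rng.uniform(0.2, 0.8, n)
        a = means + rng.normal(0, 0.05, n)
        b = means + rng.normal(0, 0.05, n)
        assert abs(centered_correlation(a, b, means)) < 3 / np.sqrt(n)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, 50)
        b = rng.uniform(0, 1, 50)
        means = rng.uniform(0, 1, 50)
        r1 = centered_correlation(a, b, means)
        shift = np.full(50, 0.1)
        r2 = centered_correlation(a + shift, b + shift, means + shift)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_residual_variance_undefined(self):
        means = np.array([0.25, 0.5, 0.75])
        a = means + 0.25  # exactly constant residuals (binary-exact values)
        b = np.array([0.3, 0.1, 0.2])
        assert np.isnan(centered_correlation(a, b, means))


class TestMeanAbsDiff:
    def test_arithmetic_and_symmetry(self):
        a = np.array([0.1, 0.3])
        b = np.array([0.2, 0.5])
        assert mean_abs_diff(a, b) == pytest.approx(0.15)
        assert mean_abs_diff(b, a) == pytest.approx(0.15)

    def test_identical_gives_zero(self):
        a = np.array([0.4, 0.6, np.nan])
        assert mean_abs_diff(a, a.copy()) == 0.0

    def test_missing_handled_jointly(self):
        a = np.array([0.1, np.nan])
        b = np.array([0.2, 0.9])
        assert mean_abs_diff(a, b) == pytest.approx(0.1)


def icc_bruteforce(x):
    """Direct one-way ANOVA sums of squares, written independently."""
    n, k = x.shape
    grand = x.mean()
    group_means = x.mean(axis=1)
    ssb = k * ((group_means - grand) ** 2).sum()
    ssw = ((x - group_means[:, None]) ** 2).sum()
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestIcc:
    def test_perfect_duplicates(self):
        rng = np.random.default_rng(0)
        pairs = rng.uniform(0, 1, (1, 50, 1))
        x = np.repeat(pairs, 2, axis=2)
        assert icc_oneway(x)[0] == pytest.approx(1.0)

    def test_noise_dominated_matches_closed_form(self):
        rng = np.random.default_rng(1)
        sb, sw = 1.0, 10.0
        subject = rng.normal(0, sb, (1, 2000, 1))
        x = subject + rng.normal(0, sw, (1, 2000, 2))
        icc = icc_oneway(x)[0]
        expected = sb**2 / (sb**2 + sw**2)
        assert icc <= 0.05
        assert icc == pytest.approx(expected, abs=0.03)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(3, 12)
            x = rng.uniform(0, 1, (1, n, 2))
            ours = icc_oneway(x)[0]
            assert ours == pytest.approx(icc_bruteforce(x[0]), abs=1e-10)

    def test_incomplete_pairs_dropped(self):
        x = np.full((1, 5, 2), 0.5)
        x[0, :, 0] = [0.1, 0.2, 0.3, 0.4, 0.5]
        x[0, 4, 1] = np.nan
        full = icc_oneway(x[:, :4])
        part = icc_oneway(x)
        assert part[0] == pytest.approx(full[0])

    def test_too_few_pairs_missing(self):
        assert np.isnan(icc_oneway(np.zeros((1, 2, 2)))[0])

    @pytest.mark.parametrize(
        "value,cls",
        [(0.49, "poor"), (0.5, "moderate"), (0.74, "moderate"),
         (0.75, "good"), (0.89, "good"), (0.9, "excellent"), (0.95, "excellent"),
         (-0.2, "poor")],
    )
    def test_classes(self, value, cls):
        assert classify_icc(value) == cls


class TestDensityMode:
    def test_symmetric_beta_mode(self):
        rng = np.random.default_rng(0)
        x = rng.beta(50, 50, 10_000)
        assert density_mode(x) == pytest.approx(0.5, abs=0.02)

    def test_constant_returns_constant(self):
        assert density_mode(np.full(200, 0.3)) == pytest.approx(0.3)

    def test_bimodal_tie_toward_lower(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0.1, 0.01, 5000), rng.normal(0.9, 0.01, 5000)])
        m = density_mode(np.clip(x, 0, 1))
        assert m == pytest.approx(0.1, abs=0.03) or m == pytest.approx(0.9, abs=0.03)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            density_mode(np.linspace(0, 1, 50))

    def test_mode_deviation_arithmetic(self):
        rng = np.random.default_rng(2)
        samples = [np.clip(rng.normal(lv, 0.005, 1000), 0, 1) for lv in (0.2, 0.45)]
        dev = mode_deviation(samples, [0.2, 0.40])
        assert dev == pytest.approx(0.025, abs=0.01)


def wilcoxon_exact_oracle(d):
    """Two-sided signed-rank p by full enumeration of sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # average ranks for ties in |d|
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    t_minus = ranks[d < 0].sum()
    t_obs = min(t_plus, t_minus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        t = sum(r for r, s in zip(ranks, signs) if s)
        if t <= t_obs:
            count += 1
    return min(1.0, 2.0 * count / 2**n)


class TestWilcoxon:
    def test_identical_vectors_give_one(self):
        a = np.arange(10.0)
        assert paired_wilcoxon(a, a.copy()) == 1.0

    def test_six_positive_differences_exact(self):
        a = np.arange(1.0, 7.0)
        b = a - np.array([0.5, 0.4, 0.3, 0.2, 0.1, 0.6])
        assert paired_wilcoxon(a, b) == pytest.approx(2 / 64)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 11))
            d = rng.normal(0.2, 1.0, n)
            d = d[d != 0]
            p = paired_wilcoxon(d, np.zeros_like(d))
            assert p == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon(np.zeros(3), np.zeros(4))


@settings(deadline=None, max_examples=25)
@given(
    st.lists(st.floats(0.01, 0.99), min_size=5, max_size=30),
    st.floats(-0.2, 0.2),
)
def test_centered_correlation_shift_property(values, shift):
    """Adding a constant to both samples and the means leaves r unchanged."""
    a = np.asarray(values)
    rng = np.random.default_rng(0)
    b = np.clip(a + rng.normal(0, 0.1, a.size), 0, 1)
    means = np.full(a.size, 0.5)
    r1 = centered_correlation(a, b, means)
    r2 = centered_correlation(a + shift, b + shift, means + shift)
    if np.isnan(r1):
        assert np.isnan(r2)
    else:
        assert r1 == pytest.approx(r2, abs=1e-9)
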
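import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circakit import (
    bingham_compare,
    circular_mean_acrophase,
    fisher_z_compare,
    fit_cosinor,
    population_mean_cosinor,
    wrap_acrophase,
    zero_amplitude_test,
)
from circakit.errors import DegenerateFitError, InsufficientDataError, UndefinedMetricError

from oracles import grid_search_cosinor

W = 2 * math.pi / 24


def cosine(t, mesor, amp, phi):
    return mesor + amp * np.cos(W * np.asarray(t, float) + phi)


class TestFitCosinor:
    def test_noiseless_closed_form(self):
        t = np.arange(24.0)
        y = 10 + 3 * np.cos(2 * np.pi * (t - 8) / 24)
        fit = fit_cosinor(t, y)
        assert fit.mesor == pytest.approx(10.0, abs=1e-8)
        assert fit.amplitude == pytest.approx(3.0, abs=1e-8)
        assert fit.acrophase == pytest.approx(-2 * math.pi * 8 / 24, abs=1e-8)
        assert fit.peak_time == pytest.approx(8.0, abs=1e-8)
        assert fit.exact_fit
        assert fit.percent_rhythm == pytest.approx(1.0)

    def test_constant_response_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_cosinor(np.arange(10.0), np.full(10, 5.0))

    def test_too_few_distinct_times(self):
        with pytest.raises(InsufficientDataError):
            fit_cosinor([0.0, 8.0, 16.0], [1.0, 2.0, 3.0])
        # 5 samples on 3 distinct clock times are still insufficient
        with pytest.raises(InsufficientDataError):
            fit_cosinor([0, 8, 16, 24, 32], [1, 2, 3, 1.1, 2.2])

    def test_percent_rhythm_equals_squared_correlation(self):
        rng = np.random.default_rng(3)
        t = np.arange(24.0)
        y = cosine(t, 5, 2, -1.0) + rng.normal(0, 1.0, 24)
        fit = fit_cosinor(t, y)
        fitted = fit.mesor + fit.beta * np.cos(W * t) + fit.gamma * np.sin(W * t)
        r = np.corrcoef(y, fitted)[0, 1]
        assert fit.percent_rhythm == pytest.approx(r**2, abs=1e-10)

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        t = np.arange(24.0)
        y = cosine(t, 5, 2, -1.3) + rng.normal(0, 0.5, 24)
        fit = fit_cosinor(t, y)
        oracle = grid_search_cosinor(t, y, phi_step=1e-3)
        assert fit.acrophase == pytest.approx(oracle["acrophase"], abs=2e-3)
        assert fit.amplitude == pytest.approx(oracle["amplitude"], rel=1e-3)
        assert fit.mesor == pytest.approx(oracle["mesor"], rel=1e-3)
        assert fit.rss <= oracle["rss"] + 1e-9

    @given(delta=st.floats(-48, 48), mesor=st.floats(1, 50), amp=st.floats(0.5, 10))
    def test_time_translation_covariance(self, delta, mesor, amp):
        rng = np.random.default_rng(11)
        t = np.arange(0, 48, 2.0)
        y = cosine(t, mesor, amp, -2.0) + rng.normal(0, 0.1, t.size)
        a = fit_cosinor(t, y)
        b = fit_cosinor(t + delta, y)
        assert b.mesor == pytest.approx(a.mesor, rel=1e-9)
        assert b.amplitude == pytest.approx(a.amplitude, rel=1e-9)
        assert b.percent_rhythm == pytest.approx(a.percent_rhythm, abs=1e-9)
        expected = wrap_acrophase(a.acrophase - W * delta)
        assert math.remainder(b.acrophase - expected, 2 * math.pi) == pytest.approx(0, abs=1e-8)

    @given(scale=st.floats(0.01, 100), shift=st.floats(-100, 100))
    def test_percent_rhythm_and_f_affine_invariant(self, scale, shift):
        rng = np.random.default_rng(13)
        t = np.arange(24.0)
        y = cosine(t, 5, 2, -1.0) + rng.normal(0, 1.0, 24)
        a = fit_cosinor(t, y)
        b = fit_cosinor(t, scale * y + shift)
        assert b.percent_rhythm == pytest.approx(a.percent_rhythm, abs=1e-9)
        assert b.f_stat == pytest.approx(a.f_stat, rel=1e-7)
        assert b.amplitude == pytest.approx(scale * a.amplitude, rel=1e-7)


class TestZeroAmplitudeTest:
    def test_noiseless_cosine_is_maximally_significant(self):
        t = np.arange(24.0)
        fit = fit_cosinor(t, cosine(t, 10, 3, -2.0))
        f, p = zero_amplitude_test(fit)
        assert p < 1e-10

    def test_needs_error_degrees_of_freedom(self):
        fit = fit_cosinor([0, 6, 12, 18.0], [1.0, 2.0, 1.2, 0.2])
        assert fit.p_value is None
        with pytest.raises(InsufficientDataError):
            zero_amplitude_test(fit)

    def test_matches_fields_on_fit(self):
        rng = np.random.default_rng(5)
        t = np.arange(24.0)
        fit = fit_cosinor(t, cosine(t, 10, 1, -1.0) + rng.normal(0, 2, 24))
        f, p = zero_amplitude_test(fit)
        assert f == pytest.approx(fit.f_stat)
        assert p == pytest.approx(fit.p_value)


class TestPopulationCosinor:
    def _fits(self, params, noise_seed=None):
        t = np.arange(0, 24, 3.0)
        out = []
        for i, (m, a, phi) in enumerate(params):
            y = cosine(t, m, a, phi)
            if noise_seed is not None:
                y = y + np.random.default_rng(noise_seed + i).normal(0, 0.01, t.size)
            out.append(fit_cosinor(t, y))
        return out

    def test_identical_subjects_reduce_to_individual(self):
        fits = self._fits([(10, 3, -2.0)] * 4)
        pop = population_mean_cosinor(fits)
        assert pop.mesor == pytest.approx(10, abs=1e-8)
        assert pop.amplitude == pytest.approx(3, abs=1e-8)
        assert pop.acrophase == pytest.approx(-2.0, abs=1e-8)

    def test_antiphase_subjects_cancel(self):
        fits = self._fits([(5, 1, 0.0), (5, 1, -math.pi)])
        pop = population_mean_cosinor(fits)
        assert pop.amplitude == pytest.approx(0.0, abs=1e-10)

    def test_population_amplitude_below_mean_individual_amplitude(self):
        fits = self._fits([(5, 2, -1.0), (5, 2, -2.5), (5, 2, -0.3)])
        pop = population_mean_cosinor(fits)
        assert pop.amplitude <= np.mean([f.amplitude for f in fits]) + 1e-12

    def test_requires_two_subjects_and_common_period(self):
        fits = self._fits([(10, 3, -2.0)])
        with pytest.raises(InsufficientDataError):
            population_mean_cosinor(fits)
        t = np.arange(0, 24, 3.0)
        odd = fit_cosinor(t, cosine(t, 10, 3, -2.0), period=12.0)
        with pytest.raises(ValueError):
            population_mean_cosinor(fits + [odd])


class TestBinghamCompare:
    def _population(self, mesor, amp, phi, k=6, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 24, 3.0)
        fits = []
        for _ in range(k):
            y = cosine(t, mesor + rng.normal(0, 0.2), amp * (1 + rng.normal(0, 0.05)),
                       phi + rng.normal(0, jitter or 0.02))
            fits.append(fit_cosinor(t, y))
        return population_mean_cosinor(fits)

    def test_identical_populations_yield_p_one(self):
        pop = self._population(10, 3, -2.0, seed=1)
        comp = bingham_compare(pop, pop)
        for test in (comp.mesor, comp.amplitude, comp.acrophase):
            assert test.difference == pytest.approx(0.0, abs=1e-12)
            assert test.p_value == pytest.approx(1.0)
        assert comp.amplitude_reliable

    def test_swapping_groups_flips_signs_not_p(self):
        p1 = self._population(10, 3, -2.0, seed=1)
        p2 = self._population(11, 2.5, -2.4, seed=2)
        ab = bingham_compare(p1, p2)
        ba = bingham_compare(p2, p1)
        for x, y in ((ab.mesor, ba.mesor), (ab.amplitude, ba.amplitude),
                     (ab.acrophase, ba.acrophase)):
            assert x.difference == pytest.approx(-y.difference)
            assert x.p_value == pytest.approx(y.p_value)

    def test_amplitude_unreliable_when_acrophases_differ(self):
        p1 = self._population(10, 3, -1.0, seed=3)
        p2 = self._population(10, 3, -2.5, seed=4)
        comp = bingham_compare(p1, p2)
        assert comp.acrophase.p_value <= 0.05
        assert not comp.amplitude_reliable

    def test_degrees_of_freedom(self):
        p1 = self._population(10, 3, -2.0, k=12, seed=5)
        p2 = self._population(10, 3, -2.0, k=11, seed=6)
        comp = bingham_compare(p1, p2)
        assert comp.mesor.df == 21

    def test_agrees_with_permutation_oracle(self):
        """Label-permutation test reaches the same accept/reject decisions."""
        rng = np.random.default_rng(17)
        t = np.arange(0, 24, 3.0)

        def subject_fits(phi, k, jitter):
            return [
                fit_cosinor(t, cosine(t, 10 + rng.normal(0, 0.3), 3, phi + rng.normal(0, jitter)))
                for _ in range(k)
            ]

        def perm_p(fits1, fits2, n_perm=10_000):
            pooled = fits1 + fits2
            k1 = len(fits1)

            def stat(fa, fb):
                pa, pb = population_mean_cosinor(fa), population_mean_cosinor(fb)
                return abs(math.remainder(pa.acrophase - pb.acrophase, 2 * math.pi))

            obs = stat(fits1, fits2)
            hits = 0
            idx = np.arange(len(pooled))
            for _ in range(n_perm):
                rng.shuffle(idx)
                fa = [pooled[i] for i in idx[:k1]]
                fb = [pooled[i] for i in idx[k1:]]
                hits += stat(fa, fb) >= obs - 1e-12
            return (hits + 1) / (n_perm + 1)

        separated = (subject_fits(-1.0, 8, 0.1), subject_fits(-2.2, 8, 0.1))
        null = (subject_fits(-1.5, 8, 0.25), subject_fits(-1.5, 8, 0.25))

        cases = [(separated[0], separated[1], True), (null[0], null[1], False)]
        for fits1, fits2, expect_reject in cases:
            bing = bingham_compare(
                population_mean_cosinor(fits1), population_mean_cosinor(fits2)
            )
            p_perm = perm_p(fits1, fits2, n_perm=2_000)
            assert (bing.acrophase.p_value <= 0.05) == expect_reject
            assert (p_perm <= 0.05) == expect_reject


def fit_with_exact_r(target_r, n=20, seed=0):
    """Build a series whose cosinor fit has exactly the requested r.

    Mix a clean cosine with noise residualized against the cosinor design;
    the orthogonal residual leaves the fitted curve untouched, so the
    observed-vs-fitted correlation is set exactly by the mixing weight.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 24, n, endpoint=False)
    c = cosine(t, 10, 3, -2.0)
    X = np.column_stack([np.ones(n), np.cos(W * t), np.sin(W * t)])
    e = rng.normal(0, 1, n)
    e -= X @ np.linalg.lstsq(X, e, rcond=None)[0]  # orthogonal to the design
    ss_c = np.sum((c - c.mean()) ** 2)
    lam = math.sqrt(ss_c * (1 / target_r**2 - 1) / np.sum(e**2))
    fit = fit_cosinor(t, c + lam * e)
    assert fit.r == pytest.approx(target_r, abs=1e-10)
    return fit


class TestFisherZ:
    def _fit_with_r(self, target_r, n=20, seed=0):
        return fit_with_exact_r(target_r, n=n, seed=seed)

    def test_equal_r_gives_zero(self):
        fit = self._fit_with_r(0.7)
        z, p = fisher_z_compare(fit, fit)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        f1 = self._fit_with_r(0.9, seed=1)
        f2 = self._fit_with_r(0.5, seed=2)
        z, p = fisher_z_compare(f1, f2)
        # closed form at r = (0.9, 0.5), n = 20 each: Z = 2.691, p = 0.0071
        assert z == pytest.approx(2.691, abs=0.05)
        assert p == pytest.approx(0.0071, abs=0.002)

    def test_antisymmetry(self):
        f1 = self._fit_with_r(0.8, seed=3)
        f2 = self._fit_with_r(0.4, seed=4)
        z12, p12 = fisher_z_compare(f1, f2)
        z21, p21 = fisher_z_compare(f2, f1)
        assert z12 == pytest.approx(-z21)
        assert p12 == pytest.approx(p21)

    def test_exact_fit_rejected(self):
        t = np.arange(24.0)
        exact = fit_cosinor(t, cosine(t, 10, 3, -2.0))
        other = self._fit_with_r(0.5, seed=5)
        with pytest.raises(UndefinedMetricError):
            fisher_z_compare(exact, other)


def test_circular_mean_handles_wraparound():
    angles = [-0.05, -2 * math.pi + 0.02 - 2 * math.pi * 0]  # -0.05 and ~-6.26 rad
    mean = circular_mean_acrophase([-0.05, -6.26])
    # both angles sit near the 0/-2pi seam; the mean must stay near it
    assert min(abs(mean), abs(mean + 2 * math.pi)) < 0.05
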
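import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circakit import (
    RhythmSpec,
    StudyConfig,
    bin_to_hours,
    collapse_duplicates,
    fit_cosinor,
    generate_activity_series,
    generate_cohort,
    generate_hormone_profile,
    generate_qpcr_profile,
    interdaily_stability,
    population_mean_cosinor,
    relative_expression,
)
from circakit.actigraphy import HourlyProfile
from circakit.errors import ConfigurationError
from circakit.synthetic import HORMONE_TIMES


class TestRhythmSpec:
    def test_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            RhythmSpec(1.0, -0.5, -1.0)
        with pytest.raises(ConfigurationError):
            RhythmSpec(1.0, 0.5, -1.0, residual_sd=-0.1)
        with pytest.raises(ConfigurationError):
            RhythmSpec(1.0, 0.5, -1.0, period=12.0)

    def test_acrophase_wrapped_on_construction(self):
        spec = RhythmSpec(1.0, 0.5, 1.0)
        assert -2 * math.pi < spec.acrophase <= 0

    def test_arrhythmic_draw_has_zero_amplitude(self):
        spec = RhythmSpec(1.0, 0.5, -1.0, arrhythmic=True, sd_amplitude=0.2)
        drawn = spec.draw_subject(np.random.default_rng(0))
        assert drawn.amplitude == 0.0


class TestDeterminism:
    def test_same_config_same_seed_identical_dataset(self):
        cfg = dict(seed=5, n_adhd=3, n_control=3, days=2)
        a = generate_cohort(StudyConfig(**cfg))
        b = generate_cohort(StudyConfig(**cfg))
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.hormones, b.hormones)
        pd.testing.assert_frame_equal(a.qpcr, b.qpcr)
        for s in a.subjects():
            pd.testing.assert_frame_equal(a.actigraphy[s].data, b.actigraphy[s].data)

    def test_different_seed_differs(self):
        a = generate_cohort(StudyConfig(seed=1, n_adhd=3, n_control=3, days=2))
        b = generate_cohort(StudyConfig(seed=2, n_adhd=3, n_control=3, days=2))
        assert not a.hormones["concentration"].equals(b.hormones["concentration"])


class TestNoiselessLimits:
    def test_hormone_profile_is_exact_cosine(self):
        spec = RhythmSpec(10.0, 3.0, -2.0944, residual_sd=0.0)
        prof = generate_hormone_profile(spec, HORMONE_TIMES, seed=0)
        assert np.allclose(prof["concentration"], spec.curve(prof["time"]), atol=1e-12)

    def test_round_trip_fit_recovers_spec(self):
        spec = RhythmSpec(10.0, 3.0, -1.7, residual_sd=0.0)
        prof = generate_hormone_profile(spec, HORMONE_TIMES, seed=0)
        fit = fit_cosinor(prof["time"].to_numpy(), prof["concentration"].to_numpy())
        assert fit.mesor == pytest.approx(10.0, abs=1e-8)
        assert fit.amplitude == pytest.approx(3.0, abs=1e-8)
        assert fit.acrophase == pytest.approx(-1.7, abs=1e-8)

    def test_amplitude_doubling_scales_fit(self):
        base = RhythmSpec(10.0, 1.5, -1.7, residual_sd=0.0)
        double = RhythmSpec(10.0, 3.0, -1.7, residual_sd=0.0)
        fits = []
        for spec in (base, double):
            prof = generate_hormone_profile(spec, HORMONE_TIMES, seed=0)
            fits.append(fit_cosinor(prof["time"].to_numpy(), prof["concentration"].to_numpy()))
        assert fits[1].amplitude == pytest.approx(2 * fits[0].amplitude, abs=1e-10)

    def test_flat_noiseless_activity_is_constant(self):
        spec = RhythmSpec(50.0, 0.0, -1.0)
        series = generate_activity_series(spec, days=2, seed=0, dispersion=None,
                                          hour_noise_sd=0.0)
        assert series.data["activity"].nunique() == 1


class TestActivitySeries:
    def test_epoch_count_and_schema(self):
        spec = RhythmSpec(33.0, 30.0, -3.67)
        series = generate_activity_series(spec, days=5, epoch_minutes=1, seed=0)
        assert len(series.data) == 5 * 1440
        assert (series.data["activity"] >= 0).all()
        assert (series.data["lux"] >= 0).all()

    def test_bad_epoch_length_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_activity_series(RhythmSpec(10, 5, -1.0), days=1, epoch_minutes=7, seed=0)

    def test_daytime_lux_exceeds_night(self):
        series = generate_activity_series(RhythmSpec(33, 30, -3.67), days=3, seed=1)
        hours = series.data.index.hour
        day = series.data.loc[(hours >= 9) & (hours < 19), "lux"].mean()
        night = series.data.loc[(hours >= 23) | (hours < 5), "lux"].mean()
        assert day > 20 * night

    def test_is_exceeds_shuffled_permutation(self):
        """A rhythmic record's IS beats its hour-shuffled permutation."""
        spec = RhythmSpec(33.0, 30.0, -3.67)
        rng = np.random.default_rng(42)
        wins = 0
        n_seeds = 100
        for _ in range(n_seeds):
            series = generate_activity_series(spec, days=5, seed=rng)
            profile = bin_to_hours(series)
            flat = profile.matrix.reshape(-1).copy()
            rng.shuffle(flat)
            shuffled = HourlyProfile(matrix=flat.reshape(profile.matrix.shape),
                                     dates=profile.dates)
            wins += interdaily_stability(profile) > interdaily_stability(shuffled)
        assert wins >= 99


class TestQpcrGenerator:
    times = (8.0, 12.0, 16.0, 20.0, 0.0, 4.0)

    def test_zero_technical_noise_gives_identical_replicates(self):
        spec = RhythmSpec(1.0, 0.5, -2.0944, residual_sd=0.0)
        wells = generate_qpcr_profile({"BMAL1": spec}, self.times, seed=0)
        spread = wells.groupby(["gene", "time"])["ct"].agg(lambda s: s.max() - s.min())
        assert (spread == 0).all()

    def test_arrhythmic_profile_rarely_tests_rhythmic(self):
        spec = RhythmSpec(1.0, 0.5, -2.0944, residual_sd=0.1, arrhythmic=True)
        rng = np.random.default_rng(0)
        nonsig = 0
        for _ in range(100):
            wells = generate_qpcr_profile({"BMAL1": spec.draw_subject(rng)}, self.times,
                                          seed=rng)
            wells.insert(0, "subject", "s")
            expr = relative_expression(collapse_duplicates(wells), target="BMAL1")
            fit = fit_cosinor(expr["time"].to_numpy(), expr["expression"].to_numpy())
            nonsig += fit.p_value > 0.05
        assert nonsig >= 90

    def test_b2m_constant_up_to_technical_noise(self):
        spec = RhythmSpec(1.0, 0.5, -2.0944, residual_sd=0.05)
        wells = generate_qpcr_profile({"BMAL1": spec}, self.times, seed=3)
        b2m = wells[wells["gene"] == "B2M"]["ct"]
        assert b2m.std() < 0.2


class TestGenerateCohort:
    def test_schema_complete(self, small_cohort, small_config):
        ds = small_cohort
        assert len(ds.metadata) == small_config.n_adhd + small_config.n_control
        assert set(ds.metadata["group"]) == {"ADHD", "control"}
        assert set(ds.hormones["analyte"]) == {"cortisol", "melatonin"}
        assert set(ds.qpcr["gene"]) == {"BMAL1", "PER2", "B2M"}
        for s in ds.subjects():
            assert len(ds.actigraphy[s].data) == small_config.days * 1440
        # one sample per subject, analyte and scheduled time
        per_subject = ds.hormones.groupby(["subject", "analyte"]).size()
        assert (per_subject == len(small_config.hormone_times)).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            StudyConfig(seed=1, n_adhd=1)
        with pytest.raises(ConfigurationError):
            StudyConfig(seed=1, hormone_times=())
        with pytest.raises(ConfigurationError):
            StudyConfig(seed=1, hormone_times=(25.0,))

    def test_population_cosinor_ci_covers_truth(self):
        """t-based 95% CI of the population mesor covers the generating value
        in >= 90% of simulated cohorts."""
        truth = RhythmSpec(0.121730139, 0.123209832, -2.136710329, residual_sd=0.05,
                           sd_mesor=0.02435, sd_amplitude=0.02464, sd_acrophase=0.4273)
        rng = np.random.default_rng(1)
        covered = 0
        n_cohorts = 100
        tcrit = stats.t.ppf(0.975, 11)
        for _ in range(n_cohorts):
            fits = []
            for _ in range(12):
                spec = truth.draw_subject(rng)
                prof = generate_hormone_profile(spec, HORMONE_TIMES, seed=rng,
                                                truncate=False)
                fits.append(fit_cosinor(prof["time"].to_numpy(),
                                        prof["concentration"].to_numpy()))
            pop = population_mean_cosinor(fits)
            half = tcrit * math.sqrt(pop.var_mesor / pop.k)
            covered += abs(pop.mesor - truth.mesor) <= half
        assert covered >= 90
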
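"""Synthetic two-group circadian cohort generator.

Emulates a small two-arm pediatric study (12 ADHD / 11 control boys) observed
at three levels over one day to several days:

* wrist actigraphy — 1-min epochs of activity counts and illuminance over
  5 consecutive days; counts follow a rectified-cosine diurnal mean curve
  with negative-binomial (overdispersed) noise, illuminance is high by day
  and near-dark at night;
* salivary hormones — cortisol (ug/dL) and melatonin (pg/mL) sampled on a
  4-hourly schedule plus a 22:00 sample (the dim-light melatonin onset
  window), each following a 24-h cosine plus Gaussian residual;
* buccal-swab qPCR — BMAL1 and PER2 expression rhythms encoded in duplicate
  Ct values against a constant B2M housekeeping baseline, so that the ddCt
  reduction recovers the generating cosine.

Group-level rhythm parameters (mesor, amplitude, acrophase) default to the
values a pilot study of this design reports; between-subject variability is
applied to each parameter independently (Gaussian, amplitude truncated at
zero) and an ``arrhythmic`` flag forces a flat expected signal with the
residual noise retained. All randomness flows from a mandatory integer seed,
so a config reproduces its cohort byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .actigraphy import EpochSeries
from .cosinor import wrap_acrophase
from .errors import ConfigurationError

__all__ = [
    "RhythmSpec",
    "StudyConfig",
    "CohortDataset",
    "default_config",
    "generate_cohort",
    "generate_activity_series",
    "generate_hormone_profile",
    "generate_qpcr_profile",
]

GROUPS = ("ADHD", "control")
HORMONES = ("cortisol", "melatonin")
TARGET_GENES = ("BMAL1", "PER2")
HOUSEKEEPING_GENE = "B2M"

#: default saliva sampling clock hours: 4-hourly plus the 22:00 DLMO-window sample
HORMONE_TIMES = (8.0, 12.0, 16.0, 20.0, 22.0, 0.0, 4.0)
#: default buccal-swab qPCR clock hours: 4-hourly over one day
QPCR_TIMES = (8.0, 12.0, 16.0, 20.0, 0.0, 4.0)

_EXPRESSION_FLOOR = 0.05  # expression cannot reach exactly 0 (log scale)
_B2M_CT = 20.0
_TARGET_CT_OFFSET = 5.0


@dataclass(frozen=True)
class RhythmSpec:
    """Group-level 24-h cosine rhythm: value(t) = mesor + amplitude*cos(w t + acrophase).

    ``sd_*`` are between-subject standard deviations of the three parameters;
    ``residual_sd`` is the within-subject residual (analyte units for
    hormones and expression; for qPCR signals it is the technical Ct noise
    in cycles). ``arrhythmic`` forces the per-subject amplitude to 0 while
    keeping the noise, modelling a flat profile.
    """

    mesor: float
    amplitude: float
    acrophase: float  # radians, (-2*pi, 0]
    period: float = 24.0
    sd_mesor: float = 0.0
    sd_amplitude: float = 0.0
    sd_acrophase: float = 0.0
    residual_sd: float = 0.0
    arrhythmic: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if min(self.sd_mesor, self.sd_amplitude, self.sd_acrophase, self.residual_sd) < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.period != 24.0:
            raise ConfigurationError("period is fixed at 24 h")
        object.__setattr__(self, "acrophase", wrap_acrophase(self.acrophase))

    def draw_subject(self, rng: np.random.Generator) -> "RhythmSpec":
        """Draw one subject's parameters around the group values.

        Mesor and acrophase are Gaussian; amplitude is Gaussian truncated at
        0 (clipped). The returned spec has zero between-subject SDs.
        """
        mesor = self.mesor + self.sd_mesor * rng.standard_normal()
        amplitude = max(0.0, self.amplitude + self.sd_amplitude * rng.standard_normal())
        acrophase = self.acrophase + self.sd_acrophase * rng.standard_normal()
        if self.arrhythmic:
            amplitude = 0.0
        return replace(
            self,
            mesor=mesor,
            amplitude=amplitude,
            acrophase=wrap_acrophase(acrophase),
            sd_mesor=0.0,
            sd_amplitude=0.0,
            sd_acrophase=0.0,
        )

    def curve(self, times_h) -> np.ndarray:
        """Noise-free cosine evaluated at clock times (hours)."""
        t = np.asarray(times_h, dtype=float)
        amp = 0.0 if self.arrhythmic else self.amplitude
        return self.mesor + amp * np.cos(2.0 * math.pi * t / self.period + self.acrophase)


def _table1_metadata_defaults() -> dict:
    """Demographics and questionnaire score distributions per group.

    (mean, sd) per (variable, group), with a clip range keeping draws inside
    each scale's plausible bounds. Questionnaire scores are opaque numeric
    columns downstream.
    """
    d = {
        "iq": {"ADHD": (95.42, 7.48), "control": (103.73, 8.36), "clip": (85, 145)},
        "age_months": {"ADHD": (117.0, 14.76), "control": (115.36, 15.01), "clip": (96, 144)},
        "height_cm": {"ADHD": (144.13, 9.86), "control": (145.00, 11.00), "clip": (110, 180)},
        "weight_kg": {"ADHD": (40.48, 13.25), "control": (36.15, 15.01), "clip": (18, 90)},
        "fbb_adhs_total": {"ADHD": (1.80, 0.45), "control": (0.50, 0.30), "clip": (0, 3)},
        "cshq_sum": {"ADHD": (40.18, 5.98), "control": (43.00, 3.57), "clip": (33, 99)},
        "cshq_bedtime_resistance": {"ADHD": (6.75, 1.06), "control": (7.09, 2.17), "clip": (6, 18)},
        "cshq_sleep_onset_delay": {"ADHD": (1.58, 0.79), "control": (1.18, 0.41), "clip": (1, 3)},
        "cshq_sleep_duration": {"ADHD": (4.50, 2.07), "control": (3.36, 0.67), "clip": (3, 9)},
        "cshq_sleep_anxiety": {"ADHD": (4.58, 1.00), "control": (4.64, 1.80), "clip": (4, 12)},
        "cshq_night_wakings": {"ADHD": (4.00, 1.50), "control": (3.45, 0.69), "clip": (3, 9)},
        "cshq_parasomnias": {"ADHD": (8.17, 1.99), "control": (8.36, 1.29), "clip": (7, 21)},
        "cshq_sdb": {"ADHD": (3.17, 1.19), "control": (3.18, 0.60), "clip": (3, 9)},
        "cshq_daytime_sleepiness": {"ADHD": (12.33, 2.87), "control": (11.18, 2.86), "clip": (8, 24)},
    }
    return d


def _default_specs() -> dict:
    """Group-level rhythm specs for every measured signal.

    Hormone and gene-expression parameters follow the chronometric values a
    pilot cohort of this design reports; activity counts (per 1-min epoch)
    are set so that hourly sums, M10/L5 and the fitted acrophase land on the
    actigraphy scale such a cohort shows (day peak mid-afternoon,
    near-zero nocturnal counts). Between-subject SDs are 20% of each
    parameter unless a published SD exists (actigraphy acrophases).
    """

    def pct20(m, a, p):
        return dict(sd_mesor=0.2 * m, sd_amplitude=0.2 * a, sd_acrophase=0.2 * abs(p))

    cortisol_adhd = RhythmSpec(0.121730139, 0.123209832, -2.136710329, residual_sd=0.05,
                               **pct20(0.121730139, 0.123209832, -2.136710329))
    cortisol_ctrl = RhythmSpec(0.16991, 0.134743, -1.77627, residual_sd=0.05,
                               **pct20(0.16991, 0.134743, -1.77627))
    melatonin_adhd = RhythmSpec(17.75686207, 12.831147, -0.490405853, residual_sd=2.0,
                                **pct20(17.75686207, 12.831147, -0.490405853))
    melatonin_ctrl = RhythmSpec(12.66987, 6.280137, -0.30878, residual_sd=2.0,
                                **pct20(12.66987, 6.280137, -0.30878))

    # counts per 1-min epoch; hourly sums then put M10 near 3.5-4e4 and L5
    # near 1e3, the scale wrist actigraphy shows in 8-12 year olds
    act_adhd = RhythmSpec(33.0, 30.0, math.radians(-210.33), sd_mesor=3.3,
                          sd_amplitude=3.6, sd_acrophase=math.radians(10.18))
    act_ctrl = RhythmSpec(35.4, 32.0, math.radians(-212.73), sd_mesor=3.5,
                          sd_amplitude=3.8, sd_acrophase=math.radians(13.81))

    # BMAL1 peaks in the morning, PER2 in the afternoon/evening in oral mucosa;
    # relative-expression mesor 1, peak/trough ratio ~3 in the rhythmic group.
    bmal1_ctrl = RhythmSpec(1.0, 0.5, -2.0944, sd_mesor=0.15, sd_amplitude=0.15,
                            sd_acrophase=0.3, residual_sd=0.1)
    per2_ctrl = RhythmSpec(1.0, 0.5, -4.1888, sd_mesor=0.15, sd_amplitude=0.15,
                           sd_acrophase=0.3, residual_sd=0.1)
    bmal1_adhd = replace(bmal1_ctrl, arrhythmic=True)
    per2_adhd = replace(per2_ctrl, arrhythmic=True)

    return {
        "activity": {"ADHD": act_adhd, "control": act_ctrl},
        "cortisol": {"ADHD": cortisol_adhd, "control": cortisol_ctrl},
        "melatonin": {"ADHD": melatonin_adhd, "control": melatonin_ctrl},
        "BMAL1": {"ADHD": bmal1_adhd, "control": bmal1_ctrl},
        "PER2": {"ADHD": per2_adhd, "control": per2_ctrl},
    }


@dataclass
class StudyConfig:
    """Full design of one synthetic cohort; the seed is mandatory."""

    seed: int
    n_adhd: int = 12
    n_control: int = 11
    days: int = 5
    epoch_minutes: int = 1
    hormone_times: tuple = HORMONE_TIMES
    qpcr_times: tuple = QPCR_TIMES
    specs: dict = field(default_factory=_default_specs)
    metadata_distributions: dict = field(default_factory=_table1_metadata_defaults)
    activity_dispersion: float = 8.0
    start_date: str = "2024-03-04"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.n_adhd < 2 or self.n_control < 2:
            raise ConfigurationError("population cosinor needs >= 2 subjects per group")
        if self.days < 1:
            raise ConfigurationError("days must be >= 1")
        if 60 % self.epoch_minutes != 0:
            raise ConfigurationError("epoch_minutes must divide 60")
        for times, label in ((self.hormone_times, "hormone"), (self.qpcr_times, "qPCR")):
            if len(times) == 0:
                raise ConfigurationError(f"empty {label} sampling schedule")
            if any(not (0 <= t < 24) for t in times):
                raise ConfigurationError(f"{label} sampling times must lie in [0, 24)")
        for signal, by_group in self.specs.items():
            for g in GROUPS:
                if g not in by_group:
                    raise ConfigurationError(f"spec for signal {signal!r} lacks group {g!r}")


@dataclass
class CohortDataset:
    """The complete two-group study bundle consumed by the pipeline."""

    metadata: pd.DataFrame  # subject, group, numeric columns
    actigraphy: dict  # subject -> EpochSeries
    hormones: pd.DataFrame  # subject, analyte, time, concentration
    qpcr: pd.DataFrame  # subject, time, gene, replicate, ct

    def subjects(self, group: str | None = None) -> list[str]:
        md = self.metadata
        if group is not None:
            md = md[md["group"] == group]
        return list(md["subject"])

    def validate(self) -> None:
        from .errors import SchemaError

        md = self.metadata
        if md["subject"].duplicated().any():
            raise SchemaError("duplicated subject ids in metadata")
        if set(md["group"].unique()) != set(GROUPS):
            raise SchemaError(f"groups must be exactly {set(GROUPS)}")
        known = set(md["subject"])
        for name, table in (("hormones", self.hormones), ("qpcr", self.qpcr)):
            orphans = set(table["subject"]) - known
            if orphans:
                raise SchemaError(f"{name} references unknown subjects: {sorted(orphans)}")
        orphans = set(self.actigraphy) - known
        if orphans:
            raise SchemaError(f"actigraphy references unknown subjects: {sorted(orphans)}")


def default_config(seed: int) -> StudyConfig:
    """The study-design defaults with the given seed."""
    return StudyConfig(seed=seed)


def generate_activity_series(
    spec: RhythmSpec,
    days: int,
    epoch_minutes: int = 1,
    seed=None,
    dispersion: float = 8.0,
    hour_noise_sd: float = 0.48,
    hour_noise_rho: float = 0.4,
    start_date: str = "2024-03-04",
) -> EpochSeries:
    """Simulate one subject's multi-day actigraphy record.

    Counts per epoch are negative-binomial around the rectified cosine mean
    ``max(0, mesor + amplitude*cos(w t + phi))`` (real accelerometry counts
    are nonnegative and overdispersed); ``dispersion`` is the NB size
    parameter (variance = mu + mu^2/dispersion; ``math.inf`` gives Poisson
    and ``None`` disables count noise entirely). On top of the cosine, a mean-one lognormal AR(1) modulation per clock
    hour (log-SD `hour_noise_sd`, lag-1 correlation `hour_noise_rho`) models
    hour-scale activity bouts and day-to-day irregularity; it leaves the
    expected curve — and hence the fitted acrophase — unchanged while
    bringing interdaily stability and intradaily variability down from their
    noiseless limits (1 and ~0.07) to the magnitudes real wrist records
    show. Set ``hour_noise_sd=0`` for a metronomic sleeper. Illuminance is
    lognormal around 250 lux between 07:00 and 21:00 and around 0.5 lux at
    night.
    """
    if days < 1:
        raise ConfigurationError("days must be >= 1")
    if 60 % epoch_minutes != 0:
        raise ConfigurationError("epoch_minutes must divide 60")
    rng = np.random.default_rng(seed)

    n = days * 24 * 60 // epoch_minutes
    index = pd.date_range(start=start_date, periods=n, freq=f"{epoch_minutes}min")
    t = index.hour + index.minute / 60.0 + index.second / 3600.0
    mu = np.maximum(0.0, spec.curve(np.asarray(t)))

    if hour_noise_sd > 0.0:
        n_hours = days * 24
        innov = rng.standard_normal(n_hours)
        logf = np.empty(n_hours)
        logf[0] = innov[0]
        rho = hour_noise_rho
        for i in range(1, n_hours):
            logf[i] = rho * logf[i - 1] + math.sqrt(1.0 - rho * rho) * innov[i]
        factor = np.exp(hour_noise_sd * logf - 0.5 * hour_noise_sd**2)
        epochs_per_hour = 60 // epoch_minutes
        mu = mu * np.repeat(factor, epochs_per_hour)

    if dispersion is None:  # noiseless limit: counts are the rounded mean curve
        counts = np.rint(mu)
    elif math.isinf(dispersion):
        counts = rng.poisson(mu)
    else:
        p = dispersion / (dispersion + mu)
        counts = np.where(mu > 0, rng.negative_binomial(dispersion, np.minimum(p, 1.0)), 0)

    daytime = (np.asarray(t) >= 7.0) & (np.asarray(t) < 21.0)
    base_lux = np.where(daytime, 250.0, 0.5)
    lux = base_lux * rng.lognormal(mean=0.0, sigma=0.8, size=n)

    data = pd.DataFrame({"activity": counts.astype(np.int64), "lux": lux}, index=index)
    data.index.name = "timestamp"
    return EpochSeries(data=data, epoch_minutes=epoch_minutes)


def generate_hormone_profile(spec: RhythmSpec, times, seed=None, truncate: bool = True) -> pd.DataFrame:
    """One subject's hormone samples: cosine + Gaussian residual per clock time.

    With ``truncate=True`` (the default) negative concentrations are clipped
    to 0, as assay readouts cannot be negative; pass ``truncate=False`` for a
    purely additive-Gaussian protocol.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ConfigurationError("empty sampling schedule")
    rng = np.random.default_rng(seed)
    conc = spec.curve(times) + spec.residual_sd * rng.standard_normal(times.size)
    if truncate:
        conc = np.maximum(conc, 0.0)
    return pd.DataFrame({"time": times, "concentration": conc})


def generate_qpcr_profile(
    specs: dict,
    times,
    seed=None,
    b2m_ct: float = _B2M_CT,
    target_offset: float = _TARGET_CT_OFFSET,
) -> pd.DataFrame:
    """One subject's duplicate-well qPCR table for the target genes plus B2M.

    The housekeeping gene B2M has constant true Ct; each target gene's true
    Ct is the B2M-anchored baseline minus log2 of its rhythmic expression,
    so that the ddCt reduction recovers the generating cosine (up to the
    reference-time normalization). Each well adds independent technical
    noise with SD ``spec.residual_sd`` cycles (the B2M wells use the largest
    residual_sd among the targets).

    Parameters
    ----------
    specs : mapping gene -> RhythmSpec
        One expression rhythm per target gene (e.g. BMAL1, PER2).
    times : clock hours
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ConfigurationError("empty sampling schedule")
    if not specs:
        raise ConfigurationError("need at least one target gene spec")
    rng = np.random.default_rng(seed)

    tech_sd_b2m = max(s.residual_sd for s in specs.values())
    rows = []
    for time in times:
        for rep in (1, 2):
            rows.append((time, HOUSEKEEPING_GENE, rep,
                         b2m_ct + tech_sd_b2m * rng.standard_normal()))
    for gene, spec in specs.items():
        expr = np.maximum(spec.curve(times), _EXPRESSION_FLOOR)
        true_ct = b2m_ct + target_offset - np.log2(expr)
        for time, ct0 in zip(times, true_ct):
            for rep in (1, 2):
                rows.append((time, gene, rep, ct0 + spec.residual_sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["time", "gene", "replicate", "ct"])


def _draw_metadata(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    subjects = [(f"A{i+1:02d}", "ADHD") for i in range(config.n_adhd)] + [
        (f"C{i+1:02d}", "control") for i in range(config.n_control)
    ]
    for subject, group in subjects:
        rec = {"subject": subject, "group": group}
        for var, dists in config.metadata_distributions.items():
            mean, sd = dists[group]
            lo, hi = dists.get("clip", (-math.inf, math.inf))
            rec[var] = float(np.clip(mean + sd * rng.standard_normal(), lo, hi))
        rows.append(rec)
    return pd.DataFrame(rows)


def generate_cohort(config: StudyConfig) -> CohortDataset:
    """Generate the complete synthetic cohort for a study configuration.

    Deterministic given the seed: the master generator is split into one
    child stream per (subject, signal) in a fixed order, so adding a signal
    or subject at the end does not disturb earlier draws.
    """
    master = np.random.default_rng(config.seed)
    meta_rng = np.random.default_rng(master.integers(2**63))
    metadata = _draw_metadata(config, meta_rng)

    actigraphy: dict[str, EpochSeries] = {}
    hormone_rows = []
    qpcr_rows = []
    for subject, group in zip(metadata["subject"], metadata["group"]):
        sub_rng = np.random.default_rng(master.integers(2**63))

        act_spec = config.specs["activity"][group].draw_subject(sub_rng)
        actigraphy[subject] = generate_activity_series(
            act_spec,
            days=config.days,
            epoch_minutes=config.epoch_minutes,
            seed=sub_rng,
            dispersion=config.activity_dispersion,
            start_date=config.start_date,
        )

        for analyte in HORMONES:
            spec = config.specs[analyte][group].draw_subject(sub_rng)
            prof = generate_hormone_profile(spec, config.hormone_times, seed=sub_rng)
            prof.insert(0, "analyte", analyte)
            prof.insert(0, "subject", subject)
            hormone_rows.append(prof)

        gene_specs = {g: config.specs[g][group].draw_subject(sub_rng) for g in TARGET_GENES}
        wells = generate_qpcr_profile(gene_specs, config.qpcr_times, seed=sub_rng)
        wells.insert(0, "subject", subject)
        qpcr_rows.append(wells)

    dataset = CohortDataset(
        metadata=metadata,
        actigraphy=actigraphy,
        hormones=pd.concat(hormone_rows, ignore_index=True),
        qpcr=pd.concat(qpcr_rows, ignore_index=True),
    )
    dataset.validate()
    return dataset
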
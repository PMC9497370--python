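"""Single and population-mean cosinor rhythmometry.

The single cosinor model fits, by ordinary least squares,

    Y(t) = M + A * cos(2*pi*t/tau + phi) + e(t)

linearized as ``Y = M + beta*cos(w t) + gamma*sin(w t)`` with
``beta = A cos(phi)``, ``gamma = -A sin(phi)`` and ``w = 2*pi/tau``.
The period ``tau`` is fixed (24 h throughout this package; no free-period
fitting). The acrophase ``phi`` is the phase angle of the fitted peak
relative to local midnight, stored in radians on ``(-2*pi, 0]`` so that the
peak clock time is ``-phi * tau / (2*pi)`` hours.

Rhythm detection uses the zero-amplitude F test; rhythm strength is the
percent rhythm (the squared correlation between observed and fitted values).
Group-level inference aggregates per-subject fits with the population-mean
cosinor and compares populations with Bingham-style t tests on the mesor,
amplitude and acrophase; rhythm strength of two fits is compared with the
Fisher z test on the observed-vs-fitted correlation coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError, UndefinedMetricError

__all__ = [
    "CosinorFit",
    "PopulationCosinor",
    "ParameterTest",
    "RhythmComparison",
    "fit_cosinor",
    "zero_amplitude_test",
    "population_mean_cosinor",
    "bingham_compare",
    "fisher_z_compare",
    "wrap_acrophase",
    "acrophase_to_degrees",
    "acrophase_to_peak_time",
    "circular_mean_acrophase",
]

DEFAULT_PERIOD = 24.0


def wrap_acrophase(phi: float) -> float:
    """Wrap a phase angle in radians onto the conventional interval (-2*pi, 0]."""
    wrapped = math.remainder(phi, 2.0 * math.pi)  # (-pi, pi]
    if wrapped > 0.0:
        wrapped -= 2.0 * math.pi
    return wrapped


def acrophase_to_degrees(phi: float) -> float:
    """Acrophase in degrees on (-360, 0], the convention of actigraphy reports."""
    return math.degrees(wrap_acrophase(phi))


def acrophase_to_peak_time(phi: float, period: float = DEFAULT_PERIOD) -> float:
    """Clock time (hours in [0, period)) of the fitted peak."""
    return (-wrap_acrophase(phi)) * period / (2.0 * math.pi) % period


def circular_mean_acrophase(phis, degrees: bool = False) -> float:
    """Circular mean of acrophase angles, mapped back onto (-2*pi, 0].

    Acrophases live on a circle; a plain arithmetic mean misbehaves near the
    wrap point, so angles are averaged as unit vectors. With ``degrees=True``
    input and output are in degrees on (-360, 0].
    """
    phis = np.asarray(phis, dtype=float)
    if degrees:
        phis = np.radians(phis)
    mean = math.atan2(np.mean(np.sin(phis)), np.mean(np.cos(phis)))
    mean = wrap_acrophase(mean)
    return math.degrees(mean) if degrees else mean


@dataclass(frozen=True)
class CosinorFit:
    """Least-squares cosinor fit of one time series at fixed period.

    Attributes
    ----------
    period : float
        Fixed period tau in hours.
    mesor : float
        Rhythm-adjusted mean (midline of the fitted cosine).
    beta, gamma : float
        Linearized coefficients of cos(wt) and sin(wt).
    amplitude : float
        Half peak-to-trough extent, ``sqrt(beta**2 + gamma**2)``.
    acrophase : float
        Peak phase angle in radians on (-2*pi, 0], midnight reference.
    n : int
        Number of observations.
    tss, rss : float
        Total and residual sums of squares.
    percent_rhythm : float
        Fraction of variance explained, ``1 - rss/tss``; equals the squared
        correlation between observed and fitted values.
    f_stat, p_value : float | None
        Zero-amplitude F test (None when n < 5 leaves no error df).
    exact_fit : bool
        True when the residuals vanish to machine precision; the F test p is
        then reported as 0.0 and must not be fed to the Fisher z test.
    """

    period: float
    mesor: float
    beta: float
    gamma: float
    amplitude: float
    acrophase: float
    n: int
    tss: float
    rss: float
    percent_rhythm: float
    f_stat: float | None = None
    p_value: float | None = None
    exact_fit: bool = False

    @property
    def r(self) -> float:
        """Correlation between observed and fitted values, sqrt(percent rhythm)."""
        return math.sqrt(max(self.percent_rhythm, 0.0))

    @property
    def acrophase_degrees(self) -> float:
        return acrophase_to_degrees(self.acrophase)

    @property
    def peak_time(self) -> float:
        return acrophase_to_peak_time(self.acrophase, self.period)


def fit_cosinor(times, values, period: float = DEFAULT_PERIOD) -> CosinorFit:
    """Fit a single-component cosinor by ordinary least squares.

    Parameters
    ----------
    times : array-like
        Sampling times in hours (clock hours or cumulative hours; only
        ``times mod period`` matters for the fixed-period fit).
    values : array-like
        Observations, same length as `times`.
    period : float
        Fixed period in hours (default 24).

    Raises
    ------
    InsufficientDataError
        Fewer than 4 distinct time points (the 3-parameter model would be
        saturated or under-determined).
    DegenerateFitError
        Constant response: amplitude is identically 0 and no rhythm
        statistics are defined.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if np.unique(np.mod(t, period)).size < 4:
        raise InsufficientDataError(
            f"cosinor fit needs >= 4 distinct time points, got {np.unique(np.mod(t, period)).size}"
        )
    if np.ptp(y) == 0.0:
        raise DegenerateFitError("constant response: cosinor fit is degenerate (amplitude 0)")

    w = 2.0 * math.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise DegenerateFitError("design matrix is rank deficient at this sampling schedule")
    mesor, beta, gamma = (float(c) for c in coef)

    fitted = X @ coef
    resid = y - fitted
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(resid**2))
    # guard tiny negative round-off
    pr = min(max(1.0 - rss / tss, 0.0), 1.0)

    amplitude = math.hypot(beta, gamma)
    acrophase = wrap_acrophase(math.atan2(-gamma, beta))
    n = int(t.size)

    exact = rss <= 1e-12 * max(tss, 1.0)
    f_stat = p_value = None
    if n >= 5:
        if exact:
            f_stat, p_value = math.inf, 0.0
        else:
            df2 = n - 3
            f_stat = ((tss - rss) / 2.0) / (rss / df2)
            p_value = float(stats.f.sf(f_stat, 2, df2))

    return CosinorFit(
        period=period,
        mesor=mesor,
        beta=beta,
        gamma=gamma,
        amplitude=amplitude,
        acrophase=acrophase,
        n=n,
        tss=tss,
        rss=rss,
        percent_rhythm=pr,
        f_stat=f_stat,
        p_value=p_value,
        exact_fit=exact,
    )


def zero_amplitude_test(fit: CosinorFit) -> tuple[float, float]:
    """F test of H0: amplitude = 0 (no 24-h rhythm).

    F = ((TSS - RSS)/2) / (RSS/(n-3)) with (2, n-3) degrees of freedom.
    Requires n >= 5 so that the error df is at least 2. An exact fit
    (RSS = 0) returns (inf, 0.0); the fit carries ``exact_fit=True``.
    """
    if fit.n <= 4:
        raise InsufficientDataError("zero-amplitude test needs n >= 5 (error df >= 2)")
    if fit.exact_fit:
        return math.inf, 0.0
    df2 = fit.n - 3
    f = ((fit.tss - fit.rss) / 2.0) / (fit.rss / df2)
    return f, float(stats.f.sf(f, 2, df2))


@dataclass(frozen=True)
class PopulationCosinor:
    """Population-mean cosinor: per-subject fits averaged on the linear scale.

    Per-subject (mesor, beta, gamma) are averaged; the population amplitude
    and acrophase come from the averaged coefficient vector, so between-
    subject phase scatter shrinks the population amplitude below the mean of
    the individual amplitudes (vector-averaging inequality).
    """

    k: int
    fits: tuple[CosinorFit, ...] = field(repr=False)
    period: float = DEFAULT_PERIOD
    mesor: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    amplitude: float = 0.0
    acrophase: float = 0.0
    var_mesor: float = 0.0
    var_beta: float = 0.0
    var_gamma: float = 0.0
    cov_beta_gamma: float = 0.0

    @property
    def var_amplitude_hat(self) -> float:
        """Delta-method variance of the population amplitude estimate."""
        b, g, a = self.beta, self.gamma, self.amplitude
        if a == 0.0:
            return math.nan
        num = b * b * self.var_beta + 2.0 * b * g * self.cov_beta_gamma + g * g * self.var_gamma
        return num / (self.k * a * a)

    @property
    def var_acrophase_hat(self) -> float:
        """Delta-method variance of the population acrophase estimate."""
        b, g, a = self.beta, self.gamma, self.amplitude
        if a == 0.0:
            return math.nan
        num = g * g * self.var_beta - 2.0 * b * g * self.cov_beta_gamma + b * b * self.var_gamma
        return num / (self.k * a**4)

    @property
    def var_mesor_hat(self) -> float:
        return self.var_mesor / self.k


def population_mean_cosinor(fits) -> PopulationCosinor:
    """Aggregate per-subject cosinor fits into a population-mean cosinor.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 subjects (no between-subject variance).
    ValueError
        Fits with mixed periods.
    """
    fits = tuple(fits)
    k = len(fits)
    if k < 2:
        raise InsufficientDataError("population-mean cosinor needs >= 2 subjects")
    periods = {f.period for f in fits}
    if len(periods) != 1:
        raise ValueError(f"all fits must share one period, got {sorted(periods)}")

    M = np.array([f.mesor for f in fits])
    B = np.array([f.beta for f in fits])
    G = np.array([f.gamma for f in fits])

    beta_bar = float(B.mean())
    gamma_bar = float(G.mean())
    amp = math.hypot(beta_bar, gamma_bar)
    phi = wrap_acrophase(math.atan2(-gamma_bar, beta_bar)) if amp > 0 else 0.0

    return PopulationCosinor(
        k=k,
        fits=fits,
        period=periods.pop(),
        mesor=float(M.mean()),
        beta=beta_bar,
        gamma=gamma_bar,
        amplitude=amp,
        acrophase=phi,
        var_mesor=float(M.var(ddof=1)),
        var_beta=float(B.var(ddof=1)),
        var_gamma=float(G.var(ddof=1)),
        cov_beta_gamma=float(np.cov(B, G, ddof=1)[0, 1]),
    )


@dataclass(frozen=True)
class ParameterTest:
    """One Bingham parameter comparison: difference, t, df, two-sided p."""

    parameter: str
    difference: float
    statistic: float
    df: int
    p_value: float
    defined: bool = True


@dataclass(frozen=True)
class RhythmComparison:
    """Between-population comparison of the three chronometric parameters.

    ``amplitude_reliable`` is False whenever the acrophase test is
    significant at 0.05: with differing acrophases the amplitude-difference
    test compares waves that peak at different times and is not
    interpretable.
    """

    mesor: ParameterTest
    amplitude: ParameterTest
    acrophase: ParameterTest
    amplitude_reliable: bool


def _t_test(name: str, diff: float, var1: float, var2: float, df: int) -> ParameterTest:
    se = math.sqrt(var1 + var2)
    if se == 0.0:
        # identical populations: difference is exactly zero or test undefined
        if diff == 0.0:
            return ParameterTest(name, 0.0, 0.0, df, 1.0)
        return ParameterTest(name, diff, math.nan, df, math.nan, defined=False)
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return ParameterTest(name, diff, t, df, min(p, 1.0))


def bingham_compare(pop1: PopulationCosinor, pop2: PopulationCosinor) -> RhythmComparison:
    """Bingham-style t tests of mesor, amplitude, and acrophase between two populations.

    The mesor test is a two-sample t on the per-subject mesor means with
    per-group variances; amplitude and acrophase use delta-method variances
    of the population estimates. All three use df = k1 + k2 - 2. The
    acrophase difference is wrapped to (-pi, pi] before testing.

    Populations with zero population amplitude have no defined acrophase, so
    their amplitude/acrophase tests are returned flagged undefined.
    """
    if pop1.period != pop2.period:
        raise ValueError("populations must share the period")
    df = pop1.k + pop2.k - 2

    mesor = _t_test(
        "mesor", pop1.mesor - pop2.mesor, pop1.var_mesor_hat, pop2.var_mesor_hat, df
    )

    if pop1.amplitude == 0.0 or pop2.amplitude == 0.0:
        nan = math.nan
        amp = ParameterTest("amplitude", nan, nan, df, nan, defined=False)
        acro = ParameterTest("acrophase", nan, nan, df, nan, defined=False)
        return RhythmComparison(mesor, amp, acro, amplitude_reliable=False)

    amp = _t_test(
        "amplitude",
        pop1.amplitude - pop2.amplitude,
        pop1.var_amplitude_hat,
        pop2.var_amplitude_hat,
        df,
    )

    dphi = math.remainder(pop1.acrophase - pop2.acrophase, 2.0 * math.pi)  # (-pi, pi]
    acro = _t_test("acrophase", dphi, pop1.var_acrophase_hat, pop2.var_acrophase_hat, df)

    reliable = not (acro.defined and not math.isnan(acro.p_value) and acro.p_value <= 0.05)
    return RhythmComparison(mesor, amp, acro, amplitude_reliable=reliable)


def fisher_z_compare(fit1: CosinorFit, fit2: CosinorFit) -> tuple[float, float]:
    """Fisher z test comparing two observed-vs-fitted correlation coefficients.

    z_g = atanh(r_g); Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided
    normal p. Used to compare the percent rhythm (r**2) of two groupwise
    cosinor fits.
    """
    for fit in (fit1, fit2):
        if fit.n <= 3:
            raise InsufficientDataError("Fisher z needs n >= 4 in each fit")
        if fit.exact_fit or fit.r >= 1.0:
            raise UndefinedMetricError(
                "r = 1 (exact fit): Fisher z is undefined; see the exact_fit flag"
            )
    z1, z2 = math.atanh(fit1.r), math.atanh(fit2.r)
    z = (z1 - z2) / math.sqrt(1.0 / (fit1.n - 3) + 1.0 / (fit2.n - 3))
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, min(p, 1.0)
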
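"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: the cosinor oracle
minimizes the residual sum of squares over an explicit acrophase grid, and
the IS/IV oracle evaluates the defining sums with plain Python loops.
"""

import math

import numpy as np


def grid_search_cosinor(times, values, period=24.0, phi_step=1e-3):
    """Exhaustive minimizer over acrophase with exact (M, A) per grid point.

    For each acrophase on a (-2*pi, 0] grid the best mesor/amplitude follow
    from a 2-parameter linear regression on cos(w t + phi); the grid point
    with the smallest RSS wins. A negative fitted amplitude is folded back
    by a half-turn phase shift.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    w = 2.0 * math.pi / period
    best = None
    for phi in np.arange(-2.0 * math.pi, 0.0, phi_step):
        reg = np.column_stack([np.ones_like(t), np.cos(w * t + phi)])
        coef, _, _, _ = np.linalg.lstsq(reg, y, rcond=None)
        rss = float(np.sum((y - reg @ coef) ** 2))
        if best is None or rss < best[0]:
            best = (rss, float(coef[0]), float(coef[1]), phi)
    rss, mesor, amp, phi = best
    if amp < 0:
        amp, phi = -amp, phi + math.pi
    phi = math.remainder(phi, 2.0 * math.pi)
    if phi > 0:
        phi -= 2.0 * math.pi
    return {"mesor": mesor, "amplitude": amp, "acrophase": phi, "rss": rss}


def is_iv_bruteforce(matrix):
    """IS and IV from their defining sums, with explicit loops.

    `matrix` is a complete days x 24 array of hourly values.
    """
    days, hours = matrix.shape
    x = [matrix[d][h] for d in range(days) for h in range(hours)]
    n = len(x)
    xbar = sum(x) / n

    hour_means = []
    for h in range(hours):
        hour_means.append(sum(matrix[d][h] for d in range(days)) / days)

    ss_total = sum((v - xbar) ** 2 for v in x)
    ss_hours = sum((m - xbar) ** 2 for m in hour_means)
    is_ = (n * ss_hours) / (hours * ss_total)

    ss_diff = sum((x[i] - x[i - 1]) ** 2 for i in range(1, n))
    iv = (n * ss_diff) / ((n - 1) * ss_total)
    return is_, iv
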
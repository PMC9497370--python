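"""Two-group comparison statistics for metadata, questionnaires and metrics.

Small-sample group contrasts use the Mann-Whitney U test with midranks for
ties, a tie-corrected normal approximation with continuity correction, and
an exact enumeration p value when the pooled sample is small enough to
enumerate (n1 + n2 <= 12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

__all__ = ["GroupComparisonResult", "mann_whitney_u", "summarize_groups", "EXACT_MAX_N"]

#: exact enumeration is feasible and reported up to this pooled sample size
EXACT_MAX_N = 12


@dataclass(frozen=True)
class GroupComparisonResult:
    """Mann-Whitney comparison of one variable between two groups."""

    variable: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    U: float
    Z: float
    p_value: float
    p_exact: float | None = None


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group A from midrank sums over the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided p by enumerating all group-label assignments.

    Conditional on the observed pooled values (midranks handle ties), U is
    symmetric around n1*n2/2, so the two-sided p is the fraction of
    assignments at least as far from the center as the observed U.
    """
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    center = n1 * n2 / 2.0
    target = abs(u_obs - center) - 1e-12
    count = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - center) >= target:
            count += 1
    return count / total


def mann_whitney_u(group_a, group_b, variable: str = "") -> GroupComparisonResult:
    """Mann-Whitney U comparison of two independent samples.

    Z uses the normal approximation with tie-corrected variance and a 0.5
    continuity correction; `p_value` is the two-sided normal p. When
    n1 + n2 <= 12 the exact enumeration p is reported alongside in
    ``p_exact``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    n1, n2, n = a.size, b.size, a.size + b.size

    u = _u_statistic(a, b)
    mu = n1 * n2 / 2.0

    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    if var <= 0.0:  # all pooled values identical
        z, p = 0.0, 1.0
    else:
        z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(var)
        p = 2.0 * float(stats.norm.sf(z))

    p_exact = _exact_two_sided_p(a, b, u) if n <= EXACT_MAX_N else None

    sd_a = float(np.std(a, ddof=1)) if n1 > 1 else math.nan
    sd_b = float(np.std(b, ddof=1)) if n2 > 1 else math.nan
    return GroupComparisonResult(
        variable=variable,
        mean_a=float(a.mean()),
        sd_a=sd_a,
        mean_b=float(b.mean()),
        sd_b=sd_b,
        U=u,
        Z=z,
        p_value=min(p, 1.0),
        p_exact=p_exact,
    )


def summarize_groups(values_by_group: dict) -> dict:
    """Mean and sample SD (n-1 denominator) per group.

    Returns ``{group: (mean, sd, n)}``; SD is NaN for single-subject groups.
    """
    out = {}
    for group, values in values_by_group.items():
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise InsufficientDataError(f"no values for group {group!r}")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else math.nan
        out[group] = (float(v.mean()), sd, int(v.size))
    return out
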
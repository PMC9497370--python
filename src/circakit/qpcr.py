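"""Relative clock-gene expression from duplicate qPCR Ct values (ddCt method).

Duplicate wells are collapsed to a mean Ct per (subject, time, gene); the
target gene is normalized to the housekeeping gene B2M (dCt = Ct_target -
Ct_housekeeping) and then to a reference condition (ddCt = dCt -
dCt_reference); relative expression is 2**(-ddCt), assuming an
amplification efficiency of 2 per cycle for both genes. By default each
subject's own first sampled time point is the reference, which preserves the
within-subject 24-h shape the cosinor stage consumes; a group-mean reference
is available via ``reference="mean"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["collapse_duplicates", "relative_expression", "DISCORDANCE_CYCLES"]

#: duplicate wells further apart than this many cycles are flagged discordant
DISCORDANCE_CYCLES = 1.0

_WELL_COLUMNS = {"subject", "time", "gene", "replicate", "ct"}


def collapse_duplicates(wells: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate wells to one mean Ct per (subject, time, gene).

    Parameters
    ----------
    wells : DataFrame
        Columns ``subject, time, gene, replicate, ct``; Ct in (0, 45).

    Returns
    -------
    DataFrame with columns ``subject, time, gene, ct, n_wells, discordant,
    singleton``. Duplicates more than 1 cycle apart are flagged discordant;
    a lone replicate is used as-is with a singleton flag.
    """
    missing = _WELL_COLUMNS - set(wells.columns)
    if missing:
        raise SchemaError(f"qPCR well table lacks columns: {sorted(missing)}")
    bad = wells[(wells["ct"] <= 0) | (wells["ct"] >= 45)]
    if len(bad):
        raise SchemaError(f"{len(bad)} Ct values outside (0, 45)")

    g = wells.groupby(["subject", "time", "gene"], sort=True)["ct"]
    out = g.agg(ct="mean", n_wells="size", spread=lambda s: s.max() - s.min()).reset_index()
    out["discordant"] = (out["n_wells"] >= 2) & (out["spread"] > DISCORDANCE_CYCLES)
    out["singleton"] = out["n_wells"] == 1
    return out.drop(columns="spread")


def relative_expression(
    mean_ct: pd.DataFrame,
    target: str,
    housekeeping: str = "B2M",
    reference: str = "first",
) -> pd.DataFrame:
    """Per-subject relative expression profile of `target` via 2**(-ddCt).

    Parameters
    ----------
    mean_ct : DataFrame
        Output of :func:`collapse_duplicates` (or any table with columns
        ``subject, time, gene, ct``).
    target, housekeeping : str
        Gene names; housekeeping Ct must be present wherever target Ct is.
        Times with no housekeeping measurement are flagged and excluded.
    reference : {"first", "mean"}
        ddCt reference condition: each subject's first sampled time point,
        or each subject's mean dCt across its time points.

    Returns
    -------
    Tidy DataFrame ``subject, gene, time, dct, ddct, expression, qc_flag``
    with expression = 2**(-ddct) > 0 and log2(expression) = -ddct exactly.
    """
    if reference not in {"first", "mean"}:
        raise ValueError("reference must be 'first' or 'mean'")
    t = mean_ct[mean_ct["gene"] == target][["subject", "time", "ct"]]
    h = mean_ct[mean_ct["gene"] == housekeeping][["subject", "time", "ct"]]
    if t.empty:
        raise SchemaError(f"no wells for target gene {target!r}")

    merged = t.merge(h, on=["subject", "time"], how="left", suffixes=("_t", "_h"))
    merged["qc_flag"] = np.where(merged["ct_h"].isna(), "missing_housekeeping", "")
    merged = merged.sort_values(["subject", "time"], kind="stable")

    rows = []
    for subject, grp in merged.groupby("subject", sort=True):
        ok = grp[grp["qc_flag"] == ""].copy()
        if ok.empty:
            continue
        dct = ok["ct_t"] - ok["ct_h"]
        ref = dct.iloc[0] if reference == "first" else dct.mean()
        ok["dct"] = dct
        ok["ddct"] = dct - ref
        ok["expression"] = np.exp2(-ok["ddct"])
        rows.append(ok)
        dropped = grp[grp["qc_flag"] != ""]
        if len(dropped):
            rows.append(dropped)
    out = pd.concat(rows, ignore_index=True)
    out["gene"] = target
    cols = ["subject", "gene", "time", "dct", "ddct", "expression", "qc_flag"]
    for c in ("dct", "ddct", "expression"):
        if c not in out:
            out[c] = np.nan
    return out[cols].sort_values(["subject", "time"], kind="stable").reset_index(drop=True)
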
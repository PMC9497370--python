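"""End-to-end study pipeline: cohort in, report tables and profile series out.

`run_study` reproduces the analysis plan of a three-level circadian pilot
study comparing an ADHD and a control group:

1. actigraphy — per-subject nonparametric metrics (IS, IV, M10, L5, RA) and
   per-subject hourly cosinor fits; a groupwise cosinor on the group-mean
   average day (percent rhythm + zero-amplitude test) and Mann-Whitney
   comparisons of the chronometric parameters;
2. hormones — groupwise cosinor per analyte (percent rhythm table), per-
   subject fits aggregated into population-mean cosinors and compared with
   Bingham parameter tests (mesor, amplitude, acrophase), plus a Fisher z
   comparison of the groupwise percent rhythms;
3. clock genes — duplicate Ct wells reduced to ddCt relative expression,
   groupwise cosinor per gene; the Bingham comparison of gene rhythms is
   only run when BOTH groups show a significant groupwise rhythm (comparing
   chronometric parameters of a non-rhythm is meaningless);
4. demographics and questionnaire scores — Mann-Whitney group comparisons.

Groupwise fits use the group-mean time profile (per-bin mean across
subjects) with n = number of time bins; population tests use per-subject
fits. Significance is marked at p <= 0.05 with no multiplicity correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .actigraphy import EpochSeries, bin_to_hours, m10_l5_ra
from .cosinor import (
    CosinorFit,
    bingham_compare,
    fisher_z_compare,
    fit_cosinor,
    population_mean_cosinor,
)
from .errors import CircakitError
from .groupstats import mann_whitney_u
from .qpcr import collapse_duplicates, relative_expression
from .synthetic import GROUPS, HORMONES, TARGET_GENES, CohortDataset, StudyConfig

__all__ = ["StudyReport", "run_study", "write_report"]

ALPHA = 0.05

DEMOGRAPHIC_VARS = ("iq", "age_months", "height_cm", "weight_kg")
ACTIGRAPHY_VARS = ("IS", "IV", "M10", "L5", "amplitude", "acrophase_deg")


def _sig(p) -> str:
    return "*" if (p is not None and not (isinstance(p, float) and math.isnan(p)) and p <= ALPHA) else ""


@dataclass
class StudyReport:
    """All table analogues and profile series of one study run."""

    demographics: pd.DataFrame  # T1
    questionnaires: pd.DataFrame  # T2
    activity_cosinor: pd.DataFrame  # T3
    actigraphy_metrics: pd.DataFrame  # T4
    hormone_cosinor: pd.DataFrame  # T5
    cortisol_comparison: pd.DataFrame  # T6
    melatonin_comparison: pd.DataFrame  # T7
    gene_cosinor: pd.DataFrame  # T8
    gene_comparisons: pd.DataFrame
    percent_rhythm_comparisons: pd.DataFrame
    profiles: dict = field(default_factory=dict)  # name -> tidy DataFrame
    manifest: dict = field(default_factory=dict)

    def tables(self) -> dict:
        return {
            "T1_demographics": self.demographics,
            "T2_questionnaires": self.questionnaires,
            "T3_activity_cosinor": self.activity_cosinor,
            "T4_actigraphy_metrics": self.actigraphy_metrics,
            "T5_hormone_cosinor": self.hormone_cosinor,
            "T6_cortisol_comparison": self.cortisol_comparison,
            "T7_melatonin_comparison": self.melatonin_comparison,
            "T8_gene_cosinor": self.gene_cosinor,
            "gene_comparisons": self.gene_comparisons,
            "percent_rhythm_comparisons": self.percent_rhythm_comparisons,
        }


class StageError(CircakitError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _mw_table(values_by_var: dict, groups_by_var: dict) -> pd.DataFrame:
    """Rows of ADHD/control mean +/- SD and Mann-Whitney U/Z/p per variable."""
    rows = []
    for var in values_by_var:
        vals = np.asarray(values_by_var[var], dtype=float)
        grps = np.asarray(groups_by_var[var])
        keep = ~np.isnan(vals)
        a = vals[keep & (grps == "ADHD")]
        c = vals[keep & (grps == "control")]
        res = mann_whitney_u(a, c, variable=var)
        rows.append(
            {
                "variable": var,
                "adhd_mean": res.mean_a,
                "adhd_sd": res.sd_a,
                "control_mean": res.mean_b,
                "control_sd": res.sd_b,
                "U": res.U,
                "Z": res.Z,
                "p": res.p_value,
                "p_exact": res.p_exact,
                "significant": _sig(res.p_value),
            }
        )
    return pd.DataFrame(rows)


def _hourly_fit(series: EpochSeries) -> tuple[CosinorFit, np.ndarray]:
    """Per-subject cosinor on the hourly activity series (bin-center times)."""
    profile = bin_to_hours(series)
    flat = profile.hourly_series()
    hours = np.tile(np.arange(24) + 0.5, profile.n_days)
    keep = ~np.isnan(flat)
    fit = fit_cosinor(hours[keep], flat[keep])
    return fit, profile.hour_means()


def _groupwise_fit(times: np.ndarray, mean_profile: np.ndarray) -> CosinorFit:
    return fit_cosinor(times, mean_profile)


def _cosinor_row(label: str, fit: CosinorFit) -> dict:
    return {
        "group": label,
        "percent_rhythm": 100.0 * fit.percent_rhythm,
        "F": fit.f_stat,
        "p": fit.p_value,
        "significant": _sig(fit.p_value),
        "mesor": fit.mesor,
        "amplitude": fit.amplitude,
        "acrophase_rad": fit.acrophase,
        "n_bins": fit.n,
    }


def _bingham_table(pops: dict, analyte: str) -> pd.DataFrame:
    comp = bingham_compare(pops["ADHD"], pops["control"])
    rows = []
    for name, test in (("mesor", comp.mesor), ("amplitude", comp.amplitude),
                       ("acrophase", comp.acrophase)):
        rows.append(
            {
                "analyte": analyte,
                "parameter": name,
                "adhd": getattr(pops["ADHD"], name if name != "acrophase" else "acrophase"),
                "control": getattr(pops["control"], name if name != "acrophase" else "acrophase"),
                "difference": test.difference,
                "t": test.statistic,
                "df": test.df,
                "p": test.p_value,
                "significant": _sig(test.p_value),
                "reliable": comp.amplitude_reliable if name == "amplitude" else True,
            }
        )
    return pd.DataFrame(rows)


def _group_mean_profile(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Mean +/- SE of `value_col` per time across subjects."""
    g = table.groupby("time")[value_col]
    out = pd.DataFrame({"mean": g.mean(), "se": g.std(ddof=1) / np.sqrt(g.size()), "n": g.size()})
    return out.reset_index()


def run_study(dataset: CohortDataset, config: StudyConfig | None = None) -> StudyReport:
    """Run the full three-level analysis on a cohort; see the module docstring."""
    dataset.validate()
    md = dataset.metadata
    groups = dict(zip(md["subject"], md["group"]))

    # ---- actigraphy level -------------------------------------------------
    stage = "actigraphy"
    try:
        act_rows = {v: [] for v in ACTIGRAPHY_VARS}
        act_groups = {v: [] for v in ACTIGRAPHY_VARS}
        hour_means_by_group: dict[str, list] = {g: [] for g in GROUPS}
        lux_by_group: dict[str, list] = {g: [] for g in GROUPS}
        for subject in dataset.subjects():
            series = dataset.actigraphy[subject]
            fit, hour_means = _hourly_fit(series)
            metrics = m10_l5_ra(bin_to_hours(series))
            values = {
                "IS": metrics.IS,
                "IV": metrics.IV,
                "M10": metrics.M10,
                "L5": metrics.L5,
                "amplitude": fit.amplitude,
                "acrophase_deg": fit.acrophase_degrees,
            }
            for var, val in values.items():
                act_rows[var].append(val)
                act_groups[var].append(groups[subject])
            hour_means_by_group[groups[subject]].append(hour_means)
            lux = series.data["lux"].groupby(series.data.index.hour).mean()
            lux_by_group[groups[subject]].append(lux.reindex(range(24)).to_numpy())

        t4 = _mw_table(act_rows, act_groups)

        bin_centers = np.arange(24) + 0.5
        t3_rows, act_group_fits = [], {}
        activity_profile_rows, lux_profile_rows = [], []
        for g in GROUPS:
            stack = np.vstack(hour_means_by_group[g])
            mean_prof = stack.mean(axis=0)
            act_group_fits[g] = _groupwise_fit(bin_centers, mean_prof)
            t3_rows.append(_cosinor_row(g, act_group_fits[g]))
            se = stack.std(axis=0, ddof=1) / math.sqrt(stack.shape[0])
            activity_profile_rows.append(
                pd.DataFrame({"group": g, "hour": bin_centers, "mean": mean_prof, "se": se})
            )
            lstack = np.vstack(lux_by_group[g])
            lux_profile_rows.append(
                pd.DataFrame(
                    {
                        "group": g,
                        "hour": bin_centers,
                        "mean": lstack.mean(axis=0),
                        "se": lstack.std(axis=0, ddof=1) / math.sqrt(lstack.shape[0]),
                    }
                )
            )
        t3 = pd.DataFrame(t3_rows)
    except CircakitError as exc:
        raise StageError(stage, exc) from exc

    # ---- endocrine level --------------------------------------------------
    stage = "hormones"
    try:
        t5_rows, pr_rows = [], []
        bingham_tables = {}
        hormone_profiles = []
        for analyte in HORMONES:
            sub = dataset.hormones[dataset.hormones["analyte"] == analyte]
            group_fit, pops = {}, {}
            for g in GROUPS:
                gsub = sub[sub["subject"].map(groups) == g]
                prof = _group_mean_profile(gsub, "concentration")
                group_fit[g] = fit_cosinor(prof["time"].to_numpy(), prof["mean"].to_numpy())
                row = _cosinor_row(g, group_fit[g])
                row["analyte"] = analyte
                t5_rows.append(row)
                fits = [
                    fit_cosinor(s["time"].to_numpy(), s["concentration"].to_numpy())
                    for _, s in gsub.groupby("subject", sort=True)
                ]
                pops[g] = population_mean_cosinor(fits)
                prof.insert(0, "group", g)
                prof.insert(0, "analyte", analyte)
                hormone_profiles.append(prof)
            z, p = fisher_z_compare(group_fit["ADHD"], group_fit["control"])
            pr_rows.append(
                {"signal": analyte, "Z": z, "p": p, "significant": _sig(p)}
            )
            bingham_tables[analyte] = _bingham_table(pops, analyte)
        t5 = pd.DataFrame(t5_rows)
        t6 = bingham_tables["cortisol"]
        t7 = bingham_tables["melatonin"]
    except CircakitError as exc:
        raise StageError(stage, exc) from exc

    # ---- molecular level --------------------------------------------------
    stage = "clock genes"
    try:
        mean_ct = collapse_duplicates(dataset.qpcr)
        t8_rows, gene_comp_rows = [], []
        gene_profiles = []
        for gene in TARGET_GENES:
            expr = relative_expression(mean_ct, target=gene)
            expr = expr[expr["qc_flag"] == ""]
            group_fit, pops, sig = {}, {}, {}
            for g in GROUPS:
                gsub = expr[expr["subject"].map(groups) == g]
                prof = _group_mean_profile(gsub, "expression")
                group_fit[g] = fit_cosinor(prof["time"].to_numpy(), prof["mean"].to_numpy())
                row = _cosinor_row(g, group_fit[g])
                row["gene"] = gene
                t8_rows.append(row)
                sig[g] = group_fit[g].p_value is not None and group_fit[g].p_value <= ALPHA
                fits = [
                    fit_cosinor(s["time"].to_numpy(), s["expression"].to_numpy())
                    for _, s in gsub.groupby("subject", sort=True)
                ]
                pops[g] = population_mean_cosinor(fits)
                prof.insert(0, "group", g)
                prof.insert(0, "gene", gene)
                gene_profiles.append(prof)
            z, p = fisher_z_compare(group_fit["ADHD"], group_fit["control"])
            pr_rows.append({"signal": gene, "Z": z, "p": p, "significant": _sig(p)})
            if all(sig.values()):
                gene_comp_rows.append(_bingham_table(pops, gene))
            else:
                not_rhythmic = [g for g in GROUPS if not sig[g]]
                gene_comp_rows.append(
                    pd.DataFrame(
                        [
                            {
                                "analyte": gene,
                                "parameter": "(skipped)",
                                "note": "chronometric comparison skipped: no significant "
                                f"groupwise rhythm in {', '.join(not_rhythmic)}",
                            }
                        ]
                    )
                )
        t8 = pd.DataFrame(t8_rows)
        gene_comparisons = pd.concat(gene_comp_rows, ignore_index=True)
    except CircakitError as exc:
        raise StageError(stage, exc) from exc

    # ---- demographics & questionnaires ------------------------------------
    stage = "group comparisons"
    try:
        demo_vars = [v for v in DEMOGRAPHIC_VARS if v in md.columns]
        quest_vars = [
            c
            for c in md.columns
            if c not in ("subject", "group") and c not in DEMOGRAPHIC_VARS
        ]
        t1 = _mw_table(
            {v: md[v].to_numpy() for v in demo_vars},
            {v: md["group"].to_numpy() for v in demo_vars},
        )
        t2 = _mw_table(
            {v: md[v].to_numpy() for v in quest_vars},
            {v: md["group"].to_numpy() for v in quest_vars},
        )
    except CircakitError as exc:
        raise StageError(stage, exc) from exc

    profiles = {
        "activity": pd.concat(activity_profile_rows, ignore_index=True),
        "illuminance": pd.concat(lux_profile_rows, ignore_index=True),
        "hormones": pd.concat(hormone_profiles, ignore_index=True),
        "gene_expression": pd.concat(gene_profiles, ignore_index=True),
    }

    manifest = {
        "package_version": __version__,
        "seed": config.seed if config is not None else None,
        "n_adhd": int((md["group"] == "ADHD").sum()),
        "n_control": int((md["group"] == "control").sum()),
        "alpha": ALPHA,
    }

    return StudyReport(
        demographics=t1,
        questionnaires=t2,
        activity_cosinor=t3,
        actigraphy_metrics=t4,
        hormone_cosinor=t5,
        cortisol_comparison=t6,
        melatonin_comparison=t7,
        gene_cosinor=t8,
        gene_comparisons=gene_comparisons,
        percent_rhythm_comparisons=pd.DataFrame(pr_rows),
        profiles=profiles,
        manifest=manifest,
    )


def write_report(report: StudyReport, outdir) -> dict:
    """Write one CSV per table, one per profile series, and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in report.tables().items():
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False)
        paths[name] = path
    for name, series in report.profiles.items():
        path = outdir / f"profile_{name}.csv"
        series.to_csv(path, index=False)
        paths[f"profile_{name}"] = path
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(report.manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path
    return paths
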
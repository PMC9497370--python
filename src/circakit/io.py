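"""Cohort CSV serialization.

A cohort is four CSV files with fixed headers:

* ``metadata.csv``   — subject, group, then numeric covariate columns
* ``actigraphy.csv`` — subject, timestamp (ISO-8601), activity, lux
* ``hormones.csv``   — subject, analyte, time (decimal clock hours), concentration
* ``qpcr.csv``       — subject, time, gene, replicate, ct
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .actigraphy import EpochSeries
from .errors import SchemaError
from .synthetic import CohortDataset

__all__ = ["write_cohort", "read_cohort", "COHORT_FILES"]

COHORT_FILES = ("metadata.csv", "actigraphy.csv", "hormones.csv", "qpcr.csv")


def write_cohort(dataset: CohortDataset, outdir) -> dict:
    """Write the four cohort CSVs into `outdir`; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["metadata"] = outdir / "metadata.csv"
    dataset.metadata.to_csv(paths["metadata"], index=False)

    frames = []
    for subject in dataset.subjects():
        df = dataset.actigraphy[subject].data.reset_index()
        df.insert(0, "subject", subject)
        frames.append(df)
    acti = pd.concat(frames, ignore_index=True)
    acti["timestamp"] = acti["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    paths["actigraphy"] = outdir / "actigraphy.csv"
    acti.to_csv(paths["actigraphy"], index=False)

    paths["hormones"] = outdir / "hormones.csv"
    dataset.hormones.to_csv(paths["hormones"], index=False)
    paths["qpcr"] = outdir / "qpcr.csv"
    dataset.qpcr.to_csv(paths["qpcr"], index=False)
    return paths


def _require_columns(df: pd.DataFrame, cols, fname: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{fname}: missing columns {sorted(missing)}")


def read_cohort(indir, skip_header_lines: int = 0) -> CohortDataset:
    """Read and validate a cohort from a directory of the four CSVs.

    ``skip_header_lines`` skips device-banner lines at the top of
    actigraphy.csv (MotionWatch-style exports prepend metadata rows).
    """
    indir = Path(indir)
    for fname in COHORT_FILES:
        if not (indir / fname).exists():
            raise SchemaError(f"cohort file missing: {indir / fname}")

    metadata = pd.read_csv(indir / "metadata.csv")
    _require_columns(metadata, ["subject", "group"], "metadata.csv")
    metadata["subject"] = metadata["subject"].astype(str)

    acti = pd.read_csv(indir / "actigraphy.csv", skiprows=skip_header_lines)
    _require_columns(acti, ["subject", "timestamp", "activity", "lux"], "actigraphy.csv")
    try:
        acti["timestamp"] = pd.to_datetime(acti["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"actigraphy.csv: malformed timestamps ({exc})") from exc

    actigraphy = {}
    for subject, grp in acti.groupby("subject", sort=False):
        df = grp.set_index("timestamp")[["activity", "lux"]].sort_index()
        deltas = df.index.to_series().diff().dropna().dt.total_seconds()
        if len(deltas) == 0:
            raise SchemaError(f"actigraphy.csv: subject {subject} has a single epoch")
        epoch_minutes = int(round(deltas.min() / 60.0)) or 1
        actigraphy[str(subject)] = EpochSeries(data=df, epoch_minutes=epoch_minutes)

    hormones = pd.read_csv(indir / "hormones.csv")
    _require_columns(hormones, ["subject", "analyte", "time", "concentration"], "hormones.csv")
    hormones["subject"] = hormones["subject"].astype(str)

    qpcr = pd.read_csv(indir / "qpcr.csv")
    _require_columns(qpcr, ["subject", "time", "gene", "replicate", "ct"], "qpcr.csv")
    qpcr["subject"] = qpcr["subject"].astype(str)

    dataset = CohortDataset(
        metadata=metadata, actigraphy=actigraphy, hormones=hormones, qpcr=qpcr
    )
    dataset.validate()
    return dataset
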
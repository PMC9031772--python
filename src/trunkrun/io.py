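"""CSV readers/writers for traces, cohort tables, feature tables and results.

Everything is plain CSV: at this data scale inspectability beats
compactness. Trace files carry a time column plus the three axes in g;
cohort files one row per subject; feature tables one row per subject with a
sidecar mapping each feature to its direction/type tags.
"""

from __future__ import annotations


from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .features import FeatureDef, FeatureTable
from .preprocessing import AccelTrace, CohortRecord, ExclusionReport, STATUSES

__all__ = [
    "read_trace",
    "write_trace",
    "read_cohort",
    "write_cohort",
    "read_feature_table",
    "write_feature_table",
    "write_stages",
    "write_exclusion_report",
]

TRACE_COLUMNS = ["t_s", "a_vt_g", "a_ml_g", "a_ap_g"]
COHORT_COLUMNS = [
    "subject_id", "gender", "mass_kg", "height_cm", "prev_injury", "insoles", "distance_m", "status",
]


def write_trace(trace: AccelTrace, path: Union[str, Path]) -> None:
    t = np.arange(len(trace)) / trace.fs
    pd.DataFrame(
        {"t_s": t, "a_vt_g": trace.vt, "a_ml_g": trace.ml, "a_ap_g": trace.ap}
    ).to_csv(path, index=False)


def read_trace(
    path: Union[str, Path], *, nominal_fs: Optional[float] = None, fs_tolerance: float = 0.01
) -> AccelTrace:
    """Read a trace CSV, inferring the sampling rate from the median timestep.

    Raises on a malformed header, non-monotone timestamps, non-finite rows
    (reported with their row numbers) or an inferred rate deviating more than
    ``fs_tolerance`` from ``nominal_fs`` (when given).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != TRACE_COLUMNS:
        raise ValueError(f"{path.name}: malformed header {list(df.columns)}, expected {TRACE_COLUMNS}")
    bad = df.index[~np.isfinite(df).all(axis=1)].tolist()
    if bad:
        raise ValueError(f"{path.name}: non-finite values in rows {bad[:10]}" + ("..." if len(bad) > 10 else ""))
    t = df["t_s"].to_numpy()
    dt = np.diff(t)
    if len(dt) and dt.min() <= 0:
        raise ValueError(f"{path.name}: timestamps are not strictly increasing")
    fs = 1.0 / float(np.median(dt)) if len(dt) else (nominal_fs or 1.0)
    if nominal_fs is not None and abs(fs - nominal_fs) / nominal_fs > fs_tolerance:
        raise ValueError(f"{path.name}: inferred fs {fs:.1f} Hz deviates >1% from nominal {nominal_fs} Hz")
    return AccelTrace(
        subject_id=path.stem,
        fs=fs,
        vt=df["a_vt_g"].to_numpy(),
        ml=df["a_ml_g"].to_numpy(),
        ap=df["a_ap_g"].to_numpy(),
    )


def write_cohort(records: Sequence[CohortRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "gender": r.gender,
                "mass_kg": r.mass_kg,
                "height_cm": r.height_cm,
                "prev_injury": None if r.prev_injury is None else int(r.prev_injury),
                "insoles": None if r.insoles is None else int(r.insoles),
                "distance_m": r.distance_m,
                "status": r.status,
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort(path: Union[str, Path]) -> list[CohortRecord]:
    """Read a cohort CSV; blank cells become missing values (exclusion fodder)."""
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != COHORT_COLUMNS:
        raise ValueError(f"{path.name}: malformed header {list(df.columns)}, expected {COHORT_COLUMNS}")
    bad_status = sorted(set(df["status"].dropna()) - set(STATUSES))
    if bad_status:
        raise ValueError(f"{path.name}: unknown status token(s) {bad_status}; expected one of {STATUSES}")

    def opt_float(v):
        return None if pd.isna(v) else float(v)

    def opt_bool(v):
        return None if pd.isna(v) else bool(int(v))

    return [
        CohortRecord(
            subject_id=str(row.subject_id),
            gender=str(row.gender),
            mass_kg=opt_float(row.mass_kg),
            height_cm=opt_float(row.height_cm),
            prev_injury=opt_bool(row.prev_injury),
            insoles=opt_bool(row.insoles),
            distance_m=opt_float(row.distance_m),
            status=str(row.status),
        )
        for row in df.itertuples()
    ]


def write_feature_table(table: FeatureTable, path: Union[str, Path]) -> None:
    """Write values to ``path`` and the category sidecar to ``<path>.defs.csv``."""
    path = Path(path)
    table.values.rename_axis("subject_id").to_csv(path)
    defs = pd.DataFrame(
        [{"name": d.name, "direction": d.direction, "ftype": d.ftype} for d in table.defs.values()]
    )
    defs.to_csv(path.with_suffix(path.suffix + ".defs.csv"), index=False)


def read_feature_table(path: Union[str, Path]) -> FeatureTable:
    path = Path(path)
    values = pd.read_csv(path, index_col="subject_id")
    defs_df = pd.read_csv(path.with_suffix(path.suffix + ".defs.csv"))
    defs = {
        row.name_: FeatureDef(row.name_, row.direction, row.ftype)
        for row in defs_df.rename(columns={"name": "name_"}).itertuples()
    }
    return FeatureTable(values=values, defs=defs)


def write_stages(stages_by_subject: dict, path: Union[str, Path]) -> None:
    rows = [
        {"subject_id": sid, "start": s.start, "end": s.end}
        for sid, stages in stages_by_subject.items()
        for s in stages
    ]
    pd.DataFrame(rows, columns=["subject_id", "start", "end"]).to_csv(path, index=False)


def write_exclusion_report(report: ExclusionReport, path: Union[str, Path]) -> None:
    rows = [{"criterion": c, "excluded": n} for c, n in report.counts.items()]
    rows.append({"criterion": "total", "excluded": report.total_excluded})
    pd.DataFrame(rows).to_csv(path, index=False)
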
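"""CSV formats and validated readers/writers.

Two long-format tables describe a dataset:

* longitudinal: columns ``id, time_days, log10_value``
* survival: columns ``id, censoring, t_left, t_right, t_cens`` with
  ``censoring`` in {interval, right}; interval rows carry the bounds and an
  empty ``t_cens``, right-censored rows the opposite.

Every id must appear exactly once in the survival table and at least once in
the longitudinal table; validation errors name the offending rows.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .model import Subject
from .simulate import SubjectTruth, truth_frame

__all__ = ["read_dataset", "write_dataset", "write_truth", "DatasetValidationError"]

LONG_COLUMNS = ["id", "time_days", "log10_value"]
SURV_COLUMNS = ["id", "censoring", "t_left", "t_right", "t_cens"]


class DatasetValidationError(ValueError):
    """Raised with a per-row account of what failed validation."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid dataset:\n" + "\n".join(f"  - {p}" for p in problems))


def write_dataset(subjects: Sequence[Subject], longitudinal_path, survival_path) -> None:
    long_rows, surv_rows = [], []
    for s in subjects:
        for t, y in zip(s.times, s.y):
            long_rows.append((s.id, t, y))
        if s.censoring == "interval":
            surv_rows.append((s.id, "interval", s.t_left, s.t_right, np.nan))
        else:
            surv_rows.append((s.id, "right", np.nan, np.nan, s.t_cens))
    # %.17g guarantees an exact float round-trip through the CSV
    pd.DataFrame(long_rows, columns=LONG_COLUMNS).to_csv(
        longitudinal_path, index=False, float_format="%.17g")
    pd.DataFrame(surv_rows, columns=SURV_COLUMNS).to_csv(
        survival_path, index=False, float_format="%.17g")


def write_truth(truths: Sequence[SubjectTruth], path) -> None:
    truth_frame(truths).to_csv(path, index=False)


def read_dataset(longitudinal_path, survival_path) -> list[Subject]:
    """Read, validate and join the two tables into a Subject list."""
    long_df = pd.read_csv(longitudinal_path, float_precision="round_trip")
    surv_df = pd.read_csv(survival_path, float_precision="round_trip")
    problems: list[str] = []

    for name, df, cols in (("longitudinal", long_df, LONG_COLUMNS),
                           ("survival", surv_df, SURV_COLUMNS)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DatasetValidationError(
                [f"{name} table is missing columns {missing}"])

    long_df["id"] = long_df["id"].astype(str)
    surv_df["id"] = surv_df["id"].astype(str)

    for col in ("time_days", "log10_value"):
        bad = long_df.index[~np.isfinite(pd.to_numeric(long_df[col], errors="coerce"))]
        for i in bad:
            problems.append(f"longitudinal row {i}: non-numeric {col}="
                            f"{long_df.loc[i, col]!r}")
    if not problems:
        dup = long_df.duplicated(subset=["id", "time_days"])
        for i in long_df.index[dup]:
            problems.append(f"longitudinal row {i}: duplicate (id, time_days)="
                            f"({long_df.loc[i, 'id']}, {long_df.loc[i, 'time_days']})")
        neg = long_df.index[long_df["time_days"] < 0]
        for i in neg:
            problems.append(f"longitudinal row {i}: negative time_days")

    dup_ids = surv_df["id"][surv_df["id"].duplicated()]
    for sid in dup_ids:
        problems.append(f"survival table: id {sid!r} appears more than once")

    long_ids = set(long_df["id"])
    surv_ids = set(surv_df["id"])
    for sid in sorted(long_ids - surv_ids):
        problems.append(f"longitudinal id {sid!r} has no survival row")
    for sid in sorted(surv_ids - long_ids):
        problems.append(f"survival id {sid!r} has no longitudinal measurements")

    subjects: list[Subject] = []
    if not problems:
        grouped = {sid: g.sort_values("time_days") for sid, g in long_df.groupby("id")}
        for i, row in surv_df.iterrows():
            sid = row["id"]
            g = grouped[sid]
            times = g["time_days"].to_numpy(dtype=float)
            y = g["log10_value"].to_numpy(dtype=float)
            cens = row["censoring"]
            try:
                if cens == "interval":
                    tL, tR = float(row["t_left"]), float(row["t_right"])
                    if not np.isfinite(tL) or not np.isfinite(tR):
                        raise ValueError("interval bounds must be numeric")
                    if tL >= tR:
                        raise ValueError(f"t_left={tL} >= t_right={tR}")
                    subjects.append(Subject(id=sid, times=times, y=y,
                                            censoring="interval",
                                            t_left=tL, t_right=tR))
                elif cens == "right":
                    tc = float(row["t_cens"])
                    if not np.isfinite(tc):
                        raise ValueError("t_cens must be numeric")
                    subjects.append(Subject(id=sid, times=times, y=y,
                                            censoring="right", t_cens=tc))
                else:
                    raise ValueError(f"unknown censoring {cens!r}")
            except ValueError as exc:
                problems.append(f"survival row {i} (id {sid!r}): {exc}")

    if problems:
        raise DatasetValidationError(problems)
    return subjects
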
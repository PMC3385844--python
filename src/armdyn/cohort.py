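"""Cohort CSV I/O.

A cohort file is a plain CSV with a small ``#``-prefixed header block
(key: value lines) followed by one row per subject x time point:

    # armdyn-cohort v1
    # ref_neglog_min: -7.4955
    # ref_neglog_max: -1.6094
    # seed: 7
    subject_id,group,phase,time_months,F,U[,wmft_seconds,aou_mean]

Times are integers on the 4-month analysis grid per phase; F and U lie in
[0, 1]. Subjects whose rows do not form a complete series for their
group/phase are excluded on read, with the reason logged.
"""

from __future__ import annotations

import logging
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .models import STEP_MONTHS, SubjectSeries

__all__ = ["SCHEMA_VERSION", "write_cohort", "read_cohort"]

SCHEMA_VERSION = "v1"
_MAGIC = "armdyn-cohort"

_EXPECTED_LENGTH = {
    ("immediate", "post_therapy"): 7,
    ("delayed", "pre_therapy"): 4,
    ("delayed", "post_therapy"): 4,
}

logger = logging.getLogger("armdyn")


def write_cohort(path, cohort: list[SubjectSeries], header: dict | None = None) -> None:
    """Write a cohort to CSV with a key-value header block."""
    path = Path(path)
    rows = []
    for s in cohort:
        for t, f, u in zip(s.times, s.F, s.U):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "phase": s.phase,
                    "time_months": int(t),
                    "F": f,
                    "U": u,
                }
            )
    frame = pd.DataFrame(rows)
    _validate_frame(frame, path)
    with path.open("w") as fh:
        fh.write(f"# {_MAGIC} {SCHEMA_VERSION}\n")
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def _validate_frame(frame: pd.DataFrame, path) -> None:
    required = {"subject_id", "group", "phase", "time_months", "F", "U"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("F", "U"):
        vals = frame[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~((vals >= 0.0) & (vals <= 1.0)))
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"{path}: row {i} column {col}: value {vals[i]} outside [0, 1]"
            )
    bad_group = ~frame["group"].isin(["immediate", "delayed"])
    if bad_group.any():
        i = int(np.flatnonzero(bad_group.to_numpy())[0])
        raise ValueError(f"{path}: row {i}: unknown group {frame['group'].iloc[i]!r}")


def read_cohort(path) -> tuple[list[SubjectSeries], dict]:
    """Read a cohort CSV; returns (series list, header metadata).

    Incomplete subjects (wrong number of points or off-grid times for their
    group/phase) are excluded with a logged reason rather than failing the
    whole file; schema violations in retained rows are hard errors naming
    the row and column.
    """
    path = Path(path)
    header: dict = {}
    body_lines = []
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith(f"# {_MAGIC}"):
            raise ValueError(f"{path}: not a cohort file (missing '# {_MAGIC}' header)")
        version = first.strip().split()[-1]
        if version != SCHEMA_VERSION:
            raise ValueError(f"{path}: unsupported schema version {version!r}")
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    frame = pd.read_csv(StringIO("".join(body_lines)))
    _validate_frame(frame, path)

    cohort: list[SubjectSeries] = []
    n_excluded = 0
    for (sid, group, phase), sub in frame.groupby(
        ["subject_id", "group", "phase"], sort=True
    ):
        sub = sub.sort_values("time_months")
        expected = _EXPECTED_LENGTH.get((group, phase))
        times = sub["time_months"].to_numpy(dtype=float)
        reason = None
        if expected is None:
            reason = f"unknown group/phase combination ({group}, {phase})"
        elif len(sub) != expected:
            reason = f"{len(sub)} points, expected {expected}"
        elif len(times) > 1 and not np.allclose(np.diff(times), STEP_MONTHS):
            reason = f"times not on the {STEP_MONTHS}-month grid"
        if reason is not None:
            n_excluded += 1
            logger.warning("excluding subject %s (%s/%s): %s", sid, group, phase, reason)
            continue
        cohort.append(
            SubjectSeries(
                subject_id=str(sid),
                group=str(group),
                phase=str(phase),
                times=times - times[0],
                F=sub["F"].to_numpy(dtype=float),
                U=sub["U"].to_numpy(dtype=float),
            )
        )
    logger.info(
        "read %s: %d series retained, %d excluded", path, len(cohort), n_excluded
    )
    return cohort, header
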
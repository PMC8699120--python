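"""Event-table dataset container and delimited-text I/O.

The dataset follows NONMEM column conventions so that real pharmacometric
datasets can be ingested unchanged: one row per event, ``EVID`` 1 for a
dose and 0 for an observation, ``AMT`` the dose amount (mg/kg) on dose
rows, ``DV`` the observed value (ug/mL for plasma rows, cumulative ug
for urine rows, tagged by ``CMT``), ``MDV`` 1 where ``DV`` is missing.
Covariates (dose arm, renal group, biochemical markers, body weight) are
carried on every row of a subject.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PKDataset", "DatasetError", "COLUMNS", "read_dataset", "write_dataset"]

COLUMNS = [
    "ID",
    "TIME",
    "EVID",
    "AMT",
    "DV",
    "MDV",
    "CMT",
    "BLQ",
    "DOSEGRP",
    "RENGRP",
    "CR",
    "BUN",
    "CCR",
    "WT",
]

MANDATORY = ["ID", "TIME", "EVID", "AMT", "DV", "MDV", "CMT"]

RENAL_GROUPS = ("normal", "mild", "severe")


class DatasetError(ValueError):
    """Raised on a structurally invalid dataset, with row-level detail."""


@dataclass
class PKDataset:
    """A validated pharmacokinetic event table.

    Wraps a :class:`pandas.DataFrame` with the columns in :data:`COLUMNS`.
    Construction validates the invariants: exactly one dose row at TIME 0
    per subject, positive non-decreasing observation times within subject,
    and DV present exactly where MDV == 0.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in MANDATORY if c not in df.columns]
        if missing:
            raise DatasetError(f"missing mandatory column(s): {missing}")
        for c in COLUMNS:
            if c not in df.columns:
                df[c] = np.nan
        df = df[COLUMNS].reset_index(drop=True)
        df["ID"] = df["ID"].astype(int)
        for c in ("EVID", "MDV", "BLQ"):
            df[c] = df[c].fillna(0).astype(int)
        for c in ("TIME", "AMT", "DV", "DOSEGRP", "CR", "BUN", "CCR", "WT"):
            df[c] = df[c].astype(float)
        self.df = df
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        df = self.df
        problems: list[str] = []
        bad_time = df.index[df["TIME"] < 0]
        for i in bad_time:
            problems.append(f"row {i}: negative TIME {df.loc[i, 'TIME']}")
        bad_cmt = df.index[~df["CMT"].isin(["plasma", "urine"])]
        for i in bad_cmt:
            problems.append(f"row {i}: unknown CMT {df.loc[i, 'CMT']!r}")
        obs = df["EVID"] == 0
        dv_missing = obs & (df["MDV"] == 0) & df["DV"].isna()
        for i in df.index[dv_missing]:
            problems.append(f"row {i}: MDV=0 but DV missing")
        for sid, sub in df.groupby("ID"):
            dose_rows = sub[sub["EVID"] == 1]
            if len(dose_rows) != 1:
                problems.append(f"subject {sid}: expected exactly 1 dose row, found {len(dose_rows)}")
            elif float(dose_rows["TIME"].iloc[0]) != 0.0:
                problems.append(f"subject {sid}: dose row not at TIME 0")
            if len(dose_rows) == 0 and len(sub[sub["EVID"] == 0]) > 0:
                problems.append(f"subject {sid}: orphan observations (no dose row)")
            sobs = sub[(sub["EVID"] == 0)]
            for cmt, grp in sobs.groupby("CMT"):
                t = grp["TIME"].to_numpy(dtype=float)
                if np.any(t <= 0):
                    rows = grp.index[t <= 0].tolist()
                    problems.append(f"subject {sid}: non-positive observation TIME at rows {rows}")
                if np.any(np.diff(t) < 0):
                    problems.append(f"subject {sid}: {cmt} observation TIMEs decrease")
        if problems:
            raise DatasetError("invalid dataset:\n  " + "\n  ".join(problems))

    # -- accessors ----------------------------------------------------------

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.df["ID"].to_numpy())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def plasma_observations(self) -> pd.DataFrame:
        """Observation rows in the plasma compartment (the modelled data)."""
        m = (self.df["EVID"] == 0) & (self.df["CMT"] == "plasma") & (self.df["MDV"] == 0)
        return self.df[m]

    def urine_observations(self) -> pd.DataFrame:
        m = (self.df["EVID"] == 0) & (self.df["CMT"] == "urine") & (self.df["MDV"] == 0)
        return self.df[m]

    def doses(self) -> pd.Series:
        """Per-subject dose in mg/kg, indexed by ID."""
        d = self.df[self.df["EVID"] == 1].set_index("ID")["AMT"]
        return d.astype(float)

    def covariates(self) -> pd.DataFrame:
        """One row per subject with dose arm, renal group and markers."""
        first = self.df.groupby("ID").first()
        return first[["DOSEGRP", "RENGRP", "CR", "BUN", "CCR", "WT"]]

    def subset(self, ids, relabel: bool = False) -> "PKDataset":
        """Dataset restricted to ``ids`` (with repeats allowed, e.g. bootstrap).

        With ``relabel`` each occurrence gets a fresh sequential ID so that
        a subject drawn twice contributes two independent subjects.
        """
        parts = []
        for new_id, sid in enumerate(ids, start=1):
            sub = self.df[self.df["ID"] == sid].copy()
            if relabel:
                sub["ID"] = new_id
            parts.append(sub)
        return PKDataset(pd.concat(parts, ignore_index=True))


def write_dataset(data: PKDataset, path) -> None:
    """Write as comma-separated text with a stable column order.

    Full ``repr`` precision; identical datasets produce byte-identical
    files.
    """
    buf = io.StringIO()
    data.df.to_csv(buf, index=False, float_format="%.17g", lineterminator="\n")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def read_dataset(path) -> PKDataset:
    """Read a comma-separated event table and validate it.

    Violations are reported with row numbers via :class:`DatasetError`.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface I/O and parse failures uniformly
        raise DatasetError(f"cannot read dataset {path}: {exc}") from exc
    return PKDataset(df)
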
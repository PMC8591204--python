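"""NONMEM-style longitudinal dataset container and CSV reader/writer.

The on-disk format is the pharmacometric lingua franca: one CSV with columns

    ID, TIME, AMT, RATE, EVID, MDV, DV, CRCL, LPM, BLQ

Dose rows carry EVID=1 with AMT (mg) and RATE (mg/h, zero-order infusion, so
the infusion duration is AMT/RATE) and an empty DV.  Observation rows carry
EVID=0 with DV (mg/L); MDV=1 marks a missing dependent value and BLQ=1 an
observation below the assay's lower limit of quantitation.  Covariate columns
(CRCL ml/min, LPM L/min, plus any extra demographics) are repeated on every
row of a subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PKDataset", "DatasetError", "read_dataset", "write_dataset"]

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV", "CRCL", "LPM", "BLQ"]


class DatasetError(ValueError):
    """Raised for malformed datasets; message names the offending row/column."""


@dataclass(frozen=True)
class PKDataset:
    """A validated cohort of dosing and observation records.

    Thin wrapper around a :class:`pandas.DataFrame` with the NONMEM-style
    column layout; rows are sorted by (ID, TIME, EVID descending) so that a
    dose at time t precedes observations at the same time, except the t=0
    predose sample which stays first.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _validate(self.df)

    # -- accessors ---------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return int(self.df["ID"].nunique())

    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def summary(self) -> str:
        obs = self.observations
        n_blq = int((obs["BLQ"] == 1).sum())
        return (
            f"{self.n_subjects} subjects, {len(self.doses)} dose records, "
            f"{self.n_observations} observation records ({n_blq} BLQ)"
        )

    def without_blq(self) -> "PKDataset":
        """Censor BLQ observations (drop the rows; M1-style handling)."""
        keep = ~((self.df["EVID"] == 0) & (self.df["BLQ"] == 1))
        return PKDataset(self.df[keep].reset_index(drop=True))

    def __eq__(self, other) -> bool:  # round-trip convenience
        if not isinstance(other, PKDataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.df.reset_index(drop=True), other.df.reset_index(drop=True),
                check_dtype=False, check_exact=False, rtol=0, atol=1e-12,
            )
        except AssertionError:
            return False
        return True


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    if df.empty or df["ID"].nunique() == 0:
        raise DatasetError("no subjects in dataset")
    bad_time = df.index[df["TIME"] < 0]
    if len(bad_time):
        raise DatasetError(f"negative TIME at row {bad_time[0]}")
    obs = df[df["EVID"] == 0]
    bad_dv = obs.index[(obs["MDV"] != 1) & obs["DV"].isna()]
    if len(bad_dv):
        raise DatasetError(f"observation row {bad_dv[0]} has MDV=0 but missing DV")
    for sid, g in df.groupby("ID", sort=False):
        if not g["TIME"].is_monotonic_increasing:
            raise DatasetError(f"TIME not sorted within subject {sid}")
        doses = g[g["EVID"] == 1]
        if len(doses):
            first_dose = doses["TIME"].iloc[0]
            early = g[(g["EVID"] == 0) & (g["TIME"] < first_dose) & (g["TIME"] > 0)]
            if len(early):
                warnings.warn(
                    f"subject {sid}: observation at t={early['TIME'].iloc[0]:g} h "
                    "precedes the first dose", stacklevel=3,
                )
        rate_rows = g[(g["EVID"] == 1) & (g["AMT"] > 0)]
        if len(rate_rows) and np.any(~(rate_rows["RATE"] > 0)):
            raise DatasetError(f"subject {sid}: infusion dose row without positive RATE")


def write_dataset(data: PKDataset, path: str | Path) -> None:
    """Write the dataset as CSV; DV of dose rows is left empty."""
    data.df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> PKDataset:
    """Read and validate a NONMEM-style CSV dataset.

    Raises
    ------
    DatasetError
        On missing columns, empty file, negative times, or unsorted records;
        messages name the first offending row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DatasetError(f"{path}: empty file, no subjects") from None
    if df.empty:
        raise DatasetError(f"{path}: no subjects")
    for col in ("TIME", "AMT", "RATE", "DV", "CRCL", "LPM"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("ID", "EVID", "MDV", "BLQ"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return PKDataset(df)
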
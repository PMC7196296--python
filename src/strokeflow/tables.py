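"""Tabular artifacts: the atlas region table and the healthy reference.

The region table enumerates atlas regions (one row per region id, with
bilateral regions flagged ``both``); exclusions are explicit flagged rows,
never silent deletions.  The healthy reference stores, per (region,
hemisphere), the mean, SD and cohort size of relative rCBF in healthy
animals; its mean ± 2SD bands define the 95% normality interval used by
every downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HEMISPHERE_CODES = {
    "left": "left", "l": "left",
    "right": "right", "r": "right",
    "both": "both", "b": "both",
}

REGION_TABLE_COLUMNS = ["region_id", "name", "hemisphere", "cortical", "is_ventricle", "excluded"]


@dataclass
class RegionTable:
    """Atlas region bookkeeping with explicit exclusion flags."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = {"region_id", "name", "hemisphere"} - set(df.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("no regions in table")
        df["region_id"] = df["region_id"].astype(int)
        if df["region_id"].duplicated().any():
            dup = df.loc[df["region_id"].duplicated(), "region_id"].tolist()
            raise ValueError(f"duplicate region_id(s): {dup}")
        hemi = df["hemisphere"].astype(str).str.lower()
        bad = sorted(set(hemi) - set(HEMISPHERE_CODES))
        if bad:
            raise ValueError(f"unknown hemisphere code(s): {bad}")
        df["hemisphere"] = hemi.map(HEMISPHERE_CODES)
        for col, default in (("cortical", True), ("is_ventricle", False), ("excluded", False)):
            if col not in df.columns:
                df[col] = default
            df[col] = df[col].astype(bool)
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def region_ids(self) -> np.ndarray:
        return self.frame["region_id"].to_numpy()

    @property
    def active(self) -> pd.DataFrame:
        """Non-excluded, non-ventricle rows."""
        f = self.frame
        return f[~f["excluded"] & ~f["is_ventricle"]]

    @property
    def n_active(self) -> int:
        return len(self.active)

    def with_exclusions(self, no_data=(), incomplete=()) -> "RegionTable":
        """Flag the given region ids as excluded (see :mod:`strokeflow.regions`)."""
        ids = list(no_data) + list(incomplete)
        known = set(self.frame["region_id"])
        unknown = [i for i in ids if i not in known]
        if unknown:
            raise ValueError(f"unknown region id(s) in exclusion list: {unknown}")
        df = self.frame.copy()
        df.loc[df["region_id"].isin(ids), "excluded"] = True
        out = RegionTable(df)
        return out


@dataclass
class HealthyReference:
    """Per-(region, hemisphere) mean/SD/n of healthy relative rCBF.

    The ``mean ± 2*sd`` interval is the healthy 95% band of a region;
    voxels and group means are classified against it.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = {"region_id", "hemisphere", "mean", "sd", "n"} - set(df.columns)
        if missing:
            raise ValueError(f"healthy reference missing columns: {sorted(missing)}")
        df["region_id"] = df["region_id"].astype(int)
        df["hemisphere"] = df["hemisphere"].astype(str).str.lower().map(HEMISPHERE_CODES)
        if df["hemisphere"].isna().any():
            raise ValueError("unknown hemisphere code in healthy reference")
        if df.duplicated(subset=["region_id", "hemisphere"]).any():
            raise ValueError("duplicate (region_id, hemisphere) in healthy reference")
        if (df["sd"] < 0).any():
            raise ValueError("negative SD in healthy reference")
        if (df["n"] < 1).any():
            raise ValueError("cohort size n must be >= 1")
        self.frame = df.reset_index(drop=True)
        self._idx = self.frame.set_index(["region_id", "hemisphere"])

    def band(self, region_id: int, hemisphere: str, k: float = 2.0) -> tuple[float, float]:
        """The healthy (mean - k*SD, mean + k*SD) band for one region."""
        row = self.row(region_id, hemisphere)
        return (row["mean"] - k * row["sd"], row["mean"] + k * row["sd"])

    def row(self, region_id: int, hemisphere: str) -> pd.Series:
        try:
            return self._idx.loc[(int(region_id), hemisphere)]
        except KeyError:
            raise KeyError(
                f"region {region_id} ({hemisphere}) has no healthy reference row"
            ) from None

    def has(self, region_id: int, hemisphere: str) -> bool:
        return (int(region_id), hemisphere) in self._idx.index

    @classmethod
    def from_cohort(cls, values: pd.DataFrame) -> "HealthyReference":
        """Build the reference from per-animal region means.

        ``values`` has columns animal, region_id, hemisphere, rcbf; SD is the
        ddof=1 standard deviation across animals (0 when n == 1).
        """
        g = values.groupby(["region_id", "hemisphere"])["rcbf"]
        df = g.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        df["sd"] = df["sd"].fillna(0.0)
        return cls(df.reset_index())
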
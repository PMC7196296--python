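"""Neurological deficit scoring and cylinder-test aggregation.

General deficits: posture (0-4), spontaneous activity (0-4), hair (0-2) and
eyes (0-4); the eye score recovers by day 8 in all groups and is therefore
excluded from the cumulative general score, whose range is 0-10.  Focal
deficits: body symmetry, gait, forelimb symmetry, compulsory circling and
whisker response, each 0-4, cumulative range 0-20.  Epileptic behaviour,
circling behaviour and climbing are structurally absent from the sheet.

The cylinder test counts wall touches of each forelimb over two minutes;
the reported asymmetry index is the unimpaired-use fraction
(unimpaired / total; 0.5 = symmetric use), with raw counts preserved so any
other index is recomputable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

GENERAL_ITEMS = {"posture": 4, "activity": 4, "hair": 2, "eyes": 4}
FOCAL_ITEMS = {"body_symmetry": 4, "gait": 4, "limb_symmetry": 4,
               "circling": 4, "whisker": 4}
SCORING_DAYS = (4, 8, 11, 15, 18, 21)

#: items entering the cumulative general score (eyes excluded by design)
CUMULATIVE_GENERAL_ITEMS = ("posture", "activity", "hair")


def validate_score_sheet(sheet: pd.DataFrame, allow_any_days: bool = False) -> pd.DataFrame:
    """Validate ranges, required columns and scoring days of a score sheet."""
    required = {"animal", "day", *GENERAL_ITEMS, *FOCAL_ITEMS}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"score sheet missing columns: {sorted(missing)}")
    if sheet[list(GENERAL_ITEMS) + list(FOCAL_ITEMS)].isna().any().any():
        bad = [c for c in (*GENERAL_ITEMS, *FOCAL_ITEMS) if sheet[c].isna().any()]
        raise ValueError(f"missing entries in item(s): {bad}")
    for item, mx in {**GENERAL_ITEMS, **FOCAL_ITEMS}.items():
        vals = sheet[item]
        if (vals < 0).any() or (vals > mx).any():
            raise ValueError(f"score out of range for {item!r} (allowed 0-{mx})")
    if not allow_any_days:
        bad_days = sorted(set(sheet["day"]) - set(SCORING_DAYS))
        if bad_days:
            raise ValueError(f"unexpected scoring day(s) {bad_days}; "
                             f"expected {SCORING_DAYS}")
    return sheet


def cumulative_general(sheet: pd.DataFrame, **kw) -> pd.DataFrame:
    """Cumulative general deficit score per animal x day (0-10, eyes excluded)."""
    sheet = validate_score_sheet(sheet, **kw)
    keep = [c for c in ("animal", "group", "day") if c in sheet.columns]
    out = sheet[keep].copy()
    out["score"] = sheet[list(CUMULATIVE_GENERAL_ITEMS)].sum(axis=1)
    return out


def cumulative_focal(sheet: pd.DataFrame, **kw) -> pd.DataFrame:
    """Cumulative focal deficit score per animal x day (0-20)."""
    sheet = validate_score_sheet(sheet, **kw)
    keep = [c for c in ("animal", "group", "day") if c in sheet.columns]
    out = sheet[keep].copy()
    out["score"] = sheet[list(FOCAL_ITEMS)].sum(axis=1)
    return out


def cylinder_asymmetry(records: pd.DataFrame) -> pd.DataFrame:
    """Unimpaired-forelimb use fraction per animal x day.

    Zero total touches yields an undefined (NaN) fraction with the
    ``undefined`` flag set; raw counts are carried through.
    """
    required = {"animal", "day", "impaired_touches", "unimpaired_touches"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"cylinder record missing columns: {sorted(missing)}")
    if (records[["impaired_touches", "unimpaired_touches"]] < 0).any().any():
        raise ValueError("touch counts must be non-negative")
    out = records.copy()
    total = out["impaired_touches"] + out["unimpaired_touches"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["asymmetry"] = np.where(total > 0,
                                    out["unimpaired_touches"] / total, np.nan)
    out["undefined"] = total == 0
    return out


def group_compare(a, b, min_n_normality: int = 3) -> dict:
    """Welch's unpaired two-sample t-test with per-group normality check.

    Returns the t statistic, p-value, per-group mean ± SEM, and the
    Shapiro–Wilk p per group (NaN below ``min_n_normality``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")

    def _shapiro(v):
        if len(v) < min_n_normality or np.ptp(v) == 0:
            return float("nan")
        return float(stats.shapiro(v).pvalue)

    from .regions import welch_ttest
    t, p = welch_ttest(a, b)
    return {
        "t": t, "p": p,
        "n_a": int(len(a)), "n_b": int(len(b)),
        "mean_a": float(a.mean()), "sem_a": float(stats.sem(a)) if len(a) > 1 else 0.0,
        "mean_b": float(b.mean()), "sem_b": float(stats.sem(b)) if len(b) > 1 else 0.0,
        "shapiro_p_a": _shapiro(a), "shapiro_p_b": _shapiro(b),
    }


def group_summaries(scores: pd.DataFrame, value: str = "score") -> pd.DataFrame:
    """Per-day group mean ± SEM plus the treated-vs-control Welch test."""
    if "group" not in scores.columns:
        raise ValueError("scores need a 'group' column")
    rows = []
    for day, sub in scores.groupby("day"):
        groups = {g: s[value].to_numpy() for g, s in sub.groupby("group")}
        row = {"day": int(day)}
        for g, v in groups.items():
            v = v[np.isfinite(v)]
            row[f"mean_{g}"] = float(v.mean()) if len(v) else float("nan")
            row[f"sem_{g}"] = float(stats.sem(v)) if len(v) > 1 else float("nan")
            row[f"n_{g}"] = int(len(v))
        if {"treated", "control"} <= set(groups):
            va = groups["treated"][np.isfinite(groups["treated"])]
            vb = groups["control"][np.isfinite(groups["control"])]
            if len(va) >= 2 and len(vb) >= 2:
                cmp = group_compare(va, vb)
                row["t"] = cmp["t"]
                row["p"] = cmp["p"]
        rows.append(row)
    return pd.DataFrame(rows).sort_values("day").reset_index(drop=True)
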
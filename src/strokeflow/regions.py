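"""Atlas-region statistics: exclusions, region rCBF, recovery classes, shells.

A region is *affected* when its group-mean rCBF at the baseline day falls
outside the healthy mean ± 2SD band of that region (and hemisphere).  An
affected region is *recovered* at a later day when its group values are no
longer distinguishable from healthy — by default when the group mean has
returned inside the band (``mode="band"``); a Welch two-sample t-test
against the healthy cohort (``mode="ttest"``) is available as the
alternative criterion.  A recovered region whose mean exceeds the upper
band is flagged ``hyper_after_recovery`` and still counts as recovered.

Shell profiles bin the classified voxels by Euclidean distance from the
injection site (voxel-center convention); *affected* tissue is the union of
hypo- and hyperperfused voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import LabelVolume, require_congruent
from .perfusion import ParametricMap, PerfusionClassification
from .tables import HealthyReference, RegionTable

RECOVERED_STATUSES = ("recovered", "hyper_after_recovery")


def apply_region_exclusions(table: RegionTable, no_data=(), incomplete=()) -> RegionTable:
    """Flag regions without (or with incomplete) measurement data as excluded.

    Exclusions are explicit flagged rows, never silent deletions; unknown
    ids raise.
    """
    return table.with_exclusions(no_data=no_data, incomplete=incomplete)


def region_rcbf(pmap: ParametricMap, labels: LabelVolume, table: RegionTable,
                include_excluded: bool = False) -> pd.DataFrame:
    """Mean rCBF over each active region's finite voxels, per hemisphere.

    Returns columns region_id, hemisphere, rcbf, n_voxels, missing; empty
    regions are flagged missing (rcbf NaN) rather than dropped.
    """
    vol = pmap.rcbf
    require_congruent(vol, labels, what="map/labels")
    rows_src = table.frame if include_excluded else table.active
    rows_src = rows_src[~rows_src["is_ventricle"]]
    inside = (labels.region_ids > 0) & vol.finite_mask
    max_id = int(max(labels.region_ids.max(), rows_src["region_id"].max()))
    hemi_idx = (labels.hemisphere_ids == LabelVolume.HEMI_RIGHT).astype(np.int8)
    key = labels.region_ids[inside] * 2 + hemi_idx[inside]
    sums = np.bincount(key, weights=vol.values[inside], minlength=2 * (max_id + 1))
    counts = np.bincount(key, minlength=2 * (max_id + 1))
    out = []
    for hemi, hcode in (("left", 0), ("right", 1)):
        for rid in rows_src["region_id"]:
            k = int(rid) * 2 + hcode
            n = int(counts[k])
            mean = float(sums[k] / n) if n else float("nan")
            out.append({"region_id": int(rid), "hemisphere": hemi,
                        "rcbf": mean, "n_voxels": n, "missing": n == 0})
    return pd.DataFrame(out)


def study_region_means(study, alpha: float | None = None) -> pd.DataFrame:
    """Per-animal region rCBF for every timepoint of a phantom study.

    Convenience driver: builds each animal's parametric map and extracts
    region means.  Columns: animal, group, day, region_id, hemisphere, rcbf.
    """
    from .perfusion import parametric_map, DEFAULT_ALPHA

    frames = []
    for animal in study.animals:
        for day, spect in animal.spect.items():
            pmap = parametric_map(spect, study.labels,
                                  alpha=alpha or DEFAULT_ALPHA)
            df = region_rcbf(pmap, study.labels, study.region_table)
            df = df.assign(animal=animal.animal_id, group=animal.group,
                           day=int(day))
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def welch_ttest(a, b) -> tuple[float, float]:
    """Welch's unpaired t-test, defined also for degenerate (constant) samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per sample")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class RecoveryReport:
    """Region x group x timepoint recovery classification.

    ``table`` rows: group, region_id, day, mean, se, n, lo, hi, p_healthy,
    affected, status.  Statuses are recomputable from the stored means/SEs
    and the healthy reference alone (band mode).
    """

    table: pd.DataFrame
    hemisphere: str
    mode: str
    sig_level: float
    baseline_day: int

    def recovered_ids(self, group: str, day: int) -> list[int]:
        t = self.table
        sel = t[(t["group"] == group) & (t["day"] == day)
                & t["status"].isin(RECOVERED_STATUSES)]
        return sorted(int(r) for r in sel["region_id"])

    def affected_ids(self, group: str) -> list[int]:
        t = self.table
        sel = t[(t["group"] == group) & (t["day"] == self.baseline_day)
                & t["affected"]]
        return sorted(int(r) for r in sel["region_id"])

    def summary(self, day: int) -> dict:
        rec_t = set(self.recovered_ids("treated", day))
        rec_c = set(self.recovered_ids("control", day))
        return {
            "day": int(day),
            "treated_affected": len(self.affected_ids("treated")),
            "control_affected": len(self.affected_ids("control")),
            "treated_recovered": len(rec_t),
            "control_recovered": len(rec_c),
            "shared": len(rec_t & rec_c),
            "treated_exclusive": len(rec_t - rec_c),
            "control_exclusive": len(rec_c - rec_t),
            "hyper_after_recovery": sorted(
                int(r) for r in self.table[
                    (self.table["day"] == day)
                    & (self.table["status"] == "hyper_after_recovery")
                ]["region_id"].unique()),
        }


def classify_recovery(region_means: pd.DataFrame, healthy: HealthyReference,
                      sig_level: float = 0.05, mode: str = "band",
                      hemisphere: str = "left", k_sd: float = 2.0,
                      baseline_day: int | None = None,
                      healthy_values: pd.DataFrame | None = None) -> RecoveryReport:
    """Classify regions as regenerated / non-regenerated per group and day.

    Parameters
    ----------
    region_means : DataFrame
        Per-animal region means: animal, group, day, region_id, hemisphere,
        rcbf (as from :func:`study_region_means`).
    healthy : HealthyReference
        Defines the mean ± ``k_sd``·SD normality band per region.
    mode : {"band", "ttest"}
        Recovery criterion: group mean back inside the band, or Welch
        t-test vs the healthy cohort at ``sig_level`` (needs
        ``healthy_values`` with per-animal healthy region means).
    """
    if mode not in ("band", "ttest"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "ttest" and healthy_values is None:
        raise ValueError("ttest mode needs per-animal healthy_values")
    df = region_means[region_means["hemisphere"] == hemisphere]
    if df.empty:
        raise ValueError(f"no region means for hemisphere {hemisphere!r}")
    days = sorted(df["day"].unique())
    baseline_day = days[0] if baseline_day is None else int(baseline_day)
    if baseline_day not in days:
        raise ValueError(f"baseline day {baseline_day} not in study days {days}")

    n_per_group = df.groupby("group")["animal"].nunique()
    if (n_per_group < 2).any():
        raise ValueError("need >= 2 animals per group")

    hv = None
    if healthy_values is not None:
        hv = healthy_values[healthy_values["hemisphere"] == hemisphere] \
            .set_index("region_id")

    rows = []
    for (group, rid), sub in df.groupby(["group", "region_id"]):
        lo, hi = healthy.band(rid, hemisphere, k=k_sd)
        # numerical guard for degenerate (zero-SD) bands
        tol = 1e-9 * (abs(lo) + abs(hi) + 1.0)
        lo, hi = lo - tol, hi + tol
        per_day = sub.groupby("day")["rcbf"]
        means = per_day.mean()
        ses = per_day.sem()
        ns = per_day.count()
        base_mean = float(means.loc[baseline_day])
        affected = not (lo <= base_mean <= hi)
        for day in days:
            m = float(means.loc[day])
            p = float("nan")
            if mode == "ttest":
                vals = sub[sub["day"] == day]["rcbf"].to_numpy()
                _, p = welch_ttest(vals, hv.loc[rid, "rcbf"].to_numpy())
                different = p < sig_level
            else:
                different = not (lo <= m <= hi)
            if not affected:
                status = "unaffected"
            elif not different:
                status = "recovered"
            elif m > hi:
                status = "hyper_after_recovery"
            else:
                status = "non_regenerated"
            rows.append({"group": group, "region_id": int(rid), "day": int(day),
                         "mean": m, "se": float(ses.loc[day]), "n": int(ns.loc[day]),
                         "lo": lo, "hi": hi, "p_healthy": p,
                         "affected": bool(affected), "status": status})
    return RecoveryReport(table=pd.DataFrame(rows), hemisphere=hemisphere,
                          mode=mode, sig_level=sig_level,
                          baseline_day=baseline_day)


# ---------------------------------------------------------------------------
# distance shells
# ---------------------------------------------------------------------------

@dataclass
class ShellProfile:
    """Affected volume binned by distance from the injection site."""

    edges_mm: np.ndarray      # bin edges, length n_shells + 1
    affected_mm3: np.ndarray  # per-shell affected (hypo ∪ hyper) volume
    total_mm3: np.ndarray     # per-shell brain volume
    is_difference: bool = False

    @property
    def n_shells(self) -> int:
        return len(self.affected_mm3)

    @property
    def total_affected_mm3(self) -> float:
        return float(self.affected_mm3.sum())


def shell_profile(classification: PerfusionClassification,
                  injection_site_mm, bin_width_mm: float = 1.0,
                  hemisphere: str | None = None,
                  labels: LabelVolume | None = None) -> ShellProfile:
    """Bin classified brain voxels into spherical shells around the site."""
    vol = classification.classes
    site = np.asarray(injection_site_mm, dtype=float)
    lo, hi = vol.world_bounds_mm()
    if np.any(site < lo) or np.any(site > hi):
        raise ValueError(f"injection site {tuple(site)} outside volume bounds")
    x, y, z = vol.voxel_centers_mm()
    dist = np.sqrt((x - site[0]) ** 2 + (y - site[1]) ** 2 + (z - site[2]) ** 2)
    brain = vol.values != 0  # classified voxels (hypo/normal/hyper)
    if hemisphere is not None:
        if labels is None:
            raise ValueError("hemisphere filtering needs the label volume")
        brain = brain & labels.hemisphere_mask(hemisphere)
    affected = brain & ((vol.values == 1) | (vol.values == 3))
    dmax = float(dist[brain].max()) if brain.any() else bin_width_mm
    n_shells = int(np.ceil(dmax / bin_width_mm)) or 1
    edges = np.arange(n_shells + 1, dtype=float) * bin_width_mm
    vv = classification.voxel_volume_mm3
    aff_counts, _ = np.histogram(dist[affected], bins=edges)
    tot_counts, _ = np.histogram(dist[brain], bins=edges)
    return ShellProfile(edges_mm=edges,
                        affected_mm3=aff_counts.astype(float) * vv,
                        total_mm3=tot_counts.astype(float) * vv)


def shell_recovery_difference(treated: ShellProfile,
                              control: ShellProfile) -> ShellProfile:
    """Per-shell volume recovered over the control level (may be negative)."""
    n = min(treated.n_shells, control.n_shells)
    et, ec = treated.edges_mm[: n + 1], control.edges_mm[: n + 1]
    if not np.allclose(et, ec):
        raise ValueError("shell edges mismatch between profiles")
    diff = control.affected_mm3[:n] - treated.affected_mm3[:n]
    return ShellProfile(edges_mm=et, affected_mm3=diff,
                        total_mm3=control.total_mm3[:n], is_difference=True)
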
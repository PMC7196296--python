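"""Relative rCBF parametric mapping and perfusion classification.

[99mTc]-HMPAO retention saturates with flow, so raw uptake ratios
underestimate high flows.  Lassen's linearization compensates: with
``R = activity / mean(reference-region activity)`` the corrected relative
flow is

    F(R) = alpha * R / (1 + (alpha - 1) * R),       0 < alpha <= 1,

which fixes F(1) = 1 (the reference region maps to flow 1 by construction),
is strictly increasing on its domain R < 1/(1 - alpha), and reduces to the
identity at alpha = 1.  The study convention is alpha = 0.5 with the
contralesional (right) hemisphere as reference region.

Classification is per-voxel against the healthy reference: a voxel is
hypoperfused when its rCBF falls below its atlas region's healthy
mean - 2*SD, hyperperfused above mean + 2*SD; the bands derive only from
the healthy cohort, never from the study data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import LabelVolume, VolumeGrid, require_congruent
from .tables import HealthyReference

DEFAULT_ALPHA = 0.5

# per-voxel class codes
CLASS_OUTSIDE = 0
CLASS_HYPO = 1
CLASS_NORMAL = 2
CLASS_HYPER = 3
CLASS_NAMES = {CLASS_OUTSIDE: "outside", CLASS_HYPO: "hypo",
               CLASS_NORMAL: "normal", CLASS_HYPER: "hyper"}


def lassen_correct(uptake_ratio, alpha: float = DEFAULT_ALPHA,
                   clamp: bool = True):
    """Lassen-linearized relative flow from an uptake ratio.

    Accepts a scalar or array.  Ratios at or beyond the pole
    ``1/(1 - alpha)`` are clamped just below it (counted in the returned
    array's companion; see :func:`lassen_clamp_count`) unless ``clamp`` is
    False, in which case they raise.  NaN passes through (masked voxels).
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    r = np.asarray(uptake_ratio, dtype=np.float64)
    scalar = r.ndim == 0
    r = np.atleast_1d(r).copy()
    if np.any(r[np.isfinite(r)] < 0):
        raise ValueError("uptake ratio must be non-negative")
    if alpha < 1.0:
        pole = 1.0 / (1.0 - alpha)
        over = np.isfinite(r) & (r >= pole)
        if over.any():
            if not clamp:
                raise ValueError(
                    f"{int(over.sum())} uptake ratio(s) at/beyond the Lassen pole "
                    f"1/(1-alpha) = {pole:g}")
            r[over] = pole * 0.995
    out = alpha * r / (1.0 + (alpha - 1.0) * r)
    return float(out[0]) if scalar else out


def lassen_clamp_count(uptake_ratio, alpha: float = DEFAULT_ALPHA) -> int:
    """Number of finite ratios that the transform would clamp."""
    if alpha >= 1.0:
        return 0
    r = np.atleast_1d(np.asarray(uptake_ratio, dtype=np.float64))
    pole = 1.0 / (1.0 - alpha)
    return int(np.sum(np.isfinite(r) & (r >= pole)))


def lassen_invert(flow, alpha: float = DEFAULT_ALPHA):
    """Inverse of :func:`lassen_correct`: the uptake ratio giving flow F."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    f = np.asarray(flow, dtype=np.float64)
    return f / (alpha - (alpha - 1.0) * f)


@dataclass
class ParametricMap:
    """A Lassen-corrected relative rCBF volume with its provenance.

    The mean relative uptake over the reference region maps to rCBF 1.0 by
    construction.  Maps built with different alpha must never be pooled;
    alpha is recorded on every map.
    """

    rcbf: VolumeGrid
    alpha: float
    reference_mean_activity: float
    reference_region: str = "contralesional hemisphere"
    n_clamped: int = 0


def reference_mean(spect: VolumeGrid, labels: LabelVolume,
                   side: str = "right", statistic: str = "mean") -> float:
    """Mean (or median) activity over the finite voxels of one hemisphere."""
    require_congruent(spect, labels, what="SPECT/labels")
    mask = labels.hemisphere_mask(side) & spect.finite_mask
    if not mask.any():
        raise ValueError(f"reference region ({side} hemisphere) is empty")
    vals = spect.values[mask]
    ref = float(np.median(vals)) if statistic == "median" else float(np.mean(vals))
    if not np.isfinite(ref) or ref == 0.0:
        raise ValueError("reference region mean activity is zero or non-finite")
    return ref


def parametric_map(spect: VolumeGrid, labels: LabelVolume,
                   alpha: float = DEFAULT_ALPHA,
                   reference_side: str = "right",
                   reference_statistic: str = "mean") -> ParametricMap:
    """Voxel-wise relative rCBF map from a masked SPECT volume.

    Each voxel's uptake ratio R = activity / reference-mean is transformed
    through Lassen's correction; masked (NaN) voxels stay NaN.
    """
    ref = reference_mean(spect, labels, side=reference_side,
                         statistic=reference_statistic)
    ratio = spect.values / ref
    n_clamped = lassen_clamp_count(ratio, alpha)
    rcbf = lassen_correct(ratio, alpha)
    return ParametricMap(
        rcbf=spect.like(rcbf, modality="PARAMETRIC"),
        alpha=alpha,
        reference_mean_activity=ref,
        reference_region=f"contralesional ({reference_side}) hemisphere "
                         f"[{reference_statistic}]",
        n_clamped=n_clamped,
    )


@dataclass
class PerfusionClassification:
    """Per-voxel and per-region perfusion classes against the healthy bands.

    ``classes`` holds the integer-coded lattice (0 outside, 1 hypo, 2 normal,
    3 hyper); hypo/normal/hyper partition the atlas-covered brain, so their
    volumes sum to the classified brain volume.
    """

    classes: VolumeGrid
    region_table: pd.DataFrame       # region_id, hemisphere, mean_rcbf, lo, hi, class, n_voxels
    voxel_volume_mm3: float

    def class_mask(self, name: str) -> np.ndarray:
        code = {v: k for k, v in CLASS_NAMES.items()}[name]
        return self.classes.values == code

    def volume_mm3(self, name: str, hemisphere: str | None = None,
                   labels: LabelVolume | None = None) -> float:
        mask = self.class_mask(name)
        if hemisphere is not None:
            if labels is None:
                raise ValueError("hemisphere filtering needs the label volume")
            mask = mask & labels.hemisphere_mask(hemisphere)
        return float(mask.sum()) * self.voxel_volume_mm3

    @property
    def brain_volume_mm3(self) -> float:
        return sum(self.volume_mm3(n) for n in ("hypo", "normal", "hyper"))


def classify_perfusion(pmap: ParametricMap, healthy: HealthyReference,
                       labels: LabelVolume, k_sd: float = 2.0) -> PerfusionClassification:
    """Classify every atlas voxel as hypo/normal/hyperperfused.

    Thresholds are the per-(region, hemisphere) healthy ``mean +/- k_sd*SD``
    bands.  Voxels outside any atlas region (or NaN) are classed ``outside``
    and excluded from volumes.  Every labeled region must have a healthy
    reference row; a missing row raises an error naming the region.
    """
    vol = pmap.rcbf
    require_congruent(vol, labels, what="map/labels")
    classes = np.full(vol.shape, CLASS_OUTSIDE, dtype=np.int16)
    finite = vol.finite_mask
    inside = (labels.region_ids > 0) & finite

    # band lookup tables indexed by (region_id, hemisphere)
    max_id = int(labels.region_ids.max()) if inside.any() else 0
    lo_lut = np.full((max_id + 1, 2), np.nan)
    hi_lut = np.full((max_id + 1, 2), np.nan)
    hemi_idx = (labels.hemisphere_ids == LabelVolume.HEMI_RIGHT).astype(np.int8)
    present = []
    for hemi, hcode in (("left", 0), ("right", 1)):
        hmask = labels.hemisphere_mask(hemi)
        ids = np.unique(labels.region_ids[hmask & (labels.region_ids > 0)])
        for rid in ids:
            if not healthy.has(rid, hemi):
                raise KeyError(f"region {rid} ({hemi}) has no healthy reference row")
            blo, bhi = healthy.band(rid, hemi, k=k_sd)
            # numerical guard: a degenerate (zero-SD) band must still contain
            # values equal to the mean up to float rounding
            tol = 1e-9 * (abs(blo) + abs(bhi) + 1.0)
            lo_lut[rid, hcode], hi_lut[rid, hcode] = blo - tol, bhi + tol
            present.append((int(rid), hemi, hcode))

    v = vol.values[inside]
    lo = lo_lut[labels.region_ids[inside], hemi_idx[inside]]
    hi = hi_lut[labels.region_ids[inside], hemi_idx[inside]]
    cls = np.where(v < lo, CLASS_HYPO, np.where(v > hi, CLASS_HYPER, CLASS_NORMAL))
    classes[inside] = cls

    # per-region means via bincount on a combined (region, hemisphere) key
    key = labels.region_ids[inside] * 2 + hemi_idx[inside]
    sums = np.bincount(key, weights=v, minlength=2 * (max_id + 1))
    counts = np.bincount(key, minlength=2 * (max_id + 1))
    rows = []
    for rid, hemi, hcode in present:
        k = rid * 2 + hcode
        n = int(counts[k])
        mean = sums[k] / n if n else float("nan")
        blo, bhi = lo_lut[rid, hcode], hi_lut[rid, hcode]
        if n == 0:
            rcls = "missing"
        elif mean < blo:
            rcls = "hypo"
        elif mean > bhi:
            rcls = "hyper"
        else:
            rcls = "normal"
        rows.append({"region_id": rid, "hemisphere": hemi,
                     "mean_rcbf": float(mean), "lo": float(blo), "hi": float(bhi),
                     "class": rcls, "n_voxels": n})
    table = pd.DataFrame(rows)
    return PerfusionClassification(
        classes=vol.like(classes.astype(np.float64), modality="PARAMETRIC"),
        region_table=table,
        voxel_volume_mm3=vol.voxel_volume_mm3,
    )


@dataclass
class MaskTimeCourse:
    """Day-0 hypoperfusion mask tracked through a time series.

    For every timepoint the mean rCBF inside the fixed day-0 mask is
    computed in two modes: ``voxel`` averages the parametric-map voxels;
    ``roi`` averages the raw SPECT signal inside the mask, forms the ratio
    to the reference region, and applies Lassen once.  The two agree exactly
    on homogeneous masks.  ``hypo_volume_mm3`` is the ipsilesional
    hypoperfused volume of each timepoint's own classification.
    """

    mask: np.ndarray
    days: list
    voxel_mean: dict
    roi_mean: dict
    hypo_volume_mm3: dict
    mask_volume_mm3: float


def track_day0_mask(maps: list[ParametricMap], spect_series: list[VolumeGrid],
                    day0_class: PerfusionClassification, labels: LabelVolume,
                    days: list | None = None, mode: str = "both",
                    healthy: HealthyReference | None = None,
                    mask_hemisphere: str | None = "left") -> MaskTimeCourse:
    """Track mean rCBF within the day-0 hypoperfused volume over time.

    The mask is fixed at day 0 for the whole series (default: restricted to
    the ipsilesional hemisphere).  ``healthy`` enables per-timepoint
    hypoperfused-volume reclassification; omit it to skip that column.
    """
    if mode not in ("voxel", "roi", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(maps) != len(spect_series):
        raise ValueError("maps and spect_series lengths differ")
    days = list(range(len(maps))) if days is None else list(days)
    if len(days) != len(maps):
        raise ValueError("days length differs from series length")
    mask = day0_class.class_mask("hypo")
    if mask_hemisphere is not None:
        mask = mask & labels.hemisphere_mask(mask_hemisphere)
    if not mask.any():
        raise ValueError("day-0 hypoperfused mask is empty")

    voxel_mean, roi_mean, hypo_vol = {}, {}, {}
    for day, pmap, spect in zip(days, maps, spect_series):
        require_congruent(pmap.rcbf, spect, labels, what="series volumes")
        if mode in ("voxel", "both"):
            voxel_mean[day] = float(np.nanmean(pmap.rcbf.values[mask]))
        if mode in ("roi", "both"):
            ref = reference_mean(spect, labels)
            mean_act = float(np.nanmean(spect.values[mask]))
            roi_mean[day] = float(lassen_correct(mean_act / ref, pmap.alpha))
        if healthy is not None:
            cls = classify_perfusion(pmap, healthy, labels)
            hypo_vol[day] = cls.volume_mm3("hypo", hemisphere=mask_hemisphere,
                                           labels=labels)
    return MaskTimeCourse(
        mask=mask, days=days, voxel_mean=voxel_mean, roi_mean=roi_mean,
        hypo_volume_mm3=hypo_vol,
        mask_volume_mm3=float(mask.sum()) * day0_class.voxel_volume_mm3,
    )
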
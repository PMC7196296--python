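"""Seeded synthetic phantoms with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: an ellipsoidal rat brain on an isotropic lattice, split at the
midline into an ipsilesional (left) and contralesional (right) hemisphere;
a 77-region atlas built by weighted-Voronoi growth from evenly spread seed
points and mirrored across the midline; lateral ventricles carved out of
both hemispheres; per-region healthy relative rCBF levels near 1 with
region- and hemisphere-specific offsets; and, for study scenarios, a
hemispherically asymmetric lesion centered at the stereotaxic injection
site whose per-region perfusion deficit decays with distance from the site
and recovers over seven imaging timepoints with group-dependent kinetics.

Everything is designed in *measured* rCBF space: a region's designed value
f is converted to a SPECT uptake ratio through the inverse Lassen
transform, so that running the analysis on noise-free output reproduces
every designed mean, count and volume exactly.  Ground-truth metadata (true
lesion mask, designed per-region day-wise means, designed recovery sets and
volume changes, true edema volume) is always emitted alongside the data.

Determinism: identical (spec, seed) pairs reproduce byte-identical outputs;
all randomness flows from ``numpy.random.SeedSequence(spec.seed)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import LabelVolume, VolumeGrid
from .perfusion import lassen_correct, lassen_invert, DEFAULT_ALPHA
from .tables import HealthyReference, RegionTable

SCENARIOS = ("reference_mcao", "lesion_free", "custom")

#: atlas region ids excluded from analysis (no / incomplete measurement data)
EXCLUDED_NO_DATA = (4, 13, 75)
EXCLUDED_INCOMPLETE = (56, 71)

_DEF_LESION = {
    # day-0 deficit profile: depth = floor + amp * exp(-(d/scale)^2)
    "deficit_floor": 0.28,
    "deficit_amp": 0.34,
    "deficit_scale_mm": 4.0,
    "core_radius_mm": 1.8,
    # group-specific recovery half-time of the designed trajectories (days)
    "recovery_half_time_days": {"treated": 1.75, "control": 1.75},
    # residual day-7 deficit of non-recovered regions, treated arm:
    # max(nonrecovered_floor, nonrecovered_scale * day0 deficit)
    "nonrecovered_floor": 0.25,
    "nonrecovered_scale": 0.62,
    # day-7 overshoot (negative deficit) of hyper-after-recovery regions
    "overshoot": 0.20,
    # study-matched designed counts and contrasts
    "n_affected_treated": 65,
    "n_affected_control": 67,
    "n_recovered_treated": 32,
    "n_recovered_control": 8,
    "n_shared_recovered": 5,
    "n_hyper_after_recovery": 3,
    "treated_volume_shrink": 0.67,   # designed day0->day7 hypoperfused-volume reduction
    "control_volume_shrink": 0.01,
    "mask_mean_uplift": 0.41,        # designed day-7 treated-vs-control mask-mean contrast
    # optional late relapse of the hypoperfused deficit (off by default)
    "relapse_amplitude": 0.0,
    "relapse_onset_day": 14,
}

_DEF_EDEMA = {
    "parenchyma_mean": 100.0,
    "parenchyma_sd": 10.0,
    "ventricle_mean": 200.0,
    "ventricle_sd": 10.0,
    "ventricle_fraction": 0.024,   # fraction of hemisphere brain volume
    "edema_volume_mm3": 40.0,
    "edema_intensity_offset": 60.0,
    "swelling_mm3": 10.0,          # ipsilesional space-occupying excess
    "onset_day": 3,                # edema appears from this day on
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic study; the defaults are the study design.

    World frame: bregma at the origin on the dorsal midline; x is
    medio-lateral (left negative), y antero-posterior, z dorso-ventral
    (dorsal = 0, ventral negative).  The default injection site is the
    stereotaxic target AP +0.3 mm, ML -4.0 mm, DV +4.8 mm.
    """

    grid_shape: tuple[int, int, int] = (54, 64, 40)
    voxel_size_mm: float = 0.33
    n_regions: int = 77
    n_healthy: int = 15
    n_per_group: int = 6
    timepoints_days: tuple[int, ...] = (0, 3, 7, 10, 14, 17, 21)
    injection_site_mm: tuple[float, float, float] = (-4.0, 0.3, -4.8)
    lesion_profile: dict = field(default_factory=dict)
    edema_params: dict = field(default_factory=dict)
    noise_sd: float = 0.05
    voxel_noise_frac: float = 0.25
    activity_scale: float = 2.0      # healthy-reference activity level, MBq/ml
    include_mri: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3:
            raise ValueError("grid_shape must have 3 axes")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("degenerate grid: every axis needs >= 8 voxels")
        if self.grid_shape[0] % 2:
            raise ValueError("grid_shape[0] must be even (mirror-symmetric midline)")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_regions < 1 or self.n_regions > 30000:
            raise ValueError("n_regions exceeds label capacity (int16) or is < 1")
        if self.n_healthy < 2:
            raise ValueError("n_healthy must be >= 2")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd < 0 or self.voxel_noise_frac < 0:
            raise ValueError("noise scales must be non-negative")
        self.lesion_profile = {**_DEF_LESION, **dict(self.lesion_profile)}
        self.edema_params = {**_DEF_EDEMA, **dict(self.edema_params)}
        self.seed = int(self.seed)

    # ---- geometry -------------------------------------------------------
    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.voxel_size_mm,) * 3

    @property
    def origin_mm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.grid_shape
        s = self.voxel_size_mm
        # bregma (0,0,0) at the dorsal midline: x and y centered, z mostly below
        return (-nx * s / 2.0, -ny * s / 2.0, -(nz - 2) * s)

    def voxel_centers(self):
        axes = []
        for n, o in zip(self.grid_shape, self.origin_mm):
            axes.append(o + (np.arange(n) + 0.5) * self.voxel_size_mm)
        return np.meshgrid(*axes, indexing="ij", sparse=True)


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------

@dataclass
class Atlas:
    """The static anatomy shared by every volume of one phantom spec."""

    spec: PhantomSpec
    labels: LabelVolume
    region_table: RegionTable
    brain_mask: np.ndarray
    design: pd.DataFrame        # region_id, hemisphere, mu (designed healthy rCBF)
    region_info: pd.DataFrame   # region_id, n_voxels, volume_mm3, dist_mm, size_class
    ventricle_rcbf: float
    site_distance_mm: np.ndarray  # per-voxel distance from the injection site

    def rcbf_field(self, f_by_region: dict[tuple[int, str], float]) -> np.ndarray:
        """Designed-rCBF lattice from per-(region, hemisphere) values."""
        max_id = int(self.labels.region_ids.max())
        lut = np.full((max_id + 1, 2), np.nan)
        for (rid, hemi), f in f_by_region.items():
            lut[rid, 0 if hemi == "left" else 1] = f
        out = np.full(self.labels.shape, np.nan)
        inside = self.labels.region_ids > 0
        hemi_idx = (self.labels.hemisphere_ids == LabelVolume.HEMI_RIGHT).astype(int)
        out[inside] = lut[self.labels.region_ids[inside], hemi_idx[inside]]
        out[self.ventricle_mask] = self.ventricle_rcbf
        return out

    @property
    def ventricle_mask(self) -> np.ndarray:
        return self.labels.ventricle_mask


def _ellipsoid_mask(x, y, z, center, semi):
    return ((x - center[0]) / semi[0]) ** 2 + ((y - center[1]) / semi[1]) ** 2 \
        + ((z - center[2]) / semi[2]) ** 2 <= 1.0


def _farthest_point_seeds(points: np.ndarray, k: int, rng) -> np.ndarray:
    """Evenly spread k seed indices by greedy farthest-point sampling."""
    n = len(points)
    first = int(rng.integers(n))
    chosen = [first]
    d = np.linalg.norm(points - points[first], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.asarray(chosen)


def build_atlas(spec: PhantomSpec) -> Atlas:
    """Construct the mirrored weighted-Voronoi atlas and healthy rCBF design."""
    ss = np.random.SeedSequence([spec.seed, 101])
    rng = np.random.default_rng(ss)
    x, y, z = spec.voxel_centers()
    nx, ny, nz = spec.grid_shape
    s = spec.voxel_size_mm

    # brain ellipsoid, symmetric about the midline x = 0
    semi = (0.90 * nx * s / 2.0, 0.90 * ny * s / 2.0, 0.85 * nz * s / 2.0)
    center = (0.0, 0.0, -(semi[2] + 0.5))
    brain = _ellipsoid_mask(x, y, z, center, semi)

    hemi = np.where(np.broadcast_to(x, spec.grid_shape) < 0,
                    LabelVolume.HEMI_LEFT, LabelVolume.HEMI_RIGHT).astype(np.int16)
    left = hemi == LabelVolume.HEMI_LEFT

    # lateral ventricles: small deep ellipsoids, mirrored
    ep = spec.edema_params
    hemi_vol_mm3 = float(brain[left].sum()) * spec.voxel_size_mm ** 3
    target_vent = ep["ventricle_fraction"] * hemi_vol_mm3
    base = np.array([0.55, 1.5, 0.45])
    scale = (target_vent / (4.0 / 3.0 * np.pi * np.prod(base))) ** (1.0 / 3.0)
    vs = base * scale
    vcen = (-1.6, -1.0, center[2] + 0.35 * semi[2])
    vent = _ellipsoid_mask(x, y, z, vcen, vs) & brain
    vent = vent | vent[::-1, :, :]          # mirror to the right hemisphere

    # Voronoi seeds among left-brain parenchyma voxels
    cand = np.argwhere(brain & left & ~vent)
    if len(cand) < spec.n_regions:
        raise ValueError("n_regions exceeds label capacity of the left hemisphere")
    origin = np.asarray(spec.origin_mm)
    pts = origin + (cand + 0.5) * spec.voxel_size_mm
    seed_idx = _farthest_point_seeds(pts, spec.n_regions, rng)
    seeds = pts[seed_idx]

    region_ids_for_seed = rng.permutation(np.arange(1, spec.n_regions + 1))
    excluded = set(EXCLUDED_NO_DATA) | set(EXCLUDED_INCOMPLETE)
    site = np.asarray(spec.injection_site_mm)
    seed_dist = np.linalg.norm(seeds - site, axis=1)

    # size classes: tiny and large regions are planted at lesion-relevant
    # distances so that designed recovery subsets with the right volume
    # fractions exist; excluded regions keep normal weight
    weights = np.ones(spec.n_regions)
    active_seed = np.array([region_ids_for_seed[i] not in excluded
                            for i in range(spec.n_regions)])
    order_tiny = np.argsort(np.abs(seed_dist - 4.2))
    tiny_sel = [i for i in order_tiny if active_seed[i] and seed_dist[i] >= 2.0][:14]
    remaining = [i for i in range(spec.n_regions) if i not in set(tiny_sel)]
    order_large = sorted(remaining, key=lambda i: abs(seed_dist[i] - 4.5))
    large_sel = [i for i in order_large if active_seed[i] and seed_dist[i] >= 1.9][:16]
    weights[tiny_sel] = 0.42
    weights[large_sel] = 1.80
    size_class = np.array(["normal"] * spec.n_regions, dtype=object)
    size_class[tiny_sel] = "tiny"
    size_class[large_sel] = "large"

    # weighted Voronoi assignment of left parenchyma voxels
    vox_pts = pts
    d = np.linalg.norm(vox_pts[:, None, :] - seeds[None, :, :], axis=2) / weights[None, :]
    assign = np.argmin(d, axis=1)
    region = np.zeros(spec.grid_shape, dtype=np.int16)
    region[tuple(cand.T)] = region_ids_for_seed[assign].astype(np.int16)
    region = np.where(region[::-1, :, :] > 0,
                      np.maximum(region, region[::-1, :, :]), region)  # mirror

    labels = LabelVolume(region_ids=region, hemisphere_ids=hemi,
                         ventricle_mask=vent, voxel_size_mm=spec.spacing,
                         origin_mm=spec.origin_mm)

    # region bookkeeping (left-hemisphere geometry; the atlas is mirrored)
    rows, info_rows = [], []
    left_ids = region[left]
    for i in range(spec.n_regions):
        rid = int(region_ids_for_seed[i])
        nvox = int(np.sum(left_ids == rid))
        rows.append({
            "region_id": rid,
            "name": f"region_{rid:02d}",
            "hemisphere": "both",
            "cortical": bool(seeds[i][2] > center[2]),
            "is_ventricle": False,
            "excluded": rid in excluded,
        })
        info_rows.append({
            "region_id": rid,
            "n_voxels": nvox,
            "volume_mm3": nvox * spec.voxel_size_mm ** 3,
            "dist_mm": float(seed_dist[i]),
            "size_class": size_class[i],
        })
    table = RegionTable(pd.DataFrame(rows).sort_values("region_id"))
    info = pd.DataFrame(info_rows).sort_values("region_id").reset_index(drop=True)

    # designed healthy rCBF: near 1 with region- and hemisphere-specific offsets
    dr = np.random.default_rng(np.random.SeedSequence([spec.seed, 102]))
    mu_rows = []
    for rid in sorted(info["region_id"]):
        base_f = 1.0 + 0.08 * (dr.uniform() - 0.5)
        hemi_off = 0.03 * (dr.uniform() - 0.5)
        mu_rows.append({"region_id": rid, "hemisphere": "left", "mu": base_f + hemi_off / 2})
        mu_rows.append({"region_id": rid, "hemisphere": "right", "mu": base_f - hemi_off / 2})
    design = pd.DataFrame(mu_rows)
    ventricle_rcbf = 0.55

    # anchor the design so the right-hemisphere uptake ratio averages to 1:
    # normalise in uptake space, then map back through Lassen
    atlas = Atlas(spec=spec, labels=labels, region_table=table,
                  brain_mask=brain, design=design, region_info=info,
                  ventricle_rcbf=ventricle_rcbf,
                  site_distance_mm=np.sqrt(
                      (np.broadcast_to(x, spec.grid_shape) - site[0]) ** 2
                      + (np.broadcast_to(y, spec.grid_shape) - site[1]) ** 2
                      + (np.broadcast_to(z, spec.grid_shape) - site[2]) ** 2),
                  )
    f_map = {(int(r.region_id), r.hemisphere): float(r.mu)
             for r in design.itertuples()}
    raw_R = lassen_invert(atlas.rcbf_field(f_map))
    right = labels.hemisphere_mask("right") & np.isfinite(raw_R)
    c = float(np.mean(raw_R[right]))
    design = design.copy()
    design["mu"] = [float(lassen_correct(lassen_invert(m) / c)) for m in design["mu"]]
    atlas.design = design
    atlas.ventricle_rcbf = float(lassen_correct(lassen_invert(ventricle_rcbf) / c))
    return atlas


# ---------------------------------------------------------------------------
# volume synthesis
# ---------------------------------------------------------------------------

def _mu_map(atlas: Atlas) -> dict[tuple[int, str], float]:
    return {(int(r.region_id), r.hemisphere): float(r.mu)
            for r in atlas.design.itertuples()}


def _spect_volume(atlas: Atlas, f_target: dict[tuple[int, str], float],
                  rng) -> VolumeGrid:
    """One SPECT acquisition: designed rCBF -> uptake -> activity + noise.

    Biological variability perturbs each region's flow (measured-space scale
    factor, sd = noise_sd); instrumental noise is additive on voxel activity
    (sd = noise_sd * voxel_noise_frac * activity_scale).
    """
    spec = atlas.spec
    if spec.noise_sd > 0:
        f_target = {k: f * (1.0 + spec.noise_sd * rng.standard_normal())
                    for k, f in f_target.items()}
    f_field = atlas.rcbf_field(f_target)
    if spec.noise_sd > 0:
        vrc = atlas.ventricle_rcbf * (1.0 + spec.noise_sd * rng.standard_normal())
        f_field[atlas.ventricle_mask] = vrc
    ratio = lassen_invert(f_field)
    act = spec.activity_scale * ratio
    sigma_v = spec.noise_sd * spec.voxel_noise_frac * spec.activity_scale
    if sigma_v > 0:
        noise = rng.standard_normal(act.shape) * sigma_v
        act = np.where(np.isfinite(act), np.maximum(act + noise, 0.0), act)
    return VolumeGrid(values=act, voxel_size_mm=spec.spacing,
                      origin_mm=spec.origin_mm, modality="SPECT")


def _edema_blob_mask(atlas: Atlas, volume_mm3: float) -> np.ndarray:
    if volume_mm3 <= 0:
        return np.zeros(atlas.spec.grid_shape, dtype=bool)
    r = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return (atlas.site_distance_mm <= r) & atlas.brain_mask \
        & atlas.labels.hemisphere_mask("left")


def _swelling_rim(atlas: Atlas, swelling_mm3: float) -> np.ndarray:
    """Deterministic rim of extra ipsilesional tissue emulating swelling."""
    n = int(round(swelling_mm3 / atlas.labels.voxel_volume_mm3))
    if n <= 0:
        return np.zeros(atlas.spec.grid_shape, dtype=bool)
    rim = np.zeros(atlas.spec.grid_shape, dtype=bool)
    shell_src = atlas.brain_mask.copy()
    picked = 0
    while picked < n:
        dil = ndimage.binary_dilation(shell_src)
        cand = dil & ~shell_src & atlas.labels.hemisphere_mask("left")
        if not cand.any():
            break
        idx = np.argwhere(cand)
        order = np.argsort(atlas.site_distance_mm[tuple(idx.T)], kind="stable")
        take = idx[order[: n - picked]]
        rim[tuple(take.T)] = True
        picked += len(take)
        shell_src = shell_src | dil
    return rim


def _mri_volume(atlas: Atlas, rng, edema_mm3: float = 0.0,
                swelling_mm3: float = 0.0) -> tuple[VolumeGrid, float]:
    """One T2 acquisition; returns the volume and the realized edema mm^3."""
    spec = atlas.spec
    ep = spec.edema_params
    vals = np.full(spec.grid_shape, np.nan)
    brain = atlas.brain_mask
    vals[brain] = ep["parenchyma_mean"] + ep["parenchyma_sd"] * rng.standard_normal(
        int(brain.sum()))
    vent = atlas.ventricle_mask
    vals[vent] = ep["ventricle_mean"] + ep["ventricle_sd"] * rng.standard_normal(
        int(vent.sum()))
    blob = _edema_blob_mask(atlas, edema_mm3)
    edema_int = ep["parenchyma_mean"] + ep["edema_intensity_offset"]
    blob_eff = blob & ~vent
    vals[blob_eff] = edema_int + ep["parenchyma_sd"] * rng.standard_normal(
        int(blob_eff.sum()))
    rim = _swelling_rim(atlas, swelling_mm3) if edema_mm3 > 0 else \
        np.zeros(spec.grid_shape, dtype=bool)
    vals[rim] = edema_int + ep["parenchyma_sd"] * rng.standard_normal(int(rim.sum()))
    realized = float((blob_eff | rim).sum()) * atlas.labels.voxel_volume_mm3
    return VolumeGrid(values=vals, voxel_size_mm=spec.spacing,
                      origin_mm=spec.origin_mm, modality="MRI"), realized


# ---------------------------------------------------------------------------
# healthy cohort
# ---------------------------------------------------------------------------

@dataclass
class HealthyCohort:
    volumes: list[VolumeGrid]
    labels: LabelVolume
    reference: HealthyReference
    region_table: RegionTable
    design: pd.DataFrame
    atlas: Atlas


def generate_healthy_cohort(spec: PhantomSpec, atlas: Atlas | None = None) -> HealthyCohort:
    """Synthesize the healthy cohort and measure its rCBF reference table.

    The reference is computed by running the actual pipeline (parametric
    mapping against the right hemisphere, atlas region averaging) on each
    cohort member, so with zero noise it equals the design exactly.
    """
    from .perfusion import parametric_map
    from .regions import region_rcbf

    atlas = atlas or build_atlas(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 201]))
    mu = _mu_map(atlas)
    volumes, per_animal = [], []
    for a in range(spec.n_healthy):
        vol = _spect_volume(atlas, mu, rng)
        volumes.append(vol)
        pmap = parametric_map(vol, atlas.labels)
        means = region_rcbf(pmap, atlas.labels, atlas.region_table,
                            include_excluded=True)
        means = means.assign(animal=f"healthy_{a:02d}")
        per_animal.append(means)
    cohort = pd.concat(per_animal, ignore_index=True)
    reference = HealthyReference.from_cohort(cohort)
    return HealthyCohort(volumes=volumes, labels=atlas.labels,
                         reference=reference, region_table=atlas.region_table,
                         design=atlas.design, atlas=atlas)


# ---------------------------------------------------------------------------
# study scenarios
# ---------------------------------------------------------------------------

def _subset_with_volume(cands: pd.DataFrame, k: int, target: float,
                        prefer: np.ndarray | None = None) -> list[int]:
    """Pick k region ids whose volumes sum as close to target as possible.

    Starts from a preference ordering and hill-climbs with in/out swaps.
    Deterministic.
    """
    ids = cands["region_id"].to_numpy()
    vols = cands["volume_mm3"].to_numpy(dtype=float)
    n = len(ids)
    if k > n:
        raise ValueError("not enough candidate regions for designed subset")
    order = np.arange(n) if prefer is None else np.asarray(prefer)
    chosen = list(order[:k])
    rest = list(order[k:])

    def total(sel):
        return vols[sel].sum() if len(sel) else 0.0

    best = abs(total(chosen) - target)
    improved = True
    while improved and best > 1e-9:
        improved = False
        cur = total(chosen)
        for ci in range(len(chosen)):
            for ri in range(len(rest)):
                delta = vols[rest[ri]] - vols[chosen[ci]]
                err = abs(cur + delta - target)
                if err < best - 1e-12:
                    chosen[ci], rest[ri] = rest[ri], chosen[ci]
                    best = err
                    cur = cur + delta
                    improved = True
        # keep sweeping until no swap improves
    return [int(ids[i]) for i in chosen]


def _exhaustive_subset(cands: pd.DataFrame, k: int, target: float) -> list[int]:
    ids = cands["region_id"].to_numpy()
    vols = cands["volume_mm3"].to_numpy(dtype=float)
    best, best_err = None, np.inf
    for combo in itertools.combinations(range(len(ids)), k):
        err = abs(vols[list(combo)].sum() - target)
        if err < best_err:
            best, best_err = combo, err
    return [int(ids[i]) for i in best]


@dataclass
class LesionDesign:
    """Per-arm designed region sets and day-wise deficit trajectories."""

    affected: dict           # group -> list of region ids
    recovered: dict          # group -> list of region ids (incl. overshoot)
    overshoot: list          # treated hyper-after-recovery region ids
    deficit: pd.DataFrame    # group, region_id, day, deficit (fraction of mu)
    designed: dict           # summary of every designed quantity


def design_reference_mcao(atlas: Atlas) -> LesionDesign:
    """The study-matched lesion design, solved on the measured atlas geometry."""
    lp = atlas.spec.lesion_profile
    info = atlas.region_info
    active = info[~info["region_id"].isin(
        set(EXCLUDED_NO_DATA) | set(EXCLUDED_INCOMPLETE))].copy()
    active = active.sort_values("dist_mm").reset_index(drop=True)
    n_at, n_ac = lp["n_affected_treated"], lp["n_affected_control"]
    if len(active) < max(n_at, n_ac):
        raise ValueError("not enough active regions for the designed lesion")
    A_c = active.head(n_ac)
    A_t = active.head(n_at)
    vol_at = A_t["volume_mm3"].sum()
    vol_ac = A_c["volume_mm3"].sum()

    # control-recovered: tiny regions summing to the designed 1% of the
    # control-affected volume
    tiny = A_t[A_t["size_class"] == "tiny"].sort_values("volume_mm3")
    n_rc = lp["n_recovered_control"]
    if len(tiny) < n_rc:
        raise ValueError("not enough tiny regions for the control-recovered set")
    R_c = _exhaustive_subset(tiny, n_rc,
                             lp["control_volume_shrink"] * vol_ac)
    n_shared = lp["n_shared_recovered"]
    shared = sorted(R_c, key=lambda r: float(
        tiny.set_index("region_id").loc[r, "volume_mm3"]))[:n_shared]
    control_only = [r for r in R_c if r not in shared]

    # treated-recovered: the shared tiny regions plus non-core regions
    # selected to reach the designed 67% of the treated-affected volume
    core_ids = set(A_t[A_t["dist_mm"] < lp["core_radius_mm"]]["region_id"])
    shared_vol = A_t[A_t["region_id"].isin(shared)]["volume_mm3"].sum()
    cand = A_t[~A_t["region_id"].isin(core_ids | set(R_c))]
    cand = cand[cand["dist_mm"] >= lp["core_radius_mm"]].reset_index(drop=True)
    n_rt = lp["n_recovered_treated"]
    target = lp["treated_volume_shrink"] * vol_at - shared_vol
    prefer = np.argsort(np.abs(cand["dist_mm"].to_numpy() - 4.0))
    rest_R_t = _subset_with_volume(cand, n_rt - n_shared, target, prefer=prefer)
    R_t = rest_R_t + shared
    achieved_t = (A_t[A_t["region_id"].isin(R_t)]["volume_mm3"].sum()) / vol_at
    achieved_c = (A_c[A_c["region_id"].isin(R_c)]["volume_mm3"].sum()) / vol_ac

    # hyper-after-recovery: smallest non-shared treated-recovered regions
    n_over = lp["n_hyper_after_recovery"]
    over = list(A_t[A_t["region_id"].isin(rest_R_t)]
                .sort_values("volume_mm3")["region_id"].head(n_over))

    # day-0 deficit by distance; day-7 residuals per class
    dist = info.set_index("region_id")["dist_mm"]
    vols = info.set_index("region_id")["volume_mm3"]
    mu_left = atlas.design[atlas.design["hemisphere"] == "left"] \
        .set_index("region_id")["mu"]

    def delta0(rid):
        d = dist.loc[rid]
        return lp["deficit_floor"] + lp["deficit_amp"] * np.exp(-(d / lp["deficit_scale_mm"]) ** 2)

    d7_t = {}
    for rid in A_t["region_id"]:
        if rid in over:
            d7_t[rid] = -lp["overshoot"]
        elif rid in R_t:
            d7_t[rid] = 0.0
        else:
            d7_t[rid] = max(lp["nonrecovered_floor"],
                            lp["nonrecovered_scale"] * delta0(rid))

    # solve the control day-7 residual scale c for the designed mask-mean
    # contrast: mean rCBF at day 7 inside the day-0 hypoperfused volume is
    # (1 + uplift) times higher in the treated arm
    w_t = vols.loc[A_t["region_id"]].to_numpy()
    mu_t = mu_left.loc[A_t["region_id"]].to_numpy()
    f7_t = mu_t * (1.0 - np.array([d7_t[r] for r in A_t["region_id"]]))
    M_t = float((w_t * f7_t).sum() / w_t.sum())
    M_c_target = M_t / (1.0 + lp["mask_mean_uplift"])
    w_c = vols.loc[A_c["region_id"]].to_numpy()
    mu_c = mu_left.loc[A_c["region_id"]].to_numpy()
    rec_c = A_c["region_id"].isin(R_c).to_numpy()
    d0_c = np.array([delta0(r) for r in A_c["region_id"]])
    # M_c(c) = sum(w*mu*(1 - c*d0*nonrec))/sum(w)
    k0 = float((w_c * mu_c).sum() / w_c.sum())
    k1 = float((w_c * mu_c * d0_c * (~rec_c)).sum() / w_c.sum())
    c_scale = (k0 - M_c_target) / k1
    if not (0.2 <= c_scale <= 1.1):
        raise RuntimeError(
            f"control day-7 residual solve out of range (c = {c_scale:.3f}); "
            "lesion design infeasible on this atlas")
    d7_c = {rid: (0.0 if rid in R_c else float(c_scale * delta0(rid)))
            for rid in A_c["region_id"]}
    M_c = k0 - c_scale * k1

    # designed day-wise trajectories: exponential approach pinned exactly at
    # day 0 and day 7, with optional late relapse
    rows = []
    half = lp["recovery_half_time_days"]
    for group, (aff, d7) in (("treated", (A_t, d7_t)), ("control", (A_c, d7_c))):
        tau = float(half[group]) if isinstance(half, dict) else float(half)
        q = 2.0 ** (-7.0 / tau)
        aff_ids = set(aff["region_id"])
        for rid in active["region_id"]:
            if rid in aff_ids:
                d0, dd7 = float(delta0(rid)), float(d7[rid])
                dinf = (dd7 - d0 * q) / (1.0 - q)
            else:
                d0 = dd7 = dinf = 0.0
            for day in atlas.spec.timepoints_days:
                dep = dinf + (d0 - dinf) * 2.0 ** (-day / tau) if rid in aff_ids else 0.0
                if lp["relapse_amplitude"] and day > lp["relapse_onset_day"]:
                    dep += lp["relapse_amplitude"] * (
                        1.0 - 2.0 ** (-(day - lp["relapse_onset_day"]) / 3.0))
                rows.append({"group": group, "region_id": int(rid),
                             "day": int(day), "deficit": float(dep)})
    deficit = pd.DataFrame(rows)

    designed = {
        "affected": {"treated": sorted(int(r) for r in A_t["region_id"]),
                     "control": sorted(int(r) for r in A_c["region_id"])},
        "recovered_day7": {"treated": sorted(int(r) for r in R_t),
                           "control": sorted(int(r) for r in R_c)},
        "hyper_after_recovery": sorted(int(r) for r in over),
        "shared_recovered": sorted(int(r) for r in shared),
        "treated_exclusive": sorted(int(r) for r in set(R_t) - set(R_c)),
        "control_exclusive": sorted(int(r) for r in control_only),
        "counts": {
            "treated_affected": int(n_at), "control_affected": int(n_ac),
            "treated_recovered": int(n_rt), "control_recovered": int(n_rc),
            "shared": int(n_shared),
            "treated_exclusive": int(n_rt - n_shared),
            "control_exclusive": int(n_rc - n_shared),
        },
        "volume_shrink_pct": {"treated": 100.0 * float(achieved_t),
                              "control": 100.0 * float(achieved_c)},
        "mask_mean_day7": {"treated": M_t, "control": float(M_c)},
        "mask_mean_uplift_pct": 100.0 * (M_t / M_c - 1.0),
        "control_residual_scale": float(c_scale),
    }
    return LesionDesign(
        affected={"treated": list(map(int, A_t["region_id"])),
                  "control": list(map(int, A_c["region_id"]))},
        recovered={"treated": [int(r) for r in R_t],
                   "control": [int(r) for r in R_c]},
        overshoot=[int(r) for r in over],
        deficit=deficit, designed=designed)


def design_lesion_free(atlas: Atlas) -> LesionDesign:
    rows = [{"group": g, "region_id": int(r), "day": int(d), "deficit": 0.0}
            for g in ("treated", "control")
            for r in atlas.region_info["region_id"]
            for d in atlas.spec.timepoints_days]
    return LesionDesign(
        affected={"treated": [], "control": []},
        recovered={"treated": [], "control": []},
        overshoot=[], deficit=pd.DataFrame(rows),
        designed={"affected": {"treated": [], "control": []},
                  "recovered_day7": {"treated": [], "control": []},
                  "hyper_after_recovery": [], "shared_recovered": [],
                  "treated_exclusive": [], "control_exclusive": [],
                  "counts": {k: 0 for k in (
                      "treated_affected", "control_affected",
                      "treated_recovered", "control_recovered", "shared",
                      "treated_exclusive", "control_exclusive")},
                  "volume_shrink_pct": {"treated": 0.0, "control": 0.0},
                  "mask_mean_day7": {}, "mask_mean_uplift_pct": 0.0})


# ---------------------------------------------------------------------------
# behavioural scores
# ---------------------------------------------------------------------------

BEHAVIOR_DAYS = (4, 8, 11, 15, 18, 21)

_GENERAL_ITEMS = {"posture": 4, "activity": 4, "hair": 2, "eyes": 4}
_FOCAL_ITEMS = {"body_symmetry": 4, "gait": 4, "limb_symmetry": 4,
                "circling": 4, "whisker": 4}


def _interp_mean(day: int, start: float, end: float) -> float:
    frac = (day - BEHAVIOR_DAYS[0]) / (BEHAVIOR_DAYS[-1] - BEHAVIOR_DAYS[0])
    return start + (end - start) * frac


def _generate_behavior(spec: PhantomSpec, lesioned: bool, rng):
    """Synthetic deficit-score sheets and cylinder counts per group."""
    item_design = {
        "treated": {"posture": (2.2, 0.7), "activity": (2.2, 0.7),
                    "hair": (1.2, 0.4), "eyes": (1.5, 0.1),
                    **{k: (2.4, 0.9) for k in _FOCAL_ITEMS}},
        "control": {"posture": (2.2, 1.6), "activity": (2.2, 1.6),
                    "hair": (1.2, 0.9), "eyes": (1.5, 0.2),
                    **{k: (2.4, 1.8) for k in _FOCAL_ITEMS}},
    }
    cyl_design = {"treated": (0.74, 0.58), "control": (0.74, 0.70)}
    if not lesioned:
        item_design = {g: {k: (0.0, 0.0) for k in {**_GENERAL_ITEMS, **_FOCAL_ITEMS}}
                       for g in ("treated", "control")}
        cyl_design = {g: (0.5, 0.5) for g in ("treated", "control")}
    score_rows, cyl_rows = [], []
    for group in ("treated", "control"):
        for a in range(spec.n_per_group):
            aid = f"{group}_{a:02d}"
            for day in BEHAVIOR_DAYS:
                row = {"animal": aid, "group": group, "day": day}
                for item, mx in {**_GENERAL_ITEMS, **_FOCAL_ITEMS}.items():
                    m = _interp_mean(day, *item_design[group][item])
                    row[item] = int(np.clip(round(m + 0.7 * rng.standard_normal()),
                                            0, mx))
                score_rows.append(row)
                frac = _interp_mean(day, *cyl_design[group])
                total = int(rng.poisson(22)) + 4
                unimp = int(rng.binomial(total, frac))
                cyl_rows.append({"animal": aid, "group": group, "day": day,
                                 "unimpaired_touches": unimp,
                                 "impaired_touches": total - unimp})
    gt = {"item_design": {g: {k: list(v) for k, v in d.items()}
                          for g, d in item_design.items()},
          "cylinder_unimpaired_fraction": {g: list(v) for g, v in cyl_design.items()}}
    return pd.DataFrame(score_rows), pd.DataFrame(cyl_rows), gt


# ---------------------------------------------------------------------------
# the study dataset
# ---------------------------------------------------------------------------

@dataclass
class AnimalSeries:
    animal_id: str
    group: str
    spect: dict
    mri: dict


@dataclass
class StudyDataset:
    spec: PhantomSpec
    scenario: str
    days: tuple
    labels: LabelVolume
    region_table: RegionTable
    healthy: HealthyCohort
    animals: list
    scores: pd.DataFrame
    cylinder: pd.DataFrame
    ground_truth: dict
    design: LesionDesign
    atlas: Atlas

    def group(self, name: str) -> list:
        return [a for a in self.animals if a.group == name]


def generate_study(spec: PhantomSpec, scenario: str = "reference_mcao") -> StudyDataset:
    """Generate a full two-arm longitudinal study with ground truth.

    ``reference_mcao`` encodes the study-matched design (65/67 affected
    regions, 32/8 recovered at day 7, 27 exclusive + 5 shared, 67%/1%
    hypoperfused-volume shrink, +41% day-7 mask-mean contrast);
    ``lesion_free`` emits healthy dynamics in both arms; ``custom`` applies
    the PhantomSpec's own ``lesion_profile`` overrides to the same machinery.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    atlas = build_atlas(spec)
    healthy = generate_healthy_cohort(spec, atlas=atlas)
    if scenario == "lesion_free":
        design = design_lesion_free(atlas)
    else:
        design = design_reference_mcao(atlas)

    mu = _mu_map(atlas)
    dist = atlas.region_info.set_index("region_id")["dist_mm"]
    dep = design.deficit.set_index(["group", "region_id", "day"])["deficit"]
    lesioned = scenario != "lesion_free"
    ep = spec.edema_params

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 301]))
    animals = []
    edema_truth = {}
    for group in ("treated", "control"):
        for a in range(spec.n_per_group):
            aid = f"{group}_{a:02d}"
            spect_by_day, mri_by_day = {}, {}
            for day in spec.timepoints_days:
                f_day = dict(mu)
                for rid in atlas.region_info["region_id"]:
                    key = (group, int(rid), int(day))
                    if key in dep.index:
                        d = float(dep.loc[key])
                        if d != 0.0:
                            f_day[(int(rid), "left")] = mu[(int(rid), "left")] * (1.0 - d)
                spect_by_day[int(day)] = _spect_volume(atlas, f_day, rng)
                if spec.include_mri:
                    ed = ep["edema_volume_mm3"] if (lesioned and day >= ep["onset_day"]) else 0.0
                    sw = ep["swelling_mm3"] if (lesioned and day >= ep["onset_day"]) else 0.0
                    mri, realized = _mri_volume(atlas, rng, edema_mm3=ed,
                                                swelling_mm3=sw)
                    mri_by_day[int(day)] = mri
                    edema_truth[str(int(day))] = realized
            animals.append(AnimalSeries(animal_id=aid, group=group,
                                        spect=spect_by_day, mri=mri_by_day))
    scores, cylinder, behavior_gt = _generate_behavior(
        spec, lesioned, np.random.default_rng(np.random.SeedSequence([spec.seed, 302])))

    lesion_mask = np.zeros(spec.grid_shape, dtype=bool)
    if lesioned:
        aff = set(design.affected["treated"])
        lesion_mask = np.isin(atlas.labels.region_ids, list(aff)) \
            & atlas.labels.hemisphere_mask("left")

    ground_truth = {
        "scenario": scenario,
        "designed": design.designed,
        "true_lesion_voxels": int(lesion_mask.sum()),
        "true_lesion_volume_mm3": float(lesion_mask.sum()) * atlas.labels.voxel_volume_mm3,
        "edema_volume_mm3_by_day": edema_truth,
        "designed_edema_volume_mm3": ep["edema_volume_mm3"] if lesioned else 0.0,
        "behavior": behavior_gt,
        "healthy_design": {f"{int(r.region_id)}:{r.hemisphere}": float(r.mu)
                           for r in atlas.design.itertuples()},
    }
    return StudyDataset(spec=spec, scenario=scenario,
                        days=tuple(int(d) for d in spec.timepoints_days),
                        labels=atlas.labels, region_table=atlas.region_table,
                        healthy=healthy, animals=animals, scores=scores,
                        cylinder=cylinder, ground_truth=ground_truth,
                        design=design, atlas=atlas)


def designed_region_means(study: StudyDataset) -> pd.DataFrame:
    """Designed (noise-free) per-region ipsilesional rCBF, group x day."""
    mu = _mu_map(study.atlas)
    out = study.design.deficit.copy()
    out["mu"] = [mu[(int(r), "left")] for r in out["region_id"]]
    out["rcbf"] = out["mu"] * (1.0 - out["deficit"])
    return out


def generate_contralesional_mri(seed: int = 0, shape=(64, 64, 50),
                                voxel_size_mm: float = 0.46,
                                ventricle_fraction: float = 0.024,
                                parenchyma_mean: float = 100.0,
                                parenchyma_sd: float = 10.0,
                                ventricle_mean: float = 200.0,
                                ventricle_sd: float = 10.0):
    """A stand-alone synthetic contralesional hemisphere for histogram work.

    Every voxel belongs to the right hemisphere; intensities are a mixture
    of a dominant Gaussian parenchymal component and a small bright
    ventricle component.  Returns ``(VolumeGrid, LabelVolume)``.
    """
    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    vals = parenchyma_mean + parenchyma_sd * rng.standard_normal(n)
    n_vent = int(round(ventricle_fraction * n))
    vent_flat = np.zeros(n, dtype=bool)
    vent_idx = rng.choice(n, size=n_vent, replace=False)
    vent_flat[vent_idx] = True
    vals[vent_flat] = ventricle_mean + ventricle_sd * rng.standard_normal(n_vent)
    vol = VolumeGrid(values=vals.reshape(shape), voxel_size_mm=(voxel_size_mm,) * 3,
                     origin_mm=(0.0, 0.0, 0.0), modality="MRI")
    labels = LabelVolume(
        region_ids=np.ones(shape, dtype=np.int16),
        hemisphere_ids=np.full(shape, LabelVolume.HEMI_RIGHT, dtype=np.int16),
        ventricle_mask=vent_flat.reshape(shape),
        voxel_size_mm=(voxel_size_mm,) * 3, origin_mm=(0.0, 0.0, 0.0))
    return vol, labels
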
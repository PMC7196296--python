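# Methods

This note documents the models, conventions and parameter choices behind
`strokeflow`, what the synthetic phantom does and does not emulate, and the
numerical decisions a user should know before trusting a number.

## Coordinates and lattices

All volumes of a study live on congruent lattices (same shape, spacing,
world origin); congruence is *required*, never repaired by resampling —
registration is upstream and out of scope. Voxel indices are 0-based; world
coordinates are continuous millimetres with the center of voxel (i, j, k)
at `origin + (index + 0.5)·spacing`, which makes shell distances
unambiguous. The NIfTI affine's translation stores the center of voxel
(0, 0, 0); the half-voxel shift is applied symmetrically on read and write,
so round trips are exact. Masked-out (extrameningeal) voxels are NaN and
excluded from every statistic. Volumes are consumed as stored; no
reorientation is attempted.

The phantom's world frame puts bregma at the origin on the dorsal midline:
x is medio-lateral (left = ipsilesional = negative), y antero-posterior,
z dorso-ventral (dorsal 0, ventral negative). The stereotaxic injection
target AP +0.3 mm, ML −4.0 mm, DV +4.8 mm therefore sits at world
(−4.0, +0.3, −4.8).

## Lassen linearization

HMPAO trapping underestimates high flow. With uptake ratio
R = activity / mean(reference activity), the corrected relative flow is
F(R) = αR / (1 + (α − 1)R). Any functional form with F(1) = 1 preserves
the anchoring of the reference region at rCBF 1; α (default 0.5) and the
form are recorded on every parametric map, and maps with different α are
never pooled. Published α conventions differ (some formulations use
α > 1); α is configurable and every test property used here is either
independent of the convention or uses the default. The reference region is
the mean over all finite contralesional (right) hemisphere voxels (median
available). For α < 1 the transform has a pole at R = 1/(1 − α); ratios at
or beyond it are clamped just below the pole and counted on the map
(`n_clamped`) — physiological ratios sit far from the pole, so a non-zero
count flags corrupt input.

## Perfusion classification

The healthy reference stores mean, SD and n of relative rCBF per (region,
hemisphere) — hemisphere-resolved because healthy rCBF differs between
hemispheres region-specifically. Voxels are classified against their own
region's mean ± 2·SD band (hypo below, hyper above, otherwise normal);
voxels outside any atlas region are `outside` and excluded from volumes, so
hypo + normal + hyper volumes always sum to the classified brain volume.
No connected-component filtering is applied: the affected volumes are pure
threshold groupings. A band of ±2 SD means ~2.3 % of genuinely healthy
tissue is flagged on each side (two Gaussian tails, 2·Φ(−2) = 4.55 %); this
false-positive floor is intrinsic to the method and visible in the
lesion-free calibration tests. Bands derive only from the healthy cohort,
never from study data. A degenerate zero-SD band (possible with a noise-free
cohort) is widened by a ~1e-9 relative tolerance so that values equal to
the mean up to float rounding stay inside.

## Recovery classification

A region is *affected* when its group-mean rCBF at the baseline day lies
outside the healthy band (group means, not any-animal criteria — the
documented default). An affected region is *recovered* at a later day when
its group values are no longer distinguishable from healthy. Two criteria
are provided:

- `band` (default): the group mean has returned inside the ±2SD band.
  This treats day-0 and day-7 calls symmetrically, is deterministic given
  the stored means, and makes the report recomputable from means/SEs and
  the reference alone.
- `ttest`: Welch's two-sample test against the per-animal healthy cohort
  values at `sig_level` (default 0.05). Note an irreducible property of
  this criterion: for a region whose true mean has returned exactly to
  healthy, the test still rejects at the α rate, so ~5 % of genuinely
  recovered regions are mislabelled regardless of sample size. That is why
  the band criterion is the default; the t-test remains available because
  "significantly different" is the field's usual phrasing.

A recovered region whose mean exceeds the upper band is `hyper_after_
recovery` and still counts as recovered. No multiple-testing correction is
applied across the 72 regions by default (matching the presentation style
of region-wise stroke analyses); Benjamini–Hochberg can be applied to the
stored p-values by the caller. The Welch test is extended to degenerate
constant samples (equal constants → p = 1, different constants → p = 0) so
noise-free phantoms classify exactly.

## Day-0 mask time course

Each animal's day-0 hypoperfused voxels (restricted to the ipsilesional
hemisphere) form a fixed 3-D mask applied to every timepoint of the same
animal. Mean rCBF inside the mask is computed voxel-wise (average of the
parametric map) and ROI-wise (average the raw SPECT, ratio to the
reference, one Lassen transform). The two agree exactly on homogeneous
masks and differ by Jensen-type curvature otherwise; both are always
reported. Per-timepoint hypoperfused volume is each day's own
classification, ipsilesionally.

## Distance shells

Classified brain voxels are binned by Euclidean distance of their centers
from the injection site into shells of width 1 mm (configurable).
"Affected" is hypo ∪ hyper — tissue significantly different from healthy
in either direction. Shell totals partition the brain, so per-shell
affected volumes conserve the total affected volume. The recovery
difference profile is control-affected − treated-affected per shell and
may be negative.

## Edema volumetry

The contralesional intensity histogram (Freedman–Diaconis bins by default;
the binning rule is configurable because none is canonical) is fitted with
a least-squares Gaussian initialized at the median/IQR so the small bright
CSF component cannot capture the fit. The absolute threshold is μ + 2σ on
the *bright* side: T2 edema and CSF are hyperintense, and only keep-above
is consistent with a threshold that excludes ~98 % of contralesional pixels
leaving the brightest ~2 % (ventricles). The literal "subtract 2 SD from
the mean" reading is available behind `literal_subtraction`. Raw edema
volume counts ipsilesional voxels above threshold; the contralesional
ventricle volume (from the ventricle label) is subtracted because
ipsilesional ventricles cannot be isolated inside the edema; the
space-occupying excess max(0, V_ipsi − V_contra) is removed, on volumes
(mm³), not per-slice areas, since a single corrected size is reported.
All terms are separately inspectable and the corrected volume is clamped
at zero with a flag.

On an ideal-Gaussian parenchyma the μ + 2σ threshold necessarily keeps
~2.3 % of healthy ipsilesional tissue, so the corrected volume carries a
false-positive offset of ~0.023 × hemisphere volume; the sharp-ground-truth
tests therefore use truncated parenchymal noise, and on real data the
offset is implicit in the method itself (thresholding real histograms has
the same property unless the parenchymal tail is sub-Gaussian).

## The phantom

The generator emulates the statistical structure the analysis assumes, at
desk scale, with every designed quantity recorded as ground truth.

**Anatomy.** An ellipsoidal brain (defaults: 54×64×40 voxels at 0.33 mm —
SPECT-like isovoxels; MRI-like specs may use 0.46 mm, but all volumes of
one spec share one lattice because the pipeline requires congruence) split
at the midline; 77 atlas regions grown by multiplicatively weighted Voronoi
from evenly spread seeds in the left hemisphere and mirrored to the right;
small deep ventricles (~2.4 % of hemisphere volume) carved out of both
hemispheres. Region ids 4, 13, 75 (no data) and 56, 71 (incomplete) are
flagged excluded, leaving 72 analyzed regions. A handful of deliberately
tiny and large regions is planted at lesion-relevant distances so that
recovery subsets with prescribed volume fractions exist — real atlases span
a similar size range.

**Healthy design.** Per-region healthy rCBF levels are not published for
this paradigm, so the phantom *designs* them: near 1.0 with region-specific
offsets (±4 %) and small hemisphere asymmetries (±1.5 %), anchored so the
right-hemisphere uptake ratio averages exactly 1. Recovery of designed
values — not agreement with unpublished animal data — is the test. The
healthy reference table is *measured* by running the actual pipeline on the
cohort (n = 15 by default), so with zero noise it equals the design
exactly.

**Lesion scenarios.** `reference_mcao` encodes the study-matched design on
the measured atlas geometry: 65 treated-arm and 67 control-arm regions
perturbed outside the healthy band at day 0, with day-0 deficit depth
decaying with distance from the injection site (55–62 % in the core,
floor 28 % far away); 32 treated regions (27 exclusive + 5 shared, three of
them overshooting into hyperperfusion) and 8 control regions designed to
return inside the band by day 7, chosen so the recovered volume fraction is
67 % (treated) and 1 % (control) of the day-0 affected volume and so the
day-7 mask-mean contrast solves to exactly +41 % (the control residual
scale is solved in closed form from the designed trajectories). Core
regions (< 1.8 mm) never recover; treated-recovered regions are selected
outward from 2 mm, concentrating the recovery difference in the 2–6 mm
penumbra shells. Designed trajectories approach their day-7 value
exponentially (half-time 1.75 d per arm, configurable per group), pinned
exactly at day 0 and day 7; an optional relapse term after day 14 is off by
default. `lesion_free` emits healthy dynamics in both arms; `custom` runs
the same machinery on user overrides of the lesion profile.

**Noise.** One knob, `noise_sd` (default 0.05), scales two components:
per-animal-per-region biological variability applied as a measured-space
flow scale factor (sd = noise_sd), and additive instrumental voxel noise on
activity (sd = noise_sd × `voxel_noise_frac`, default 0.25 — reconstructed
SPECT is smooth, so region-scale variability dominates). `noise_sd = 0`
therefore makes every output exactly equal to the design, which the test
suite exploits: the full pipeline on a noise-free `reference_mcao` dataset
reproduces every designed count, mask and volume exactly. Draws are
independent across animals, regions and days; all randomness flows from
`SeedSequence(seed)`, so identical (spec, seed) pairs are byte-identical.

**MRI.** Parenchyma N(100, 10), ventricles N(200, 10), an edema sphere at
the injection site (default 40 mm³, +60 intensity) appearing at the onset
day (default day 3, matching the observed development of vasogenic edema
by day 3 and its persistence to day 21), plus a deterministic swollen rim
of ipsilesional tissue (default 10 mm³) emulating the space-occupying
effect.

**Behaviour.** Score sheets and cylinder counts are drawn around designed
group trajectories (treated deficits resolving faster; eye scores recovering
by day 8 in both arms; cylinder unimpaired-use fraction 0.74 → 0.58 treated
vs 0.74 → 0.70 control) on the standard testing days 4–21.

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: photon transport, collimator blur, partial-volume
effects, motion, registration or skull-stripping error; spatially
correlated or heavy-tailed noise; inter-regional covariance of healthy
rCBF; contralesional (diaschisis-like) perturbations — the reference
hemisphere stays at healthy levels by design; anatomically realistic region
shapes or any mapping of synthetic region ids onto a real atlas's anatomy.

## Expected values of the headline quantities

Because classification carries the 2·Φ(−2) false-positive floor, measured
study-scale quantities sit near, not exactly at, their designed values: the
day-7 hypoperfused volume regains ~3 % of the recovered-region volume from
band tails, so the measured treated-arm shrink runs ~2–5 points below the
designed 67 %, and the measured threshold-exclusion percentage on the
mixture hemisphere is Φ(2) × (1 − ventricle fraction) ≈ 95.4 % rather than
the ~97.7 % of a ventricle-free hemisphere. The acceptance script reports
the measured values, never the designed ones.

## Problem sizes

Default study scale — 54×64×40 voxels, 15 healthy + 2×6 study animals,
7 timepoints — was chosen so a full generate-and-analyze cycle completes in
seconds on one CPU while every region keeps enough voxels for stable means
(tiny regions ≥ ~10 voxels). Unit tests use smaller grids where geometry
does not matter.

## Known limitations

- Recovery calls are group-level; per-animal recovery heterogeneity is not
  classified (per-animal masks are used only for volumes and mask means).
- The band criterion inherits the healthy cohort's SD estimate; with very
  small cohorts (n < 10) band widths are noisy and false-affected calls
  rise accordingly.
- ROI-wise and voxel-wise mask means are both reported but no preference is
  enforced; they diverge when the mask is heterogeneous.
- Absolute CBF is out of scope (no arterial input function); all rCBF is
  relative to the contralesional hemisphere, so bilateral perfusion changes
  are invisible by construction.
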
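import numpy as np
import pandas as pd
import pytest

from strokeflow.grid import LabelVolume, VolumeGrid
from strokeflow.perfusion import (PerfusionClassification, parametric_map)
from strokeflow.regions import (apply_region_exclusions, classify_recovery,
                                region_rcbf, shell_profile,
                                shell_recovery_difference, study_region_means,
                                welch_ttest)
from strokeflow.tables import HealthyReference, RegionTable

from conftest import make_hemisphere_labels, make_volume


def _table(n=77):
    return RegionTable(pd.DataFrame({
        "region_id": range(1, n + 1),
        "name": [f"r{i}" for i in range(1, n + 1)],
        "hemisphere": ["both"] * n}))


class TestExclusions:
    def test_named_exclusions_leave_72_active(self):
        table = apply_region_exclusions(_table(), no_data=[4, 13, 75],
                                        incomplete=[56, 71])
        assert len(table) == 77          # rows are flagged, never deleted
        assert table.n_active == 72
        assert table.frame.loc[table.frame.region_id == 4, "excluded"].item()

    def test_empty_exclusions(self):
        assert apply_region_exclusions(_table()).n_active == 77

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="999"):
            apply_region_exclusions(_table(), no_data=[999])


class TestRegionRcbf:
    def test_uniform_map_gives_unit_means(self):
        labels = make_hemisphere_labels()
        pmap = parametric_map(make_volume(np.full(labels.shape, 3.0)), labels)
        means = region_rcbf(pmap, labels, _table(1))
        assert np.allclose(means["rcbf"], 1.0)
        assert set(means["hemisphere"]) == {"left", "right"}

    def test_zero_noise_study_matches_design(self, zero_noise_study):
        from strokeflow.phantom import designed_region_means
        study = zero_noise_study
        means = study_region_means(study)
        des = designed_region_means(study)
        merged = means[means["hemisphere"] == "left"].merge(
            des, on=["group", "day", "region_id"], suffixes=("", "_designed"))
        assert np.abs(merged["rcbf"] - merged["rcbf_designed"]).max() < 1e-10

    def test_excluded_regions_absent(self, ref_study):
        study = ref_study
        a = study.animals[0]
        pmap = parametric_map(a.spect[0], study.labels)
        means = region_rcbf(pmap, study.labels, study.region_table)
        assert set(means["region_id"]).isdisjoint({4, 13, 75, 56, 71})
        assert means["region_id"].nunique() == 72


def _toy_study(seed=0, n_regions=6, n_animals=4, days=(0, 7), shift=None):
    """Hand-sized per-animal region means plus a healthy reference."""
    rng = np.random.default_rng(seed)
    healthy_mean = {r: 1.0 + 0.02 * r for r in range(1, n_regions + 1)}
    sd = 0.05
    ref = HealthyReference(pd.DataFrame(
        [{"region_id": r, "hemisphere": "left", "mean": healthy_mean[r],
          "sd": sd, "n": 15} for r in healthy_mean]))
    rows = []
    for g in ("treated", "control"):
        for a in range(n_animals):
            for d in days:
                for r in healthy_mean:
                    mu = healthy_mean[r]
                    if shift is not None:
                        mu = mu * (1.0 - shift.get((g, r, d), 0.0))
                    rows.append({"animal": f"{g}{a}", "group": g, "day": d,
                                 "region_id": r, "hemisphere": "left",
                                 "rcbf": mu + 0.01 * rng.standard_normal()})
    return pd.DataFrame(rows), ref


class TestRecovery:
    def test_null_case_all_unaffected(self):
        means, ref = _toy_study()
        rep = classify_recovery(means, ref)
        assert (rep.table["status"] == "unaffected").all()

    def test_shifted_region_non_regenerated(self):
        shift = {(g, 1, d): 0.25 for g in ("treated", "control") for d in (0, 7)}
        means, ref = _toy_study(shift=shift)
        rep = classify_recovery(means, ref)
        r1 = rep.table[rep.table["region_id"] == 1]
        assert (r1["status"] == "non_regenerated").all()

    def test_recovered_and_hyper_after_recovery(self):
        shift = {("treated", 1, 0): 0.25, ("treated", 2, 0): 0.25,
                 ("treated", 2, 7): -0.25}
        means, ref = _toy_study(shift=shift)
        rep = classify_recovery(means, ref)
        t = rep.table[(rep.table["group"] == "treated") & (rep.table["day"] == 7)]
        assert t[t["region_id"] == 1]["status"].item() == "recovered"
        assert t[t["region_id"] == 2]["status"].item() == "hyper_after_recovery"
        assert rep.recovered_ids("treated", 7) == [1, 2]

    def test_summary_count_identities(self, ref_study):
        rep = classify_recovery(study_region_means(ref_study),
                                ref_study.healthy.reference)
        s = rep.summary(7)
        assert s["treated_recovered"] == s["treated_exclusive"] + s["shared"]
        assert s["control_recovered"] == s["control_exclusive"] + s["shared"]
        assert set(rep.recovered_ids("treated", 7)) <= set(rep.affected_ids("treated"))

    def test_stricter_band_never_increases_recovered(self):
        shift = {("treated", r, 0): 0.3 for r in range(1, 7)}
        shift.update({("treated", r, 7): 0.06 for r in (1, 2, 3)})
        means, ref = _toy_study(shift=shift)
        prev = None
        for k in (3.0, 2.0, 1.0, 0.5):
            rep = classify_recovery(means, ref, k_sd=k)
            n = len(rep.recovered_ids("treated", 7))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_ttest_mode_matches_band_on_clear_cases(self):
        shift = {("treated", 1, 0): 0.3, ("treated", 1, 7): 0.3,
                 ("treated", 2, 0): 0.3}
        means, ref = _toy_study(shift=shift, n_animals=6)
        rng = np.random.default_rng(3)
        hv = pd.DataFrame([{"animal": f"h{a}", "region_id": r, "hemisphere": "left",
                            "rcbf": ref.row(r, "left")["mean"]
                            + 0.05 * rng.standard_normal()}
                           for a in range(15) for r in range(1, 7)])
        rep = classify_recovery(means, ref, mode="ttest", healthy_values=hv)
        t = rep.table[(rep.table["group"] == "treated") & (rep.table["day"] == 7)]
        assert t[t["region_id"] == 1]["status"].item() == "non_regenerated"
        assert t[t["region_id"] == 2]["status"].item() == "recovered"
        assert np.isfinite(t["p_healthy"]).all()

    def test_exhaustive_oracle_small_study(self):
        """Report equals a straightforward per-region reimplementation."""
        shift = {("treated", 1, 0): 0.3, ("treated", 1, 7): 0.3,
                 ("treated", 2, 0): 0.3, ("control", 3, 0): -0.3,
                 ("control", 3, 7): -0.3}
        means, ref = _toy_study(shift=shift, n_regions=8)
        rep = classify_recovery(means, ref)
        df = means[means["hemisphere"] == "left"]
        for row in rep.table.itertuples():
            sub = df[(df["group"] == row.group) & (df["region_id"] == row.region_id)]
            lo, hi = ref.band(row.region_id, "left")
            m0 = sub[sub["day"] == rep.baseline_day]["rcbf"].mean()
            md = sub[sub["day"] == row.day]["rcbf"].mean()
            affected = not (lo <= m0 <= hi)
            if not affected:
                expected = "unaffected"
            elif lo <= md <= hi:
                expected = "recovered"
            elif md > hi:
                expected = "hyper_after_recovery"
            else:
                expected = "non_regenerated"
            assert row.status == expected
            assert row.mean == pytest.approx(md)

    def test_degenerate_group_rejected(self):
        means, ref = _toy_study(n_animals=1)
        with pytest.raises(ValueError, match="2 animals"):
            classify_recovery(means, ref)


def test_welch_degenerate_samples():
    assert welch_ttest([1, 1, 1], [1, 1, 1])[1] == 1.0
    assert welch_ttest([1, 1, 1], [2, 2, 2])[1] == 0.0


def _classification_from_classes(classes, voxel_size_mm=0.5):
    vol = VolumeGrid(classes.astype(float), voxel_size_mm=(voxel_size_mm,) * 3,
                     origin_mm=(0.0, 0.0, 0.0), modality="PARAMETRIC")
    return PerfusionClassification(classes=vol, region_table=pd.DataFrame(),
                                   voxel_volume_mm3=voxel_size_mm ** 3)


class TestShells:
    def test_single_affected_voxel_at_site(self):
        classes = np.full((10, 10, 10), 2, dtype=np.int16)
        classes[4, 4, 4] = 1
        cls = _classification_from_classes(classes, voxel_size_mm=1.0)
        site = (4.5, 4.5, 4.5)  # the voxel center
        prof = shell_profile(cls, site)
        assert prof.affected_mm3[0] == pytest.approx(1.0)
        assert prof.affected_mm3[1:].sum() == 0.0

    def test_shells_partition_brain(self):
        rng = np.random.default_rng(0)
        classes = rng.choice([0, 1, 2, 3], size=(12, 12, 12)).astype(np.int16)
        cls = _classification_from_classes(classes)
        prof = shell_profile(cls, (3.0, 3.0, 3.0))
        brain_mm3 = np.sum(classes != 0) * 0.5 ** 3
        assert prof.total_mm3.sum() == pytest.approx(brain_mm3)
        affected_mm3 = np.sum((classes == 1) | (classes == 3)) * 0.5 ** 3
        assert prof.total_affected_mm3 == pytest.approx(affected_mm3)

    def test_uniform_sphere_matches_analytic_shell_volumes(self):
        n, vx = 48, 0.5
        classes = np.full((n, n, n), 2, dtype=np.int16)
        center = np.array([n * vx / 2] * 3)
        ax = (np.arange(n) + 0.5) * vx
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        dist = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2
                       + (z - center[2]) ** 2)
        r = 3.0
        classes[dist <= r] = 1
        cls = _classification_from_classes(classes, voxel_size_mm=vx)
        prof = shell_profile(cls, tuple(center))
        for i in range(4):
            lo, hi = i, min(i + 1, r)
            analytic = 4.0 / 3.0 * np.pi * (hi ** 3 - lo ** 3) if lo < r else 0.0
            # within one voxel layer of the shell surface
            layer = 4.0 * np.pi * max(hi, 1.0) ** 2 * vx
            assert abs(prof.affected_mm3[i] - analytic) < layer

    def test_site_outside_bounds_rejected(self):
        cls = _classification_from_classes(np.ones((8, 8, 8), dtype=np.int16))
        with pytest.raises(ValueError, match="outside"):
            shell_profile(cls, (100.0, 0.0, 0.0))

    def test_difference_identical_profiles_is_zero(self):
        classes = np.full((10, 10, 10), 1, dtype=np.int16)
        cls = _classification_from_classes(classes)
        p = shell_profile(cls, (2.5, 2.5, 2.5))
        d = shell_recovery_difference(p, p)
        assert np.all(d.affected_mm3 == 0.0)

    def test_difference_edges_mismatch_rejected(self):
        classes = np.full((10, 10, 10), 1, dtype=np.int16)
        cls = _classification_from_classes(classes)
        a = shell_profile(cls, (2.5, 2.5, 2.5), bin_width_mm=1.0)
        b = shell_profile(cls, (2.5, 2.5, 2.5), bin_width_mm=0.7)
        with pytest.raises(ValueError, match="mismatch"):
            shell_recovery_difference(a, b)

    def test_reference_mcao_recovery_concentrated_in_penumbra(self, ref_study):
        from strokeflow.perfusion import classify_perfusion
        study = ref_study
        site = study.spec.injection_site_mm
        profs = {}
        for g in ("treated", "control"):
            a = study.group(g)[0]
            pm = parametric_map(a.spect[7], study.labels)
            cls = classify_perfusion(pm, study.healthy.reference, study.labels)
            profs[g] = shell_profile(cls, site, hemisphere="left",
                                     labels=study.labels)
        d = shell_recovery_difference(profs["treated"], profs["control"])
        total = d.affected_mm3.sum()
        assert total > 0
        # the 0-1 mm core is not recovered; the 2-6 mm penumbra dominates
        assert d.affected_mm3[0] < 0.02 * total
        assert d.affected_mm3[2:6].sum() > 0.5 * total
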
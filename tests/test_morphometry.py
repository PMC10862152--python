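"""Morphometry: volumes, bone lengths, relative volumes, summaries."""

import numpy as np
import pytest

import leggrowth as lg
from leggrowth.morphometry import (
    DegenerateGeometryError,
    UnknownLabelError,
    relative_volumes,
)


def _cuboid_phantom(spacing=(1.0, 1.0, 1.0)):
    shape = lg.Shape("cuboid", 1, (15, 15, 15), (10, 10, 10))
    return lg.make_phantom(lg.PhantomSpec((30, 30, 30), spacing, (shape,)))


class TestLabelVolume:
    def test_cuboid_volume(self):
        lv = _cuboid_phantom()
        assert lg.label_volume(lv, 1) == pytest.approx(1.0, rel=0.05)

    def test_label_absent_from_array_is_zero(self):
        lv = _cuboid_phantom()
        lv.labels[9] = ("GHOST", "muscle")
        assert lg.label_volume(lv, 9) == 0.0

    def test_unknown_label_raises(self):
        with pytest.raises(UnknownLabelError):
            lg.label_volume(_cuboid_phantom(), 42)

    def test_volume_additivity_over_labels(self):
        s1 = lg.Shape("cuboid", 1, (8, 8, 8), (8, 8, 8))
        s2 = lg.Shape("ellipsoid", 2, (24, 24, 24), (6, 5, 4))
        lv = lg.make_phantom(lg.PhantomSpec((36, 36, 36), (1, 1, 1), (s1, s2)))
        grid_cm3 = lv.data.size * lv.voxel_volume_mm3 / 1000
        background = np.count_nonzero(lv.data == 0) * lv.voxel_volume_mm3 / 1000
        total = lg.label_volume(lv, 1) + lg.label_volume(lv, 2) + background
        assert total == pytest.approx(grid_cm3, abs=1e-12)

    def test_anisotropic_spacing_preserves_physical_volume(self):
        # same 10 mm cuboid voxelized at 1 mm and at 2 mm slices: the
        # physical volume is spacing-independent even though each
        # anisotropic voxel is twice as large
        iso = _cuboid_phantom((1.0, 1.0, 1.0))
        aniso = _cuboid_phantom((1.0, 1.0, 2.0))
        assert aniso.voxel_volume_mm3 == 2 * iso.voxel_volume_mm3
        assert lg.label_volume(iso, 1) == pytest.approx(1.0, rel=0.01)
        assert lg.label_volume(aniso, 1) == pytest.approx(1.0, rel=0.01)


class TestBoneLength:
    def test_axis_aligned_rod(self):
        rod = lg.Shape("cylinder", 1, (20, 20, 60), (4, 100))
        lv = lg.make_phantom(lg.PhantomSpec((40, 40, 120), (1, 1, 1), (rod,)))
        assert lg.bone_length(lv, 1) == pytest.approx(10.0, abs=0.1)

    def test_rotation_invariance_within_voxel_diagonal(self):
        lengths = []
        for angles in [(0, 0, 0), (30, 0, 0), (30, 40, 0), (20, 35, 50)]:
            rod = lg.Shape("cylinder", 1, (60, 60, 60), (4, 100), angles)
            lv = lg.make_phantom(lg.PhantomSpec((120, 120, 120), (1, 1, 1), (rod,)))
            lengths.append(lg.bone_length(lv, 1))
        diag_cm = np.sqrt(3) / 10
        assert max(lengths) - min(lengths) <= diag_cm

    def test_sphere_length_is_diameter(self):
        ball = lg.Shape("ellipsoid", 1, (30, 30, 30), (12, 12, 12))
        lv = lg.make_phantom(lg.PhantomSpec((60, 60, 60), (1, 1, 1), (ball,)))
        # isotropic cloud: any principal axis returns the diameter
        assert lg.bone_length(lv, 1) == pytest.approx(2.4, abs=0.2)

    def test_single_voxel_degenerate(self):
        lv = _cuboid_phantom()
        lv.data[:] = 0
        lv.data[3, 3, 3] = 1
        with pytest.raises(DegenerateGeometryError):
            lg.bone_length(lv, 1)


class TestRelativeVolumes:
    def test_reference_infant_boys_proportions(self):
        ref = lg.reference_summary()
        means = ref.query("sex == 'boy' and band_lo == 0").set_index("variable")["mean"]
        record = {f"V_{m}": means[m] for m in lg.MUSCLES}
        r = relative_volumes(record)
        assert r["r_SOL"] == pytest.approx(6.7 / 31.0, abs=1e-3)
        assert sum(r.values()) == pytest.approx(1.0, abs=1e-9)

    def test_equal_volumes_give_tenths(self):
        r = relative_volumes({f"V_{m}": 5.0 for m in lg.MUSCLES})
        assert all(v == pytest.approx(0.1, abs=1e-12) for v in r.values())

    def test_scale_invariance(self, rng):
        vols = {f"V_{m}": float(v) for m, v in zip(lg.MUSCLES, rng.uniform(1, 50, 10))}
        scaled = {k: 7.3 * v for k, v in vols.items()}
        r1, r2 = relative_volumes(vols), relative_volumes(scaled)
        assert all(r1[k] == pytest.approx(r2[k], rel=1e-12) for k in r1)

    def test_missing_muscle_rejected(self):
        record = {f"V_{m}": 1.0 for m in lg.MUSCLES[:-1]}
        with pytest.raises(ValueError):
            relative_volumes(record)


class TestGroupSummary:
    def test_single_row_stratum_sd_flagged(self, calibrated_spec):
        df = lg.simulate_cohort(calibrated_spec, {"boy": (1, 0, 0, 0, 0)}, seed=0)
        summ = lg.summarize_groups(df)
        row = summ.query("sex == 'boy' and band == '[0,0.3)' and variable == 'V_SOL'")
        assert row["n"].item() == 1
        assert row["sd_undefined"].item()
        assert row["min"].item() == row["max"].item() == row["mean"].item()

    def test_tsurae_mean_is_sum_of_component_means(self, calibrated_cohort):
        summ = lg.summarize_groups(calibrated_cohort)
        sub = summ.query("sex == 'girl' and band == '[5,7.5)'").set_index("variable")
        expected = sub.loc[["V_LG", "V_MG", "V_SOL"], "mean"].sum()
        assert sub.loc["TSURAE", "mean"] == pytest.approx(expected, abs=1e-9)

    def test_unbinned_ages_reported_not_dropped(self, calibrated_cohort):
        df = calibrated_cohort.copy()
        df.loc[df.index[0], "age"] = 3.0  # inside the unscanned gap
        summ = lg.summarize_groups(df)
        unb = summ[summ.band == "unbinned"]
        assert len(unb) > 0 and unb["n"].max() == 1
        total_n = summ[summ.variable == "V_SOL"]["n"].sum()
        assert total_n == int(df["included"].sum())

    def test_excluded_rows_omitted(self, calibrated_cohort):
        df = calibrated_cohort.copy()
        df.loc[df.index[:5], "included"] = False
        summ = lg.summarize_groups(df)
        assert summ[summ.variable == "V_SOL"]["n"].sum() == len(df) - 5


class TestLabelVolumeIO:
    def test_nifti_sidecar_roundtrip(self, tmp_path):
        shape = lg.Shape("ellipsoid", 2, (20, 18, 25), (8, 6, 12), (15, 0, 30))
        lv = lg.make_phantom(
            lg.PhantomSpec((40, 36, 50), (1.0, 1.0, 1.0), (shape,)),
            label_kinds={2: ("SOL", "muscle")},
        )
        path = tmp_path / "phantom.nii"
        lg.write_label_volume(lv, path)
        back = lg.read_label_volume(path)
        assert np.array_equal(back.data, lv.data)
        assert back.spacing == lv.spacing
        assert back.labels == lv.labels
        assert back.ground_truth[2]["volume_cm3"] == pytest.approx(
            lv.ground_truth[2]["volume_cm3"]
        )

    def test_measure_participant_collects_volumes_and_lengths(self):
        muscle = lg.Shape("ellipsoid", 1, (20, 20, 30), (8, 6, 15))
        bone = lg.Shape("cylinder", 2, (45, 45, 35), (3, 60))
        lv = lg.make_phantom(
            lg.PhantomSpec((60, 60, 70), (1, 1, 1), (muscle, bone)),
            label_kinds={1: ("SOL", "muscle"), 2: ("TIB", "bone")},
        )
        rec = lg.measure_participant(lv)
        assert rec["V_SOL"] == pytest.approx(
            lv.ground_truth[1]["volume_cm3"], rel=0.02
        )
        assert rec["tib_length"] == pytest.approx(6.0, abs=0.2)
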
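import numpy as np
import pandas as pd
import pytest

from lymphspect.core import (
    CompartmentMasks,
    ContingencyTable,
    FormatError,
    ImageVolume,
    PatientRecord,
    SchemaError,
    read_cohort_table,
    read_volume,
    write_cohort_table,
    write_volume,
)


class TestVolumeIO:
    def test_write_read_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(1)
        vol = ImageVolume(rng.integers(-1000, 1000, (8, 9, 10)).astype(np.int16),
                          spacing=(0.98, 0.98, 2.0), modality="CT")
        path = tmp_path / "v.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.voxels, vol.voxels)
        assert back.modality == "CT"
        assert back.limb_axis == vol.limb_axis
        assert np.allclose(back.spacing, vol.spacing, atol=1e-6, rtol=0)

    def test_float_roundtrip_and_spect_modality(self, tmp_path):
        rng = np.random.default_rng(2)
        vol = ImageVolume(rng.random((5, 6, 7)) * 100, spacing=(2, 2, 2), modality="SPECT")
        path = tmp_path / "s.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.voxels, vol.voxels, rtol=1e-6)
        assert back.modality == "SPECT"

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FormatError, match="not found"):
            read_volume(tmp_path / "nope.nii.gz")

    def test_garbage_file_raises(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"this is not a nifti")
        with pytest.raises(FormatError):
            read_volume(bad)


class TestImageVolume:
    def test_rejects_bad_spacing_and_shape(self):
        with pytest.raises(ValueError, match="spacing"):
            ImageVolume(np.zeros((4, 4, 4)), spacing=(1, 0, 1))
        with pytest.raises(ValueError, match=">= 2 voxels"):
            ImageVolume(np.zeros((1, 4, 4)), spacing=(1, 1, 1))

    def test_rejects_negative_spect(self):
        with pytest.raises(ValueError, match="non-negative"):
            ImageVolume(np.full((4, 4, 4), -1.0), spacing=(1, 1, 1), modality="SPECT")

    def test_same_grid(self):
        a = ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        b = ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1), modality="SPECT")
        c = ImageVolume(np.zeros((4, 4, 5)), (1, 1, 1))
        assert a.same_grid(b) and not a.same_grid(c)


class TestCompartmentMasks:
    def test_subtraction_identity_constructor(self):
        limb = np.zeros((6, 6, 6), bool)
        limb[1:5, 1:5, :] = True
        bone = np.zeros_like(limb)
        bone[2:4, 2:4, :] = True
        masks = CompartmentMasks.from_limb_bone_muscle(limb, bone, np.zeros_like(limb))
        np.testing.assert_array_equal(masks.subcutaneous, limb & ~bone)

    def test_rejects_identity_violation(self):
        limb = np.ones((4, 4, 4), bool)
        bone = np.zeros_like(limb)
        bone[0] = True
        with pytest.raises(ValueError, match="subtraction identity"):
            CompartmentMasks(limb=limb, bone=bone, muscle=np.zeros_like(limb),
                             subcutaneous=limb)  # SC should exclude bone

    def test_rejects_bone_muscle_overlap(self):
        limb = np.ones((4, 4, 4), bool)
        both = np.zeros_like(limb)
        both[1] = True
        with pytest.raises(ValueError, match="overlap"):
            CompartmentMasks(limb=limb, bone=both, muscle=both,
                             subcutaneous=limb & ~both)

    def test_rejects_mask_outside_limb(self):
        limb = np.zeros((4, 4, 4), bool)
        limb[1:3] = True
        bone = np.ones_like(limb)
        # from_limb_bone_muscle clips inputs to the limb; direct
        # construction is what rejects a leaking mask
        clipped = CompartmentMasks.from_limb_bone_muscle(limb, bone, np.zeros_like(limb))
        assert not (clipped.bone & ~limb).any()
        with pytest.raises(ValueError, match="outside the limb"):
            CompartmentMasks(limb=limb, bone=bone, muscle=np.zeros_like(limb),
                             subcutaneous=limb & ~bone)


class TestPatientRecord:
    @pytest.mark.parametrize("duration,chronic", [
        (60.83, True),   # typical chronic duration
        (11.9, False),   # just under one year
        (12.0, True),    # inclusive boundary
        (0.0, False),
    ])
    def test_chronicity_cut(self, duration, chronic):
        rec = PatientRecord(id="p", extremity="lower", affected_side="left",
                            duration_months=duration)
        assert rec.chronic is chronic

    def test_validation(self):
        with pytest.raises(ValueError):
            PatientRecord(id="p", extremity="arm", affected_side="left", duration_months=1)
        with pytest.raises(ValueError):
            PatientRecord(id="p", extremity="upper", affected_side="left",
                          duration_months=-1)


class TestCohortTable:
    def test_roundtrip_with_extras(self, tmp_path):
        records = [
            PatientRecord(id="a", extremity="upper", affected_side="left",
                          duration_months=60.83, age=61, sex="F",
                          extras={"cancer": "breast"}),
            PatientRecord(id="b", extremity="lower", affected_side="right",
                          duration_months=11.9, contamination_flag=True),
        ]
        path = tmp_path / "cohort.csv"
        write_cohort_table(records, path)
        back = read_cohort_table(path)
        assert [r.id for r in back] == ["a", "b"]
        assert back[0].chronic and not back[1].chronic
        assert back[1].contamination_flag
        assert back[0].extras["cancer"] == "breast"

    def test_missing_required_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"id": ["x"], "extremity": ["upper"],
                      "affected_side": ["left"]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="duration_months"):
            read_cohort_table(path)


class TestContingencyTable:
    def test_marginals_and_total(self):
        t = ContingencyTable(labels=("a", "b"), counts=[[1, 2], [3, 4]])
        assert t.total == 10
        assert t.counts.sum(axis=0).tolist() == [4, 6]

    def test_rejects_negative_and_shape_mismatch(self):
        with pytest.raises(ValueError):
            ContingencyTable(labels=("a", "b"), counts=[[1, -1], [0, 0]])
        with pytest.raises(ValueError):
            ContingencyTable(labels=("a", "b", "c"), counts=[[1, 0], [0, 1]])
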
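"""Volume/structure/dose I-O: round trips, rescale arithmetic, ROI embed."""

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from synct import ct_io
from synct.core import CTVolume, DoseGrid, GeometryError, Grid


def make_volume(rng, shape=(12, 10, 6), spacing=(1.0, 1.2, 2.0)):
    vox = rng.integers(-1000, 1000, size=shape).astype(np.float32)
    return CTVolume(vox, Grid(shape, spacing, (1.0, -2.0, 3.0)))


def write_ct_slice(path, stored, z, rows, cols, spacing, slope=1.0,
                   intercept=-1024.0, with_rescale=True):
    ds = Dataset()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = list(spacing)
    ds.ImagePositionPatient = [0.0, 0.0, z]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    if with_rescale:
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(stored.astype(np.uint16)).tobytes()
    ds.save_as(path, enforce_file_format=True)


class TestNifti:
    def test_round_trip_is_voxel_identical(self, rng, tmp_path):
        vol = make_volume(rng)
        p = tmp_path / "v.nii"
        ct_io.write_nifti(vol, str(p))
        back = ct_io.read_ct(str(p), "nifti")
        np.testing.assert_array_equal(back.voxels, vol.voxels)
        assert back.grid.same_as(vol.grid)

    def test_dose_round_trip(self, rng, tmp_path):
        grid = Grid((6, 6, 4), (2.0, 2.0, 3.0))
        dose = DoseGrid(rng.random((6, 6, 4)).astype(np.float32) * 40, grid)
        p = tmp_path / "d.nii"
        ct_io.write_dose_nifti(dose, str(p))
        back = ct_io.read_dose(str(p), "nifti")
        np.testing.assert_array_equal(back.voxels, dose.voxels)

    def test_negative_dose_rejected(self, tmp_path):
        grid = Grid((4, 4, 2), (1, 1, 1))
        vol = CTVolume(np.full((4, 4, 2), -1.0, np.float32), grid)
        p = tmp_path / "neg.nii"
        ct_io.write_nifti(vol, str(p))
        with pytest.raises(ValueError):
            ct_io.read_dose(str(p), "nifti")


class TestDicomSeries:
    def test_rescale_maps_stored_1024_to_hu_zero(self, tmp_path):
        stored = np.full((4, 5), 1024, dtype=np.uint16)
        for k, z in enumerate((0.0, 2.0, 4.0)):
            write_ct_slice(tmp_path / f"s{k}.dcm", stored, z, 4, 5, (0.8, 0.7))
        vol = ct_io.read_ct(str(tmp_path), "dicom_series")
        np.testing.assert_array_equal(vol.voxels, 0.0)
        assert vol.grid.shape == (5, 4, 3)       # (x=cols, y=rows, z)
        assert vol.grid.spacing == (0.7, 0.8, 2.0)

    def test_inconsistent_slice_spacing_raises(self, tmp_path):
        stored = np.zeros((4, 4), dtype=np.uint16)
        for k, z in enumerate((0.0, 2.0, 5.0)):
            write_ct_slice(tmp_path / f"s{k}.dcm", stored, z, 4, 4, (1, 1))
        with pytest.raises(GeometryError):
            ct_io.read_ct(str(tmp_path), "dicom_series")

    def test_missing_rescale_tags_raise_format_error(self, tmp_path):
        stored = np.zeros((4, 4), dtype=np.uint16)
        write_ct_slice(tmp_path / "s0.dcm", stored, 0.0, 4, 4, (1, 1),
                       with_rescale=False)
        with pytest.raises(ct_io.FormatError):
            ct_io.read_ct(str(tmp_path), "dicom_series")

    def test_write_read_round_trip_within_half_hu(self, rng, tmp_path):
        vol = make_volume(rng, shape=(8, 8, 3))
        ct_io.write_dicom_series(vol, str(tmp_path / "series"))
        back = ct_io.read_ct(str(tmp_path / "series"), "dicom_series")
        assert np.abs(back.voxels - vol.voxels).max() <= 0.5


class TestRtdose:
    def test_scaling_applied_on_read(self, tmp_path):
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTDOSE"
        ds.DoseGridScaling = 0.001
        ds.Rows, ds.Columns = 3, 4
        ds.NumberOfFrames = 2
        ds.PixelSpacing = [1.0, 1.0]
        ds.GridFrameOffsetVector = [0.0, 2.5]
        ds.ImagePositionPatient = [0.0, 0.0, 10.0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        arr = np.full((2, 3, 4), 40000, dtype=np.uint16)
        ds.PixelData = arr.tobytes()
        p = tmp_path / "dose.dcm"
        ds.save_as(p, enforce_file_format=True)
        dose = ct_io.read_dose(str(p), "rtdose")
        np.testing.assert_allclose(dose.voxels, 40.0)
        assert dose.grid.shape == (4, 3, 2)
        assert dose.grid.spacing[2] == 2.5
        assert dose.grid.origin[2] == 10.0


class TestStructures:
    def test_mask_volume_on_reference_grid_returned_untouched(self, rng, tmp_path):
        ref = make_volume(rng, shape=(8, 8, 4), spacing=(1, 1, 2))
        mask = (rng.random((8, 8, 4)) < 0.4).astype(np.float32)
        ct_io.write_nifti(CTVolume(mask, ref.grid),
                          str(tmp_path / "a_mask_lv.nii"))
        out = ct_io.read_structures(str(tmp_path), "mask_volumes", ref)
        np.testing.assert_array_equal(out["lv"].mask, mask > 0.5)

    def test_rtstruct_rectangle_rasterizes_area_times_slices(self, tmp_path):
        # rectangle covering exactly 10 x 10 voxel centers on 3 slices
        ref = CTVolume(np.zeros((20, 20, 5), np.float32),
                       Grid((20, 20, 5), (1.0, 1.0, 2.0)))
        rect = [(1.5, 1.5), (11.5, 1.5), (11.5, 11.5), (1.5, 11.5)]
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        roi = Dataset()
        roi.ROINumber = 1
        roi.ROIName = "heart"
        ds.StructureSetROISequence = [roi]
        rc = Dataset()
        rc.ReferencedROINumber = 1
        contours = []
        for z in (0.0, 2.0, 4.0):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.ContourData = [v for x, y in rect for v in (x, y, z)]
            c.NumberOfContourPoints = 4
            contours.append(c)
        rc.ContourSequence = contours
        ds.ROIContourSequence = [rc]
        p = tmp_path / "rs.dcm"
        ds.save_as(p, enforce_file_format=True)
        out = ct_io.read_structures(str(p), "rtstruct", ref)
        assert out["heart"].voxel_count() == 10 * 10 * 3

    def test_empty_structure_flagged_not_raised(self, rng, tmp_path):
        ref = make_volume(rng, shape=(8, 8, 4), spacing=(1, 1, 1))
        ct_io.write_nifti(CTVolume(np.zeros((8, 8, 4), np.float32), ref.grid),
                          str(tmp_path / "b_mask_la.nii"))
        out = ct_io.read_structures(str(tmp_path), "mask_volumes", ref)
        assert out["la"].is_empty and out["la"].empty_ok


class TestEmbedRoi:
    def test_identity_patch_reproduces_base(self, rng):
        base = make_volume(rng, shape=(10, 10, 6), spacing=(1, 1, 1))
        sub = base.voxels[2:6, 3:7, 1:4]
        patch = CTVolume(sub, Grid(sub.shape, base.grid.spacing))
        out = ct_io.embed_roi(base, patch, (2, 3, 1))
        np.testing.assert_array_equal(out.voxels, base.voxels)

    def test_zero_patch_zeroes_exactly_the_box(self, rng):
        base = make_volume(rng, shape=(10, 10, 6), spacing=(1, 1, 1))
        base.voxels += 2000  # ensure nonzero everywhere
        patch = CTVolume(np.zeros((4, 4, 3), np.float32),
                         Grid((4, 4, 3), base.grid.spacing))
        out = ct_io.embed_roi(base, patch, (2, 3, 1))
        box = (slice(2, 6), slice(3, 7), slice(1, 4))
        assert (out.voxels[box] == 0).all()
        mask = np.ones_like(base.voxels, bool)
        mask[box] = False
        np.testing.assert_array_equal(out.voxels[mask], base.voxels[mask])

    def test_full_cover_patch_replaces_everything(self, rng):
        base = make_volume(rng, shape=(6, 6, 4), spacing=(1, 1, 1))
        patch = CTVolume(np.ones_like(base.voxels), base.grid)
        out = ct_io.embed_roi(base, patch, (0, 0, 0))
        np.testing.assert_array_equal(out.voxels, 1.0)

    def test_overrun_raises(self, rng):
        base = make_volume(rng, shape=(6, 6, 4), spacing=(1, 1, 1))
        patch = CTVolume(np.zeros((4, 4, 2), np.float32),
                         Grid((4, 4, 2), base.grid.spacing))
        with pytest.raises(IndexError):
            ct_io.embed_roi(base, patch, (4, 0, 0))
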
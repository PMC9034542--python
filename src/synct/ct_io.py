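"""Reading and writing CT volumes, structure sets and dose grids.

Formats are normalized onto the package's internal data model
(:class:`~synct.core.CTVolume` and friends, canonical ``(x, y, z)`` axis
order with ``z`` axial).  NIfTI goes through nibabel; DICOM CT series,
RTSTRUCT and RTDOSE go through pydicom.  Geometry always travels with
the voxels — no operation in this module accepts or returns a bare
array.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import nibabel as nib
import pydicom
from scipy import ndimage

from .core import (
    CTVolume,
    DoseGrid,
    GeometryError,
    Grid,
    StructureMask,
)


class FormatError(ValueError):
    """A file lacks tags or structure required to interpret it."""


# --------------------------------------------------------------------- NIfTI
def write_nifti(volume: CTVolume, path: str):
    """Write a volume as NIfTI-1; spacing/origin go into the affine."""
    affine = np.diag(list(volume.grid.spacing) + [1.0])
    affine[:3, 3] = volume.grid.origin
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine)
    nib.save(img, path)


def _read_nifti_raw(path: str):
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(s) for s in affine[:3, 3])
    return data, Grid(data.shape, spacing, origin)


def read_nifti(path: str) -> CTVolume:
    data, grid = _read_nifti_raw(path)
    return CTVolume(data, grid)


# --------------------------------------------------------------------- DICOM
def _read_dicom_series(path: str):
    """Read a directory of CT slices into (voxels, grid) with HU rescale."""
    files = sorted(
        os.path.join(path, f) for f in os.listdir(path)
        if not f.startswith(".") and not f.endswith(".json")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no DICOM image slices found under {path}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))

    first = slices[0]
    if not hasattr(first, "RescaleSlope") or not hasattr(first, "RescaleIntercept"):
        raise FormatError("missing RescaleSlope/RescaleIntercept tags")
    rows, cols = int(first.Rows), int(first.Columns)
    px = [float(v) for v in first.PixelSpacing]  # (row=y, col=x) spacing

    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if dz.min() <= 0 or not np.allclose(dz, dz[0], atol=1e-3):
            raise GeometryError("inconsistent slice positions in series")
        z_spacing = float(dz[0])
    else:
        z_spacing = float(getattr(first, "SliceThickness", 1.0))

    vol = np.empty((cols, rows, len(slices)), dtype=np.float32)
    for k, ds in enumerate(slices):
        if (int(ds.Rows), int(ds.Columns)) != (rows, cols) or \
                [float(v) for v in ds.PixelSpacing] != px:
            raise GeometryError("mixed in-plane geometry in series")
        slope = float(ds.RescaleSlope)
        intercept = float(ds.RescaleIntercept)
        arr = ds.pixel_array.astype(np.float32) * slope + intercept
        vol[:, :, k] = arr.T  # (rows=y, cols=x) -> (x, y)

    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(zs[0]),
    )
    grid = Grid((cols, rows, len(slices)), (px[1], px[0], z_spacing), origin)
    return vol, grid


def read_ct(path: str, format: str = "nifti") -> CTVolume:
    """Read a CT volume in HU (rescale applied, slices sorted along z)."""
    if format == "nifti":
        return read_nifti(path)
    if format == "dicom_series":
        vol, grid = _read_dicom_series(path)
        return CTVolume(vol, grid)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------- structures
def read_structures(path, format, reference: CTVolume,
                    name_map: dict | None = None) -> dict[str, StructureMask]:
    """Read a structure set onto the reference grid.

    ``rtstruct``: planar contours rasterized voxel-center-in-polygon.
    ``mask_volumes``: a directory of per-structure NIfTI masks, resampled
    nearest-neighbour if their grid differs from the reference.
    """
    name_map = name_map or {}
    out = {}
    if format == "rtstruct":
        from .structure_eval import rasterize_polygons

        ds = pydicom.dcmread(path)
        rois = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
        for rc in ds.ROIContourSequence:
            name = rois.get(int(rc.ReferencedROINumber), "unknown")
            name = name_map.get(name, name)
            contours = []
            for c in getattr(rc, "ContourSequence", []):
                pts = np.array(c.ContourData, dtype=float).reshape(-1, 3)
                contours.append(pts)
            if not contours:
                out[name] = StructureMask(
                    name, np.zeros(reference.grid.shape, bool),
                    reference.grid, empty_ok=True)
                continue
            out[name] = rasterize_polygons(contours, reference.grid, name=name)
    elif format == "mask_volumes":
        for f in sorted(os.listdir(path)):
            if "_mask_" not in f or not f.endswith((".nii", ".nii.gz")):
                continue
            name = f.split("_mask_")[-1].split(".nii")[0]
            name = name_map.get(name, name)
            data, grid = _read_nifti_raw(os.path.join(path, f))
            if grid.same_as(reference.grid):
                mask = data > 0.5
            else:
                mask = _resample_mask_nearest(data > 0.5, grid, reference.grid)
            out[name] = StructureMask(name, mask, reference.grid,
                                      empty_ok=not mask.any())
    else:
        raise ValueError(f"unknown structure format {format!r}")
    return out


def _resample_mask_nearest(mask, src_grid: Grid, dst_grid: Grid):
    idx = []
    for a in range(3):
        world = dst_grid.origin[a] + np.arange(dst_grid.shape[a]) * dst_grid.spacing[a]
        idx.append((world - src_grid.origin[a]) / src_grid.spacing[a])
    I, J, K = np.meshgrid(*idx, indexing="ij")
    coords = np.stack([I, J, K])
    out = ndimage.map_coordinates(mask.astype(np.float32), coords, order=0,
                                  mode="constant", cval=0.0)
    return out > 0.5


# ----------------------------------------------------------------------- dose
def read_dose(path: str, format: str = "nifti") -> DoseGrid:
    """Read a dose grid in Gy, applying the dose-grid scaling on read."""
    if format == "nifti":
        data, grid = _read_nifti_raw(path)
        if data.min() < 0:
            raise ValueError("negative dose values on read")
        return DoseGrid(data, grid)
    if format == "rtdose":
        ds = pydicom.dcmread(path)
        if not hasattr(ds, "DoseGridScaling"):
            raise FormatError("RTDOSE missing DoseGridScaling")
        scaling = float(ds.DoseGridScaling)
        arr = ds.pixel_array.astype(np.float64) * scaling  # (frames=z, rows=y, cols=x)
        vol = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32)
        px = [float(v) for v in ds.PixelSpacing]
        offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
        dz = float(np.diff(offsets)[0]) if len(offsets) > 1 else 1.0
        origin = (
            float(ds.ImagePositionPatient[0]),
            float(ds.ImagePositionPatient[1]),
            float(ds.ImagePositionPatient[2]) + float(offsets[0]),
        )
        grid = Grid(vol.shape, (px[1], px[0], dz), origin)
        if vol.min() < 0:
            raise ValueError("negative dose values on read")
        return DoseGrid(vol, grid)
    raise ValueError(f"unknown dose format {format!r}")


def write_dose_nifti(dose: DoseGrid, path: str):
    write_nifti(CTVolume(dose.voxels, dose.grid), path)


# ------------------------------------------------------------------ ROI embed
def embed_roi(base: CTVolume, patch: CTVolume, roi_origin) -> CTVolume:
    """Return a copy of ``base`` with ``patch`` written into the half-open
    box ``[roi_origin, roi_origin + patch.shape)``; voxels outside the box
    are bit-identical to ``base``."""
    roi_origin = tuple(int(v) for v in roi_origin)
    for a in range(3):
        if roi_origin[a] < 0 or roi_origin[a] + patch.voxels.shape[a] > base.voxels.shape[a]:
            raise IndexError(
                f"patch of shape {patch.voxels.shape} at {roi_origin} overruns "
                f"base of shape {base.voxels.shape}")
    out = base.voxels.copy()
    sl = tuple(slice(o, o + s) for o, s in zip(roi_origin, patch.voxels.shape))
    out[sl] = patch.voxels
    return CTVolume(out, base.grid)


def write_dicom_series(volume: CTVolume, out_dir: str, series_description="synct"):
    """Write a volume as a fresh CT DICOM series (new UIDs, geometry from
    the grid, HU stored with slope 1 / intercept -1024)."""
    os.makedirs(out_dir, exist_ok=True)
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    intercept = -1024.0
    stored = np.clip(np.round(volume.voxels - intercept), 0, 65535).astype(np.uint16)

    for k in range(volume.grid.shape[2]):
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.SeriesDescription = series_description
        ds.Modality = "CT"
        ds.Rows = volume.grid.shape[1]
        ds.Columns = volume.grid.shape[0]
        ds.PixelSpacing = [volume.grid.spacing[1], volume.grid.spacing[0]]
        ds.SliceThickness = volume.grid.spacing[2]
        ds.ImagePositionPatient = [
            volume.grid.origin[0], volume.grid.origin[1],
            volume.grid.origin[2] + k * volume.grid.spacing[2]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.InstanceNumber = k + 1
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        ds.save_as(os.path.join(out_dir, f"slice_{k:04d}.dcm"),
                   enforce_file_format=True)
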
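"""Image volumes, tumor masks and tumor-region selection.

Volumes are 3D arrays indexed ``(slice, row, col)``; axis 0 is the scan
direction (axial stack), with ``slice_thickness`` mm between slices and
``pixel_spacing`` mm in-plane.  A tumor ROI is a binary mask on the same
grid.  Region selection implements the single-slice rules used throughout
the analysis: the *central* slice carries the largest tumor cross-section,
the *edge* is the second-to-last slice on which tumor is still visible, and
the *middle* sits halfway between the two.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "SizingError",
    "FormatError",
    "ImageVolume",
    "ROIMask",
    "RegionSelection",
    "REGION_KINDS",
    "slice_areas",
    "locate_region_slices",
    "region_for_kind",
    "load_volume",
    "load_mask",
    "save_nifti",
    "save_dicom_series",
]

REGION_KINDS = ("central", "middle", "edge", "whole")


class ValidationError(ValueError):
    """An argument violates a precondition of the analysis."""


class SizingError(ValidationError):
    """A requested tumor does not fit inside the imaging grid."""


class FormatError(RuntimeError):
    """An on-disk series is internally inconsistent."""


@dataclass
class ImageVolume:
    """A 3D intensity grid with acquisition geometry and scan metadata.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
    pixel_spacing : (float, float)
        In-plane spacing in mm (row, col).
    slice_thickness : float
        Distance between slices in mm.
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float] = (0.117, 0.117)
    slice_thickness: float = 0.5
    scan_id: Optional[str] = None
    animal_id: Optional[str] = None
    class_label: Optional[str] = None
    day_post_implant: Optional[float] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValidationError("volume must be a 3D array with >= 1 slice")
        if self.slice_thickness <= 0 or any(s <= 0 for s in self.pixel_spacing):
            raise ValidationError("spacing values must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1] * self.slice_thickness


@dataclass
class ROIMask:
    """Binary tumor mask co-indexed with an :class:`ImageVolume`."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError("mask must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def volume_mm3(self, volume: "ImageVolume") -> float:
        if self.shape != volume.shape:
            raise ValidationError("mask and volume shapes differ")
        return self.n_voxels * volume.voxel_volume_mm3


@dataclass
class RegionSelection:
    """A resolved tumor region: which slices feed feature extraction."""

    kind: str
    chosen_slice_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValidationError(f"unknown region kind {self.kind!r}")

    @property
    def available(self) -> bool:
        return len(self.chosen_slice_indices) > 0


def slice_areas(mask: ROIMask) -> np.ndarray:
    """Per-slice in-mask voxel counts (tumor cross-section in voxels)."""
    return mask.voxels.reshape(mask.shape[0], -1).sum(axis=1).astype(int)


def _round_away(x: float) -> int:
    # round-half-away-from-zero (python round() is banker's rounding)
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def locate_region_slices(
    mask: ROIMask,
    seed: Optional[int] = None,
    side: str = "auto",
) -> dict[str, RegionSelection]:
    """Resolve the central, middle and edge slices of a tumor mask.

    The central slice is the one with the largest cross-section (first
    occurrence on ties).  The tumor edge is the second-to-last slice on
    which tumor is visible, counted outward from the central slice on one
    side; the middle slice is halfway between central and edge, rounding
    away from the central slice.  Tumors spanning too few slices get
    ``middle`` and/or ``edge`` selections flagged absent (empty index list).

    Parameters
    ----------
    side : {"auto", "random", "low", "high"}
        Which side of the central slice to walk toward the edge.  ``auto``
        (default) picks the side with more visible slices beyond the central
        slice, tie broken toward higher indices — deterministic.  ``random``
        draws the side from ``seed`` whenever both sides have visible
        slices, mimicking a rater picking either side.
    """
    areas = slice_areas(mask)
    visible = np.flatnonzero(areas > 0)
    if visible.size == 0:
        raise ValidationError("mask has no visible tumor slice")
    central = int(np.argmax(areas))

    lo_side = visible[visible < central]
    hi_side = visible[visible > central]
    if side == "low":
        chosen = lo_side
    elif side == "high":
        chosen = hi_side
    elif side == "random":
        rng = np.random.default_rng(seed)
        if lo_side.size and hi_side.size:
            chosen = hi_side if rng.integers(2) else lo_side
        else:
            chosen = hi_side if hi_side.size else lo_side
    elif side == "auto":
        chosen = hi_side if hi_side.size >= lo_side.size else lo_side
    else:
        raise ValidationError(f"unknown side policy {side!r}")

    out = {"central": RegionSelection("central", [central])}
    # walk outward: visible slices on the chosen side ordered away from central
    if chosen.size >= 1:
        ordered = np.sort(chosen)
        if ordered[0] > central:
            outward = list(ordered)
        else:
            outward = list(ordered[::-1])
    else:
        outward = []
    # second-to-last visible slice, central itself never counts as edge
    if len(outward) >= 2:
        edge = int(outward[-2])
    else:
        edge = None
    out["edge"] = RegionSelection("edge", [edge] if edge is not None else [])

    middle = None
    if edge is not None:
        mid = central + _round_away(abs(edge - central) / 2.0) * (1 if edge > central else -1)
        if mid != central and mid != edge and areas[mid] > 0:
            middle = mid
    out["middle"] = RegionSelection("middle", [middle] if middle is not None else [])
    return out


def region_for_kind(
    mask: ROIMask, kind: str, seed: Optional[int] = None, side: str = "auto"
) -> RegionSelection:
    """Resolve a single region by name; ``whole`` means all visible slices."""
    if kind == "whole":
        visible = np.flatnonzero(slice_areas(mask) > 0)
        if visible.size == 0:
            raise ValidationError("mask has no visible tumor slice")
        return RegionSelection("whole", [int(i) for i in visible])
    return locate_region_slices(mask, seed=seed, side=side)[kind]


# ---------------------------------------------------------------------------
# I/O: NIfTI and single-slice DICOM series
# ---------------------------------------------------------------------------

def save_nifti(volume: ImageVolume, path: os.PathLike | str) -> Path:
    """Write a volume (or a mask wrapped as a volume) as NIfTI.

    Axis 0 (slices) maps to the first NIfTI axis with zoom equal to the
    slice thickness; in-plane axes keep the pixel spacing.
    """
    import nibabel as nib

    path = Path(path)
    affine = np.diag(
        [volume.slice_thickness, volume.pixel_spacing[0], volume.pixel_spacing[1], 1.0]
    )
    img = nib.Nifti1Image(np.asarray(volume.voxels), affine)
    nib.save(img, str(path))
    return path


def _load_nifti(path: Path) -> ImageVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(
        voxels=data,
        pixel_spacing=(float(zooms[1]), float(zooms[2])),
        slice_thickness=float(zooms[0]),
    )


def save_dicom_series(volume: ImageVolume, directory: os.PathLike | str) -> Path:
    """Write a volume as one DICOM file per axial slice (secondary capture).

    Intensities are rounded to uint16; position tags encode the slice
    stacking so a reader can restore spatial order from shuffled filenames.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vox = np.asarray(volume.voxels)
    lo = min(0.0, float(vox.min()))
    pixel = np.clip(np.rint(vox - lo), 0, 65535).astype(np.uint16)
    series_uid = generate_uid(entropy_srcs=[str(volume.scan_id), "series"])
    study_uid = generate_uid(entropy_srcs=[str(volume.scan_id), "study"])
    for k in range(pixel.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[str(volume.scan_id), str(k)]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "MR"
        ds.PatientID = str(volume.animal_id or "")
        ds.SeriesDescription = str(volume.scan_id or "")
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = pixel.shape[1:]
        ds.PixelSpacing = [f"{volume.pixel_spacing[0]:.6f}", f"{volume.pixel_spacing[1]:.6f}"]
        ds.SliceThickness = f"{volume.slice_thickness:.6f}"
        ds.ImagePositionPatient = ["0", "0", f"{k * volume.slice_thickness:.6f}"]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleIntercept = f"{lo:.6f}"
        ds.RescaleSlope = "1"
        ds.PixelData = pixel[k].tobytes()
        ds.save_as(directory / f"slice_{k:04d}.dcm", enforce_file_format=True)
    return directory


def _load_dicom_dir(directory: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue
    if not datasets:
        raise FileNotFoundError(f"no readable DICOM slices in {directory}")

    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=zpos)
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    spacings = {tuple(float(x) for x in ds.PixelSpacing) for ds in datasets}
    if len(shapes) > 1 or len(spacings) > 1:
        raise FormatError(f"mixed geometry in DICOM series at {directory}")
    slope = float(getattr(datasets[0], "RescaleSlope", 1.0))
    inter = float(getattr(datasets[0], "RescaleIntercept", 0.0))
    stack = np.stack([ds.pixel_array.astype(np.float64) * slope + inter for ds in datasets])
    spacing = next(iter(spacings))
    thickness = float(getattr(datasets[0], "SliceThickness", 1.0))
    vol = ImageVolume(
        voxels=stack,
        pixel_spacing=(spacing[0], spacing[1]),
        slice_thickness=thickness,
    )
    vol.animal_id = str(getattr(datasets[0], "PatientID", "")) or None
    vol.scan_id = str(getattr(datasets[0], "SeriesDescription", "")) or None
    return vol


def load_volume(path: os.PathLike | str, **metadata) -> ImageVolume:
    """Read a NIfTI file or a directory of single-slice DICOM files.

    Slices come back ordered by spatial position; keyword overrides fill
    metadata fields (scan_id, animal_id, class_label, day_post_implant).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        vol = _load_dicom_dir(path)
    else:
        vol = _load_nifti(path)
    for key, val in metadata.items():
        setattr(vol, key, val)
    return vol


def load_mask(path: os.PathLike | str) -> ROIMask:
    """Read a binary mask stored as NIfTI (nonzero voxels are in-mask)."""
    vol = load_volume(path)
    return ROIMask(vol.voxels > 0)
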
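"""DICOM CT series export and read-back.

One CT Image Storage file is written per axial slice, Explicit VR Little
Endian, with geometry derived from the voxel grid: axial identity
orientation, ImagePositionPatient at the centre of the first transmitted
voxel (DICOM convention), PixelSpacing = (row, column) = (y, x) spacing
and SliceThickness = z spacing.  HU are encoded as unsigned 16-bit stored
pixels with RescaleSlope 1 / RescaleIntercept -1024 (the 12-bit clinical
CT convention, HU in [-1024, 3071]); values are rounded to the nearest
integer on export, so integer-valued HU round-trip bit-exactly.

4D series write each temporal phase as its own series under one study and
frame of reference, tagged with TemporalPositionIndex and
NumberOfTemporalPositions on every slice.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import (
    AmbiguousSeriesError,
    EncodingError,
    SeriesInconsistencyError,
)
from .hu import HU_MAX, HU_MIN
from .voxel_core import GridSpec, VoxelVolume

CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"


@dataclass
class SeriesMeta:
    """Patient demographics, UIDs and encoding for one exported series.

    UID fields left as None are generated at export under ``uid_root``
    (pydicom's root by default).  Temporal fields must be present together
    with 1 <= index <= count.
    """

    patient_name: str = "SYNTHETIC^PHANTOM"
    patient_id: str = "SYN000"
    patient_birthdate: str = "19700101"
    patient_sex: str = "O"
    study_uid: str | None = None
    series_uid: str | None = None
    frame_of_reference_uid: str | None = None
    study_date: str | None = None
    study_time: str | None = None
    temporal_position_index: int | None = None
    number_of_temporal_positions: int | None = None
    rescale_slope: float = 1.0
    rescale_intercept: float = -1024.0
    manufacturer: str = "meshct"
    software_versions: str = "1.0"
    uid_root: str | None = None

    def __post_init__(self):
        t_idx, t_n = self.temporal_position_index, self.number_of_temporal_positions
        if (t_idx is None) != (t_n is None):
            raise SeriesInconsistencyError(
                "temporal index and count must be present together"
            )
        if t_idx is not None and not 1 <= t_idx <= t_n:
            raise SeriesInconsistencyError(
                f"temporal index {t_idx} outside 1..{t_n}"
            )

    def _uid(self) -> str:
        return generate_uid(prefix=self.uid_root) if self.uid_root else generate_uid()

    def resolved(self) -> "SeriesMeta":
        """Fill in any unset UIDs and timestamps."""
        now = _dt.datetime.now()
        return replace(
            self,
            study_uid=self.study_uid or self._uid(),
            series_uid=self.series_uid or self._uid(),
            frame_of_reference_uid=self.frame_of_reference_uid or self._uid(),
            study_date=self.study_date or now.strftime("%Y%m%d"),
            study_time=self.study_time or now.strftime("%H%M%S"),
        )


def _encode_slice(hu_slice: np.ndarray, intercept: float, slope: float) -> np.ndarray:
    stored = np.rint((hu_slice - intercept) / slope)
    if stored.min() < 0 or stored.max() > 65535:
        raise EncodingError(
            f"HU range [{hu_slice.min():.1f}, {hu_slice.max():.1f}] not encodable"
        )
    return stored.astype(np.uint16)


def export_series(vol: VoxelVolume, meta: SeriesMeta, out_dir) -> list:
    """Write one DICOM CT file per axial slice; returns the file paths in
    ascending z (InstanceNumber) order."""
    hu = vol.hu
    if np.rint(hu.min()) < HU_MIN or np.rint(hu.max()) > HU_MAX:
        raise EncodingError(
            f"HU range [{hu.min():.1f}, {hu.max():.1f}] outside "
            f"[{HU_MIN:.0f}, {HU_MAX:.0f}]; clip before export"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = meta.resolved()
    grid = vol.grid
    nx, ny, nz = grid.shape
    spx, spy, spz = grid.spacing
    origin = np.asarray(grid.bbox_min) + 0.5 * np.asarray(grid.spacing)
    paths = []
    for k in range(nz):
        ds = Dataset()
        ds.SOPClassUID = CT_IMAGE_STORAGE
        ds.SOPInstanceUID = meta._uid()
        ds.StudyInstanceUID = meta.study_uid
        ds.SeriesInstanceUID = meta.series_uid
        ds.FrameOfReferenceUID = meta.frame_of_reference_uid
        ds.PositionReferenceIndicator = ""
        ds.Modality = "CT"
        ds.Manufacturer = meta.manufacturer
        ds.SoftwareVersions = meta.software_versions
        ds.ImageType = ["DERIVED", "SECONDARY", "AXIAL"]
        ds.PatientName = meta.patient_name
        ds.PatientID = meta.patient_id
        ds.PatientBirthDate = meta.patient_birthdate
        ds.PatientSex = meta.patient_sex
        ds.PatientPosition = "HFS"
        ds.StudyDate = meta.study_date
        ds.StudyTime = meta.study_time
        ds.SeriesDate = meta.study_date
        ds.SeriesTime = meta.study_time
        ds.StudyID = "1"
        ds.SeriesNumber = meta.temporal_position_index or 1
        ds.AccessionNumber = ""
        ds.ReferringPhysicianName = ""
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            float(origin[0]),
            float(origin[1]),
            float(origin[2] + k * spz),
        ]
        ds.SliceLocation = float(origin[2] + k * spz)
        ds.SliceThickness = float(spz)
        ds.PixelSpacing = [float(spy), float(spx)]
        ds.Rows = ny
        ds.Columns = nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = meta.rescale_slope
        ds.RescaleIntercept = meta.rescale_intercept
        ds.RescaleType = "HU"
        ds.KVP = ""
        if meta.temporal_position_index is not None:
            ds.TemporalPositionIndex = meta.temporal_position_index
            ds.NumberOfTemporalPositions = meta.number_of_temporal_positions
        # pixel array is (Rows, Columns) = (y, x): transpose the (x, y) slice
        ds.PixelData = _encode_slice(
            hu[:, :, k].T, meta.rescale_intercept, meta.rescale_slope
        ).tobytes()
        fm = FileMetaDataset()
        fm.MediaStorageSOPClassUID = CT_IMAGE_STORAGE
        fm.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        fm.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = fm
        path = out_dir / f"CT_{k + 1:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def export_4d_series(phases, meta: SeriesMeta, out_dir) -> list:
    """Write an ordered list of phase volumes as a 4D series.

    Each phase becomes its own series (subdirectory ``phase_XX``) sharing
    the study and frame-of-reference UIDs; every slice of phase p carries
    TemporalPositionIndex p+1 and NumberOfTemporalPositions = len(phases).
    """
    phases = list(phases)
    if not phases:
        raise SeriesInconsistencyError("no phase volumes given")
    g0 = phases[0].grid
    for p, vol in enumerate(phases):
        g = vol.grid
        if (
            g.shape != g0.shape
            or not np.allclose(g.spacing, g0.spacing)
            or not np.allclose(g.bbox_min, g0.bbox_min)
        ):
            raise SeriesInconsistencyError(f"phase {p} grid differs from phase 0")
    out_dir = Path(out_dir)
    base = meta.resolved()
    n = len(phases)
    paths = []
    for p, vol in enumerate(phases):
        phase_meta = replace(
            base,
            series_uid=base._uid() if n > 1 or base.series_uid is None else base.series_uid,
            temporal_position_index=p + 1,
            number_of_temporal_positions=n,
        )
        paths.extend(
            export_series(vol, phase_meta, out_dir / f"phase_{p + 1:02d}")
        )
    return paths


def read_series(source):
    """Read one CT series (one temporal phase) back into a volume.

    ``source`` is a directory or explicit file list; slices are sorted by
    ImagePositionPatient z, so file order does not matter.  Mixed series
    UIDs raise :class:`AmbiguousSeriesError`.
    Returns ``(VoxelVolume, SeriesMeta)``.
    """
    if isinstance(source, (str, Path)):
        files = sorted(p for p in Path(source).iterdir() if p.suffix == ".dcm")
    else:
        files = [Path(p) for p in source]
    if not files:
        raise SeriesInconsistencyError(f"no DICOM files in {source}")
    datasets = [pydicom.dcmread(str(p)) for p in files]
    series_uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(series_uids) != 1:
        raise AmbiguousSeriesError(
            f"directory mixes {len(series_uids)} series: {sorted(series_uids)}"
        )
    for ds in datasets:
        if "ImagePositionPatient" not in ds or "PixelSpacing" not in ds:
            raise SeriesInconsistencyError("missing geometry tags")
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    first = datasets[0]
    ny, nx = int(first.Rows), int(first.Columns)
    spy, spx = (float(v) for v in first.PixelSpacing)
    zs = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
    if len(zs) > 1:
        dz = np.diff(zs)
        if not np.allclose(dz, dz[0], atol=1e-6):
            raise SeriesInconsistencyError("non-uniform slice spacing")
        spz = float(dz[0])
    else:
        spz = float(getattr(first, "SliceThickness", 1.0) or 1.0)
    nz = len(datasets)
    slope = float(first.RescaleSlope)
    intercept = float(first.RescaleIntercept)
    hu = np.empty((nx, ny, nz))
    for k, ds in enumerate(datasets):
        hu[:, :, k] = ds.pixel_array.astype(np.float64).T * slope + intercept
    origin = np.array(
        [float(v) for v in first.ImagePositionPatient], dtype=np.float64
    )
    spacing = (spx, spy, spz)
    bbox_min = origin - 0.5 * np.asarray(spacing)
    grid = GridSpec(
        bbox_min=tuple(bbox_min),
        bbox_max=tuple(bbox_min + np.asarray(spacing) * np.array([nx, ny, nz])),
        spacing=spacing,
        dims=(nx, ny, nz),
    )
    t_idx = getattr(first, "TemporalPositionIndex", None)
    t_n = getattr(first, "NumberOfTemporalPositions", None)
    meta = SeriesMeta(
        patient_name=str(first.PatientName),
        patient_id=str(first.PatientID),
        patient_birthdate=str(first.PatientBirthDate),
        patient_sex=str(first.PatientSex),
        study_uid=str(first.StudyInstanceUID),
        series_uid=str(first.SeriesInstanceUID),
        frame_of_reference_uid=str(first.FrameOfReferenceUID),
        study_date=str(first.StudyDate),
        study_time=str(first.StudyTime),
        temporal_position_index=int(t_idx) if t_idx is not None else None,
        number_of_temporal_positions=int(t_n) if t_n is not None else None,
        rescale_slope=slope,
        rescale_intercept=intercept,
        manufacturer=str(first.Manufacturer),
        software_versions=str(first.SoftwareVersions),
    )
    return VoxelVolume(grid=grid, hu=hu), meta
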
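"""Data model for L3 CT slice stacks and Hounsfield-unit conversion.

A CT scanner stores each axial slice as an integer raster plus an affine
rescale (slope, intercept) mapping stored pixel values to Hounsfield units
(air about -1000 HU, water 0 HU).  The model here keeps per-slice geometry
(pixel spacing, slice thickness, z position) explicit because stacks may mix
slice thicknesses and downstream volume integration must respect them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import dicom_io
from .dicom_io import DicomError


class InvalidMetadataError(ValueError):
    """CT metadata violates the model invariants (e.g. zero rescale slope)."""


@dataclass(frozen=True)
class SliceGeometry:
    """Physical geometry of one axial slice."""

    row_spacing_mm: float
    col_spacing_mm: float
    thickness_mm: float

    def __post_init__(self):
        if min(self.row_spacing_mm, self.col_spacing_mm, self.thickness_mm) <= 0:
            raise InvalidMetadataError("pixel spacing and slice thickness must be > 0")

    @property
    def pixel_area_cm2(self) -> float:
        return self.row_spacing_mm * self.col_spacing_mm / 100.0


@dataclass(frozen=True)
class CTSlice:
    """One stored-pixel axial slice with its rescale and geometry metadata."""

    pixels: np.ndarray
    rescale_slope: float
    rescale_intercept: float
    geometry: SliceGeometry
    z_position: float

    def __post_init__(self):
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise InvalidMetadataError("pixel raster must be 2-D and non-empty")
        if self.rescale_slope == 0:
            raise InvalidMetadataError("rescale slope must be nonzero")


@dataclass(frozen=True)
class HUImage:
    """A slice converted to Hounsfield units, geometry carried along."""

    values: np.ndarray
    geometry: SliceGeometry


@dataclass
class CTSeries:
    """Ordered stack of L3 slices with a designated mid-L3 slice.

    ``mid_index`` defaults to the median slice by z position (lower of the two
    central slices for even counts); clinically the mid-L3 slice is chosen by
    a human grader, so the index is an explicit, overridable input.
    """

    slices: list[CTSlice]
    patient_id: str = "anon"
    mid_index: int | None = None

    def __post_init__(self):
        if not self.slices:
            raise InvalidMetadataError("a series needs at least one slice")
        z = [s.z_position for s in self.slices]
        if any(b <= a for a, b in zip(z, z[1:])):
            raise InvalidMetadataError("slices must be strictly ordered by z position")
        shapes = {s.pixels.shape for s in self.slices}
        if len(shapes) > 1:
            raise InvalidMetadataError(f"inconsistent raster shapes in series: {sorted(shapes)}")
        if self.mid_index is None:
            self.mid_index = (len(self.slices) - 1) // 2
        if not 0 <= self.mid_index < len(self.slices):
            raise InvalidMetadataError(f"mid_index {self.mid_index} out of range")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def mid_slice(self) -> CTSlice:
        return self.slices[self.mid_index]


def to_hounsfield(ct_slice: CTSlice) -> HUImage:
    """Convert stored pixel values to HU: value = pixel * slope + intercept."""
    values = ct_slice.pixels.astype(np.float64) * ct_slice.rescale_slope + ct_slice.rescale_intercept
    return HUImage(values=values, geometry=ct_slice.geometry)


def _slice_from_dicom(ds: dicom_io.DicomFile) -> tuple[CTSlice, str]:
    required = {
        "RescaleSlope": (0x0028, 0x1053),
        "RescaleIntercept": (0x0028, 0x1052),
        "PixelSpacing": (0x0028, 0x0030),
        "SliceThickness": (0x0018, 0x0050),
    }
    missing = [name for name, tag in required.items() if not ds.has(tag)]
    if missing:
        raise DicomError(f"{ds.path}: missing required tag(s) {', '.join(missing)}")
    spacing = ds.get_floats((0x0028, 0x0030))
    if len(spacing) == 1:
        spacing = spacing * 2
    if ds.has((0x0020, 0x0032)):
        z = ds.get_floats((0x0020, 0x0032))[2]
    elif ds.has((0x0020, 0x1041)):
        z = ds.get_float((0x0020, 0x1041))
    elif ds.has((0x0020, 0x0013)):
        z = float(ds.get_int((0x0020, 0x0013)))
    else:
        raise DicomError(f"{ds.path}: no z-ordering attribute (ImagePositionPatient, "
                         "SliceLocation or InstanceNumber)")
    patient_id = ds.get_str((0x0010, 0x0020)) if ds.has((0x0010, 0x0020)) else "anon"
    ct = CTSlice(
        pixels=ds.pixel_array(),
        rescale_slope=ds.get_float((0x0028, 0x1053)),
        rescale_intercept=ds.get_float((0x0028, 0x1052)),
        geometry=SliceGeometry(spacing[0], spacing[1], ds.get_float((0x0018, 0x0050))),
        z_position=z,
    )
    return ct, patient_id


def read_series(path: str | Path, mid_index: int | None = None) -> CTSeries:
    """Read a directory of single-slice DICOM files into an ordered CTSeries.

    Slices are sorted by z position regardless of file enumeration order.
    ``mid_index`` (if given) refers to the sorted order.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    if not files:
        raise DicomError(f"{path}: no DICOM slice files found")
    parsed = []
    patient_ids = set()
    for f in files:
        ct, pid = _slice_from_dicom(dicom_io.read_dicom(f))
        parsed.append(ct)
        patient_ids.add(pid)
    parsed.sort(key=lambda s: s.z_position)
    pid = patient_ids.pop() if len(patient_ids) == 1 else "mixed"
    return CTSeries(slices=parsed, patient_id=pid, mid_index=mid_index)


def write_series(series: CTSeries, out_dir: str | Path) -> list[Path]:
    """Write a CTSeries as one DICOM file per slice; inverse of read_series."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(series.slices):
        p = out_dir / f"slice_{i:03d}.dcm"
        dicom_io.write_ct_slice(
            p,
            s.pixels,
            rescale_slope=s.rescale_slope,
            rescale_intercept=s.rescale_intercept,
            row_spacing_mm=s.geometry.row_spacing_mm,
            col_spacing_mm=s.geometry.col_spacing_mm,
            thickness_mm=s.geometry.thickness_mm,
            z_position=s.z_position,
            instance_number=i + 1,
            patient_id=series.patient_id,
        )
        paths.append(p)
    return paths
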
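"""2D (mid-L3) and 3D (whole-L3) body-composition measurements.

Per compartment (SM, VAT, SAT) the mid-L3 slice yields a surface area (cm^2)
and a mean radiodensity (HU); dividing areas by height squared gives the
height-normalised indices SMI / VFI / SFI (cm^2/m^2).  Over the whole stack,
volume (cm^3) integrates per-slice area times slice thickness, and the 3D
average radiodensity is the unweighted mean of per-slice mean HU values —
deliberately NOT volume-weighted, matching the conventional slice-mean
formula (a thickness-weighted variant is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import CTSeries, SliceGeometry, to_hounsfield
from .segmentation import COMPARTMENTS, TissueMaskSet

MEASUREMENT_COLUMNS = [
    "sm_area_cm2", "sm_hu", "vat_area_cm2", "vat_hu", "sat_area_cm2", "sat_hu",
    "smi_cm2_m2", "vfi_cm2_m2", "sfi_cm2_m2",
    "sm_volume_cm3", "sm_hu_3d", "vat_volume_cm3", "vat_hu_3d",
    "sat_volume_cm3", "sat_hu_3d",
]


@dataclass(frozen=True)
class Composition2D:
    """Mid-L3 measurements: areas, radiodensities and height indices."""

    sm_area_cm2: float
    sm_hu: float | None
    vat_area_cm2: float
    vat_hu: float | None
    sat_area_cm2: float
    sat_hu: float | None
    height_m: float | None = None

    def index(self, compartment: str) -> float | None:
        """Area / height^2 (cm^2/m^2); None when height is missing."""
        if self.height_m is None:
            return None
        area = getattr(self, f"{compartment}_area_cm2")
        return tissue_index(area, self.height_m)

    @property
    def smi_cm2_m2(self) -> float | None:
        return self.index("sm")

    @property
    def vfi_cm2_m2(self) -> float | None:
        return self.index("vat")

    @property
    def sfi_cm2_m2(self) -> float | None:
        return self.index("sat")


@dataclass(frozen=True)
class Composition3D:
    """Whole-L3 measurements: volumes and stack-average radiodensities."""

    sm_volume_cm3: float
    sm_hu_3d: float | None
    vat_volume_cm3: float
    vat_hu_3d: float | None
    sat_volume_cm3: float
    sat_hu_3d: float | None
    n_slices: int
    n_slices_hu: dict[str, int] | None = None  # slices with a defined mean per compartment


def surface_area(mask: np.ndarray, geometry: SliceGeometry) -> float:
    """Compartment area in cm^2: pixel count times pixel spacing product."""
    return float(np.sum(mask)) * geometry.pixel_area_cm2


def radiodensity_2d(mask: np.ndarray, hu_values: np.ndarray) -> float | None:
    """Mean HU under the mask; None (undefined) for an empty mask."""
    if mask.shape != hu_values.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {hu_values.shape}")
    if not mask.any():
        return None
    return float(hu_values[mask].mean())


def tissue_index(area_cm2: float, height_m: float) -> float:
    """Height-normalised index in cm^2/m^2 (SMI / VFI / SFI)."""
    if height_m <= 0:
        raise ValueError(f"height must be > 0 m, got {height_m}")
    return area_cm2 / height_m**2


def volume_3d(masks: list[np.ndarray], geometries: list[SliceGeometry]) -> float:
    """Volume in cm^3: sum over slices of area (cm^2) x thickness (cm)."""
    if len(masks) != len(geometries):
        raise ValueError("one geometry per mask required")
    if not masks:
        raise ValueError("at least one slice required")
    return sum(surface_area(m, g) * g.thickness_mm / 10.0 for m, g in zip(masks, geometries))


def avg_radiodensity_3d(
    slice_means: list[float | None],
    thicknesses_mm: list[float] | None = None,
    weighted: bool = False,
) -> float | None:
    """Stack radiodensity: unweighted mean of per-slice mean HU values.

    Slices with an undefined mean (empty mask) are skipped.  With
    ``weighted=True`` the per-slice means are weighted by slice thickness
    instead (non-default; the unweighted form is the reference definition).
    """
    defined = [(m, i) for i, m in enumerate(slice_means) if m is not None]
    if not defined:
        return None
    if weighted:
        if thicknesses_mm is None:
            raise ValueError("weighted average needs slice thicknesses")
        w = np.array([thicknesses_mm[i] for _, i in defined], dtype=float)
        v = np.array([m for m, _ in defined], dtype=float)
        return float(np.average(v, weights=w))
    return float(np.mean([m for m, _ in defined]))


def measure_patient(
    series: CTSeries,
    mask_sets: list[TissueMaskSet],
    height_m: float | None = None,
    weighted_3d_hu: bool = False,
) -> tuple[Composition2D, Composition3D]:
    """Compute all 15 measurements for one patient.

    2D values come from the series' mid-L3 slice only; 3D values integrate
    every slice in the stack.
    """
    if len(mask_sets) != len(series):
        raise ValueError(f"{len(mask_sets)} mask sets for {len(series)} slices")
    hu_images = [to_hounsfield(s) for s in series.slices]
    mid = series.mid_index

    fields2d: dict[str, float | None] = {"height_m": height_m}
    for c in COMPARTMENTS:
        mask = mask_sets[mid][c]
        fields2d[f"{c}_area_cm2"] = surface_area(mask, series.mid_slice.geometry)
        fields2d[f"{c}_hu"] = radiodensity_2d(mask, hu_images[mid].values)
    comp2d = Composition2D(**fields2d)

    geometries = [s.geometry for s in series.slices]
    thicknesses = [g.thickness_mm for g in geometries]
    fields3d: dict = {"n_slices": len(series), "n_slices_hu": {}}
    for c in COMPARTMENTS:
        masks = [ms[c] for ms in mask_sets]
        means = [radiodensity_2d(m, img.values) for m, img in zip(masks, hu_images)]
        fields3d[f"{c}_volume_cm3"] = volume_3d(masks, geometries)
        fields3d[f"{c}_hu_3d"] = avg_radiodensity_3d(means, thicknesses, weighted=weighted_3d_hu)
        fields3d["n_slices_hu"][c] = sum(m is not None for m in means)
    comp3d = Composition3D(**fields3d)
    return comp2d, comp3d


def measurement_row(
    comp2d: Composition2D, comp3d: Composition3D, patient_id: str = "anon"
) -> dict[str, float | str | None]:
    """Flatten the two records into one report row (stable public columns)."""
    row: dict[str, float | str | None] = {"patient_id": patient_id}
    for c in COMPARTMENTS:
        row[f"{c}_area_cm2"] = getattr(comp2d, f"{c}_area_cm2")
        row[f"{c}_hu"] = getattr(comp2d, f"{c}_hu")
    row["smi_cm2_m2"] = comp2d.smi_cm2_m2
    row["vfi_cm2_m2"] = comp2d.vfi_cm2_m2
    row["sfi_cm2_m2"] = comp2d.sfi_cm2_m2
    for c in COMPARTMENTS:
        row[f"{c}_volume_cm3"] = getattr(comp3d, f"{c}_volume_cm3")
        row[f"{c}_hu_3d"] = getattr(comp3d, f"{c}_hu_3d")
    row["n_slices"] = comp3d.n_slices
    row["height_m"] = comp2d.height_m
    return row
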
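"""HU-threshold tissue segmentation and external mask loading.

The compartments quantified at L3 are skeletal muscle (SM), visceral adipose
tissue (VAT) and subcutaneous adipose tissue (SAT).  Learned segmentation
models are deliberately out of scope here: this module provides (a) a
transparent threshold-plus-geometry stand-in so the downstream metrics are
testable end to end, and (b) loaders so masks produced by any external model
can be dropped in.

The stand-in uses the Alberta-protocol HU windows (SM -29..150, VAT
-150..-50, SAT -190..-30).  VAT and SAT overlap in HU, so they are separated
geometrically: the closed muscle-wall contour is filled and adipose pixels
inside it are visceral, those outside (but within the body) subcutaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .image_model import CTSeries, HUImage

COMPARTMENTS = ("sm", "vat", "sat")


class SegmentationError(ValueError):
    """Non-anatomical input or invalid mask set."""


@dataclass(frozen=True)
class SegmentationConfig:
    """HU windows and spatial parameters for the threshold stand-in."""

    sm_window: tuple[float, float] = (-29.0, 150.0)
    vat_window: tuple[float, float] = (-150.0, -50.0)
    sat_window: tuple[float, float] = (-190.0, -30.0)
    body_threshold: float = -500.0  # HU; anything above is candidate body
    morphology_radius: int = 3      # px; closes gaps in the muscle wall

    def __post_init__(self):
        for name in ("sm_window", "vat_window", "sat_window"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise SegmentationError(f"{name}: low {lo} must be < high {hi}")
        if self.morphology_radius < 0:
            raise SegmentationError("morphology_radius must be >= 0")


@dataclass
class TissueMaskSet:
    """Per-slice binary masks for SM / VAT / SAT, pairwise disjoint."""

    sm: np.ndarray
    vat: np.ndarray
    sat: np.ndarray
    qc_touches_border: bool = False

    def __post_init__(self):
        shapes = {self.sm.shape, self.vat.shape, self.sat.shape}
        if len(shapes) > 1:
            raise SegmentationError(f"mask shapes differ: {sorted(shapes)}")
        for a, b in (("sm", "vat"), ("sm", "sat"), ("vat", "sat")):
            overlap = int(np.sum(getattr(self, a) & getattr(self, b)))
            if overlap:
                raise SegmentationError(f"{a} and {b} masks overlap on {overlap} pixel(s)")

    def __getitem__(self, compartment: str) -> np.ndarray:
        if compartment not in COMPARTMENTS:
            raise KeyError(compartment)
        return getattr(self, compartment)


def _in_window(values: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (values >= window[0]) & (values <= window[1])


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndi.sum_labels(np.ones_like(mask, dtype=np.int64), labels, index=range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def segment_slice(image: HUImage, config: SegmentationConfig | None = None) -> TissueMaskSet:
    """Segment one HU slice into SM / VAT / SAT by thresholds and geometry.

    Raises SegmentationError when no body region exists (e.g. an all-air
    slice).  A QC flag is set when any compartment touches the raster border,
    a proxy for tissue extending beyond the field of view.
    """
    config = config or SegmentationConfig()
    hu = image.values
    body = _largest_component(hu > config.body_threshold)
    if not body.any():
        raise SegmentationError("no body region above the body threshold (non-anatomical input)")
    body = ndi.binary_fill_holes(body)

    sm = _in_window(hu, config.sm_window) & body
    # Close the muscle ring and fill it: inside = visceral territory.
    if config.morphology_radius > 0:
        wall = morphology.closing(sm, morphology.disk(config.morphology_radius))
    else:
        wall = sm
    interior = ndi.binary_fill_holes(wall)
    vat = _in_window(hu, config.vat_window) & interior & ~sm & body
    sat = _in_window(hu, config.sat_window) & body & ~interior & ~sm

    border = np.zeros_like(body)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    qc = bool(((sm | vat | sat) & border).any())
    return TissueMaskSet(sm=sm, vat=vat, sat=sat, qc_touches_border=qc)


def segment_series(images: list[HUImage], config: SegmentationConfig | None = None) -> list[TissueMaskSet]:
    return [segment_slice(img, config) for img in images]


def _read_mask_file(path: Path, shape: tuple[int, int]) -> np.ndarray:
    if path.suffix.lower() in {".nii", ".gz"}:
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
        if data.ndim == 3:  # RGB(A) PNG; any channel
            data = data[..., 0]
    if data.shape != shape:
        raise SegmentationError(f"{path}: mask shape {data.shape} != slice shape {shape}")
    return data > 0


def load_masks(paths_per_slice: list[dict[str, str | Path]], series: CTSeries) -> list[TissueMaskSet]:
    """Load external per-slice masks (PNG 0/255 or NIfTI 0/1) for a series.

    ``paths_per_slice[i]`` maps each compartment name to that slice's mask
    file.  Shape mismatches and compartment overlaps raise SegmentationError.
    """
    if len(paths_per_slice) != len(series):
        raise SegmentationError(
            f"got masks for {len(paths_per_slice)} slices, series has {len(series)}")
    out = []
    for i, (paths, ct) in enumerate(zip(paths_per_slice, series.slices)):
        missing = [c for c in COMPARTMENTS if c not in paths]
        if missing:
            raise SegmentationError(f"slice {i}: missing compartment mask(s) {missing}")
        masks = {c: _read_mask_file(Path(paths[c]), ct.pixels.shape) for c in COMPARTMENTS}
        out.append(TissueMaskSet(**masks))
    return out


def write_masks(mask_sets: list[TissueMaskSet], out_dir: str | Path, fmt: str = "png") -> list[dict[str, Path]]:
    """Write per-slice compartment masks; inverse of load_masks."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, ms in enumerate(mask_sets):
        entry = {}
        for c in COMPARTMENTS:
            p = out_dir / f"slice_{i:03d}_{c}.{fmt}"
            iio.imwrite(p, (ms[c].astype(np.uint8) * 255))
            entry[c] = p
        written.append(entry)
    return written
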
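"""Minimal DICOM reader/writer for uncompressed axial CT slices.

Supports the little-endian transfer syntaxes (explicit VR ``1.2.840.10008.1.2.1``
and implicit VR ``1.2.840.10008.1.2``) with single-frame MONOCHROME2 pixel data,
which covers the slice exports this package consumes and produces.  Sequences,
compressed pixel data and big-endian files are rejected with a clear error.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EXPLICIT_LE = "1.2.840.10008.1.2.1"
IMPLICIT_LE = "1.2.840.10008.1.2"
_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"

# Tags used by the package, (group, element) -> (name, VR)
TAGS = {
    (0x0008, 0x0016): ("SOPClassUID", "UI"),
    (0x0008, 0x0018): ("SOPInstanceUID", "UI"),
    (0x0010, 0x0020): ("PatientID", "LO"),
    (0x0018, 0x0050): ("SliceThickness", "DS"),
    (0x0020, 0x0013): ("InstanceNumber", "IS"),
    (0x0020, 0x0032): ("ImagePositionPatient", "DS"),
    (0x0020, 0x1041): ("SliceLocation", "DS"),
    (0x0028, 0x0002): ("SamplesPerPixel", "US"),
    (0x0028, 0x0004): ("PhotometricInterpretation", "CS"),
    (0x0028, 0x0010): ("Rows", "US"),
    (0x0028, 0x0011): ("Columns", "US"),
    (0x0028, 0x0030): ("PixelSpacing", "DS"),
    (0x0028, 0x0100): ("BitsAllocated", "US"),
    (0x0028, 0x0101): ("BitsStored", "US"),
    (0x0028, 0x0102): ("HighBit", "US"),
    (0x0028, 0x0103): ("PixelRepresentation", "US"),
    (0x0028, 0x1052): ("RescaleIntercept", "DS"),
    (0x0028, 0x1053): ("RescaleSlope", "DS"),
    (0x7FE0, 0x0010): ("PixelData", "OW"),
}
_VR_BY_TAG = {tag: vr for tag, (_, vr) in TAGS.items()}
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}


class DicomError(ValueError):
    """Malformed, unsupported, or incomplete DICOM input."""


@dataclass
class DicomFile:
    """Flat bag of data elements keyed by (group, element)."""

    elements: dict[tuple[int, int], bytes] = field(default_factory=dict)
    transfer_syntax: str = EXPLICIT_LE
    path: str = ""

    def _raw(self, tag: tuple[int, int]) -> bytes:
        try:
            return self.elements[tag]
        except KeyError:
            name = TAGS.get(tag, (f"{tag[0]:04x},{tag[1]:04x}", "?"))[0]
            raise DicomError(f"{self.path or 'dataset'}: missing required tag {name}") from None

    def get_str(self, tag: tuple[int, int]) -> str:
        return self._raw(tag).decode("ascii", "replace").rstrip(" \x00")

    def get_floats(self, tag: tuple[int, int]) -> list[float]:
        text = self.get_str(tag)
        try:
            return [float(v) for v in text.split("\\") if v.strip() != ""]
        except ValueError as exc:
            raise DicomError(f"{self.path}: cannot parse decimal string {text!r}") from exc

    def get_float(self, tag: tuple[int, int]) -> float:
        values = self.get_floats(tag)
        if not values:
            name = TAGS.get(tag, ("?",))[0]
            raise DicomError(f"{self.path}: empty value for {name}")
        return values[0]

    def get_int(self, tag: tuple[int, int]) -> int:
        return int(self.get_str(tag))

    def get_us(self, tag: tuple[int, int]) -> int:
        raw = self._raw(tag)
        return struct.unpack("<H", raw[:2])[0]

    def has(self, tag: tuple[int, int]) -> bool:
        return tag in self.elements

    def pixel_array(self) -> np.ndarray:
        rows = self.get_us((0x0028, 0x0010))
        cols = self.get_us((0x0028, 0x0011))
        bits = self.get_us((0x0028, 0x0100)) if self.has((0x0028, 0x0100)) else 16
        signed = self.get_us((0x0028, 0x0103)) if self.has((0x0028, 0x0103)) else 1
        if bits == 16:
            dtype = np.int16 if signed else np.uint16
        elif bits == 8:
            dtype = np.int8 if signed else np.uint8
        else:
            raise DicomError(f"{self.path}: unsupported BitsAllocated={bits}")
        raw = self._raw((0x7FE0, 0x0010))
        expected = rows * cols * (bits // 8)
        if len(raw) < expected:
            raise DicomError(f"{self.path}: pixel data truncated ({len(raw)} < {expected} bytes)")
        return np.frombuffer(raw[:expected], dtype=np.dtype(dtype).newbyteorder("<")).reshape(rows, cols)


def _parse_elements(buf: bytes, offset: int, explicit: bool, stop_group: int | None, path: str) -> tuple[dict, int]:
    elements: dict[tuple[int, int], bytes] = {}
    n = len(buf)
    while offset + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, offset)
        if stop_group is not None and group != stop_group:
            break
        if explicit:
            vr = buf[offset + 4 : offset + 6].decode("ascii", "replace")
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, offset + 8)
                value_off = offset + 12
            else:
                (length,) = struct.unpack_from("<H", buf, offset + 6)
                value_off = offset + 8
        else:
            vr = _VR_BY_TAG.get((group, elem), "UN")
            (length,) = struct.unpack_from("<I", buf, offset + 4)
            value_off = offset + 8
        if length == 0xFFFFFFFF or vr == "SQ":
            raise DicomError(f"{path}: sequences / undefined-length elements are not supported")
        if value_off + length > n:
            raise DicomError(f"{path}: element ({group:04x},{elem:04x}) overruns file")
        elements[(group, elem)] = buf[value_off : value_off + length]
        offset = value_off + length
    return elements, offset


def read_dicom(path: str | Path) -> DicomFile:
    """Read one single-frame little-endian DICOM file."""
    path = Path(path)
    buf = path.read_bytes()
    if len(buf) > 132 and buf[128:132] == b"DICM":
        meta, offset = _parse_elements(buf, 132, explicit=True, stop_group=0x0002, path=str(path))
        ts = meta.get((0x0002, 0x0010), EXPLICIT_LE.encode()).decode("ascii").rstrip(" \x00")
    else:
        # headerless stream; sniff VR of the first element
        offset = 0
        ts = EXPLICIT_LE if buf[4:6].isalpha() else IMPLICIT_LE
    if ts not in (EXPLICIT_LE, IMPLICIT_LE):
        raise DicomError(f"{path}: unsupported transfer syntax {ts}")
    elements, _ = _parse_elements(buf, offset, explicit=(ts == EXPLICIT_LE), stop_group=None, path=str(path))
    return DicomFile(elements=elements, transfer_syntax=ts, path=str(path))


def _encode_value(vr: str, value) -> bytes:
    if vr == "US":
        seq = value if isinstance(value, (list, tuple)) else [value]
        return b"".join(struct.pack("<H", int(v)) for v in seq)
    if vr in ("DS", "IS"):
        seq = value if isinstance(value, (list, tuple)) else [value]
        if vr == "DS":
            text = "\\".join(f"{float(v):.10g}" for v in seq)
        else:
            text = "\\".join(str(int(v)) for v in seq)
        raw = text.encode("ascii")
        return raw + b" " if len(raw) % 2 else raw
    if vr in ("UI", "LO", "CS"):
        raw = str(value).encode("ascii")
        pad = b"\x00" if vr == "UI" else b" "
        return raw + pad if len(raw) % 2 else raw
    if vr == "OW":
        return bytes(value)
    raise DicomError(f"cannot encode VR {vr}")


def _encode_element(group: int, elem: int, vr: str, raw: bytes) -> bytes:
    head = struct.pack("<HH", group, elem) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(raw)) + raw
    return head + struct.pack("<H", len(raw)) + raw


def write_ct_slice(
    path: str | Path,
    pixels: np.ndarray,
    *,
    rescale_slope: float,
    rescale_intercept: float,
    row_spacing_mm: float,
    col_spacing_mm: float,
    thickness_mm: float,
    z_position: float,
    instance_number: int,
    patient_id: str = "anon",
) -> None:
    """Write a single axial CT slice as explicit-VR little-endian DICOM."""
    pixels = np.ascontiguousarray(pixels, dtype="<i2")
    if pixels.ndim != 2:
        raise DicomError("pixel raster must be 2-D")
    sop_uid = f"2.25.{abs(hash((patient_id, instance_number))) % 10**12}.{instance_number}"
    body: dict[tuple[int, int], tuple[str, object]] = {
        (0x0008, 0x0016): ("UI", _CT_STORAGE),
        (0x0008, 0x0018): ("UI", sop_uid),
        (0x0010, 0x0020): ("LO", patient_id),
        (0x0018, 0x0050): ("DS", thickness_mm),
        (0x0020, 0x0013): ("IS", instance_number),
        (0x0020, 0x0032): ("DS", [0.0, 0.0, z_position]),
        (0x0020, 0x1041): ("DS", z_position),
        (0x0028, 0x0002): ("US", 1),
        (0x0028, 0x0004): ("CS", "MONOCHROME2"),
        (0x0028, 0x0010): ("US", pixels.shape[0]),
        (0x0028, 0x0011): ("US", pixels.shape[1]),
        (0x0028, 0x0030): ("DS", [row_spacing_mm, col_spacing_mm]),
        (0x0028, 0x0100): ("US", 16),
        (0x0028, 0x0101): ("US", 16),
        (0x0028, 0x0102): ("US", 15),
        (0x0028, 0x0103): ("US", 1),
        (0x0028, 0x1052): ("DS", rescale_intercept),
        (0x0028, 0x1053): ("DS", rescale_slope),
        (0x7FE0, 0x0010): ("OW", pixels.tobytes()),
    }
    meta_items = [
        ((0x0002, 0x0002), "UI", _CT_STORAGE),
        ((0x0002, 0x0003), "UI", sop_uid),
        ((0x0002, 0x0010), "UI", EXPLICIT_LE),
    ]
    meta_body = b"".join(
        _encode_element(g, e, vr, _encode_value(vr, v)) for (g, e), vr, v in meta_items
    )
    group_len = _encode_element(0x0002, 0x0000, "UL", struct.pack("<I", len(meta_body)))
    payload = b"".join(
        _encode_element(g, e, vr, _encode_value(vr, v)) for (g, e), (vr, v) in sorted(body.items())
    )
    Path(path).write_bytes(b"\x00" * 128 + b"DICM" + group_len + meta_body + payload)
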